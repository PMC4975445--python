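# Methods

## Model

The package models hydrogen-peroxide dynamics in a well-mixed suspension of
*E. coli*. Each strain *i* carries two intracellular species — superoxide
and H₂O₂ — and all strains exchange H₂O₂ with a single external pool across
their membranes. The processes retained are the kinetically significant
ones for H₂O₂ bookkeeping:

* metabolic superoxide production (zeroth order, `k1`) and SOD dismutation
  (pseudo-first order, `k2_sod = k2·[SOD]`), each dismutation yielding half
  a molecule of H₂O₂;
* direct metabolic H₂O₂ production (`k1_prime`);
* scavenging by Ahp and Cat with Michaelis–Menten kinetics. The two
  enzymes are complementary: Ahp is high-affinity/low-capacity
  (`KM ≈ 1.2 µM`, saturating near micromolar substrate) and Cat is
  low-affinity/high-capacity (`KM ≈ 5.9 mM`);
* passive membrane exchange, first order with `kdiff = P·A/V_in ≈ 70 s⁻¹`;
* external-pool drainage through the total cell volume fraction,
  `kdiff′ = kdiff·nV_in/(V_out − nV_in)`.

Deliberately **not** modelled: hydroxyl-radical chemistry and DNA damage,
the Haber–Weiss reaction, spatial/stochastic effects (the well-mixed ODE
description is valid for H₂O₂ concentrations far below molar, where
intracellular diffusion is much faster than reaction), and any quantitative
survival model — the package computes exposure, not death probabilities.

### Homogeneity and quasi-steady superoxide

Superoxide relaxes with time constant `1/k2_sod ≈ 35 µs`, so on every
timescale of interest its dismutation contributes the constant `k1/2` to
H₂O₂ production (`kprod = k1_prime + k1/2`, a ~25% boost over direct
production). The simulator integrates the superoxide ODE by default —
it costs little and keeps the state interpretable — and offers a
`quasi_steady` mode substituting the lumped production; both agree on
H₂O₂ trajectories to well under 0.5%.

### Linear regimes

With all concentrations far below the enzymes' `KM`, the internal/external
pair is linear with matrix
`[[-(kenz+kdiff), kdiff], [kdiff', -kdiff']]`. The package always computes
the exact quadratic eigenvalues; the literature's small-`kdiff'`
approximations (`λ₁ ≈ −kenz·kdiff′/(kenz+kdiff)`, `λ₂ ≈ −(kenz+kdiff)`)
are exposed as separately named helpers because the approximate forms are
only ~1% accurate in the operating range `kdiff′ ≤ 10⁻² kenz` and should
never silently replace the exact roots.

Regime selection is by *external* concentration: LOW below 10 µM (both
enzymes linear), HIGH above 30 µM (Ahp saturated; its flux becomes the
constant sink `Vmax_Ahp`, so the effective production is
`kprod′ = kprod − Vmax_Ahp`, negative for the wild type, and the effective
scavenging constant is `kenz′ = Vmax_Cat/KM_Cat`). Between 10 and 30 µM
neither premise holds and the analytic module refuses
(`UnsupportedRegimeError`) rather than interpolate; callers fall back to the
simulator. The thresholds are configurable (`RegimeThresholds`) but the
defaults are part of the model.

The HIGH-regime peak formula `kdiff·C_out0/(kdiff + kenz′)` is offered in
two variants: the plain form, and a corrected form that keeps the
saturated-Ahp sink in the quasi-steady balance
(`(kdiff·C_out0 + kprod′)/(kdiff + kenz′)`). For a 1 mM stress these give
0.457 and 0.453 mM; the full simulation peaks at 0.472 mM, the further
difference being the Cat Michaelis correction (internal peak ≈ 8% of
`KM_Cat`). The plain form is the default.

## Parameters

All defaults are the literature constants for exponentially growing
*E. coli* and ship in `data/table1.json` (identical to the dataclass
defaults):

| constant | default | units | meaning |
|---|---|---|---|
| `k1` | 5.7×10⁻⁶ | mol L⁻¹ s⁻¹ | superoxide production |
| `k2` | 1.5×10⁹ | L mol⁻¹ s⁻¹ | SOD rate constant |
| `k2_sod` | 2.8×10⁴ | s⁻¹ | lumped SOD dismutation |
| `k1_prime` | 1.2×10⁻⁵ | mol L⁻¹ s⁻¹ | direct H₂O₂ production |
| `vmax_ahp` | 6.6×10⁻⁴ | mol L⁻¹ s⁻¹ | Ahp capacity (kcat·[Ahp]) |
| `km_ahp` | 1.2×10⁻⁶ | mol L⁻¹ | Ahp Michaelis constant |
| `vmax_cat` | 4.9×10⁻¹ | mol L⁻¹ s⁻¹ | Cat capacity (kcat·[Cat]) |
| `km_cat` | 5.9×10⁻³ | mol L⁻¹ | Cat Michaelis constant |
| `kdiff` | 70 | s⁻¹ | membrane exchange (P·A/V) |
| `vin` | 3.2×10⁻¹⁵ | L | single-cell volume |

Construction cross-checks `kdiff` against `P·A/V_in` (70.5 s⁻¹ from
P = 1.6×10⁻³ cm s⁻¹, A = 1.41×10⁻⁷ cm²) and rejects disagreement beyond 1%.

Strain genotypes scale the capacities: `ahp_factor`/`cat_factor` of 0 model
null mutants; `cat_factor = 7` models the Cat induction measured in Ahp-null
strains. `has_membrane = False` models a cell extract — the enzymes act
directly on the medium, diluted by the cytoplasm volume fraction, and the
"internal" series tracks the medium; `endogenous_production = False` removes
metabolic ROS input (extracts, or thought experiments).

Internally everything is mol L⁻¹, seconds, cells L⁻¹ and litres. The
configuration boundary accepts explicit unit suffixes (`"1 mM"`,
`"1.45e7 /mL"`, `"40 min"`) and converts once; this is deliberate — the
constants span eleven orders of magnitude and unit slips are the dominant
failure mode in this kind of model. The OD calibration used by the scenario
library is OD 0.1 ↔ 1.45×10⁷ cells mL⁻¹. One packaged experiment carries two
published densities for nominally the same optical density; both variants
are exposed as named scenarios (`fig9` at 2×10⁸ mL⁻¹, `fig9_od1` at
1.45×10⁸ mL⁻¹) rather than silently picking one.

## Population dynamics

Density follows either constant mode (appropriate for experiments under
~10 minutes) or the Verhulst closed form with `r = ln2/τ_d`
(default doubling time 20 min, carrying capacity 5×10⁹ cells mL⁻¹). After
each stress event growth is frozen for `lag_duration` (default 40 min),
reflecting the viable-count lag after sub-lethal H₂O₂ exposure; overlapping
lag windows merge. Because the growth law has a closed form it is evaluated
inside the right-hand side rather than integrated, which keeps the ODE
state small and the stiff Jacobian well-behaved.

## Numerics

* **Integrator**: implicit BDF (`scipy.integrate.solve_ivp`), rtol 1e-8,
  atol 1e-15 mol L⁻¹. The system is stiff: superoxide at 35 µs, internal
  H₂O₂ at ~1.4 ms, medium drainage at minutes–hours. Halving the
  tolerances moves reported peaks by <10⁻⁶ relative.
* **Stress events** are instantaneous jumps in the external concentration,
  implemented by stopping and restarting the integrator at the event time
  (a forcing-term implementation would destroy error control across a 1 mM
  discontinuity). For extract strains the jump is applied to their merged
  pool as well.
* **Output grid**: `t = 0` plus 400 log-spaced points from 10⁻⁵ s to
  `t_end`, resolving both the millisecond peak and the slow decay. Peaks
  are refined by a parabola through the three bracketing samples.
* **Steady-state root finding**: bracketed Brent on the production–
  scavenging balance, with the absolute tolerance tightened to 10⁻²⁴
  because the roots are tens of nM — far below `brentq`'s default `xtol`.
* **Negative undershoot**: the integrator may undershoot zero by a few
  `atol`; output series are clipped at zero. Degenerate configurations
  (no scavenging at all, production exceeding total capacity, cells
  overfilling the medium) raise typed errors instead of returning garbage.
* **Quadratic eigenvalue computation** uses Vieta's product for the small
  root to avoid cancellation (`λ_slow = kenz·kdiff′/λ_fast`).

## Multi-strain coupling

Several strains share the external pool; each contributes its own flux
`kdiff·n_i·V_in/(V_out − Σ_j n_j V_in)·(C_i − C_out)`. This is the direct
flux-balance generalization of the single-strain equation and reduces to it
for one strain. It is what makes the shared-medium rescue experiment
representable: a catalase-proficient partner strain detoxifies the medium
that a catalase-null strain is helpless against, cutting the null strain's
cumulative exposure without changing its peak.

## What the packaged scenarios do and do not show

The scenario library reproduces idealized *in silico* experiments: step
additions of H₂O₂ to suspensions with fixed genotype compositions and the
table constants. Real cultures differ in ways the model ignores — OxyR
induction dynamics (enzyme levels here are constant within a run; induction
is modelled only as static factors), medium composition effects on
permeability, cell-size distributions, and any feedback of damage on
physiology. Passing tests therefore validate the mathematics and the
implementation, not the biology beyond what the constants encode.

Two systematic biases of the linearized formulas are worth knowing when
comparing against simulations (the tests pin both):

* At 1.5 µM external stress the internal peak reaches ~16% of `KM_Ahp`,
  so the low-regime linear solution under-predicts internal H₂O₂ by ~12%
  plateau-wide and the peak time by ~21%; at 0.15 µM both agree to a few
  percent. The external pool is insensitive to this (≤2%).
* The membrane-limited half-life approximation `ln2/kdiff′` omits the
  back-diffusion factor `kenz/(kenz+kdiff) ≈ 0.90`; the simulated external
  half-life matches `ln2/|λ₁|` with the exact eigenvalue to ~4%, and the
  approximation only to ~15%.

## Dose metrics

`cmax`/`tmax` are read from the refined trajectory maximum. Half-lives are
first crossings of half the reference value with linear interpolation; the
external pool references its initial value, the internal pool its peak
(the post-peak decline is the physiologically meaningful phase). A series
that never crosses returns a distinct not-reached value (`None`), not an
error. Cumulative dose is the trapezoidal integral of internal H₂O₂ over a
window (exact for piecewise-linear series, with interpolated window
endpoints), reported in mol L⁻¹ s and convertible to µM min. The
decomposition-rate curves solve the quasi-steady internal concentration
from the flux balance at each external level; the Ahp/Cat crossover finder
locates the external concentration where a Cat-only strain overtakes an
Ahp-only strain (~15 µM at basal enzyme levels; the published ~17 µM
depends on the unstated induction state of the mutants, so the finder takes
both genotypes explicitly).

## Problem sizes

All shipped analyses are desk-scale: closed forms are microseconds, steady
states a single bracketed root, and every simulation in the registry and
test suite integrates 3–7 ODE states over at most 2400 model seconds
(about a second of wall time each). The density sweeps use five logarithmic
points across 10⁵–10⁹ cells mL⁻¹, enough to pin the peak's density
invariance (<2% spread) and the cumulative dose's strict decrease.
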