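# peroxidyn

Kinetic modelling of hydrogen-peroxide stress in *Escherichia coli*: how much
H₂O₂ does a cell actually experience when its medium is spiked, and which of
its defences — alkyl hydroperoxide reductase (Ahp), catalase (Cat), or simply
the membrane — carries the load?

The package is a simulator + analysis library for microbiologists and
modellers studying oxidative stress: it integrates the full nonlinear
reaction–diffusion system for one or several strains sharing one medium,
provides the closed-form solutions of its linearized regimes, and reduces
trajectories to the dose metrics (peak and cumulative internal exposure) that
discriminate between modes of H₂O₂-mediated killing.

## The model

Each strain carries an internal H₂O₂ pool and a superoxide pool; all strains
share one external H₂O₂ pool. For a membrane-bound strain at density *n*
(cells L⁻¹) in a medium of volume *V*<sub>out</sub>:

```
d[O₂•⁻]/dt   = k₁ − k₂[SOD][O₂•⁻]

d[H₂O₂]/dt   = k₁′ + ½k₂[SOD][O₂•⁻]
               − Vmax_Ahp·[H₂O₂]/([H₂O₂]+KM_Ahp)
               − Vmax_Cat·[H₂O₂]/([H₂O₂]+KM_Cat)
               − k_diff([H₂O₂] − [H₂O₂]out)

d[H₂O₂]out/dt = k_diff · nV_in/(V_out − nV_in) · ([H₂O₂] − [H₂O₂]out)
```

with `k_diff = P·A/V_in` from the membrane permeability. Superoxide relaxes
in ~35 µs, so its dismutation contributes a constant ½k₁ to production:
`k_prod = k₁′ + k₁/2`. Away from saturation the H₂O₂ pair is a linear 2×2
system whose exact eigenvalues, bi-exponential trajectories, steady states
(`k_prod/k_enz`), plateau (`k_prod/(k_enz+k_diff)`), peak time
(`ln(λ₁/λ₂)/(λ₂−λ₁)`), peak concentration (`k_diff[H₂O₂]out0/(k_diff+k_enz)`)
and half-lives are available in closed form. Two linearizations apply —
below ~10 µM external H₂O₂ (Ahp linear, `k_enz = Vmax_Ahp/KM_Ahp +
Vmax_Cat/KM_Cat ≈ 633 s⁻¹`) and above ~30 µM (Ahp saturated, Cat alone,
`k_enz′ ≈ 83 s⁻¹`); in between only the simulator applies.

Default constants (aerobically growing *E. coli*) ship with the package
(`peroxidyn/data/table1.json`); cell growth follows a Verhulst law with a
~40-minute post-stress lag.

## Worked example

Millimolar shock of a wild-type culture at 1.45×10⁷ cells mL⁻¹ (OD ≈ 0.1):

```
$ peroxidyn simulate --scenario fig10 --out fig10.tsv
wrote fig10.tsv (401 time points, 1 strain(s))
$ peroxidyn metrics --in fig10.tsv
strain     cmax_M      tmax_s   t_half_external_s  t_half_internal_s  cumulative_dose_Ms  cumulative_dose_uM_min
wild type  0.00047207  0.07983  398.842            382.522            0.249826            4163.76
```

Reading: after a 1 mM addition the internal concentration peaks at
0.47 mM — about half the external level, because at millimolar
concentrations Ahp is saturated and only catalase (54%) and the membrane
barrier (46%) stand between the cell and the medium — and it does so within
~80 ms. The medium is then cleared with a ~6.6 min half-life, and the cell
integrates a cumulative exposure of ≈0.25 M·s (≈4.2×10³ µM·min) over the
40-minute window. The same machinery in Python:

```python
import peroxidyn as px

params = px.KineticParameters()          # packaged defaults
print(px.steady_state_nonlinear(params)) # 2.39e-08 M unstressed steady state
traj = px.simulate(px.get_scenario("fig10"))
print(px.peak(traj))                     # (0.000472 M, 0.080 s)
```

The closed-form table for any configuration:

```
$ peroxidyn analytic --scenario fig10
strain     quantity               value        unit
wild type  regime                 high
wild type  steady_state_nonlinear 2.38621e-08  M
wild type  lambda_slow            -0.00176255  1/s
wild type  cmax                   0.000457364  M
wild type  half_life_external     393.261      s
...
```

Scenario names for every packaged experiment (`fig1` … `fig15`,
`ma_eaton_*`, `table2_*`) are listed by `peroxidyn list-scenarios`; custom
runs use a JSON config with explicit units (`"add": "1 mM"`,
`"density": "1.45e7 /mL"`) via `--config`.

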