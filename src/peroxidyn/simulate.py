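"""Stiff numerical integration of the full nonlinear model.

One :class:`Scenario` couples any number of strains through a single
well-mixed medium; exogenous H2O2 additions are instantaneous jumps in the
external concentration, implemented by stopping and restarting the
integrator so its error control survives the discontinuity.  The system is
stiff (superoxide relaxes in ~35 us while medium detoxification takes
minutes), so the BDF method is used throughout.

Cell growth is decoupled from the chemistry: the Verhulst closed form (with
a post-stress lag during which the density is frozen) is evaluated inside
the right-hand side, rather than integrated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, SolverError
from .kinetics import (
    KineticParameters,
    PopulationModel,
    StrainConfig,
    derived_rates,
    rhs_arrays,
    superoxide_steady_state,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "simulate",
    "grow",
    "run_ma_eaton",
    "CELLS_PER_ML_PER_OD",
]

#: OD 0.1 corresponds to ~1.45e7 cells/mL in the calibration used here.
CELLS_PER_ML_PER_OD = 1.45e8


# ---------------------------------------------------------------------------
# Growth law
# ---------------------------------------------------------------------------


def _effective_growth_time(
    t: float, stress_times: Sequence[float], lag: float
) -> float:
    """Time spent growing up to ``t``, excluding post-stress lag windows.

    Each stress event freezes growth for ``lag`` seconds; overlapping
    windows are merged.
    """
    if not stress_times or lag <= 0:
        return t
    frozen = 0.0
    window_end = -math.inf
    for t_event in sorted(stress_times):
        if t_event >= t:
            break
        start = max(t_event, window_end)
        end = min(t_event + lag, t)
        if end > start:
            frozen += end - start
            window_end = max(window_end, t_event + lag)
    return t - frozen


def grow(
    population: PopulationModel,
    n0: float,
    t: float,
    stress_times: Sequence[float] = (),
) -> float:
    """Cell density at time ``t`` (cells/L).

    ``constant`` mode returns ``n0``.  ``logistic`` mode evaluates the
    Verhulst closed form ``n0 e^{rt} / (1 + (n0/nmax)(e^{rt} - 1))`` with
    r = ln2 / tau_d, on the effective growth time that excludes the
    ``lag_duration`` freeze following each stress event.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if population.growth_mode == "constant":
        return n0
    tg = _effective_growth_time(t, stress_times, population.lag_duration)
    r = population.growth_rate
    e = math.exp(r * tg)
    return n0 * e / (1.0 + (n0 / population.n_max) * (e - 1.0))


# ---------------------------------------------------------------------------
# Scenario / trajectory containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Everything needed for one simulation run."""

    params: KineticParameters = KineticParameters()
    #: (genotype, initial density cells/L) per strain
    strains: Tuple[Tuple[StrainConfig, float], ...] = ()
    population: PopulationModel = PopulationModel()
    #: (time s, added external H2O2 mol/L) jumps
    stress_events: Tuple[Tuple[float, float], ...] = ()
    t_end: float = 600.0
    #: number of log-spaced output points, or an explicit time array
    output_grid: Union[int, Tuple[float, ...]] = 400
    #: "ode" integrates superoxide; "quasi_steady" substitutes k1/2
    superoxide_mode: str = "ode"
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be > 0")
        if not self.strains:
            raise ConfigurationError("a scenario needs at least one strain")
        for t_event, amount in self.stress_events:
            if not 0 <= t_event <= self.t_end:
                raise ConfigurationError(
                    f"stress event at t={t_event} s outside [0, {self.t_end}]"
                )
            if amount < 0:
                raise ConfigurationError("stress additions must be >= 0")
        if self.superoxide_mode not in ("ode", "quasi_steady"):
            raise ConfigurationError(
                "superoxide_mode must be 'ode' or 'quasi_steady'"
            )
        total_cells = sum(n for _, n in self.strains)
        if self.population.vout - total_cells * self.params.vin <= 0:
            raise ConfigurationError(
                "total cell volume exceeds the medium volume"
            )

    def times(self) -> np.ndarray:
        """Output grid: t=0 plus log-spaced points down to 1e-5 s."""
        if not isinstance(self.output_grid, int):
            ts = np.asarray(self.output_grid, dtype=float)
            if np.any(np.diff(ts) <= 0):
                raise ConfigurationError("output grid must be strictly increasing")
            return ts
        lo = min(1e-5, self.t_end / 10.0)
        grid = np.geomspace(lo, self.t_end, self.output_grid)
        return np.concatenate(([0.0], grid))

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "params": vars(self.params),
                "strains": [(vars(s), n) for s, n in self.strains],
                "population": vars(self.population),
                "events": list(self.stress_events),
                "t_end": self.t_end,
                "superoxide_mode": self.superoxide_mode,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """Time series of one simulation; per-strain rows, shared external pool."""

    times: np.ndarray
    h2o2_out: np.ndarray
    #: shape (n_strains, n_times)
    h2o2_in: np.ndarray
    superoxide: np.ndarray
    densities: np.ndarray
    strain_labels: Tuple[str, ...]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_t = len(self.times)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("h2o2_out",):
            if len(getattr(self, name)) != n_t:
                raise ValueError(f"{name} length mismatch")
        for name in ("h2o2_in", "superoxide", "densities"):
            arr = getattr(self, name)
            if arr.shape != (len(self.strain_labels), n_t):
                raise ValueError(f"{name} shape mismatch")

    @property
    def n_strains(self) -> int:
        return len(self.strain_labels)

    def strain_index(self, strain: Union[int, str]) -> int:
        if isinstance(strain, int):
            return strain
        return self.strain_labels.index(strain)

    def to_frame(self):
        """Wide pandas DataFrame, one column per series (SI units)."""
        import pandas as pd

        data = {"time_s": self.times, "h2o2_out_M": self.h2o2_out}
        for i, label in enumerate(self.strain_labels):
            data[f"{label}:h2o2_in_M"] = self.h2o2_in[i]
            data[f"{label}:superoxide_M"] = self.superoxide[i]
            data[f"{label}:density_per_L"] = self.densities[i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _pack(h2o2_in, superoxide, h2o2_out):
    return np.concatenate([h2o2_in, superoxide, [h2o2_out]])


def _unpack(y, n_strains):
    return y[:n_strains], y[n_strains : 2 * n_strains], y[2 * n_strains]


def simulate(
    scenario: Scenario,
    rtol: float = 1e-8,
    atol: float = 1e-15,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the full nonlinear model over ``scenario``.

    Returns concentrations clipped to zero on output (the integrator may
    undershoot by a few absolute tolerances).  Raises :class:`SolverError`
    carrying the last valid state if the stiff solver fails.
    """
    strains = [s for s, _ in scenario.strains]
    n0s = np.array([n for _, n in scenario.strains], dtype=float)
    params = scenario.params
    pop = scenario.population
    quasi = scenario.superoxide_mode == "quasi_steady"

    # pre-stress steady state initial condition
    o2_ss = superoxide_steady_state(params)
    h2o2_in0 = np.zeros(len(strains))
    o2_0 = np.zeros(len(strains))
    for i, strain in enumerate(strains):
        if strain.endogenous_production:
            o2_0[i] = o2_ss
            rates = derived_rates(params, strain, pop, n=0.0)
            if rates.kenz > 0:
                h2o2_in0[i] = rates.kprod / rates.kenz
    h2o2_out0 = 0.0

    events = sorted(scenario.stress_events)
    event_times = [t for t, _ in events]

    def density(i: int, t: float) -> float:
        past = [te for te in event_times if te <= t]
        return grow(pop, n0s[i], t, past)

    def odefun(t, y):
        h_in, o2, h_out = _unpack(y, len(strains))
        n_now = np.array([density(i, t) for i in range(len(strains))])
        dc_in, do2, dc_out = rhs_arrays(
            t, h_in, o2, h_out, n_now, params, strains, pop.vout,
            quasi_steady_superoxide=quasi,
        )
        return _pack(dc_in, do2, dc_out)

    t_grid = scenario.times()
    if t_grid[-1] > scenario.t_end:
        raise ConfigurationError("output grid extends beyond t_end")

    # segment boundaries: 0, each event time, t_end
    boundaries = sorted(
        {0.0, scenario.t_end}
        | {t for t in event_times if 0.0 < t < scenario.t_end}
    )

    extract_idx = [i for i, s in enumerate(strains) if not s.has_membrane]

    def apply_stress(y: np.ndarray, amount: float) -> None:
        y[-1] += amount
        for i in extract_idx:  # extract pools are part of the medium
            y[i] += amount

    y = _pack(h2o2_in0, o2_0, h2o2_out0)
    # events at t=0 apply before integration starts
    for t_event, amount in events:
        if t_event == 0.0:
            apply_stress(y, amount)

    out_t: List[float] = []
    out_y: List[np.ndarray] = []
    if t_grid[0] == 0.0:
        out_t.append(0.0)
        out_y.append(y.copy())

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        mask = (t_grid > seg_start) & (t_grid <= seg_end)
        t_eval = t_grid[mask]
        # always integrate the full segment so the state at seg_end is exact
        sol = solve_ivp(
            odefun,
            (seg_start, seg_end),
            y,
            method=method,
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(
                f"stiff integration failed on [{seg_start}, {seg_end}]: "
                f"{sol.message}",
                t=sol.t[-1] if len(sol.t) else seg_start,
                state=sol.y[:, -1] if sol.y.size else y,
            )
        if len(t_eval):
            if sol.t[-1] == seg_end:
                out_t.extend(sol.t)
                out_y.extend(sol.y.T)
                y = sol.y[:, -1].copy()
            else:
                out_t.extend(sol.t)
                out_y.extend(sol.y.T)
                tail = solve_ivp(
                    odefun, (sol.t[-1], seg_end), sol.y[:, -1],
                    method=method, rtol=rtol, atol=atol,
                )
                if not tail.success:
                    raise SolverError(
                        f"stiff integration failed near t={seg_end}: "
                        f"{tail.message}",
                        t=tail.t[-1],
                        state=tail.y[:, -1],
                    )
                y = tail.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()
        # apply stress jumps scheduled exactly at seg_end
        for t_event, amount in events:
            if t_event == seg_end and t_event != 0.0:
                apply_stress(y, amount)

    out_t_arr = np.array(out_t)
    out_y_arr = np.array(out_y).T
    order = np.argsort(out_t_arr, kind="stable")
    out_t_arr = out_t_arr[order]
    out_y_arr = out_y_arr[:, order]
    # drop duplicate time points from segment seams
    keep = np.concatenate(([True], np.diff(out_t_arr) > 0))
    out_t_arr = out_t_arr[keep]
    out_y_arr = out_y_arr[:, keep]

    n_strains = len(strains)
    h_in = np.clip(out_y_arr[:n_strains], 0.0, None)
    o2 = np.clip(out_y_arr[n_strains : 2 * n_strains], 0.0, None)
    h_out = np.clip(out_y_arr[2 * n_strains], 0.0, None)
    dens = np.array(
        [[density(i, t) for t in out_t_arr] for i in range(n_strains)]
    )

    labels = []
    for i, strain in enumerate(strains):
        label = strain.label or f"strain{i}"
        while label in labels:
            label += "'"
        labels.append(label)

    return Trajectory(
        times=out_t_arr,
        h2o2_out=h_out,
        h2o2_in=h_in,
        superoxide=o2,
        densities=dens,
        strain_labels=tuple(labels),
        metadata={
            "scenario": scenario.label or scenario.content_hash(),
            "scenario_hash": scenario.content_hash(),
            "rtol": rtol,
            "atol": atol,
            "method": method,
        },
    )


# ---------------------------------------------------------------------------
# Mixed-population detoxification experiment (Ma & Eaton)
# ---------------------------------------------------------------------------


def run_ma_eaton(
    params: KineticParameters = KineticParameters(),
    dilute: float = 1e2 * 1e3,
    dense: float = 1e7 * 1e3,
    external0: float = 1e-3,
    t_end: float = 1200.0,
    vout: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-15,
) -> Dict[str, Trajectory]:
    """Six-scenario suite: catalase rescue of a shared medium.

    Dilute (1e2 cells/mL) and dense (1e7 cells/mL) populations of a
    Cat-null strain alone, a Cat-positive (wild-type) strain alone, and a
    1:1 mixture, all hit with 1 mM exogenous H2O2 at t=0.  Densities are
    per strain (the mixture holds equal numbers of each genotype).
    """
    cat_plus = StrainConfig(label="Cat(+)")
    cat_minus = StrainConfig.cat_null()
    suite = {}
    for level, n in (("dilute", dilute), ("dense", dense)):
        combos = {
            f"ma_eaton_{level}_cat_minus": ((cat_minus, n),),
            f"ma_eaton_{level}_cat_plus": ((cat_plus, n),),
            f"ma_eaton_{level}_mixed": ((cat_minus, n), (cat_plus, n)),
        }
        for name, strains in combos.items():
            scenario = Scenario(
                params=params,
                strains=strains,
                population=PopulationModel(vout=vout),
                stress_events=((0.0, external0),),
                t_end=t_end,
                label=name,
            )
            suite[name] = simulate(scenario, rtol=rtol, atol=atol)
    return suite
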