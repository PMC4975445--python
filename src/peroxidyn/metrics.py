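"""Dose metrics derived from trajectories and from quasi-steady balances.

Two complementary exposure measures for one oxidative-stress episode:

* the *maximal* internal H2O2 concentration (density-independent — each
  cell faces the same peak regardless of how many neighbours it has), and
* the *cumulative* internal exposure, the time integral of internal H2O2
  (strongly density-dependent — dense or catalase-proficient populations
  detoxify the shared medium and shorten everyone's exposure).

The cumulative dose, not the peak, is the quantity that tracks
H2O2-mediated killing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidParameterError
from .kinetics import (
    KineticParameters,
    StrainConfig,
    effective_production,
)
from .simulate import Trajectory

__all__ = [
    "DoseMetrics",
    "NOT_REACHED",
    "peak",
    "half_life",
    "cumulative_dose",
    "compute_metrics",
    "decomposition_rate_curve",
    "scavenger_crossover",
]

#: Sentinel returned when a series never crosses the half-reference level.
NOT_REACHED = None


@dataclass(frozen=True)
class DoseMetrics:
    """Headline exposure numbers for one strain in one trajectory."""

    #: peak internal H2O2, mol/L
    cmax: float
    #: time of the peak, s
    tmax: float
    #: external half-life from the initial value, s (None if not reached)
    t_half_external: Optional[float]
    #: internal half-life from the peak downward, s (None if not reached)
    t_half_internal: Optional[float]
    #: integral of internal H2O2 over the window, mol/L * s
    cumulative_dose: float

    @property
    def cumulative_dose_uM_min(self) -> float:
        """Cumulative dose in uM * min, for readability."""
        return self.cumulative_dose * 1e6 / 60.0


def _quadratic_refine(ts, ys, idx):
    """Vertex of the parabola through the three samples around ``idx``."""
    if idx == 0 or idx == len(ts) - 1:
        return ts[idx], ys[idx]
    t_local = np.asarray(ts[idx - 1 : idx + 2], dtype=float)
    y_local = np.asarray(ys[idx - 1 : idx + 2], dtype=float)
    # shift for conditioning: times can span ms to hours
    a, b, c = np.polyfit(t_local - t_local[1], y_local, 2)
    if a >= 0:  # not a local maximum; keep the sample
        return ts[idx], ys[idx]
    dt = -b / (2 * a)
    if not (t_local[0] - t_local[1] <= dt <= t_local[2] - t_local[1]):
        return ts[idx], ys[idx]
    return t_local[1] + dt, a * dt**2 + b * dt + c


def peak(trajectory: Trajectory, strain: Union[int, str] = 0) -> Tuple[float, float]:
    """``(cmax, tmax)`` of the internal H2O2 series, quadratically refined.

    For a monotone series the last sample is returned unrefined.
    """
    i = trajectory.strain_index(strain)
    ys = trajectory.h2o2_in[i]
    ts = trajectory.times
    if len(ts) == 0:
        raise InvalidParameterError("empty trajectory")
    idx = int(np.argmax(ys))
    t_peak, c_peak = _quadratic_refine(ts, ys, idx)
    return float(c_peak), float(t_peak)


def half_life(
    trajectory: Trajectory,
    species: str = "external",
    strain: Union[int, str] = 0,
    reference: Optional[str] = None,
) -> Optional[float]:
    """First time the series falls to half its reference value, s.

    ``reference`` is ``"initial"`` (default for the external pool) or
    ``"peak"`` (default for internal: measured from the maximum downward).
    Linear interpolation between samples; returns :data:`NOT_REACHED`
    (``None``) when the series never crosses.
    """
    if species == "external":
        series = trajectory.h2o2_out
        reference = reference or "initial"
    elif species == "internal":
        series = trajectory.h2o2_in[trajectory.strain_index(strain)]
        reference = reference or "peak"
    else:
        raise InvalidParameterError(f"unknown species {species!r}")
    ts = trajectory.times
    if reference == "initial":
        start = 0
        ref = series[0]
    elif reference == "peak":
        start = int(np.argmax(series))
        ref = series[start]
    else:
        raise InvalidParameterError(f"unknown reference {reference!r}")
    if ref <= 0:
        return NOT_REACHED
    target = 0.5 * ref
    below = np.nonzero(series[start:] <= target)[0]
    if len(below) == 0:
        return NOT_REACHED
    j = start + below[0]
    if series[j] == target or j == start:
        return float(ts[j] - ts[start])
    t_lo, t_hi = ts[j - 1], ts[j]
    y_lo, y_hi = series[j - 1], series[j]
    t_cross = t_lo + (y_lo - target) / (y_lo - y_hi) * (t_hi - t_lo)
    return float(t_cross - ts[start])


def cumulative_dose(
    trajectory: Trajectory,
    strain: Union[int, str] = 0,
    t_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Trapezoidal integral of internal H2O2 over the window, mol/L * s."""
    i = trajectory.strain_index(strain)
    ts = trajectory.times
    ys = trajectory.h2o2_in[i]
    if t_window is None:
        t0, t1 = ts[0], ts[-1]
    else:
        t0, t1 = t_window
        if t0 < ts[0] or t1 > ts[-1] or t0 >= t1:
            raise InvalidParameterError(
                f"window [{t0}, {t1}] outside trajectory span "
                f"[{ts[0]}, {ts[-1]}]"
            )
    # interpolated window endpoints so partial windows are exact for
    # piecewise-linear series
    grid = ts[(ts > t0) & (ts < t1)]
    full_t = np.concatenate(([t0], grid, [t1]))
    full_y = np.interp(full_t, ts, ys)
    return float(np.trapezoid(full_y, full_t))


def compute_metrics(
    trajectory: Trajectory,
    strain: Union[int, str] = 0,
    t_window: Optional[Tuple[float, float]] = None,
) -> DoseMetrics:
    """All headline metrics for one strain of a trajectory."""
    cmax, tmax = peak(trajectory, strain)
    return DoseMetrics(
        cmax=cmax,
        tmax=tmax,
        t_half_external=half_life(trajectory, "external"),
        t_half_internal=half_life(trajectory, "internal", strain),
        cumulative_dose=cumulative_dose(trajectory, strain, t_window),
    )


# ---------------------------------------------------------------------------
# Quasi-steady decomposition-rate curves
# ---------------------------------------------------------------------------


def _quasi_steady_internal(
    params: KineticParameters, strain: StrainConfig, c_out: float
) -> float:
    """Internal H2O2 at which membrane influx balances net scavenging.

    Root of ``kdiff (C_out - C) + kprod = Ahp(C) + Cat(C)``.
    """
    kprod = effective_production(params) if strain.endogenous_production else 0.0

    def balance(c: float) -> float:
        scav = (
            strain.ahp_factor * params.vmax_ahp * c / (c + params.km_ahp)
            + strain.cat_factor * params.vmax_cat * c / (c + params.km_cat)
        )
        return params.kdiff * (c_out - c) + kprod - scav

    upper = c_out + kprod / params.kdiff
    if upper == 0.0:
        return 0.0
    if balance(upper) >= 0:  # no scavenging: influx balances at C >= C_out
        return upper
    return brentq(balance, 0.0, upper, rtol=1e-12)


def decomposition_rate_curve(
    params: KineticParameters,
    strain: StrainConfig,
    external_range: np.ndarray,
    n: float,
    vout: float = 1.0,
) -> pd.DataFrame:
    """Medium H2O2 decomposition rate vs external concentration.

    For each external concentration the quasi-steady internal level is
    solved from the flux balance, and the rate at which the whole
    population removes H2O2 from the medium,
    ``kdiff n Vin / (Vout - n Vin) * (C_out - C)``, is reported.

    Returns a DataFrame with columns ``external_M``, ``internal_M``,
    ``rate_M_per_s``.
    """
    external_range = np.asarray(external_range, dtype=float)
    if np.any(external_range <= 0):
        raise InvalidParameterError("external concentrations must be > 0")
    free_volume = vout - n * params.vin
    if free_volume <= 0:
        raise InvalidParameterError("cell volume exceeds the medium")
    prefactor = params.kdiff * n * params.vin / free_volume
    internal = np.array(
        [_quasi_steady_internal(params, strain, c) for c in external_range]
    )
    rate = prefactor * (external_range - internal)
    return pd.DataFrame(
        {
            "external_M": external_range,
            "internal_M": internal,
            "rate_M_per_s": rate,
        }
    )


def scavenger_crossover(
    params: KineticParameters,
    external_range: Tuple[float, float] = (1e-7, 1e-3),
    n: float = 1.5e11,
    vout: float = 1.0,
    ahp_strain: Optional[StrainConfig] = None,
    cat_strain: Optional[StrainConfig] = None,
) -> Optional[float]:
    """External H2O2 level where Cat-only overtakes Ahp-only decomposition.

    Compares a catalase-null strain (Ahp the sole scavenger) with an
    Ahp-null strain (Cat the sole scavenger, ``cat_factor`` configurable to
    model induction).  Returns the crossover concentration in mol/L, or
    ``None`` when the two curves do not intersect in ``external_range``.
    """
    ahp_strain = ahp_strain or StrainConfig.cat_null(label="Ahp only")
    cat_strain = cat_strain or StrainConfig.ahp_null(label="Cat only")

    def rate(strain: StrainConfig, c_out: float) -> float:
        c = _quasi_steady_internal(params, strain, c_out)
        return c_out - c  # common prefactor cancels in the comparison

    def diff(log_c: float) -> float:
        c_out = math.exp(log_c)
        return rate(cat_strain, c_out) - rate(ahp_strain, c_out)

    lo, hi = (math.log(external_range[0]), math.log(external_range[1]))
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo * f_hi > 0:
        return None
    return math.exp(brentq(diff, lo, hi, rtol=1e-12))
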