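"""Closed-form solutions of the linearized two-compartment H2O2 system.

Away from enzyme saturation the internal/external H2O2 pair obeys a linear
2x2 system

    d/dt (C, C_out) = (kprod, 0) + M (C, C_out),
    M = [[-(kenz + kdiff), kdiff], [kdiff', -kdiff']]

whose eigenvalues are the roots of ``x^2 + (kenz + kdiff + kdiff') x +
kenz kdiff'``.  Two linearizations apply, selected by the *external* H2O2
level:

* LOW (< ~10 uM): both enzymes in their linear range; kenz = Ahp/KM +
  Cat/KM, kprod = k1' + k1/2.
* HIGH (> ~30 uM): Ahp saturated; Cat alone stays linear.  kenz' = Cat/KM
  and the constant term becomes kprod' = kprod - Vmax_Ahp (the saturated
  Ahp flux acts as a constant sink).

In between neither approximation holds and this module refuses, directing
callers to the numerical simulator.

All eigenvalues here are the exact quadratic roots; the literature's
small-``kdiff'`` approximations are exposed separately
(:func:`lambda_slow_approx`, :func:`lambda_fast_approx`) for comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import NoSteadyStateError, UnsupportedRegimeError
from .kinetics import (
    DerivedRates,
    KineticParameters,
    PopulationModel,
    StrainConfig,
    derived_rates,
)

__all__ = [
    "Regime",
    "RegimeThresholds",
    "LinearRegimeSolution",
    "classify_regime",
    "solve_linear",
    "steady_state_linear",
    "plateau_concentration",
    "steady_state_nonlinear",
    "tmax_analytic",
    "cmax_analytic",
    "cmax_ratio",
    "half_life_external",
    "induction_speedup",
    "contribution_fractions",
    "lambda_slow_approx",
    "lambda_fast_approx",
]


class Regime(enum.Enum):
    """Which linearization of the scavenging kinetics applies."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class RegimeThresholds:
    """External-H2O2 bounds of the two linear regimes, mol/L."""

    low: float = 10e-6
    high: float = 30e-6

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low threshold must be below high threshold")


def classify_regime(
    external0: float, thresholds: RegimeThresholds = RegimeThresholds()
) -> Regime:
    """LOW below ``thresholds.low``, HIGH above ``thresholds.high``."""
    if external0 < 0:
        raise ValueError("external concentration must be >= 0")
    if external0 < thresholds.low:
        return Regime.LOW
    if external0 > thresholds.high:
        return Regime.HIGH
    return Regime.INTERMEDIATE


def _regime_rates(rates: DerivedRates, regime: Regime):
    """(kprod_eff, kenz_eff) of the requested linearization."""
    if regime is Regime.LOW:
        return rates.kprod, rates.kenz
    if regime is Regime.HIGH:
        return rates.kprod_prime, rates.kenz_prime
    raise UnsupportedRegimeError(
        "no closed form exists between the low and high thresholds; "
        "use the numerical simulator"
    )


def _eigenvalues(kenz_eff: float, kdiff: float, kdiff_prime: float):
    """Exact roots of x^2 + (kenz+kdiff+kdiff') x + kenz kdiff' = 0.

    Returns (lambda_slow, lambda_fast), both negative, |slow| < |fast|.
    """
    s = kenz_eff + kdiff + kdiff_prime
    p = kenz_eff * kdiff_prime
    disc = math.sqrt(s * s - 4.0 * p)
    lam_fast = -(s + disc) / 2.0
    # stable computation of the small root via Vieta's product
    lam_slow = p / lam_fast if lam_fast != 0 else 0.0
    return lam_slow, lam_fast


def lambda_slow_approx(kenz_eff: float, kdiff: float, kdiff_prime: float) -> float:
    """Literature approximation lambda_1 ~ -kenz kdiff' / (kenz + kdiff)."""
    return -kenz_eff * kdiff_prime / (kenz_eff + kdiff)


def lambda_fast_approx(kenz_eff: float, kdiff: float) -> float:
    """Literature approximation lambda_2 ~ -(kenz + kdiff)."""
    return -(kenz_eff + kdiff)


@dataclass(frozen=True)
class LinearRegimeSolution:
    """Bi-exponential solution of one linear regime.

    The trajectories are

        C(t)     = (kdiff' + l1) A e^{l1 t} + (kdiff' + l2) B e^{l2 t} + C_inf
        C_out(t) = kdiff' A e^{l1 t} + kdiff' B e^{l2 t} + C_inf

    with C_inf = kprod_eff / kenz_eff and A, B fixed by the initial
    conditions.
    """

    regime: Regime
    kprod_eff: float
    kenz_eff: float
    kdiff: float
    kdiff_prime: float
    lambda_slow: float
    lambda_fast: float
    coef_slow: float
    coef_fast: float
    init_in: float
    init_out: float

    @property
    def steady_state(self) -> float:
        """Long-time internal concentration kprod_eff / kenz_eff, mol/L."""
        return self.kprod_eff / self.kenz_eff

    def internal(self, t):
        """Internal H2O2 concentration at time(s) ``t`` (s), mol/L."""
        t = np.asarray(t, dtype=float)
        return (
            (self.kdiff_prime + self.lambda_slow)
            * self.coef_slow
            * np.exp(self.lambda_slow * t)
            + (self.kdiff_prime + self.lambda_fast)
            * self.coef_fast
            * np.exp(self.lambda_fast * t)
            + self.steady_state
        )

    def external(self, t):
        """External H2O2 concentration at time(s) ``t`` (s), mol/L."""
        t = np.asarray(t, dtype=float)
        return (
            self.kdiff_prime * self.coef_slow * np.exp(self.lambda_slow * t)
            + self.kdiff_prime * self.coef_fast * np.exp(self.lambda_fast * t)
            + self.steady_state
        )


def solve_linear(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    n: float = 1e10,
    external0: float = 0.0,
    init_in: Optional[float] = None,
    vout: float = 1.0,
    thresholds: RegimeThresholds = RegimeThresholds(),
    regime: Optional[Regime] = None,
) -> LinearRegimeSolution:
    """Eigen-solution of the linearized system for one strain.

    ``n`` is the cell density (cells/L).  ``init_in`` defaults to the
    pre-stress steady state ``kprod/kenz``.  The regime is classified from
    ``external0`` unless given explicitly.
    """
    rates = derived_rates(params, strain, PopulationModel(vout=vout), n)
    if regime is None:
        regime = classify_regime(external0, thresholds)
    kprod_eff, kenz_eff = _regime_rates(rates, regime)
    if kenz_eff <= 0:
        raise NoSteadyStateError(
            "the linearized system needs a positive scavenging constant"
        )
    lam_slow, lam_fast = _eigenvalues(kenz_eff, params.kdiff, rates.kdiff_prime)
    c_inf = kprod_eff / kenz_eff
    if init_in is None:
        # pre-stress steady state of the low regime
        init_in = rates.kprod / rates.kenz if rates.kenz > 0 else 0.0
    kd = rates.kdiff_prime
    a = (
        (init_in - c_inf) * kd - (external0 - c_inf) * (kd + lam_fast)
    ) / ((lam_slow - lam_fast) * kd)
    b = (
        (init_in - c_inf) * kd - (external0 - c_inf) * (kd + lam_slow)
    ) / ((lam_fast - lam_slow) * kd)
    return LinearRegimeSolution(
        regime=regime,
        kprod_eff=kprod_eff,
        kenz_eff=kenz_eff,
        kdiff=params.kdiff,
        kdiff_prime=rates.kdiff_prime,
        lambda_slow=lam_slow,
        lambda_fast=lam_fast,
        coef_slow=a,
        coef_fast=b,
        init_in=init_in,
        init_out=external0,
    )


# ---------------------------------------------------------------------------
# Steady states and plateaus (no exogenous stress)
# ---------------------------------------------------------------------------


def steady_state_linear(
    params: KineticParameters, strain: StrainConfig = StrainConfig()
) -> float:
    """Unstressed steady state kprod / kenz, mol/L (~23.5 nM wild type)."""
    rates = derived_rates(params, strain, n=0.0)
    if rates.kenz <= 0:
        raise NoSteadyStateError("no scavenging: linear steady state undefined")
    return rates.kprod / rates.kenz


def plateau_concentration(
    params: KineticParameters, strain: StrainConfig = StrainConfig()
) -> float:
    """Fast first plateau kprod / (kenz + kdiff), mol/L (~21 nM wild type).

    Reached within milliseconds of growth start, before the much slower
    equilibration of the (initially empty) external pool.
    """
    rates = derived_rates(params, strain, n=0.0)
    return rates.kprod / (rates.kenz + params.kdiff)


def steady_state_nonlinear(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    rtol: float = 1e-12,
) -> float:
    """Unstressed steady state of the full Michaelis-Menten balance.

    Solves ``kprod = VmaxAhp C/(C+KM) + VmaxCat C/(C+KM)`` by bracketed
    root finding.  Raises :class:`NoSteadyStateError` when production
    exceeds the total scavenging capacity.
    """
    rates = derived_rates(params, strain, n=0.0)
    kprod = rates.kprod
    if kprod == 0:
        return 0.0
    vmax_total = (
        strain.ahp_factor * params.vmax_ahp + strain.cat_factor * params.vmax_cat
    )
    if vmax_total <= kprod:
        raise NoSteadyStateError(
            f"production {kprod:.3g} mol/L/s exceeds total scavenging "
            f"capacity {vmax_total:.3g} mol/L/s"
        )

    def balance(c: float) -> float:
        return (
            strain.ahp_factor * params.vmax_ahp * c / (c + params.km_ahp)
            + strain.cat_factor * params.vmax_cat * c / (c + params.km_cat)
            - kprod
        )

    # the linearized value underestimates the root; expand upward for the
    # upper bracket
    lower = 0.0
    upper = max(kprod / rates.kenz if rates.kenz > 0 else params.km_ahp, 1e-12)
    while balance(upper) < 0:
        upper *= 2.0
    # xtol tightened: the root is tens of nM, far below brentq's default
    # absolute tolerance
    return brentq(balance, lower, upper, rtol=rtol, xtol=1e-24)


# ---------------------------------------------------------------------------
# Stress-response quantities
# ---------------------------------------------------------------------------


def tmax_analytic(solution: LinearRegimeSolution) -> float:
    """Time of the internal peak, ln(l1/l2) / (l2 - l1), s."""
    l1, l2 = solution.lambda_slow, solution.lambda_fast
    return math.log(l1 / l2) / (l2 - l1)


def cmax_analytic(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    external0: float = 0.0,
    regime: Optional[Regime] = None,
    thresholds: RegimeThresholds = RegimeThresholds(),
    saturated_ahp_correction: bool = False,
) -> float:
    """Peak internal concentration kdiff C_out0 / (kdiff + kenz_eff), mol/L.

    The peak is density-independent: it balances diffusive influx against
    first-order removal.  In the HIGH regime ``saturated_ahp_correction``
    additionally subtracts the constant saturated-Ahp flux (net
    ``Vmax_Ahp - kprod``) from the quasi-steady balance, which the full
    simulation reflects; the uncorrected textbook form is the default.
    """
    rates = derived_rates(params, strain, n=0.0)
    if regime is None:
        regime = classify_regime(external0, thresholds)
    _, kenz_eff = _regime_rates(rates, regime)
    peak = params.kdiff * external0 / (params.kdiff + kenz_eff)
    if saturated_ahp_correction and regime is Regime.HIGH:
        peak += rates.kprod_prime / (params.kdiff + kenz_eff)
    return peak


def cmax_ratio(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    regime: Regime = Regime.LOW,
) -> float:
    """Peak-to-initial ratio C_max / C_out0 = kdiff / (kdiff + kenz_eff)."""
    return cmax_analytic(params, strain, external0=1.0, regime=regime)


def half_life_external(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    n: float = 1e10,
    regime: Regime = Regime.LOW,
    vout: float = 1.0,
) -> float:
    """External H2O2 half-life, s.

    LOW regime: the medium drains at ~kdiff' (membrane-limited), so
    t_1/2 = ln2 / kdiff'.  HIGH regime: the decay constant is
    |lambda_1'| = kenz' kdiff' / (kenz' + kdiff).
    """
    rates = derived_rates(params, strain, PopulationModel(vout=vout), n)
    if rates.kdiff_prime <= 0:
        raise NoSteadyStateError("half-life undefined at zero cell density")
    if regime is Regime.LOW:
        return math.log(2.0) / rates.kdiff_prime
    if regime is Regime.HIGH:
        if rates.kenz_prime <= 0:
            raise NoSteadyStateError(
                "high-regime half-life undefined without catalase"
            )
        return (
            math.log(2.0)
            * (rates.kenz_prime + params.kdiff)
            / (rates.kenz_prime * rates.kdiff_prime)
        )
    raise UnsupportedRegimeError("half-life has no closed form between regimes")


def induction_speedup(params: KineticParameters, fold: float = 10.0) -> float:
    """Detoxification speed-up from a ``fold`` increase of Cat.

    Ratio of high-regime decay constants with and without induction:
    fold (kenz' + kdiff) / (fold kenz' + kdiff).  Saturates at
    (kenz' + kdiff) / kenz' as fold -> infinity: membrane diffusion, not
    enzyme capacity, ends up rate-limiting.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    kenz_prime = params.vmax_cat / params.km_cat
    return fold * (kenz_prime + params.kdiff) / (fold * kenz_prime + params.kdiff)


def contribution_fractions(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    regime: Regime = Regime.LOW,
) -> Dict[str, float]:
    """Share of each elimination route in the peak-setting balance.

    LOW regime: Ahp, Cat and membrane diffusion each relative to
    (kenz + kdiff) — roughly 78 / 12 / 10 % for the wild type.  HIGH
    regime: Cat and membrane relative to (kenz' + kdiff) — roughly
    55 / 45 %.
    """
    rates = derived_rates(params, strain, n=0.0)
    if regime is Regime.LOW:
        total = rates.kenz + params.kdiff
        return {
            "Ahp": strain.ahp_factor * params.vmax_ahp / params.km_ahp / total,
            "Cat": strain.cat_factor * params.vmax_cat / params.km_cat / total,
            "membrane": params.kdiff / total,
        }
    if regime is Regime.HIGH:
        total = rates.kenz_prime + params.kdiff
        return {
            "Cat": rates.kenz_prime / total,
            "membrane": params.kdiff / total,
        }
    raise UnsupportedRegimeError("contribution split has no closed form here")
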