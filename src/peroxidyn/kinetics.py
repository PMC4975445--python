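"""Kinetic parameters and the exact nonlinear right-hand side of the model.

The model couples, for each bacterial strain sharing one medium:

* internal superoxide, produced by metabolism at rate ``k1`` and dismuted by
  SOD with pseudo-first-order constant ``k2_sod`` (each dismutation yields
  half a molecule of H2O2);
* internal H2O2, produced directly (``k1_prime``) and via SOD, scavenged by
  alkyl hydroperoxide reductase (Ahp, high affinity / low capacity) and
  catalase (Cat, low affinity / high capacity) with Michaelis-Menten
  kinetics, and exchanged across the membrane with first-order constant
  ``kdiff``;
* a shared external H2O2 pool drained/filled by the membrane flux of every
  strain, weighted by the cell volume fraction.

All internal units are SI-molar (mol/L) and seconds; densities are cells/L.
Unit conversion from user-facing notations (uM, cells/mL, minutes) happens
at the configuration boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "KineticParameters",
    "StrainConfig",
    "PopulationModel",
    "SystemState",
    "DerivedRates",
    "membrane_kdiff",
    "effective_production",
    "superoxide_steady_state",
    "superoxide_relaxation_time",
    "derived_rates",
    "rhs",
    "rhs_arrays",
]

#: litres per cubic centimetre, used when deriving kdiff from permeability.
_L_PER_CM3 = 1e-3


def membrane_kdiff(permeability: float, area: float, vin: float) -> float:
    """First-order membrane exchange constant ``P * A / V`` in 1/s.

    Parameters
    ----------
    permeability : membrane permeability coefficient P, cm/s.
    area : membrane surface area A, cm^2.
    vin : single-cell internal volume, L.
    """
    if permeability <= 0 or area <= 0 or vin <= 0:
        raise InvalidParameterError(
            "permeability, area and vin must all be strictly positive"
        )
    return permeability * area * _L_PER_CM3 / vin


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and volumes of the H2O2 model (E. coli defaults).

    Defaults are the literature constants for exponentially growing
    *E. coli*: endogenous superoxide and H2O2 production, SOD dismutation,
    Ahp and Cat scavenging (lumped Vmax = kcat * [enzyme]), and membrane
    exchange derived from the permeability coefficient.
    """

    #: superoxide production rate, mol/L/s
    k1: float = 5.7e-6
    #: second-order SOD rate constant, 1/(mol/L)/s
    k2: float = 1.5e9
    #: lumped SOD dismutation constant k2*[SOD], 1/s
    k2_sod: float = 2.8e4
    #: direct endogenous H2O2 production rate, mol/L/s
    k1_prime: float = 12e-6
    #: lumped Ahp capacity kcat*[Ahp], mol/L/s
    vmax_ahp: float = 6.6e-4
    #: Michaelis constant of Ahp, mol/L
    km_ahp: float = 1.2e-6
    #: lumped Cat capacity kcat*[Cat], mol/L/s
    vmax_cat: float = 4.9e-1
    #: Michaelis constant of Cat, mol/L
    km_cat: float = 5.9e-3
    #: membrane exchange constant, 1/s
    kdiff: float = 70.0
    #: single-cell internal volume, L
    vin: float = 3.2e-15
    #: membrane permeability coefficient, cm/s (optional, documents kdiff)
    permeability: Optional[float] = 1.6e-3
    #: membrane surface area, cm^2 (optional, documents kdiff)
    area: Optional[float] = 1.41e-7

    def __post_init__(self) -> None:
        for name in (
            "k1",
            "k2",
            "k2_sod",
            "k1_prime",
            "vmax_ahp",
            "km_ahp",
            "vmax_cat",
            "km_cat",
            "kdiff",
            "vin",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.permeability is not None and self.area is not None:
            derived = membrane_kdiff(self.permeability, self.area, self.vin)
            if abs(derived - self.kdiff) > 0.01 * derived:
                raise InvalidParameterError(
                    f"kdiff={self.kdiff} disagrees with P*A/V={derived:.4g} "
                    "by more than 1%; drop permeability/area or fix kdiff"
                )

    def with_updates(self, **kwargs) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StrainConfig:
    """Genotype of one strain: scaling of enzyme capacities and flags.

    ``ahp_factor`` / ``cat_factor`` multiply the lumped Vmax terms (0 models
    a null mutant; 7 the Cat induction level measured in Ahp-null strains).
    ``has_membrane=False`` models a cell extract: the internal pool merges
    with the medium. ``endogenous_production=False`` removes metabolic ROS
    production (also used for extracts).
    """

    label: str = "wild type"
    ahp_factor: float = 1.0
    cat_factor: float = 1.0
    has_membrane: bool = True
    endogenous_production: bool = True

    def __post_init__(self) -> None:
        if self.ahp_factor < 0 or self.cat_factor < 0:
            raise InvalidParameterError("strain enzyme factors must be >= 0")

    # Common genotypes.
    @staticmethod
    def wild_type() -> "StrainConfig":
        return StrainConfig(label="wild type")

    @staticmethod
    def ahp_null(cat_factor: float = 1.0, label: str = "Ahp(-)") -> "StrainConfig":
        return StrainConfig(label=label, ahp_factor=0.0, cat_factor=cat_factor)

    @staticmethod
    def cat_null(label: str = "Cat(-)") -> "StrainConfig":
        return StrainConfig(label=label, cat_factor=0.0)

    @staticmethod
    def extract(ahp_factor: float = 1.0, cat_factor: float = 1.0,
                label: str = "cell extract") -> "StrainConfig":
        return StrainConfig(
            label=label,
            ahp_factor=ahp_factor,
            cat_factor=cat_factor,
            has_membrane=False,
            endogenous_production=False,
        )


@dataclass(frozen=True)
class PopulationModel:
    """Cell density and growth law shared by all strains in one medium.

    Densities are stored as cells/L.  In ``logistic`` mode the density
    follows the Verhulst closed form with rate ``r = ln2 / tau_d``; after
    each oxidative-stress event growth is frozen for ``lag_duration``
    seconds (viable-count lag observed after sub-lethal H2O2 exposure).
    """

    #: initial cell density, cells/L (may be overridden per strain)
    n0: Optional[float] = None
    #: total medium volume, L
    vout: float = 1.0
    #: "constant" or "logistic"
    growth_mode: str = "constant"
    #: doubling time, s (logistic mode)
    tau_d: float = 1200.0
    #: carrying capacity, cells/L (logistic mode; 5e9 cells/mL)
    n_max: float = 5e12
    #: growth freeze after each stress event, s (~40 min)
    lag_duration: float = 2400.0

    def __post_init__(self) -> None:
        if self.vout <= 0:
            raise InvalidParameterError("vout must be strictly positive")
        if self.growth_mode not in ("constant", "logistic"):
            raise InvalidParameterError(
                f"growth_mode must be 'constant' or 'logistic', got "
                f"{self.growth_mode!r}"
            )
        if self.growth_mode == "logistic":
            if self.tau_d <= 0 or self.n_max <= 0:
                raise InvalidParameterError("tau_d and n_max must be positive")
            if self.n0 is not None and not (0 < self.n0 <= self.n_max):
                raise InvalidParameterError("logistic mode requires 0 < n0 <= n_max")
        if self.n0 is not None and self.n0 < 0:
            raise InvalidParameterError("n0 must be non-negative")
        if self.lag_duration < 0:
            raise InvalidParameterError("lag_duration must be >= 0")

    @property
    def growth_rate(self) -> float:
        """Malthusian rate r = ln2 / tau_d, 1/s."""
        return np.log(2.0) / self.tau_d


@dataclass
class SystemState:
    """Instantaneous state: per-strain pools plus the shared external pool."""

    #: per-strain internal H2O2, mol/L
    h2o2_in: np.ndarray
    #: per-strain superoxide, mol/L
    superoxide: np.ndarray
    #: shared external H2O2, mol/L
    h2o2_out: float
    #: per-strain cell density, cells/L
    densities: np.ndarray
    #: time, s
    t: float = 0.0

    def validate(self) -> None:
        if (
            np.any(np.asarray(self.h2o2_in) < 0)
            or np.any(np.asarray(self.superoxide) < 0)
            or self.h2o2_out < 0
            or np.any(np.asarray(self.densities) < 0)
        ):
            raise InvalidParameterError("state concentrations must be >= 0")


# ---------------------------------------------------------------------------
# Derived lumped rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DerivedRates:
    """Lumped first-order constants of the linearized regimes.

    kenz:        Ahp/KM + Cat/KM (low regime, both enzymes linear), 1/s
    kenz_prime:  Cat/KM alone (high regime, Ahp saturated), 1/s
    kprod:       k1' + k1/2 (SOD contributes half an H2O2 per superoxide)
    kprod_prime: kprod - Vmax_Ahp (high regime: saturated Ahp flux removed)
    kdiff_prime: kdiff * n*Vin / (Vout - n*Vin), external-pool drainage, 1/s
    """

    kenz: float
    kenz_prime: float
    kprod: float
    kprod_prime: float
    kdiff_prime: float


def effective_production(params: KineticParameters) -> float:
    """Net endogenous H2O2 production k_prod = k1' + k1/2, mol/L/s."""
    return params.k1_prime + 0.5 * params.k1


def superoxide_steady_state(params: KineticParameters) -> float:
    """Steady-state superoxide concentration k1 / (k2*[SOD]), mol/L."""
    return params.k1 / params.k2_sod


def superoxide_relaxation_time(params: KineticParameters) -> float:
    """Superoxide relaxation time 1 / (k2*[SOD]), s (~35 us in E. coli)."""
    return 1.0 / params.k2_sod


def derived_rates(
    params: KineticParameters,
    strain: StrainConfig = StrainConfig(),
    population: Optional[PopulationModel] = None,
    n: Optional[float] = None,
) -> DerivedRates:
    """Lumped rates for one strain at density ``n`` (cells/L).

    ``n`` defaults to ``population.n0``; ``population`` defaults to a 1 L
    medium.  Raises :class:`ConfigurationError` when the cells would not
    fit in the medium (Vout - n*Vin <= 0).
    """
    pop = population or PopulationModel()
    if n is None:
        if pop.n0 is None:
            raise ConfigurationError("cell density n is required")
        n = pop.n0
    if n < 0:
        raise InvalidParameterError("cell density must be >= 0")
    free_volume = pop.vout - n * params.vin
    if free_volume <= 0:
        raise ConfigurationError(
            f"cell volume n*Vin={n * params.vin:.3g} L exceeds the medium "
            f"volume Vout={pop.vout:.3g} L"
        )
    ahp_linear = strain.ahp_factor * params.vmax_ahp / params.km_ahp
    cat_linear = strain.cat_factor * params.vmax_cat / params.km_cat
    kprod = effective_production(params) if strain.endogenous_production else 0.0
    return DerivedRates(
        kenz=ahp_linear + cat_linear,
        kenz_prime=cat_linear,
        kprod=kprod,
        kprod_prime=kprod - strain.ahp_factor * params.vmax_ahp,
        kdiff_prime=params.kdiff * n * params.vin / free_volume,
    )


# ---------------------------------------------------------------------------
# Nonlinear right-hand side
# ---------------------------------------------------------------------------


def _scavenging(params: KineticParameters, strain: StrainConfig, c: float):
    """Michaelis-Menten removal rate of H2O2 at concentration ``c``."""
    ahp = strain.ahp_factor * params.vmax_ahp * c / (c + params.km_ahp)
    cat = strain.cat_factor * params.vmax_cat * c / (c + params.km_cat)
    return ahp + cat


def rhs_arrays(
    t: float,
    h2o2_in: np.ndarray,
    superoxide: np.ndarray,
    h2o2_out: float,
    densities: np.ndarray,
    params: KineticParameters,
    strains: Sequence[StrainConfig],
    vout: float,
    quasi_steady_superoxide: bool = False,
):
    """Time derivatives ``(dh2o2_in, dsuperoxide, dh2o2_out)``.

    For membrane-bound strains the internal balance is

        dC/dt = k1' + (1/2) k2[SOD][O2-] - Ahp(C) - Cat(C) - kdiff (C - Cout)

    and each strain contributes ``kdiff * n_i Vin / (Vout - sum_j n_j Vin)
    * (C_i - Cout)`` to the external balance.  A strain with
    ``has_membrane=False`` models a cell extract: its enzymes act directly
    on the medium (scaled by the volume fraction its cytoplasm contributes)
    and its "internal" series simply tracks the external pool.

    With ``quasi_steady_superoxide`` the SOD source term is replaced by its
    stationary value ``k1/2`` and superoxide is held constant — the
    production lumping used throughout the closed-form analysis.
    """
    n_strains = len(strains)
    dc_in = np.zeros(n_strains)
    do2 = np.zeros(n_strains)
    dc_out = 0.0

    # total cell volume of membrane-bound strains occupying the medium
    cell_volume = sum(
        densities[i] * params.vin for i in range(n_strains) if strains[i].has_membrane
    )
    free_volume = vout - cell_volume
    if free_volume <= 0:
        raise ConfigurationError("total cell volume exceeds the medium volume")

    extract_idx = []
    for i, strain in enumerate(strains):
        if strain.endogenous_production:
            if quasi_steady_superoxide:
                source = params.k1_prime + 0.5 * params.k1
                do2[i] = 0.0
            else:
                source = params.k1_prime + 0.5 * params.k2_sod * superoxide[i]
                do2[i] = params.k1 - params.k2_sod * superoxide[i]
        else:
            source = 0.0
            do2[i] = 0.0 if quasi_steady_superoxide else -params.k2_sod * superoxide[i]

        if strain.has_membrane:
            c = h2o2_in[i]
            dc_in[i] = (
                source - _scavenging(params, strain, c)
                - params.kdiff * (c - h2o2_out)
            )
            dc_out += (
                params.kdiff
                * densities[i] * params.vin / free_volume
                * (c - h2o2_out)
            )
        else:
            # extract: enzymes released into the medium, diluted by the
            # cytoplasm volume fraction; no membrane barrier
            fraction = densities[i] * params.vin / vout
            dc_out += fraction * (source - _scavenging(params, strain, h2o2_out))
            extract_idx.append(i)

    for i in extract_idx:
        dc_in[i] = dc_out  # internal pool is the medium

    return dc_in, do2, dc_out


def rhs(
    state: SystemState,
    params: KineticParameters,
    strains: Sequence[StrainConfig],
    population: PopulationModel,
    quasi_steady_superoxide: bool = False,
) -> SystemState:
    """Derivative of ``state`` as a :class:`SystemState` (densities frozen).

    Density dynamics are handled analytically by the simulator (closed-form
    Verhulst growth), so the density derivative reported here is zero.
    """
    state.validate()
    dc_in, do2, dc_out = rhs_arrays(
        state.t,
        np.asarray(state.h2o2_in, dtype=float),
        np.asarray(state.superoxide, dtype=float),
        float(state.h2o2_out),
        np.asarray(state.densities, dtype=float),
        params,
        strains,
        population.vout,
        quasi_steady_superoxide=quasi_steady_superoxide,
    )
    return SystemState(
        h2o2_in=dc_in,
        superoxide=do2,
        h2o2_out=dc_out,
        densities=np.zeros_like(np.asarray(state.densities, dtype=float)),
        t=state.t,
    )
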