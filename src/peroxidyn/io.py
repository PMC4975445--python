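"""Configuration parsing, unit handling and trajectory round-tripping.

Configuration files are single JSON documents.  Every dimensional value may
be written either as a plain number (interpreted in the internal SI-molar /
seconds / cells-per-litre convention) or as a string with an explicit unit
suffix (``"1 mM"``, ``"1.45e7 /mL"``, ``"40 min"``), which is the
recommended style — the constants of this model span eleven orders of
magnitude and silent scale mistakes are the main failure mode.

Trajectories are written as TSV with unit-bearing column names plus a JSON
metadata sidecar; ``read_trajectory(write_trajectory(t))`` is the identity
to double precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinetics import KineticParameters, PopulationModel, StrainConfig
from .simulate import Scenario, Trajectory

__all__ = [
    "parse_quantity",
    "default_parameters",
    "load_config",
    "scenario_from_dict",
    "write_trajectory",
    "read_trajectory",
]

_UNITS: Dict[str, Dict[str, float]] = {
    "concentration": {
        "M": 1.0, "mol/L": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
        "nM": 1e-9, "pM": 1e-12,
    },
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "min": 60.0,
             "h": 3600.0},
    "density": {"/L": 1.0, "cells/L": 1.0, "/mL": 1e3, "cells/mL": 1e3,
                "/ml": 1e3},
    "volume": {"L": 1.0, "mL": 1e-3, "ml": 1e-3, "uL": 1e-6, "µL": 1e-6},
    "rate": {"/s": 1.0, "1/s": 1.0, "s^-1": 1.0},
    "production": {"M/s": 1.0, "mol/L/s": 1.0, "uM/s": 1e-6, "µM/s": 1e-6},
    "dimensionless": {"": 1.0},
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def parse_quantity(value: Union[str, float, int], dimension: str) -> float:
    """Convert ``value`` to internal SI units for the given dimension.

    Plain numbers pass through unchanged (assumed already SI); strings must
    carry one of the recognised unit suffixes.
    """
    if dimension not in _UNITS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ConfigurationError(f"cannot parse quantity {value!r}")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ConfigurationError(f"cannot parse quantity {value!r}")
    number, unit = m.groups()
    try:
        magnitude = float(number)
    except ValueError as exc:
        raise ConfigurationError(f"bad number in quantity {value!r}") from exc
    table = _UNITS[dimension]
    if unit not in table:
        raise ConfigurationError(
            f"unit {unit!r} not valid for {dimension} "
            f"(expected one of {sorted(table)})"
        )
    return magnitude * table[unit]


# dimension of each configurable kinetic constant
_PARAM_DIMENSIONS = {
    "k1": "production",
    "k2_sod": "rate",
    "k2": "dimensionless",  # second-order constant, SI only
    "k1_prime": "production",
    "vmax_ahp": "production",
    "km_ahp": "concentration",
    "vmax_cat": "production",
    "km_cat": "concentration",
    "kdiff": "rate",
    "vin": "volume",
    "permeability": "dimensionless",  # cm/s, SI only
    "area": "dimensionless",  # cm^2, SI only
}


def _reject_unknown(section: dict, allowed, path: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} at {path!r}"
        )


def _parse_params(section: dict) -> KineticParameters:
    _reject_unknown(section, _PARAM_DIMENSIONS, "params")
    kwargs = {
        key: parse_quantity(value, _PARAM_DIMENSIONS[key])
        for key, value in section.items()
    }
    return KineticParameters(**kwargs)


_STRAIN_KEYS = {
    "label", "ahp_factor", "cat_factor", "has_membrane",
    "endogenous_production", "density",
}


def _parse_strain(section: dict, index: int):
    _reject_unknown(section, _STRAIN_KEYS, f"strains[{index}]")
    density = section.get("density")
    if density is not None:
        density = parse_quantity(density, "density")
    kwargs = {k: v for k, v in section.items() if k != "density"}
    return StrainConfig(**kwargs), density


_POPULATION_DIMENSIONS = {
    "n0": "density",
    "vout": "volume",
    "tau_d": "time",
    "n_max": "density",
    "lag_duration": "time",
}


def _parse_population(section: dict) -> PopulationModel:
    allowed = set(_POPULATION_DIMENSIONS) | {"growth_mode"}
    _reject_unknown(section, allowed, "population")
    kwargs = {}
    for key, value in section.items():
        if key == "growth_mode":
            kwargs[key] = value
        else:
            kwargs[key] = parse_quantity(value, _POPULATION_DIMENSIONS[key])
    return PopulationModel(**kwargs)


_TOP_KEYS = {
    "params", "strains", "population", "stress_events", "t_end",
    "output_grid", "superoxide_mode", "label",
}


def scenario_from_dict(doc: dict) -> Scenario:
    """Validated :class:`Scenario` from a configuration mapping."""
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration must be a JSON object")
    _reject_unknown(doc, _TOP_KEYS, "<top level>")
    params = _parse_params(doc.get("params", {}))
    population = _parse_population(doc.get("population", {}))

    strain_sections = doc.get("strains", [{}])
    if not isinstance(strain_sections, list) or not strain_sections:
        raise ConfigurationError("'strains' must be a non-empty list")
    strains = []
    for i, section in enumerate(strain_sections):
        strain, density = _parse_strain(section, i)
        if density is None:
            density = population.n0
        if density is None:
            raise ConfigurationError(
                f"strains[{i}]: a cell density is required "
                "(strain 'density' or population 'n0')"
            )
        strains.append((strain, density))

    events = []
    for i, event in enumerate(doc.get("stress_events", [])):
        _reject_unknown(event, {"time", "add"}, f"stress_events[{i}]")
        if "add" not in event:
            raise ConfigurationError(f"stress_events[{i}]: 'add' is required")
        events.append(
            (
                parse_quantity(event.get("time", 0.0), "time"),
                parse_quantity(event["add"], "concentration"),
            )
        )

    kwargs = {}
    if "t_end" in doc:
        kwargs["t_end"] = parse_quantity(doc["t_end"], "time")
    if "output_grid" in doc:
        kwargs["output_grid"] = doc["output_grid"]
    if "superoxide_mode" in doc:
        kwargs["superoxide_mode"] = doc["superoxide_mode"]
    if "label" in doc:
        kwargs["label"] = doc["label"]

    try:
        return Scenario(
            params=params,
            strains=tuple(strains),
            population=population,
            stress_events=tuple(events),
            **kwargs,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc


def default_parameters() -> KineticParameters:
    """The packaged reference constant set (identical to the class defaults)."""
    from importlib import resources

    doc = json.loads(
        resources.files("peroxidyn").joinpath("data/table1.json").read_text()
    )
    return _parse_params(doc)


def load_config(path: Union[str, Path]) -> Scenario:
    """Read and validate a JSON scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON: {exc}") from exc
    return scenario_from_dict(doc)


# ---------------------------------------------------------------------------
# Trajectory TSV round trip
# ---------------------------------------------------------------------------


def write_trajectory(
    trajectory: Trajectory, path: Union[str, Path], sidecar: bool = True
) -> None:
    """Write a trajectory as TSV (plus a JSON metadata sidecar)."""
    path = Path(path)
    frame = trajectory.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if sidecar:
        meta_path = path.with_name(path.name + ".meta.json")
        meta_path.write_text(
            json.dumps(
                {
                    "strain_labels": list(trajectory.strain_labels),
                    **trajectory.metadata,
                },
                indent=2,
                default=str,
            )
        )


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read a trajectory TSV written by :func:`write_trajectory`.

    Columns are matched by header name, so their order is irrelevant.
    Ragged or non-numeric rows raise :class:`ConfigurationError` with the
    offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"trajectory file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ConfigurationError(f"{path}: malformed TSV: {exc}") from exc
    if frame.empty:
        raise ConfigurationError(f"{path}: no data rows")
    for column in ("time_s", "h2o2_out_M"):
        if column not in frame.columns:
            raise ConfigurationError(f"{path}: missing column {column!r}")
    if frame.isna().any().any():
        bad = int(frame[frame.isna().any(axis=1)].index[0]) + 2
        raise ConfigurationError(f"{path}: non-numeric or missing value "
                                 f"near line {bad}")

    labels = []
    for column in frame.columns:
        if column.endswith(":h2o2_in_M"):
            labels.append(column[: -len(":h2o2_in_M")])
    if not labels:
        raise ConfigurationError(f"{path}: no per-strain h2o2_in_M columns")
    for label in labels:
        for suffix in (":superoxide_M", ":density_per_L"):
            if f"{label}{suffix}" not in frame.columns:
                raise ConfigurationError(
                    f"{path}: missing column {label + suffix!r}"
                )

    metadata = {}
    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        metadata.pop("strain_labels", None)

    return Trajectory(
        times=frame["time_s"].to_numpy(dtype=float),
        h2o2_out=frame["h2o2_out_M"].to_numpy(dtype=float),
        h2o2_in=np.vstack(
            [frame[f"{label}:h2o2_in_M"].to_numpy(dtype=float) for label in labels]
        ),
        superoxide=np.vstack(
            [frame[f"{label}:superoxide_M"].to_numpy(dtype=float)
             for label in labels]
        ),
        densities=np.vstack(
            [frame[f"{label}:density_per_L"].to_numpy(dtype=float)
             for label in labels]
        ),
        strain_labels=tuple(labels),
        metadata=metadata,
    )
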