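"""Tabular I/O: packaged reference tables and TSV read/write helpers.

All tabular artifacts are tab-separated with a header row, '.' decimal
separator, scientific notation allowed.  The packaged data directory
ships the published parameter table (initial and optimized columns with
sensitivities and enzyme assignments), the per-activity dN/dS table, the
steady-state concentration targets, and the reference steady-state
concentrations used by the tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .model import PARAM_NAMES, SPECIES, ParameterSet, PathwayState

__all__ = [
    "load_reference_table",
    "load_parameters",
    "load_initial_parameters",
    "load_optimized_parameters",
    "load_reference_sensitivities",
    "load_dnds_table",
    "load_observation_table",
    "load_reference_steady_state",
    "read_parameter_tsv",
    "write_parameter_tsv",
    "write_state_tsv",
    "read_state_tsv",
]

_DATA = resources.files("pyrflux") / "data"


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_table() -> pd.DataFrame:
    """The full packaged parameter table (one row per model parameter).

    Columns: parameter, description, initial_value, optimized_value,
    sensitivity, activity ('-' for parameters outside any enzymatic
    activity), prior_class ('measured' or 'reference'), unit.
    """
    df = _read_packaged("kinetic_parameters.tsv")
    if list(df["parameter"]) != list(PARAM_NAMES):
        raise RuntimeError("packaged parameter table is out of order")
    return df


def load_parameters(column: str = "optimized_value") -> ParameterSet:
    df = load_reference_table()
    return ParameterSet(df[column].to_numpy(dtype=float))


def load_initial_parameters() -> ParameterSet:
    """The experimentally referenced (pre-calibration) parameter values."""
    return load_parameters("initial_value")


def load_optimized_parameters() -> ParameterSet:
    """The published best-fit parameter values."""
    return load_parameters("optimized_value")


def load_reference_sensitivities() -> pd.Series:
    """Published normalized steady-state UMP sensitivities, by parameter."""
    df = load_reference_table()
    return df.set_index("parameter")["sensitivity"].astype(float)


def load_dnds_table() -> pd.DataFrame:
    """Per-activity dN/dS (1-ratio estimates), columns: activity, omega."""
    return _read_packaged("dnds.tsv")


def load_observation_table() -> pd.DataFrame:
    """Steady-state concentration targets (μM) with their common scale."""
    return _read_packaged("observations.tsv")


def load_reference_steady_state() -> pd.DataFrame:
    """Published model and experimental steady-state concentrations (mM)."""
    return _read_packaged("steady_state_reference.tsv")


def read_parameter_tsv(path: str | Path) -> ParameterSet:
    """Read a parameter TSV (columns: name, value[, unit]) into a ParameterSet."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    name_col = "name" if "name" in df.columns else "parameter"
    return ParameterSet.from_dict(dict(zip(df[name_col], df["value"].astype(float))))


def write_parameter_tsv(params: ParameterSet, path: str | Path) -> None:
    units = dict(zip(load_reference_table()["parameter"], load_reference_table()["unit"]))
    df = pd.DataFrame({
        "name": PARAM_NAMES,
        "value": params.as_array(),
        "unit": [units[n] for n in PARAM_NAMES],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_state_tsv(state: PathwayState, path: str | Path) -> None:
    pd.DataFrame({
        "metabolite": SPECIES,
        "concentration_mM": state.as_array(),
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_state_tsv(path: str | Path) -> PathwayState:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return PathwayState.from_dict(
        dict(zip(df["metabolite"], df["concentration_mM"].astype(float))))
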