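"""Normalized steady-state UMP sensitivities and per-enzyme influence.

For each parameter p the sensitivity is the normalized first derivative of
the steady-state UMP concentration,

    s = d[ump]/dp * p/[ump],

evaluated by central finite differences with a step of 1 % of the
parameter value (both perturbed steady states are warm-started from the
unperturbed solution).  Per-enzyme influence is the geometric mean of the
absolute sensitivities of the parameters belonging to that enzymatic
activity; member signs differ within an activity, so the absolute value
is the only well-defined aggregation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import (
    ACTIVITY_MAP,
    PARAM_NAMES,
    ParameterSet,
    ReactionNetwork,
    SteadyStateResult,
    build_network,
    steady_state,
)

__all__ = [
    "normalized_sensitivity",
    "sensitivity_table",
    "enzyme_influence",
]

#: Floor applied to |s| = 0 before taking logs in the geometric mean.
ZERO_SENSITIVITY_FLOOR = 1e-12


def normalized_sensitivity(
    params: ParameterSet,
    pname: str,
    network: ReactionNetwork | None = None,
    h: float = 0.01,
    base: SteadyStateResult | None = None,
) -> float:
    """Central-difference normalized sensitivity of steady-state UMP.

    ``h`` is the relative step (default 1 % of the parameter value; must
    be in (0, 0.05]).  ``base`` may carry a precomputed unperturbed steady
    state to reuse as warm start and normalization point.
    """
    if not 0 < h <= 0.05:
        raise ValueError("step fraction h must be in (0, 0.05]")
    network = network or build_network()
    if base is None:
        base = steady_state(params, network)
    p = params[pname]
    up = steady_state(params.with_value(pname, p * (1 + h)), network, x0=base.state)
    dn = steady_state(params.with_value(pname, p * (1 - h)), network, x0=base.state)
    # ([ump](p+hp) - [ump](p-hp)) / (2hp) * p / [ump](p)
    return (up["ump"] - dn["ump"]) / (2 * h * base["ump"])


def sensitivity_table(
    params: ParameterSet,
    network: ReactionNetwork | None = None,
    h: float = 0.01,
) -> pd.DataFrame:
    """Normalized UMP sensitivities for all 28 parameters.

    Returns a DataFrame with columns parameter, sensitivity, activity
    ('-' for parameters outside any enzymatic activity), and the step
    fraction used.  Per-parameter steady-state failures are recorded as
    NaN with a warning rather than silently dropped.
    """
    network = network or build_network()
    base = steady_state(params, network)
    param_to_activity = {p: a for a, ps in ACTIVITY_MAP.items() for p in ps}
    sens = []
    for name in PARAM_NAMES:
        try:
            sens.append(normalized_sensitivity(params, name, network, h, base))
        except Exception as exc:  # steady-state failure at a perturbed point
            warnings.warn(f"sensitivity for {name} failed: {exc}", RuntimeWarning)
            sens.append(np.nan)
    return pd.DataFrame({
        "parameter": PARAM_NAMES,
        "sensitivity": sens,
        "activity": [param_to_activity.get(n, "-") for n in PARAM_NAMES],
        "h": h,
    })


def enzyme_influence(
    table: pd.DataFrame,
    mapping: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Geometric-mean absolute sensitivity per enzymatic activity.

    Returns a DataFrame (activity, parameters, influence) sorted by
    influence descending.  An exactly-zero member sensitivity is floored
    at ``ZERO_SENSITIVITY_FLOOR`` with a warning.
    """
    mapping = mapping or ACTIVITY_MAP
    s = table.set_index("parameter")["sensitivity"]
    rows = []
    for activity, members in mapping.items():
        missing = [m for m in members if m not in s.index]
        if missing:
            raise KeyError(f"activity {activity}: parameters missing from table: {missing}")
        vals = np.abs(s.loc[list(members)].to_numpy(dtype=float))
        if np.any(np.isnan(vals)):
            raise ValueError(f"activity {activity}: NaN member sensitivity")
        if np.any(vals == 0):
            warnings.warn(
                f"activity {activity}: zero sensitivity floored at {ZERO_SENSITIVITY_FLOOR}",
                RuntimeWarning)
            vals = np.maximum(vals, ZERO_SENSITIVITY_FLOOR)
        rows.append({
            "activity": activity,
            "parameters": ",".join(members),
            "influence": float(np.exp(np.mean(np.log(vals)))),
        })
    return (pd.DataFrame(rows)
            .sort_values("influence", ascending=False)
            .reset_index(drop=True))
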