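"""Rank correlation between enzyme influence and selective constraint.

Couples the per-activity influence scores from the kinetic model with
per-activity dN/dS estimates (1-ratio codon-model values; URA2 is split
into its CPSase and ATCase activities, URA5 represents the URA5/URA10
isozyme pair and URA7 the URA7/URA8 pair).  Spearman correlation uses
average ranks for ties; two-sided p-values come from exact permutation
enumeration for small n (<= 10) and from the t-approximation otherwise.
Partial correlation (controlling for expression level and solvent
accessibility) is the correlation of rank residuals after regressing the
rank vectors on the covariate ranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .model import ACTIVITY_MAP

__all__ = [
    "CORE_ACTIVITIES",
    "DEFAULT_OMEGA",
    "EvolutionaryRates",
    "CorrelationResult",
    "spearman",
    "partial_spearman",
    "link_analysis",
]

#: Activities of the core linear pathway (URA2 contributes both of its
#: catalytic activities); excludes the UMP->CTP feedback arm.
CORE_ACTIVITIES: tuple[str, ...] = ("CPSase", "ATCase", "URA4", "URA1", "URA5", "URA3")

#: Default per-activity dN/dS (1-ratio estimates).
DEFAULT_OMEGA: dict[str, float] = {
    "CPSase": 0.01, "ATCase": 0.02, "URA1": 0.05, "URA3": 0.04,
    "URA4": 0.14, "URA5": 0.14, "URA6": 0.11, "URA7": 0.05, "YNK1": 0.05,
}

#: Exact permutation enumeration is used up to this sample size.
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class EvolutionaryRates:
    """Per-activity dN/dS with optional covariates.

    ``omega`` maps activity name to dN/dS (>= 0).  ``covariates`` is an
    optional DataFrame indexed by activity (e.g. columns ``expression``
    in molecules/cell and ``solvent_accessibility`` as a fraction).
    """

    omega: dict[str, float]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omega.values()):
            raise ValueError("dN/dS must be non-negative")
        if self.covariates is not None:
            missing = set(self.omega) - set(self.covariates.index)
            if missing:
                raise ValueError(f"covariates missing for activities: {sorted(missing)}")

    @classmethod
    def default(cls) -> "EvolutionaryRates":
        return cls(dict(DEFAULT_OMEGA))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvolutionaryRates":
        omega = dict(zip(df["activity"], df["omega"].astype(float)))
        cov_cols = [c for c in df.columns if c not in ("activity", "omega")]
        cov = df.set_index("activity")[cov_cols] if cov_cols else None
        return cls(omega, cov)


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman (or partial Spearman) correlation with its p-value."""

    rho: float
    p_value: float
    n: int
    method: str                 # 'plain' | 'partial'
    p_method: str               # 'exact' | 't'
    covariates: tuple[str, ...] = ()
    subset: str = ""

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(a @ b) / denom


@lru_cache(maxsize=32)
def _null_abs_rho(xr: tuple, yr_sorted: tuple) -> np.ndarray:
    """|rho| over all permutations of the y rank vector, sorted ascending.

    The null set depends only on the two (tied) rank multisets, so it is
    cached: repeated tests on same-shaped data reuse one enumeration.
    """
    x = np.asarray(xr, float)
    xc = x - x.mean()
    nx = math.sqrt(float(xc @ xc))
    y = np.asarray(yr_sorted, float)
    yc_norm = math.sqrt(float(((y - y.mean()) ** 2).sum()))
    perms = np.array(list(itertools.permutations(y)))
    rhos = (perms - y.mean()) @ xc / (nx * yc_norm)
    return np.sort(np.abs(rhos))


def spearman(x, y, p_method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    ``p_method``: ``"exact"`` enumerates all n! permutations of one rank
    vector (feasible and default for n <= 10), ``"t"`` uses the
    t-approximation with n-2 degrees of freedom, ``"auto"`` picks exact
    for small n.  Two-sided throughout.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    xr, yr = _rank(x), _rank(y)
    rho = _pearson(xr, yr)

    if p_method == "auto":
        p_method = "exact" if n <= EXACT_PERMUTATION_MAX_N else "t"
    if p_method == "exact":
        null = _null_abs_rho(tuple(xr), tuple(np.sort(yr)))
        n_extreme = len(null) - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        p = n_extreme / len(null)
    elif p_method == "t":
        if abs(rho) >= 1.0:
            p = 2.0 * stats.t.sf(np.inf, n - 2) + np.finfo(float).tiny
            p = min(max(p, np.finfo(float).tiny), 1.0)
        else:
            tstat = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(tstat), n - 2))
            p = min(max(p, np.finfo(float).tiny), 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(rho, p, n, "plain", p_method)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of v after least-squares regression on [1, Z]."""
    design = np.column_stack([np.ones(len(v)), Z])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_spearman(x, y, covariates) -> CorrelationResult:
    """Partial Spearman correlation controlling for covariates.

    Rank-transforms x, y, and each covariate column, regresses both rank
    vectors on the covariate ranks, and correlates the residuals; the
    two-sided p-value uses the t-distribution with n - 2 - k degrees of
    freedom (k covariates).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y, covariates must have equal length")
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    Zr = np.column_stack([_rank(Z[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Zr])) < k + 1:
        raise ValueError("collinear covariates")
    rx = _residualize(_rank(x), Zr)
    ry = _residualize(_rank(y), Zr)
    if float(rx @ rx) < 1e-12 * n or float(ry @ ry) < 1e-12 * n:
        raise ValueError("degenerate control: residual variance is zero")
    rho = _pearson(rx, ry)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = np.finfo(float).tiny
    else:
        tstat = rho * math.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(tstat), df))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    return CorrelationResult(rho, p, n, "partial", "t")


def link_analysis(
    influence: pd.DataFrame,
    rates: EvolutionaryRates | None = None,
    subset: str = "all",
    covariates: list[str] | None = None,
) -> CorrelationResult:
    """Correlate per-activity influence with dN/dS over a pathway subset.

    ``influence`` is the (activity, influence) table from
    :func:`pyrflux.sensitivity.enzyme_influence`; ``subset`` is ``"all"``
    (the nine activities with kinetic parameters) or ``"core"`` (the six
    core-pathway activities).  If ``covariates`` names columns of
    ``rates.covariates``, a partial Spearman correlation is returned.
    """
    rates = rates or EvolutionaryRates.default()
    if subset == "all":
        activities = tuple(ACTIVITY_MAP)
    elif subset == "core":
        activities = CORE_ACTIVITIES
    else:
        raise ValueError(f"unknown subset {subset!r}")

    infl = influence.set_index("activity")["influence"]
    for a in activities:
        if a not in infl.index:
            raise KeyError(f"missing influence for activity {a!r}")
        if a not in rates.omega:
            raise KeyError(f"missing dN/dS for activity {a!r}")
    x = infl.loc[list(activities)].to_numpy(dtype=float)
    y = np.array([rates.omega[a] for a in activities])

    if covariates:
        if rates.covariates is None:
            raise ValueError("covariates requested but none supplied")
        Z = rates.covariates.loc[list(activities), list(covariates)].to_numpy(dtype=float)
        result = partial_spearman(x, y, Z)
        return CorrelationResult(result.rho, result.p_value, result.n,
                                 "partial", result.p_method,
                                 tuple(covariates), subset)
    result = spearman(x, y)
    return CorrelationResult(result.rho, result.p_value, result.n,
                             "plain", result.p_method, (), subset)
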