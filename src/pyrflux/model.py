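"""Kinetic model of de novo pyrimidine biosynthesis in *S. cerevisiae*.

The pathway is modeled as nine dynamic metabolites — carbamoyl phosphate
(cp), N-carbamoyl-aspartate (ca), dihydroorotate (dho), orotate (oro),
orotidylate (omp), and the nucleotides ump, udp, utp, ctp — connected by
ten enzymatic/utilization reactions, each with Michaelis–Menten kinetics.
Four substrate pools (bicarbonate, glutamine, aspartate, ATP) are clamped
at fixed concentrations.  Every dynamic species is additionally diluted at
the cell growth rate ``d`` (default 0.11/hr, matching chemostat growth).

The first reaction (CPSase, the N-terminal activity of the bifunctional
URA2 enzyme) is allosterically inhibited by UTP through a noncompetitive
factor ``K_utp / (K_utp + utp)``; a configuration flag extends the same
factor to the ATCase reaction.  Pyrimidine consumption for RNA synthesis
is a saturable drain ``g_pyr * s / (K_Mp + s)`` on UTP and CTP.

Concentrations are in mM, rates in mM/hr, time in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "PARAM_NAMES",
    "SPECIES",
    "FIXED_SPECIES",
    "ACTIVITY_MAP",
    "ParameterSet",
    "PathwayState",
    "NetworkConfig",
    "Reaction",
    "ReactionNetwork",
    "SteadyStateResult",
    "SteadyStateError",
    "build_network",
    "reaction_rates",
    "time_derivatives",
    "steady_state",
]

#: Canonical parameter order (the order of the published parameter table).
PARAM_NAMES: tuple[str, ...] = (
    "vmax1", "K_utp", "K_atp", "K_q", "K_bc",
    "vmax2", "K_asp", "K_m2",
    "vmax3", "K_m3",
    "vmax4", "K_m4",
    "vmax5", "K_m5",
    "vmax6", "K_m6",
    "vmax7", "K_m7",
    "vmax8", "K_m8",
    "vmax10", "K_m10",
    "g_pyr", "K_Mp",
    "bc", "glu", "asp", "atp",
)

#: Dynamic metabolites, in pathway order.
SPECIES: tuple[str, ...] = ("cp", "ca", "dho", "oro", "omp", "ump", "udp", "utp", "ctp")

#: Clamped substrate pools (their concentrations are parameters).
FIXED_SPECIES: tuple[str, ...] = ("bc", "glu", "asp", "atp")

#: Map from enzymatic activity to its kinetic parameters.  URA2 is split
#: into its two catalytic activities (CPSase and ATCase); the utilization
#: parameters (g_pyr, K_Mp) and the clamped pools belong to no activity.
ACTIVITY_MAP: dict[str, tuple[str, ...]] = {
    "CPSase": ("vmax1", "K_utp", "K_atp", "K_q", "K_bc"),
    "ATCase": ("vmax2", "K_asp", "K_m2"),
    "URA4": ("vmax3", "K_m3"),
    "URA1": ("vmax4", "K_m4"),
    "URA5": ("vmax5", "K_m5"),
    "URA3": ("vmax6", "K_m6"),
    "YNK1": ("vmax7", "K_m7"),
    "URA7": ("vmax8", "K_m8"),
    "URA6": ("vmax10", "K_m10"),
}

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}
_SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class ParameterSet:
    """The 28 model parameters as an immutable named vector.

    vmax parameters and ``g_pyr`` are in mM/hr; Michaelis/binding constants
    and the clamped substrate concentrations are in mM.  All values must be
    strictly positive.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} parameters, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("all parameters must be finite and strictly positive")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(mapping)
        extra = set(mapping) - set(PARAM_NAMES)
        if missing or extra:
            raise ValueError(f"bad parameter names: missing={sorted(missing)}, extra={sorted(extra)}")
        return cls(np.array([mapping[n] for n in PARAM_NAMES], dtype=float))

    def as_array(self) -> np.ndarray:
        return self.values

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[_PARAM_INDEX[name]])

    def with_value(self, name: str, value: float) -> "ParameterSet":
        arr = self.values.copy()
        arr[_PARAM_INDEX[name]] = value
        return ParameterSet(arr)


@dataclass(frozen=True)
class PathwayState:
    """Concentrations (mM) of the nine dynamic metabolites."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} species, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("concentrations must be finite and non-negative")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PathwayState":
        missing = set(SPECIES) - set(mapping)
        extra = set(mapping) - set(SPECIES)
        if missing or extra:
            raise ValueError(f"bad species names: missing={sorted(missing)}, extra={sorted(extra)}")
        return cls(np.array([mapping[n] for n in SPECIES], dtype=float))

    def as_array(self) -> np.ndarray:
        return self.values

    def to_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[_SPECIES_INDEX[name]])


@dataclass(frozen=True)
class NetworkConfig:
    """Structural options for the reaction network.

    dilution_rate
        First-order dilution of every dynamic species due to cell growth
        (1/hr).  0.11/hr matches the chemostat conditions of the reference
        metabolite measurements.
    utp_inhibits_atcase
        If True, the noncompetitive UTP inhibition factor also multiplies
        the ATCase rate (both URA2 activities are reported to be inhibited
        by UTP); the default applies it to CPSase only, where the K_utp
        binding constant is catalogued.
    km2_substrate
        Which substrate the second ATCase Michaelis constant ``K_m2``
        refers to: ``"cp"`` (carbamoyl phosphate, the bi-substrate reading
        used by the E. coli template) or ``"asp"`` (a second aspartate
        constant).
    drain_species
        Dynamic species subject to the saturable pyrimidine-utilization
        drain (RNA-precursor consumption).
    """

    dilution_rate: float = 0.11
    utp_inhibits_atcase: bool = False
    km2_substrate: str = "cp"
    drain_species: tuple[str, ...] = ("utp", "ctp")

    def __post_init__(self) -> None:
        if self.dilution_rate < 0:
            raise ValueError("dilution_rate must be >= 0")
        if self.km2_substrate not in ("cp", "asp"):
            raise ValueError(f"unknown km2_substrate variant {self.km2_substrate!r}")
        for s in self.drain_species:
            if s not in SPECIES:
                raise ValueError(f"unknown drain species {s!r}")


@dataclass(frozen=True)
class Reaction:
    """One reaction: substrates -> products with named parameters.

    ``substrates`` lists the species whose saturable factors multiply vmax
    (clamped pools included); ``modifiers`` lists inhibitors.
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    vmax: str
    km: tuple[str, ...]  # one Michaelis constant per substrate, same order
    modifiers: tuple[str, ...] = ()


class ReactionNetwork:
    """The pathway topology plus fast rate/derivative kernels.

    Built by :func:`build_network`; holds an ordered reaction list for
    introspection/export and closures evaluating per-reaction fluxes and
    species time derivatives on raw arrays.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.reactions = self._build_reactions(config)
        self._check_parameter_coverage()

    @staticmethod
    def _build_reactions(config: NetworkConfig) -> tuple[Reaction, ...]:
        r1_mod = ("utp",)
        r2_mod = ("utp",) if config.utp_inhibits_atcase else ()
        if config.km2_substrate == "cp":
            r2_subs, r2_km = ("cp", "asp"), ("K_m2", "K_asp")
        else:
            r2_subs, r2_km = ("cp", "asp"), ("K_asp", "K_m2")  # cp unsaturated reading unused
        reactions = [
            Reaction("r1", ("glu", "bc", "atp"), ("cp",), "vmax1",
                     ("K_q", "K_bc", "K_atp"), r1_mod),
            Reaction("r2", r2_subs, ("ca",), "vmax2", r2_km, r2_mod),
            Reaction("r3", ("ca",), ("dho",), "vmax3", ("K_m3",)),
            Reaction("r4", ("dho",), ("oro",), "vmax4", ("K_m4",)),
            Reaction("r5", ("oro",), ("omp",), "vmax5", ("K_m5",)),
            Reaction("r6", ("omp",), ("ump",), "vmax6", ("K_m6",)),
            Reaction("r10", ("ump",), ("udp",), "vmax10", ("K_m10",)),
            Reaction("r7", ("udp",), ("utp",), "vmax7", ("K_m7",)),
            Reaction("r8", ("utp",), ("ctp",), "vmax8", ("K_m8",)),
        ]
        for s in config.drain_species:
            reactions.append(Reaction(f"util_{s}", (s,), (), "g_pyr", ("K_Mp",)))
        return tuple(reactions)

    def _check_parameter_coverage(self) -> None:
        used = set(FIXED_SPECIES)
        for r in self.reactions:
            used.add(r.vmax)
            used.update(r.km)
            used.update("K_utp" for _ in r.modifiers)
        unused = set(PARAM_NAMES) - used
        if unused:
            raise ValueError(f"parameters referenced by no reaction: {sorted(unused)}")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    # -- fast kernels -------------------------------------------------------

    def rates_array(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Per-reaction fluxes (mM/hr) for raw state/parameter arrays."""
        (vmax1, K_utp, K_atp, K_q, K_bc,
         vmax2, K_asp, K_m2,
         vmax3, K_m3, vmax4, K_m4, vmax5, K_m5, vmax6, K_m6,
         vmax7, K_m7, vmax8, K_m8, vmax10, K_m10,
         g_pyr, K_Mp, bc, glu, asp, atp) = p
        cp, ca, dho, oro, omp, ump, udp, utp, ctp = x

        inhib = K_utp / (K_utp + utp)
        r1 = vmax1 * (glu / (K_q + glu)) * (bc / (K_bc + bc)) * (atp / (K_atp + atp)) * inhib
        if self.config.km2_substrate == "cp":
            r2 = vmax2 * (cp / (K_m2 + cp)) * (asp / (K_asp + asp))
        else:
            r2 = vmax2 * (cp / (K_asp + cp)) * (asp / (K_m2 + asp))
        if self.config.utp_inhibits_atcase:
            r2 *= inhib
        r3 = vmax3 * ca / (K_m3 + ca)
        r4 = vmax4 * dho / (K_m4 + dho)
        r5 = vmax5 * oro / (K_m5 + oro)
        r6 = vmax6 * omp / (K_m6 + omp)
        r10 = vmax10 * ump / (K_m10 + ump)
        r7 = vmax7 * udp / (K_m7 + udp)
        r8 = vmax8 * utp / (K_m8 + utp)
        fluxes = [r1, r2, r3, r4, r5, r6, r10, r7, r8]
        conc = dict(zip(SPECIES, x))
        for s in self.config.drain_species:
            fluxes.append(g_pyr * conc[s] / (K_Mp + conc[s]))
        return np.array(fluxes)

    def derivatives_array(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Time derivatives dX/dt (mM/hr) for raw state/parameter arrays."""
        (vmax1, K_utp, K_atp, K_q, K_bc,
         vmax2, K_asp, K_m2,
         vmax3, K_m3, vmax4, K_m4, vmax5, K_m5, vmax6, K_m6,
         vmax7, K_m7, vmax8, K_m8, vmax10, K_m10,
         g_pyr, K_Mp, bc, glu, asp, atp) = p
        cp, ca, dho, oro, omp, ump, udp, utp, ctp = x
        d = self.config.dilution_rate

        inhib = K_utp / (K_utp + utp)
        r1 = vmax1 * (glu / (K_q + glu)) * (bc / (K_bc + bc)) * (atp / (K_atp + atp)) * inhib
        if self.config.km2_substrate == "cp":
            r2 = vmax2 * (cp / (K_m2 + cp)) * (asp / (K_asp + asp))
        else:
            r2 = vmax2 * (cp / (K_asp + cp)) * (asp / (K_m2 + asp))
        if self.config.utp_inhibits_atcase:
            r2 *= inhib
        r3 = vmax3 * ca / (K_m3 + ca)
        r4 = vmax4 * dho / (K_m4 + dho)
        r5 = vmax5 * oro / (K_m5 + oro)
        r6 = vmax6 * omp / (K_m6 + omp)
        r10 = vmax10 * ump / (K_m10 + ump)
        r7 = vmax7 * udp / (K_m7 + udp)
        r8 = vmax8 * utp / (K_m8 + utp)

        drain_utp = g_pyr * utp / (K_Mp + utp) if "utp" in self.config.drain_species else 0.0
        drain_ctp = g_pyr * ctp / (K_Mp + ctp) if "ctp" in self.config.drain_species else 0.0

        return np.array([
            r1 - r2 - d * cp,
            r2 - r3 - d * ca,
            r3 - r4 - d * dho,
            r4 - r5 - d * oro,
            r5 - r6 - d * omp,
            r6 - r10 - d * ump,
            r10 - r7 - d * udp,
            r7 - r8 - drain_utp - d * utp,
            r8 - drain_ctp - d * ctp,
        ])

    def jacobian_array(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Jacobian d(dX/dt)/dX by central finite differences."""
        n = len(x)
        jac = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(x[j]), 1e-9)
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] = max(xm[j] - h, 0.0)
            jac[:, j] = (self.derivatives_array(xp, p) - self.derivatives_array(xm, p)) / (xp[j] - xm[j])
        return jac


def build_network(config: NetworkConfig | None = None) -> ReactionNetwork:
    """Construct the pathway :class:`ReactionNetwork` for a configuration."""
    return ReactionNetwork(config or NetworkConfig())


def _validate(state: PathwayState | np.ndarray, params: ParameterSet | np.ndarray):
    x = state.as_array() if isinstance(state, PathwayState) else np.asarray(state, float)
    p = params.as_array() if isinstance(params, ParameterSet) else np.asarray(params, float)
    if np.any(x < 0):
        raise ValueError("negative concentration")
    if np.any(p <= 0):
        raise ValueError("non-positive parameter")
    return x, p


def reaction_rates(state, params, network: ReactionNetwork) -> dict[str, float]:
    """Per-reaction Michaelis–Menten fluxes (mM/hr), keyed by reaction id."""
    x, p = _validate(state, params)
    return dict(zip(network.reaction_ids, network.rates_array(x, p).tolist()))


def time_derivatives(state, params, network: ReactionNetwork) -> np.ndarray:
    """dX/dt (mM/hr) for the nine dynamic species, in :data:`SPECIES` order."""
    x, p = _validate(state, params)
    return network.derivatives_array(x, p)


class SteadyStateError(RuntimeError):
    """Raised when no steady state could be located within the budget."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class SteadyStateResult:
    """A located steady state plus its local stability report."""

    state: PathwayState
    residual: float           # max |dX/dt| at the state, mM/hr
    eigenvalues: np.ndarray   # Jacobian spectrum at the state
    stable: bool              # all eigenvalue real parts < 0
    method: str               # "integrate+polish" | "polish" | "integrate"

    def __getitem__(self, name: str) -> float:
        return self.state[name]


def _integrate_to_plateau(network, p, x0, rate_tol=1e-9, t_max=25600.0):
    """Integrate the ODE until relative state change per hour < rate_tol."""
    x = np.asarray(x0, float)
    t_end = 400.0
    fun = lambda t, y: network.derivatives_array(np.maximum(y, 0.0), p)
    while True:
        sol = solve_ivp(fun, (0.0, t_end), x, method="LSODA",
                        rtol=1e-9, atol=1e-16)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}", x)
        x = np.maximum(sol.y[:, -1], 0.0)
        dx = network.derivatives_array(x, p)
        rel_rate = np.max(np.abs(dx) / np.maximum(np.abs(x), 1e-12))
        if rel_rate < rate_tol or t_end >= t_max:
            return x
        t_end *= 4.0


def steady_state(
    params: ParameterSet,
    network: ReactionNetwork,
    x0: PathwayState | np.ndarray | None = None,
    f_tol: float = 1e-10,
    rate_tol: float = 1e-9,
) -> SteadyStateResult:
    """Locate a stable steady state of the pathway ODEs.

    Strategy: integrate from a small positive initial state (1e-6 mM for
    every species unless ``x0`` is given) until the relative rate of change
    falls below ``rate_tol`` per hour, then Newton-polish the algebraic
    system in log-concentration space (which enforces positivity).  When a
    good ``x0`` is supplied, the integration phase is skipped and only
    re-entered if the polish fails.

    Raises :class:`SteadyStateError` if the residual ‖dX/dt‖∞ cannot be
    brought below ``f_tol`` (mM/hr) or a non-positive component emerges.
    """
    p = params.as_array() if isinstance(params, ParameterSet) else np.asarray(params, float)
    if np.any(p <= 0):
        raise ValueError("non-positive parameter")

    guess = None
    if x0 is not None:
        guess = x0.as_array() if isinstance(x0, PathwayState) else np.asarray(x0, float)
        if np.any(guess <= 0):
            guess = None

    def polish(x_start: np.ndarray) -> np.ndarray | None:
        u0 = np.log(x_start)
        # clamp the log-state so solver exploration cannot overflow exp
        sol = root(lambda u: network.derivatives_array(np.exp(np.clip(u, -700, 300)), p),
                   u0, method="hybr", options={"xtol": 1e-13})
        # Judge by the achieved residual, not the solver status: hybr
        # reports "no progress" when started at the solution itself.
        x = np.exp(sol.x)
        if np.max(np.abs(network.derivatives_array(x, p))) > f_tol:
            return None
        return x

    method = None
    x = None
    if guess is not None:
        x = polish(guess)
        if x is not None:
            method = "polish"
    if x is None:
        start = guess if guess is not None else np.full(len(SPECIES), 1e-6)
        plateau = _integrate_to_plateau(network, p, start, rate_tol=rate_tol)
        x = polish(np.maximum(plateau, 1e-300)) if np.all(plateau > 0) else None
        if x is not None:
            method = "integrate+polish"
        else:
            resid = np.max(np.abs(network.derivatives_array(plateau, p)))
            if resid < f_tol:
                x, method = plateau, "integrate"
            else:
                raise SteadyStateError(
                    f"no steady state: residual {resid:.3e} mM/hr after integration",
                    plateau)

    residual = float(np.max(np.abs(network.derivatives_array(x, p))))
    eig = np.linalg.eigvals(network.jacobian_array(x, p))
    stable = bool(np.all(eig.real < 0))
    if not stable:
        warnings.warn("steady state has non-negative Jacobian eigenvalue real part",
                      RuntimeWarning, stacklevel=2)
    return SteadyStateResult(PathwayState(np.maximum(x, 0.0)), residual, eig, stable, method)
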