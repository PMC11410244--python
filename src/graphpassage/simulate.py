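"""Stochastic serial-passage dynamics: growth then dilution-with-migration.

One elementary step of the model takes a bottleneck state of a
deme-structured population to the next bottleneck:

1. **Growth phase** — each deme grows exponentially for a fixed time t.
   Wild-types grow at rate 1 and mutants at rate 1 + s, so the mutant
   fraction in a deme moves deterministically from x to
   ``x e^{st} / (1 + x (e^{st} - 1))``; only the *effective fitness
   advantage* st matters for fractions.
2. **Dilution and migration phase** — serial passage with exchanges
   between demes.  The number of mutants (wild-types) sent from deme i
   to deme j is an independent binomial draw with ``round(N'_i)`` trials
   and success probability ``m_ij x'_i B / N'_i``
   (``m_ij (1 - x'_i) B / N'_i``), where N'_i is the post-growth deme
   size.  Each deme's new bottleneck is the sum of what it receives.

This is soft selection: a deme's post-growth size does not affect its
contribution to the next bottleneck.  See :mod:`graphpassage.hard_selection`
for the hard-selection variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .graphs import MigrationGraph

__all__ = [
    "DEFAULT_GROWTH_TIME",
    "PopulationParams",
    "PopulationState",
    "PostGrowthState",
    "Trajectory",
    "EnsembleResult",
    "grow",
    "sample_bottleneck",
    "make_initial_state",
    "run_trajectory",
    "run_ensemble",
]

#: Default exponential growth time between passages: a 100-fold dilution
#: regrown overnight corresponds to t = ln(100).
DEFAULT_GROWTH_TIME = math.log(100.0)

FIXED = "fixed"
EXTINCT = "extinct"
UNRESOLVED = "unresolved"

_FIXED_CODE, _EXTINCT_CODE, _UNRESOLVED_CODE = 1, 0, 2
_CODE_TO_OUTCOME = {_FIXED_CODE: FIXED, _EXTINCT_CODE: EXTINCT, _UNRESOLVED_CODE: UNRESOLVED}


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the serial-passage dynamics.

    Parameters
    ----------
    B
        Mean deme bottleneck size (individuals).
    st
        Effective fitness advantage, the product of the relative growth
        advantage s and the growth time t.  May be given directly, or
        through ``s`` (with ``t`` defaulting to ln 100).  Zero or
        negative values model neutral or deleterious mutants.
    s, t
        Relative advantage and growth time.  Fraction dynamics depend on
        them only through st, but t sets the post-growth deme sizes
        (hence binomial trial counts and division numbers).
    max_steps
        Cap on bottleneck steps before a trajectory is declared
        unresolved.
    """

    B: float
    st: float | None = None
    s: float | None = None
    t: float = DEFAULT_GROWTH_TIME
    max_steps: int = 10**6

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("bottleneck size B must be at least 1")
        if self.t <= 0:
            raise ValueError("growth time t must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be at least 1")
        if self.st is None and self.s is None:
            raise ValueError("provide the effective advantage st, or s (and t)")
        if self.st is None:
            object.__setattr__(self, "st", self.s * self.t)
        elif self.s is None:
            object.__setattr__(self, "s", self.st / self.t)
        elif not math.isclose(self.s * self.t, self.st, rel_tol=1e-9, abs_tol=1e-15):
            raise ValueError(f"inconsistent parameters: s*t = {self.s * self.t} but st = {self.st}")
        if not math.isfinite(self.st):
            raise ValueError("effective advantage st must be finite")


@dataclass
class PopulationState:
    """Per-deme integer mutant and wild-type counts at a bottleneck."""

    M: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.W = np.asarray(self.W, dtype=np.int64)
        if self.M.shape != self.W.shape or self.M.ndim != 1:
            raise ValueError("M and W must be 1-D arrays of equal length")
        if np.any(self.M < 0) or np.any(self.W < 0):
            raise ValueError("counts must be non-negative")

    @property
    def D(self) -> int:
        return self.M.shape[0]

    def total_fraction(self) -> float:
        """Overall mutant fraction across all demes."""
        tot = int(self.M.sum() + self.W.sum())
        return float(self.M.sum()) / tot if tot else 0.0


@dataclass
class PostGrowthState:
    """Real-valued per-deme sizes after the exponential growth phase."""

    Mp: np.ndarray
    Wp: np.ndarray

    @property
    def Np(self) -> np.ndarray:
        return self.Mp + self.Wp


@dataclass
class Trajectory:
    """One realisation of the dynamics, recorded at bottlenecks.

    ``fractions[k]`` is the overall mutant fraction at bottleneck k
    (entry 0 is the initial state).  ``absorption_step`` is the
    bottleneck index at which fixation or extinction occurred; ``None``
    for unresolved trajectories.
    """

    fractions: np.ndarray
    outcome: str
    absorption_step: int | None


# ---------------------------------------------------------------------------
# vectorised kernels operating on (R, D) count arrays


def _grow_arrays(M: np.ndarray, W: np.ndarray, s: float, t: float) -> tuple[np.ndarray, np.ndarray]:
    return M * math.exp((1.0 + s) * t), W * math.exp(t)


def _sample_arrays(
    Mp: np.ndarray,
    Wp: np.ndarray,
    g: MigrationGraph,
    B: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dilution-migration step for a batch of replicates.

    Mp, Wp have shape (R, D); returns new integer count arrays (R, D).
    Draws one independent binomial per (source, destination, type).
    """
    R, D = Mp.shape
    Np = Mp + Wp
    nonempty = Np > 0
    trials = np.rint(Np).astype(np.int64)
    newM = np.zeros((R, D), dtype=np.int64)
    newW = np.zeros((R, D), dtype=np.int64)
    # per-source total sampling probability m_ij * B / N'_i must be <= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_Np = np.where(nonempty, 1.0 / Np, 0.0)
    xp = Mp * inv_Np
    for i in range(D):
        src_ok = nonempty[:, i]
        if not src_ok.any():
            continue
        for j in range(D):
            mij = g.m[i, j]
            if mij == 0.0:
                continue
            p_tot = mij * B * inv_Np[:, i]
            if np.any(p_tot[src_ok] > 1.0 + 1e-12):
                raise ValueError(
                    f"sampling probability m[{i},{j}]*B/N' = "
                    f"{float(p_tot[src_ok].max())} exceeds 1; post-growth deme "
                    "size is too small for this migration weight and B"
                )
            p_mut = np.clip(p_tot * xp[:, i], 0.0, 1.0)
            p_wt = np.clip(p_tot * (1.0 - xp[:, i]), 0.0, 1.0)
            n_i = np.where(src_ok, trials[:, i], 0)
            newM[:, j] += rng.binomial(n_i, p_mut)
            newW[:, j] += rng.binomial(n_i, p_wt)
    return newM, newW


# ---------------------------------------------------------------------------
# single-state API


def grow(state: PopulationState, params: PopulationParams) -> PostGrowthState:
    """Deterministic exponential growth of every deme for time t."""
    Mp, Wp = _grow_arrays(state.M.astype(float), state.W.astype(float), params.s, params.t)
    return PostGrowthState(Mp=Mp, Wp=Wp)


def sample_bottleneck(
    post: PostGrowthState,
    g: MigrationGraph,
    params: PopulationParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Binomial dilution-with-migration from a post-growth state."""
    newM, newW = _sample_arrays(post.Mp[None, :], post.Wp[None, :], g, params.B, rng)
    return PopulationState(M=newM[0], W=newW[0])


def make_initial_state(
    g: MigrationGraph,
    params: PopulationParams,
    placement: str,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Build the initial bottleneck state from a placement keyword.

    Placements: ``"center"`` / ``"leaf"`` (star only; the center is deme
    0 and the leaf used is deme 1), ``"uniform"`` (one fully mutant deme
    chosen uniformly at random), ``"deme:k"`` (deme k fully mutant) and
    ``"count:n"`` or ``"count:n:k"`` (n mutants and B - n wild-types in
    deme k, default deme 0, as for a partially mutant well-mixed
    population).
    """
    D = g.D
    B = int(round(params.B))
    M = np.zeros(D, dtype=np.int64)
    W = np.full(D, B, dtype=np.int64)
    target, n_mut = _resolve_placement(g, placement, rng)
    if n_mut == -1:
        n_mut = B
    if n_mut > B:
        raise ValueError(f"initial mutant count {n_mut} exceeds bottleneck size {B}")
    M[target] = n_mut
    W[target] = B - n_mut
    return PopulationState(M=M, W=W)


def _resolve_placement(
    g: MigrationGraph, placement: str, rng: np.random.Generator | None
) -> tuple[int, int]:
    placement = str(placement)
    if placement in ("center", "leaf") and getattr(g, "kind", "custom") != "star":
        raise ValueError(f"placement '{placement}' requires a star graph")
    if placement == "center":
        return 0, _full(g)
    if placement == "leaf":
        return 1, _full(g)
    if placement in ("uniform", "uniform_random"):
        if rng is None:
            raise ValueError("uniform placement needs a random generator")
        return int(rng.integers(g.D)), _full(g)
    if placement.startswith("deme:"):
        k = int(placement.split(":", 1)[1])
        if not 0 <= k < g.D:
            raise ValueError(f"deme index {k} out of range for D = {g.D}")
        return k, _full(g)
    if placement.startswith("count:"):
        parts = placement.split(":")
        n = int(parts[1])
        k = int(parts[2]) if len(parts) > 2 else 0
        if not 0 <= k < g.D:
            raise ValueError(f"deme index {k} out of range for D = {g.D}")
        return k, n
    raise ValueError(f"unknown placement {placement!r}")


def _full(g: MigrationGraph) -> int:
    # marker: the whole deme is mutant; resolved against B by the caller
    return -1


def run_trajectory(
    init: PopulationState,
    g: MigrationGraph,
    params: PopulationParams,
    rng: np.random.Generator,
) -> Trajectory:
    """Run a single replicate to fixation, extinction or the step cap."""
    if init.M.sum() + init.W.sum() == 0:
        raise ValueError("initial state must contain at least one individual")
    res = _run_batch(
        init.M[None, :].copy(),
        init.W[None, :].copy(),
        rng,
        params.max_steps,
        _soft_step_fn(g, params),
        record_fractions=True,
    )
    return next(res.trajectories())


@dataclass
class EnsembleResult:
    """Outcome of a batch of replicate trajectories.

    ``outcomes`` holds per-replicate codes (see :meth:`outcome_labels`),
    ``absorption_steps`` the bottleneck index of absorption (-1 if
    unresolved).  When recorded, ``fractions`` is an (R, T+1) matrix of
    overall mutant fractions in which absorbed replicates are held at
    their absorbing value (0 or 1) after absorption, so step-wise
    averages over the ensemble are always defined.
    """

    outcomes: np.ndarray
    absorption_steps: np.ndarray
    fractions: np.ndarray | None = None

    @property
    def reps(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_fixed(self) -> int:
        return int(np.sum(self.outcomes == _FIXED_CODE))

    @property
    def n_extinct(self) -> int:
        return int(np.sum(self.outcomes == _EXTINCT_CODE))

    @property
    def n_unresolved(self) -> int:
        return int(np.sum(self.outcomes == _UNRESOLVED_CODE))

    def outcome_labels(self) -> np.ndarray:
        return np.array([_CODE_TO_OUTCOME[c] for c in self.outcomes])

    def fixation_times(self) -> np.ndarray:
        return self.absorption_steps[self.outcomes == _FIXED_CODE]

    def extinction_times(self) -> np.ndarray:
        return self.absorption_steps[self.outcomes == _EXTINCT_CODE]

    def trajectories(self) -> Iterator[Trajectory]:
        """Yield per-replicate :class:`Trajectory` views.

        Requires recorded fractions.  An absorbed trajectory's series is
        truncated at its absorption step.
        """
        if self.fractions is None:
            raise ValueError("ensemble was run without fraction recording")
        for r in range(self.reps):
            code = self.outcomes[r]
            step = int(self.absorption_steps[r])
            if code == _UNRESOLVED_CODE:
                yield Trajectory(self.fractions[r].copy(), UNRESOLVED, None)
            else:
                yield Trajectory(self.fractions[r, : step + 1].copy(), _CODE_TO_OUTCOME[code], step)


def run_ensemble(
    g: MigrationGraph,
    params: PopulationParams,
    placement: str | PopulationState,
    reps: int,
    rng: np.random.Generator | int | None = None,
    record_fractions: bool = True,
) -> EnsembleResult:
    """Run many replicates in vectorised lockstep.

    All replicates share one generator: draws for a given bottleneck step
    are made jointly across the still-active replicates, which makes
    large ensembles fast.  Results are reproducible for a fixed
    ``(seed, reps)`` pair.  ``placement`` may be a placement keyword
    (re-drawn per replicate for ``"uniform"``) or an explicit common
    initial :class:`PopulationState`.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(rng)
    D = g.D
    if isinstance(placement, PopulationState):
        M = np.tile(placement.M, (reps, 1))
        W = np.tile(placement.W, (reps, 1))
    else:
        B = int(round(params.B))
        M = np.zeros((reps, D), dtype=np.int64)
        W = np.full((reps, D), B, dtype=np.int64)
        if placement in ("uniform", "uniform_random"):
            target = rng.integers(D, size=reps)
            n_mut = np.full(reps, B)
        else:
            tgt, n = _resolve_placement(g, placement, rng)
            n = B if n == -1 else n
            if n > B:
                raise ValueError(f"initial mutant count {n} exceeds bottleneck size {B}")
            target = np.full(reps, tgt)
            n_mut = np.full(reps, n)
        rows = np.arange(reps)
        M[rows, target] = n_mut
        W[rows, target] = int(round(params.B)) - n_mut
    return _run_batch(M, W, rng, params.max_steps, _soft_step_fn(g, params), record_fractions)


def _soft_step_fn(g: MigrationGraph, params: PopulationParams):
    def step_fn(Mc: np.ndarray, Wc: np.ndarray, rng: np.random.Generator):
        Mp, Wp = _grow_arrays(Mc.astype(float), Wc.astype(float), params.s, params.t)
        return _sample_arrays(Mp, Wp, g, params.B, rng)

    return step_fn


def _run_batch(
    M: np.ndarray,
    W: np.ndarray,
    rng: np.random.Generator,
    max_steps: int,
    step_fn,
    record_fractions: bool,
) -> EnsembleResult:
    """Lockstep batch loop; ``step_fn(M, W, rng) -> (M, W)`` is one full
    bottleneck-to-bottleneck update."""
    R, D = M.shape
    outcomes = np.full(R, _UNRESOLVED_CODE, dtype=np.int8)
    steps = np.full(R, -1, dtype=np.int64)
    tot_m = M.sum(axis=1)
    tot_w = W.sum(axis=1)
    frac = np.where(tot_m + tot_w > 0, tot_m / np.maximum(tot_m + tot_w, 1), 0.0)
    record: list[np.ndarray] | None = [frac.copy()] if record_fractions else None

    ext = tot_m == 0
    fix = (tot_w == 0) & ~ext
    outcomes[ext] = _EXTINCT_CODE
    outcomes[fix] = _FIXED_CODE
    steps[ext | fix] = 0
    active = ~(ext | fix)

    for step in range(1, max_steps + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        newM, newW = step_fn(M[idx], W[idx], rng)
        M[idx] = newM
        W[idx] = newW
        tm = newM.sum(axis=1)
        tw = newW.sum(axis=1)
        frac[idx] = np.where(tm + tw > 0, tm / np.maximum(tm + tw, 1), 0.0)
        ext = tm == 0
        fix = (tw == 0) & ~ext
        done = ext | fix
        outcomes[idx[ext]] = _EXTINCT_CODE
        outcomes[idx[fix]] = _FIXED_CODE
        steps[idx[done]] = step
        active[idx[done]] = False
        if record is not None:
            record.append(frac.copy())

    fractions = np.vstack(record).T if record is not None else None
    return EnsembleResult(outcomes=outcomes, absorption_steps=steps, fractions=fractions)
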