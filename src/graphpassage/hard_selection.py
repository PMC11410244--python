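"""Hard-selection variant: logistic growth and a fixed dilution factor.

Under soft selection (the default model), every deme contributes to the
next bottleneck independently of how large it grew.  Under hard
selection, demes grow logistically toward a carrying capacity and the
passage dilutes each deme by the same fixed factor d, so a deme that
grew fuller seeds proportionally more of the next bottleneck.

The growth law applies a shared logistic brake to both types::

    dW/dt = W (1 - N / K),    dM/dt = (1 + s) M (1 - N / K)

with N = W + M and a composition-dependent capacity
``K = K_wt (1 - x + x r)`` where x is the current mutant fraction and r
the post-growth density of a fully mutant deme relative to a fully
wild-type one (e.g. r = 1.4 for a 40% optical-density difference).
Because the brake multiplies both rates, the relative enrichment of
mutants is exactly the soft-selection growth map at every time: the two
variants differ only through the deme sizes that set contributions to
the next bottleneck.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphs import MigrationGraph
from .simulate import EnsembleResult, PopulationState, PostGrowthState, _run_batch

__all__ = [
    "HardSelectionParams",
    "grow_hard",
    "sample_bottleneck_hard",
    "run_ensemble_hard",
]


@dataclass(frozen=True)
class HardSelectionParams:
    """Parameters of the hard-selection growth and dilution step.

    Parameters
    ----------
    d
        Fixed dilution factor applied at each passage (e.g. 100).
    K_wt
        Carrying capacity of a fully wild-type deme (individuals);
        ``math.inf`` recovers unbounded exponential growth.
    s
        Relative fitness advantage of mutants.
    t
        Growth time between passages.
    density_ratio
        Post-growth density of a fully mutant deme relative to a fully
        wild-type deme.  Applied as mutant-deme capacity
        ``density_ratio * K_wt`` when ``mutant_denser`` (the default),
        or ``K_wt / density_ratio`` otherwise.
    rk_steps
        Number of fixed Runge-Kutta substeps used to integrate mixed
        demes over the growth phase.
    """

    d: float
    K_wt: float
    s: float
    t: float = math.log(100.0)
    density_ratio: float = 1.4
    mutant_denser: bool = True
    rk_steps: int = 1000
    max_steps: int = 10**6

    def __post_init__(self) -> None:
        if self.d <= 1:
            raise ValueError("dilution factor d must exceed 1")
        if self.K_wt <= 0:
            raise ValueError("carrying capacity K_wt must be positive")
        if self.density_ratio <= 0:
            raise ValueError("density_ratio must be positive")
        if self.t <= 0 or self.rk_steps < 1:
            raise ValueError("t must be positive and rk_steps at least 1")

    @property
    def capacity_ratio(self) -> float:
        """Capacity of a fully mutant deme relative to K_wt."""
        return self.density_ratio if self.mutant_denser else 1.0 / self.density_ratio

    def capacity(self, x) -> np.ndarray:
        """Deme capacity at mutant fraction x (linear interpolation)."""
        return self.K_wt * (1.0 - np.asarray(x, dtype=float) * (1.0 - self.capacity_ratio))


def _logistic_closed_form(N0: np.ndarray, rate: float, K: float, t: float) -> np.ndarray:
    e = math.exp(rate * t)
    return K * N0 * e / (K + N0 * (e - 1.0))


def _grow_hard_arrays(
    M: np.ndarray, W: np.ndarray, hp: HardSelectionParams
) -> tuple[np.ndarray, np.ndarray]:
    M = M.astype(float)
    W = W.astype(float)
    if math.isinf(hp.K_wt):
        return M * math.exp((1.0 + hp.s) * hp.t), W * math.exp(hp.t)
    Mp = np.zeros_like(M)
    Wp = np.zeros_like(W)
    N = M + W
    pure_w = (M == 0) & (W > 0)
    pure_m = (W == 0) & (M > 0)
    mixed = (M > 0) & (W > 0)
    # single-type demes follow the plain logistic law exactly
    Wp[pure_w] = _logistic_closed_form(W[pure_w], 1.0, hp.K_wt, hp.t)
    Mp[pure_m] = _logistic_closed_form(
        M[pure_m], 1.0 + hp.s, hp.K_wt * hp.capacity_ratio, hp.t
    )
    if mixed.any():
        w = W[mixed]
        m = M[mixed]
        h = hp.t / hp.rk_steps

        def deriv(w, m):
            n = w + m
            brake = 1.0 - n / hp.capacity(m / n)
            return w * brake, (1.0 + hp.s) * m * brake

        for _ in range(hp.rk_steps):
            k1w, k1m = deriv(w, m)
            k2w, k2m = deriv(w + 0.5 * h * k1w, m + 0.5 * h * k1m)
            k3w, k3m = deriv(w + 0.5 * h * k2w, m + 0.5 * h * k2m)
            k4w, k4m = deriv(w + h * k3w, m + h * k3m)
            w = w + h / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
            m = m + h / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        Wp[mixed] = w
        Mp[mixed] = m
    return Mp, Wp


def grow_hard(state: PopulationState, hp: HardSelectionParams) -> PostGrowthState:
    """Deterministic logistic growth of every deme for time t."""
    Mp, Wp = _grow_hard_arrays(state.M[None, :], state.W[None, :], hp)
    return PostGrowthState(Mp=Mp[0], Wp=Wp[0])


def _sample_hard_arrays(
    Mp: np.ndarray,
    Wp: np.ndarray,
    g: MigrationGraph,
    hp: HardSelectionParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    R, D = Mp.shape
    Np = Mp + Wp
    nonempty = Np > 0
    trials = np.rint(Np).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = np.where(nonempty, Mp / np.maximum(Np, 1e-300), 0.0)
    newM = np.zeros((R, D), dtype=np.int64)
    newW = np.zeros((R, D), dtype=np.int64)
    for i in range(D):
        src_ok = nonempty[:, i]
        if not src_ok.any():
            continue
        n_i = np.where(src_ok, trials[:, i], 0)
        for j in range(D):
            mij = g.m[i, j]
            if mij == 0.0:
                continue
            if mij / hp.d > 1.0:
                raise ValueError(
                    f"sampling probability m[{i},{j}]/d = {mij / hp.d} exceeds 1"
                )
            newM[:, j] += rng.binomial(n_i, np.clip(mij * xp[:, i] / hp.d, 0.0, 1.0))
            newW[:, j] += rng.binomial(n_i, np.clip(mij * (1.0 - xp[:, i]) / hp.d, 0.0, 1.0))
    return newM, newW


def sample_bottleneck_hard(
    post: PostGrowthState,
    g: MigrationGraph,
    hp: HardSelectionParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Fixed-factor dilution with migration.

    The number of mutants (wild-types) sent from deme i to deme j is
    binomial with ``round(N'_i)`` trials and success probability
    ``m_ij x'_i / d`` (``m_ij (1 - x'_i) / d``): a deme's contribution
    scales with its post-growth size, which is what makes selection hard.
    """
    newM, newW = _sample_hard_arrays(post.Mp[None, :], post.Wp[None, :], g, hp, rng)
    return PopulationState(M=newM[0], W=newW[0])


def run_ensemble_hard(
    g: MigrationGraph,
    hp: HardSelectionParams,
    init: PopulationState,
    reps: int,
    rng: np.random.Generator | int | None = None,
    record_fractions: bool = True,
) -> EnsembleResult:
    """Replicate trajectories under hard selection, in vectorised lockstep."""
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(rng)
    M = np.tile(init.M, (reps, 1))
    W = np.tile(init.W, (reps, 1))

    def step_fn(Mc, Wc, rng):
        Mp, Wp = _grow_hard_arrays(Mc, Wc, hp)
        return _sample_hard_arrays(Mp, Wp, g, hp, rng)

    return _run_batch(M, W, rng, hp.max_steps, step_fn, record_fractions)
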