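"""Aggregation of trajectory ensembles into experimental observables.

Turns collections of replicate trajectories into the quantities an
evolution experiment would report: the fixation proportion, conditional
fixation and extinction time statistics, outcome-conditioned average
trajectories, and rescaled average trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import EXTINCT, FIXED, UNRESOLVED, EnsembleResult, Trajectory

__all__ = ["EnsembleSummary", "summarize", "average_trajectories", "rescale_trajectory"]


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate counts and outcome-conditioned statistics of an ensemble.

    ``rho_hat`` is the fixation proportion among *resolved* trajectories;
    time statistics (bottleneck steps) are conditioned on the outcome,
    with NaN where no trajectory had that outcome.  Medians and
    interquartile bounds use linear interpolation between order
    statistics.
    """

    reps: int
    n_fixed: int
    n_extinct: int
    n_unresolved: int
    rho_hat: float
    fix_time_mean: float
    fix_time_sd: float
    fix_time_median: float
    fix_time_iqr: tuple[float, float]
    ext_time_mean: float
    ext_time_sd: float
    ext_time_median: float
    ext_time_iqr: tuple[float, float]


math_nan = float("nan")


def _time_stats(times: np.ndarray) -> tuple[float, float, float, tuple[float, float]]:
    if times.size == 0:
        return math_nan, math_nan, math_nan, (math_nan, math_nan)
    mean = float(np.mean(times))
    sd = float(np.std(times, ddof=1)) if times.size > 1 else 0.0
    med = float(np.median(times))
    q1, q3 = np.percentile(times, [25, 75])
    return mean, sd, med, (float(q1), float(q3))


def _as_arrays(trajs: EnsembleResult | Iterable[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Outcome labels and absorption steps from either ensemble form."""
    if isinstance(trajs, EnsembleResult):
        return trajs.outcome_labels(), trajs.absorption_steps
    trajs = list(trajs)
    if not trajs:
        raise ValueError("empty trajectory collection")
    labels = np.array([t.outcome for t in trajs])
    steps = np.array(
        [-1 if t.absorption_step is None else t.absorption_step for t in trajs], dtype=np.int64
    )
    return labels, steps


def summarize(trajs: EnsembleResult | Iterable[Trajectory]) -> EnsembleSummary:
    """Outcome counts, fixation proportion and conditional time statistics.

    Unresolved (step-capped) trajectories are excluded from both the
    fixation proportion and the time statistics; a warning is issued when
    any are present, since silent censoring would bias the estimates.
    """
    labels, steps = _as_arrays(trajs)
    reps = labels.size
    if reps == 0:
        raise ValueError("empty trajectory collection")
    n_fixed = int(np.sum(labels == FIXED))
    n_extinct = int(np.sum(labels == EXTINCT))
    n_unresolved = int(np.sum(labels == UNRESOLVED))
    resolved = n_fixed + n_extinct
    if n_unresolved > 0:
        warnings.warn(
            f"{n_unresolved} of {reps} trajectories hit the step cap; they are "
            "excluded from the fixation proportion and time statistics",
            stacklevel=2,
        )
    rho_hat = n_fixed / resolved if resolved else math_nan
    fix_mean, fix_sd, fix_med, fix_iqr = _time_stats(steps[labels == FIXED])
    ext_mean, ext_sd, ext_med, ext_iqr = _time_stats(steps[labels == EXTINCT])
    return EnsembleSummary(
        reps=reps,
        n_fixed=n_fixed,
        n_extinct=n_extinct,
        n_unresolved=n_unresolved,
        rho_hat=rho_hat,
        fix_time_mean=fix_mean,
        fix_time_sd=fix_sd,
        fix_time_median=fix_med,
        fix_time_iqr=fix_iqr,
        ext_time_mean=ext_mean,
        ext_time_sd=ext_sd,
        ext_time_median=ext_med,
        ext_time_iqr=ext_iqr,
    )


def _padded_matrix(trajs: EnsembleResult | Sequence[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    """(R, T+1) fraction matrix with absorbed values held, plus outcome labels."""
    if isinstance(trajs, EnsembleResult):
        if trajs.fractions is None:
            raise ValueError("ensemble was run without fraction recording")
        return trajs.fractions, trajs.outcome_labels()
    trajs = list(trajs)
    if not trajs:
        raise ValueError("empty trajectory collection")
    horizon = max(t.fractions.size for t in trajs)
    mat = np.empty((len(trajs), horizon))
    for r, t in enumerate(trajs):
        k = t.fractions.size
        mat[r, :k] = t.fractions
        # hold the absorbing value so means over mixed lengths are defined
        mat[r, k:] = t.fractions[-1]
    return mat, np.array([t.outcome for t in trajs])


def average_trajectories(
    trajs: EnsembleResult | Sequence[Trajectory], condition: str = "all"
) -> np.ndarray:
    """Step-wise mean overall mutant fraction, conditioned on the outcome.

    ``condition`` is ``"fixed"``, ``"extinct"`` or ``"all"``.  After a
    trajectory absorbs, its fraction is held at the absorbing value (1 or
    0), so the unconditioned average converges to the fixation
    proportion.
    """
    mat, labels = _padded_matrix(trajs)
    if condition == "all":
        keep = np.ones(labels.size, dtype=bool)
    elif condition in (FIXED, EXTINCT):
        keep = labels == condition
    else:
        raise ValueError(f"condition must be 'fixed', 'extinct' or 'all', got {condition!r}")
    if not keep.any():
        raise ValueError(f"no trajectories with outcome {condition!r}")
    return mat[keep].mean(axis=0)


def rescale_trajectory(avg: np.ndarray, x0: float, rho_hat: float) -> np.ndarray:
    """Rescale an average trajectory to start at 0 and converge to 1.

    ``y = (x - x0) / (rho_hat - x0)`` maps the initial overall fraction
    to 0 and the long-time limit of the unconditioned average (the
    fixation proportion) to 1, making acceleration comparisons across
    structures readable.
    """
    if rho_hat == x0:
        raise ValueError("rho_hat equals the initial fraction; rescaling is undefined")
    avg = np.asarray(avg, dtype=float)
    return (avg - x0) / (rho_hat - x0)
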