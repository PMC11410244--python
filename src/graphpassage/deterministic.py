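"""Fluctuation-free recurrence for per-deme mutant fractions.

Neglecting sampling noise, the mutant fraction in deme i at the next
bottleneck is the migration-weighted average of the post-growth
fractions of its source demes::

    x_{i, n+1} = sum_j m_ji x'_{j, n} / sum_j m_ji

with ``x' = x e^{st} / (1 + x (e^{st} - 1))`` the growth map.  The
denominator is the column sum of the migration matrix, so the same
expression serves both bottleneck conventions (it equals one when every
deme receives B on average).  This recurrence is accurate for large
demes, large initial mutant numbers and non-rare migrations; it is the
prediction layer behind the plateau structure of mutant-fraction
trajectories under rare migrations, where demes are invaded
sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FractionState", "growth_map", "det_step", "det_trajectory", "find_plateaus"]


@dataclass
class FractionState:
    """Per-deme mutant fractions at bottleneck ``step``."""

    x: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0) or np.any(self.x > 1):
            raise ValueError("mutant fractions must lie in [0, 1]")


def growth_map(x, st: float):
    """Within-deme mutant fraction after one growth phase.

    ``x -> x e^{st} / (1 + x (e^{st} - 1))``; strictly increasing in x on
    (0, 1) and in st, with fixed points 0 and 1.
    """
    x = np.asarray(x, dtype=float)
    e = np.exp(st)
    out = x * e / (1.0 + x * (e - 1.0))
    return out if out.ndim else float(out)


def det_step(fs: FractionState, g, st: float) -> FractionState:
    """One deterministic bottleneck step on graph ``g``."""
    xp = growth_map(fs.x, st)
    col = g.m.sum(axis=0)
    x_next = (g.m.T @ xp) / col
    # clip float round-off; the exact map preserves [0, 1]
    return FractionState(np.clip(x_next, 0.0, 1.0), fs.step + 1)


def det_trajectory(init: FractionState, g, st: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the recurrence for ``n_steps`` bottlenecks.

    Returns ``(states, overall)`` where ``states`` is an
    (n_steps + 1, D) matrix of per-deme fractions and ``overall`` the
    overall-fraction series.  Demes enter the overall fraction weighted
    by their expected bottleneck size: B at step 0, and ``B`` times the
    migration-matrix column sum afterwards.  Under the receive-B
    convention all column sums are 1 and this is the plain deme mean;
    under contribute-B with strong asymmetric migrations, expected deme
    sizes differ and the weighting is what the stochastic overall
    fraction (total mutants over total individuals) averages to.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    states = np.empty((n_steps + 1, g.D))
    states[0] = init.x
    fs = init
    for n in range(1, n_steps + 1):
        fs = det_step(fs, g, st)
        states[n] = fs.x
    col = g.m.sum(axis=0)
    overall = (states @ col) / col.sum()
    overall[0] = states[0].mean()
    return states, overall


def find_plateaus(
    series: np.ndarray,
    flat_tol: float = 0.015,
    min_len: int = 3,
    edge_tol: float = 0.01,
) -> list[tuple[float, int, int]]:
    """Locate interior plateaus of a fraction series.

    A plateau is a maximal run of at least ``min_len`` points whose
    successive changes are all below ``flat_tol`` in magnitude, and whose
    level lies strictly inside ``(edge_tol, 1 - edge_tol)``: the slow
    terminal approach to the absorbing values 0 and 1 is not an interior
    plateau.  Returns ``(level, start, end)`` triples with ``level`` the
    run mean and ``end`` inclusive.

    The defaults are tuned to the sequential-invasion regime at
    migration probabilities around 1e-5 and effective advantage near 1:
    there, successive deme invasions are separated by a seeding lag
    ``-ln(m) / st`` only slightly longer than the width of one sigmoid
    transition, so the intermediate levels are flat only to about 0.01
    per step.  A tighter ``flat_tol`` (e.g. 1e-3) resolves just the
    first plateau, where the not-yet-seeded demes are still essentially
    mutant-free.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series is empty")
    if flat_tol <= 0:
        raise ValueError("flat_tol must be positive")
    flat = np.abs(np.diff(series)) < flat_tol
    plateaus: list[tuple[float, int, int]] = []
    i = 0
    n = flat.size
    while i < n:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j < n and flat[j]:
            j += 1
        start, end = i, j  # run covers series[start .. end] inclusive
        if end - start + 1 >= min_len:
            level = float(series[start : end + 1].mean())
            if edge_tol < level < 1.0 - edge_tol:
                plateaus.append((level, start, end))
        i = j + 1
    return plateaus
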