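"""Migration structures for deme-structured populations on graphs.

A spatially structured population is a set of D well-mixed demes placed on
the nodes of a directed graph.  Migration probabilities ``m[i, j]`` are
attached to each ordered pair of demes, with row ``i`` the source and
column ``j`` the destination; the diagonal holds the probability of
staying in place.  Because serial passage resamples every deme from the
post-growth pools, the matrix must be normalised: either every deme
*receives* an average bottleneck of B individuals (columns sum to one),
or every deme *contributes* an average of B individuals to the next
bottleneck (rows sum to one).  The two conventions coincide for doubly
stochastic matrices such as the clique.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Convention",
    "MigrationGraph",
    "build_clique",
    "build_star",
    "build_well_mixed",
    "build_custom",
    "is_circulation",
    "matched_clique_m",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

#: Tolerance on the stochastic-normalisation constraint.
NORM_TOL = 1e-12


class Convention(str, enum.Enum):
    """Bottleneck normalisation of the migration matrix.

    ``RECEIVE_B``: every column sums to one, so each deme receives the
    same average bottleneck size B.  ``CONTRIBUTE_B``: every row sums to
    one, so each deme contributes the same average amount B to the next
    bottleneck.
    """

    RECEIVE_B = "receive_B"
    CONTRIBUTE_B = "contribute_B"


@dataclass(frozen=True)
class MigrationGraph:
    """Directed, weighted migration structure over D demes.

    Parameters
    ----------
    m
        D x D matrix of migration probabilities; ``m[i, j]`` is the
        probability weight for individuals moving from deme ``i`` to
        deme ``j`` at a dilution step. Diagonal entries are explicit
        stay-probabilities.
    convention
        Declared bottleneck normalisation; verified, never inferred.
    """

    m: np.ndarray
    convention: Convention
    kind: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"migration matrix must be square, got shape {m.shape}")
        object.__setattr__(self, "m", m)
        if np.any(m < 0) or np.any(m > 1):
            bad = np.argwhere((m < 0) | (m > 1))[0]
            raise ValueError(
                f"migration probability m[{bad[0]},{bad[1]}] = {m[tuple(bad)]} "
                "outside [0, 1]"
            )
        sums = m.sum(axis=0) if self.convention is Convention.RECEIVE_B else m.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > NORM_TOL):
            deme = int(np.argmax(off))
            kind = "column" if self.convention is Convention.RECEIVE_B else "row"
            raise ValueError(
                f"{kind} sum for deme {deme} is {sums[deme]!r}, expected 1 "
                f"under convention {self.convention.value}"
            )
        self._check_connected()

    def _check_connected(self) -> None:
        if self.D == 1:
            return
        support = (self.m > 0).astype(np.int8)
        np.fill_diagonal(support, 0)
        n, _ = connected_components(csr_matrix(support), directed=True, connection="strong")
        if n != 1:
            raise ValueError(
                "off-diagonal migration support is not strongly connected; "
                "every deme must be reachable from every other"
            )

    @property
    def D(self) -> int:
        """Number of demes."""
        return self.m.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.m.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.m.sum(axis=0)


def build_clique(D: int, m: float, convention: Convention | str = Convention.RECEIVE_B) -> MigrationGraph:
    """Fully connected graph (island model) with equal pairwise migration m.

    Self-weights are the residual ``1 - (D-1) m``; the matrix is doubly
    stochastic, so it satisfies both conventions simultaneously.
    """
    convention = Convention(convention)
    if D < 2:
        raise ValueError("clique needs D >= 2 demes")
    if m < 0 or (D - 1) * m > 1:
        raise ValueError(
            f"(D-1)*m = {(D - 1) * m} must lie in [0, 1]; "
            f"self-weight would be negative for m = {m}, D = {D}"
        )
    mat = np.full((D, D), float(m))
    np.fill_diagonal(mat, 1.0 - (D - 1) * m)
    return MigrationGraph(mat, convention, kind="clique")


def build_star(
    D: int,
    m_I: float,
    alpha: float,
    convention: Convention | str = Convention.RECEIVE_B,
) -> MigrationGraph:
    """Star graph: center (deme 0) linked to D-1 leaves.

    Leaf-to-center migration probability is ``m_I``, center-to-leaf is
    ``m_O = m_I / alpha`` where ``alpha = m_I / m_O`` is the migration
    asymmetry.  Leaves do not exchange directly.  Diagonal entries are
    set so that the declared convention's marginals equal one:

    * receive_B: center self-weight ``1 - (D-1) m_I``, leaf ``1 - m_O``;
    * contribute_B: center self-weight ``1 - (D-1) m_O``, leaf ``1 - m_I``.
    """
    convention = Convention(convention)
    if D < 3:
        raise ValueError("star needs D >= 3 demes (a center and at least two leaves)")
    if alpha <= 0:
        raise ValueError("migration asymmetry alpha must be positive")
    m_O = m_I / alpha
    mat = np.zeros((D, D))
    mat[0, 1:] = m_O
    mat[1:, 0] = m_I
    if convention is Convention.RECEIVE_B:
        center_self = 1.0 - (D - 1) * m_I
        leaf_self = 1.0 - m_O
    else:
        center_self = 1.0 - (D - 1) * m_O
        leaf_self = 1.0 - m_I
    if center_self < 0:
        raise ValueError(
            f"center (deme 0) self-weight {center_self} is negative under "
            f"convention {convention.value}; reduce migration probabilities"
        )
    if leaf_self < 0:
        raise ValueError(
            f"leaf self-weight {leaf_self} is negative under convention "
            f"{convention.value}; reduce migration probabilities"
        )
    mat[0, 0] = center_self
    mat[np.arange(1, D), np.arange(1, D)] = leaf_self
    return MigrationGraph(mat, convention, kind="star")


def build_well_mixed(total_B: int, convention: Convention | str = Convention.RECEIVE_B) -> MigrationGraph:
    """Single-deme reference population (no spatial structure).

    ``total_B`` is the total bottleneck size DB of the structured
    populations it is compared against; the graph itself is the trivial
    1 x 1 identity and carries the convention trivially.
    """
    if total_B < 1:
        raise ValueError("total bottleneck size must be at least 1")
    return MigrationGraph(np.ones((1, 1)), Convention(convention), kind="well_mixed")


def build_custom(m: np.ndarray, convention: Convention | str) -> MigrationGraph:
    """Wrap and validate a user-supplied migration matrix."""
    return MigrationGraph(np.asarray(m, dtype=float), Convention(convention))


def is_circulation(g: MigrationGraph, tol: float = NORM_TOL) -> bool:
    """True iff every deme has equal incoming and outgoing migration flow.

    Operationally: all row sums and all column sums equal one.  On a
    circulation, migration conserves the overall mutant fraction in
    expectation and the fixation probability matches the well-mixed
    population of the same total size.
    """
    return bool(
        np.all(np.abs(g.row_sums() - 1.0) <= tol)
        and np.all(np.abs(g.column_sums() - 1.0) <= tol)
    )


def matched_clique_m(star: MigrationGraph) -> float:
    """Clique migration probability with the same total inter-deme exchange.

    For a star with D demes the total off-diagonal weight is
    ``(D-1)(m_I + m_O)``; a clique on D demes has ``D(D-1) m``.  Equating
    the two gives ``m = (m_I + m_O) / D``.
    """
    D = star.D
    if D < 3:
        raise ValueError("expected a star graph with at least 3 demes")
    total = star.m.sum() - np.trace(star.m)
    m = total / (D * (D - 1))
    if (D - 1) * m > 1:
        raise ValueError(f"matched clique migration m = {m} exceeds 1/(D-1)")
    return float(m)


def write_matrix_tsv(g: MigrationGraph, path: str | Path) -> None:
    """Write the matrix as header-free TSV plus a one-line convention sidecar."""
    path = Path(path)
    np.savetxt(path, g.m, delimiter="\t", fmt="%.17g")
    path.with_suffix(path.suffix + ".convention").write_text(g.convention.value + "\n")


def read_matrix_tsv(path: str | Path, convention: Convention | str | None = None) -> MigrationGraph:
    """Read a migration matrix from TSV.

    The convention must be declared, either explicitly or through the
    sidecar file written by :func:`write_matrix_tsv`; it is verified by
    construction, never inferred from the matrix.
    """
    path = Path(path)
    if convention is None:
        sidecar = path.with_suffix(path.suffix + ".convention")
        if not sidecar.exists():
            raise ValueError(
                f"no convention declared for {path}: pass convention= or "
                f"provide sidecar {sidecar.name}"
            )
        convention = sidecar.read_text().strip()
    mat = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return MigrationGraph(mat, Convention(convention))
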