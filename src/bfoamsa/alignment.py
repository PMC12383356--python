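"""Alignment matrices and the move operators that act on them.

A candidate solution — a *bacterium* in the foraging metaphor — is one
complete multiple alignment: a rectangular matrix whose rows are the input
sequences with gap characters (``-``) interspersed.  Every operator defined
here (padding, gap-column cleaning, tumble, swim) conserves each row's
gap-stripped residue content, so any bacterium reachable from the inputs is
a feasible alignment of exactly those inputs.

The sum-of-pairs objective is evaluated column by column over all unordered
row pairs; :func:`column_pairs` materialises that pair list and
:func:`count_pairs` gives its size in closed form,
``matrices * m * n(n-1)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

GAP = "-"

__all__ = [
    "GAP",
    "Bacterium",
    "ColumnPair",
    "cuadra",
    "gap_column_indices",
    "clean_gap_columns",
    "tumble",
    "swim",
    "column_pairs",
    "count_pairs",
    "evaluation_time_seconds",
]


@dataclass
class Bacterium:
    """One candidate alignment: a list of (possibly gapped) sequence rows.

    Parameters
    ----------
    rows
        One string per input sequence, in fixed input order.  Rows may be
        ragged until :func:`cuadra` is applied.
    blosum
        Cached sum-of-pairs score, filled in by the scoring layer; not part
        of equality.
    """

    rows: list[str]
    blosum: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.rows = [str(r) for r in self.rows]

    @property
    def n(self) -> int:
        """Number of sequences (matrix rows)."""
        return len(self.rows)

    @property
    def width(self) -> int:
        """Alignment length ``m``; meaningful once the matrix is rectangular."""
        return max((len(r) for r in self.rows), default=0)

    def is_rectangular(self) -> bool:
        return len({len(r) for r in self.rows}) <= 1

    def gap_count(self) -> int:
        return sum(r.count(GAP) for r in self.rows)

    def gapstripped(self) -> list[str]:
        """The underlying ungapped sequences, row by row."""
        return [r.replace(GAP, "") for r in self.rows]

    def copy(self) -> "Bacterium":
        return Bacterium(list(self.rows), blosum=self.blosum)

    @classmethod
    def from_records(cls, records: Iterable) -> "Bacterium":
        """Build a (ragged) bacterium from seqio records."""
        return cls([rec.residues for rec in records])

    def to_matrix(self) -> np.ndarray:
        """The alignment as an ``(n, m)`` uint8 array of character codes."""
        if not self.is_rectangular():
            raise ValueError("bacterium is ragged; apply cuadra() first")
        if self.width == 0:
            return np.zeros((self.n, 0), dtype=np.uint8)
        return np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8).reshape(
            self.n, self.width
        )


class ColumnPair(NamedTuple):
    """An unordered character pair drawn from one alignment column."""

    a: str
    b: str
    column: int


def cuadra(bact: Bacterium) -> Bacterium:
    """Pad ragged rows with trailing gaps so all rows share the maximum length.

    Idempotent on rectangular input; residue order is untouched.
    """
    m = bact.width
    return Bacterium([r + GAP * (m - len(r)) for r in bact.rows])


def gap_column_indices(bact: Bacterium) -> list[int]:
    """0-based indices of columns that consist entirely of gaps."""
    if not bact.is_rectangular():
        raise ValueError("matrix must be rectangular")
    if bact.width == 0 or bact.n == 0:
        return []
    mat = bact.to_matrix()
    all_gap = (mat == ord(GAP)).all(axis=0)
    return [int(j) for j in np.nonzero(all_gap)[0]]

def clean_gap_columns(bact: Bacterium) -> Bacterium:
    """Drop all-gap columns, preserving the order of the remaining columns.

    Idempotent.  If *every* column is all-gap the result is a zero-width
    matrix; the scoring layer rejects such degenerate alignments.
    """
    drop = set(gap_column_indices(bact))
    if not drop:
        return bact.copy()
    rows = ["".join(ch for j, ch in enumerate(r) if j not in drop) for r in bact.rows]
    return Bacterium(rows)


def tumble(bact: Bacterium, num_gaps: int, rng: np.random.Generator) -> Bacterium:
    """Chemotactic move: insert ``num_gaps`` gaps at uniform (row, position) spots.

    Each insertion picks a row uniformly and an intra-row position uniformly
    over ``0..len(row)`` inclusive, then the matrix is re-squared with
    :func:`cuadra`.  The input bacterium is not mutated.
    """
    if num_gaps < 0:
        raise ValueError(f"num_gaps must be >= 0, got {num_gaps}")
    rows = list(bact.rows)
    for _ in range(num_gaps):
        r = int(rng.integers(len(rows)))
        p = int(rng.integers(len(rows[r]) + 1))
        rows[r] = rows[r][:p] + GAP + rows[r][p:]
    return cuadra(Bacterium(rows))


def swim(bact: Bacterium, num_deletions: int, rng: np.random.Generator) -> Bacterium:
    """Delete up to ``num_deletions`` gaps at uniformly chosen gap positions.

    Counters gap saturation.  If fewer gaps exist, all are removed.  The
    matrix is then re-squared and cleaned of all-gap columns.
    """
    if num_deletions < 0:
        raise ValueError(f"num_deletions must be >= 0, got {num_deletions}")
    coords = [
        (i, j) for i, row in enumerate(bact.rows) for j, ch in enumerate(row) if ch == GAP
    ]
    k = min(num_deletions, len(coords))
    rows = list(bact.rows)
    if k:
        chosen = rng.choice(len(coords), size=k, replace=False)
        per_row: dict[int, list[int]] = {}
        for idx in chosen:
            i, j = coords[int(idx)]
            per_row.setdefault(i, []).append(j)
        for i, positions in per_row.items():
            for j in sorted(positions, reverse=True):
                rows[i] = rows[i][:j] + rows[i][j + 1 :]
    return clean_gap_columns(cuadra(Bacterium(rows)))


def column_pairs(bact: Bacterium) -> list[ColumnPair]:
    """All unordered row pairs for every column: ``m * C(n, 2)`` entries."""
    if bact.n < 2:
        raise ValueError("need at least 2 rows to form column pairs")
    if not bact.is_rectangular():
        raise ValueError("matrix must be rectangular")
    n = bact.n
    pairs: list[ColumnPair] = []
    for j in range(bact.width):
        col = [row[j] for row in bact.rows]
        for i in range(n - 1):
            for k in range(i + 1, n):
                pairs.append(ColumnPair(col[i], col[k], j))
    return pairs


def count_pairs(n: int, m: int, matrices: int = 1) -> int:
    """Closed-form pair count: ``matrices * m * n(n-1)/2``.

    For 100 matrices of 100 sequences x 100 columns this is 49,500,000
    pairwise substitution-matrix lookups — the quantity the list-based
    parallel evaluation is designed to spread across workers.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if matrices < 1:
        raise ValueError(f"matrices must be >= 1, got {matrices}")
    return matrices * m * (n * (n - 1) // 2)


def evaluation_time_seconds(
    pairs: int, ms_per_pair: float = 1.0, workers: int = 1
) -> float:
    """Idealised wall time to score ``pairs`` pairs with linear parallel scaling."""
    if workers < 1:
        raise ValueError(f"workers must be >= 1, got {workers}")
    return pairs * (ms_per_pair / 1000.0) / workers
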