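"""BLOSUM62 sum-of-pairs scoring of alignment matrices.

The objective maximised by all optimizers is the column-wise sum of BLOSUM62
log-odds scores over every unordered sequence pair, with an indel penalty of
0.1 per residue/gap pair and 0 for gap/gap pairs.  DNA inputs are scored with
the same BLOSUM62 lookup on the {A,C,G,T} letters (all valid amino-acid
codes) — one evaluator for both genetic and protein sets, a deliberate
modelling quirk documented in the methods note.

Ambiguity codes are scored as information-free 0: ``N`` for DNA, ``B/Z/X``
for protein.

Scoring is vectorised per column; an optional process pool splits the column
range into contiguous chunks whose per-column score arrays are concatenated
in order before the final reduction, so the result is bit-identical for any
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import GAP, Bacterium

__all__ = ["ScoringConfig", "ScoringError", "score_pair", "blosum_score"]

_PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_DNA_LETTERS = "ACGT"


class ScoringError(ValueError):
    """A character cannot be scored, or the alignment is degenerate."""


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the pairwise scoring function.

    Attributes
    ----------
    matrix_name
        Substitution matrix; only BLOSUM62 is supported.
    indel_penalty
        Penalty subtracted for each residue/gap pair (default 0.1).
    gap_gap_score
        Score for a gap/gap pair (default 0; such pairs carry no signal).
    normalize
        If true, report the mean per-pair score instead of the raw sum
        (the BFOAdtp convention, stable across alignment lengths).
    alphabet
        ``"protein"`` or ``"dna"``; controls which letters are ambiguity
        codes scored as 0.
    """

    matrix_name: str = "BLOSUM62"
    indel_penalty: float = 0.1
    gap_gap_score: float = 0.0
    normalize: bool = False
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if self.matrix_name != "BLOSUM62":
            raise ValueError(f"unsupported matrix {self.matrix_name!r}")
        if self.indel_penalty < 0:
            raise ValueError("indel_penalty must be >= 0")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"alphabet must be 'protein' or 'dna', got {self.alphabet!r}")


@lru_cache(maxsize=8)
def _pair_lut(indel_penalty: float, gap_gap_score: float, alphabet: str) -> np.ndarray:
    """128x128 lookup of pair scores indexed by ASCII code; NaN = unscorable."""
    lut = np.full((128, 128), np.nan)
    mat = substitution_matrices.load("BLOSUM62")
    letters = _DNA_LETTERS if alphabet == "dna" else _PROTEIN_LETTERS
    for a in letters:
        for b in letters:
            lut[ord(a), ord(b)] = float(mat[a, b])
    ambiguity = "N" if alphabet == "dna" else "BZX"
    scorable = letters + ambiguity
    for c in ambiguity:
        for d in scorable:
            lut[ord(c), ord(d)] = 0.0
            lut[ord(d), ord(c)] = 0.0
    g = ord(GAP)
    for c in scorable:
        lut[g, ord(c)] = -indel_penalty
        lut[ord(c), g] = -indel_penalty
    lut[g, g] = gap_gap_score
    return lut


def score_pair(a: str, b: str, cfg: ScoringConfig = ScoringConfig()) -> float:
    """Score one aligned character pair.

    Residue/residue pairs use BLOSUM62; residue/gap pairs (indels) cost
    ``-indel_penalty``; gap/gap pairs score ``gap_gap_score``; ambiguity
    codes score 0 against anything scorable.
    """
    lut = _pair_lut(cfg.indel_penalty, cfg.gap_gap_score, cfg.alphabet)
    try:
        val = lut[ord(a), ord(b)]
    except (IndexError, TypeError):
        raise ScoringError(f"cannot score character pair ({a!r}, {b!r})") from None
    if np.isnan(val):
        bad = a if np.isnan(lut[ord(a), ord(a)]) else b
        raise ScoringError(
            f"character {bad!r} is not scorable under the {cfg.alphabet} alphabet"
        )
    return float(val)


def _column_scores(mat: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Per-column sums over all unordered row pairs; fixed accumulation order."""
    n = mat.shape[0]
    out = np.zeros(mat.shape[1])
    for i in range(n - 1):
        for j in range(i + 1, n):
            out += lut[mat[i], mat[j]]
    return out


def _score_chunk(args) -> np.ndarray:
    rows, lo, hi, indel, gapgap, alphabet = args
    bact = Bacterium([r[lo:hi] for r in rows])
    return _column_scores(bact.to_matrix(), _pair_lut(indel, gapgap, alphabet))


def blosum_score(bact: Bacterium, cfg: ScoringConfig = ScoringConfig(), pool=None) -> float:
    """Sum-of-pairs BLOSUM62 score of a rectangular alignment.

    With ``cfg.normalize`` the raw sum is divided by the number of pairs,
    ``m * C(n, 2)``.  ``pool`` may be a ``multiprocessing.Pool``; the result
    is identical to the serial computation for any worker count.
    """
    if bact.n < 2:
        raise ScoringError("need at least 2 sequences to score an alignment")
    if not bact.is_rectangular():
        raise ScoringError("alignment must be rectangular; apply cuadra() first")
    m = bact.width
    if m == 0:
        raise ScoringError("degenerate zero-width alignment cannot be scored")
    lut = _pair_lut(cfg.indel_penalty, cfg.gap_gap_score, cfg.alphabet)
    if pool is None:
        col_scores = _column_scores(bact.to_matrix(), lut)
    else:
        nchunks = max(1, getattr(pool, "_processes", 1))
        bounds = np.linspace(0, m, nchunks + 1, dtype=int)
        tasks = [
            (bact.rows, int(lo), int(hi), cfg.indel_penalty, cfg.gap_gap_score, cfg.alphabet)
            for lo, hi in zip(bounds[:-1], bounds[1:])
            if hi > lo
        ]
        col_scores = np.concatenate(pool.map(_score_chunk, tasks))
    if np.isnan(col_scores).any():
        j = int(np.nonzero(np.isnan(col_scores))[0][0])
        col = "".join(r[j] for r in bact.rows)
        raise ScoringError(f"unscorable character in column {j} ({col!r})")
    total = float(np.sum(col_scores))
    if cfg.normalize:
        total /= m * (bact.n * (bact.n - 1) // 2)
    return total


def _blosum_rows(args) -> float:
    """Pool worker: score one bacterium given (rows, cfg)."""
    rows, cfg = args
    return blosum_score(Bacterium(rows), cfg)
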