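"""Swarming: attraction/repulsion interaction, fitness tables, NFE accounting.

Each bacterium k receives an interaction term

    g(cell_k) = sum_i -d_attr * exp(-w_attr * D_ki)
              + sum_i  h_repel * exp(-w_repel * D_ki)

where ``D_ki`` is the squared Euclidean distance between the coordinates of
bacteria k and i, and both sums run over the whole population *including*
i = k (the self-term contributes the constant ``h_repel - d_attr``, harmless
to ranking).  Coordinates embed each bacterium as its scalar sum-of-pairs
score (P = 1): the interaction model was conceived for continuous search
spaces and carries no canonical alignment embedding, so the score axis is
the minimal faithful choice.

Fitness is ``blosum + attract + repel``.  The score tables mirror the
shared, index-disjoint "notebooks" of the parallel design: each worker may
write only its own bacterium's slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Bacterium
from .scoring import ScoringConfig, blosum_score, _blosum_rows

__all__ = [
    "SwarmParams",
    "ScoreTables",
    "StateError",
    "coordinate_of",
    "interaction",
    "record_nfe",
    "fitness_table",
]

NFE_MODES = ("per_interaction", "per_matrix")


class StateError(RuntimeError):
    """An operation needed state (e.g. a cached score) that is absent."""


@dataclass(frozen=True)
class SwarmParams:
    """Attraction/repulsion coefficients.

    Defaults are the shared settings of schemes A-D: attraction depth and
    repulsion height 0.1, attraction width 0.002; the repulsion width is the
    scheme-dependent knob (0.001 for A-D, 0.002 for K, 1 for the elitist
    variant).
    """

    d_attr: float = 0.1
    w_attr: float = 0.002
    h_repel: float = 0.1
    w_repel: float = 0.001

    def __post_init__(self) -> None:
        for name in ("d_attr", "w_attr", "h_repel", "w_repel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ScoreTables:
    """Per-population score tables plus the cumulative evaluation counter."""

    blosum: np.ndarray
    attract: np.ndarray
    repel: np.ndarray
    interaction: np.ndarray
    fitness: np.ndarray
    nfe: int = 0

    @classmethod
    def empty(cls, size: int, nfe: int = 0) -> "ScoreTables":
        z = lambda: np.zeros(size)  # noqa: E731
        return cls(z(), z(), z(), z(), z(), nfe=nfe)

    @property
    def size(self) -> int:
        return len(self.fitness)


def coordinate_of(bact: Bacterium, cfg: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """P=1 coordinate vector: the bacterium's cached sum-of-pairs score."""
    if bact.blosum is None:
        raise StateError("bacterium has no cached score; run the scoring step first")
    return np.array([bact.blosum], dtype=float)


def interaction(
    k: int, coords: list[np.ndarray] | np.ndarray, p: SwarmParams
) -> tuple[float, float]:
    """Attraction and repulsion felt by bacterium ``k`` from the whole swarm.

    Returns ``(attract, repel)`` with ``attract <= 0 <= repel``; the sums
    include the self-term i = k.
    """
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    S = c.shape[0]
    if S == 0:
        raise ValueError("empty population")
    if not 0 <= k < S:
        raise ValueError(f"bacterium index {k} out of range for population {S}")
    d2 = ((c - c[k]) ** 2).sum(axis=1)
    attract = float(-p.d_attr * np.exp(-p.w_attr * d2).sum())
    repel = float(p.h_repel * np.exp(-p.w_repel * d2).sum())
    return attract, repel


def record_nfe(tables: ScoreTables, mode: str, S: int) -> int:
    """Advance the cumulative function-evaluation counter.

    ``per_interaction`` counts one attraction plus one repulsion term per
    ordered bacterium pair (+2*S*S per step); ``per_matrix`` counts one
    evaluation per bacterium alignment matrix (+S per step), the convention
    the elitist variant and the GA share.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if mode == "per_interaction":
        tables.nfe += 2 * S * S
    elif mode == "per_matrix":
        tables.nfe += S
    else:
        raise ValueError(f"unknown NFE mode {mode!r}; expected one of {NFE_MODES}")
    return tables.nfe


def fitness_table(
    bacteria: list[Bacterium],
    cfg: ScoringConfig,
    p: SwarmParams,
    tables: ScoreTables | None = None,
    pool=None,
    nfe_mode: str = "per_interaction",
) -> ScoreTables:
    """Score a whole population: BLOSUM, interaction, fitness, NFE.

    A fresh set of tables is built each call (stale data never accumulates);
    the cumulative NFE of ``tables``, if given, is carried forward.  With a
    process pool the per-bacterium scores are computed in parallel and
    written back in index order, so the fill is identical to the serial one.
    """
    S = len(bacteria)
    if S == 0:
        raise ValueError("empty population")
    out = ScoreTables.empty(S, nfe=tables.nfe if tables is not None else 0)
    if pool is None:
        for k, b in enumerate(bacteria):
            try:
                out.blosum[k] = blosum_score(b, cfg)
            except Exception as exc:
                raise type(exc)(f"bacterium {k}: {exc}") from exc
    else:
        out.blosum[:] = pool.map(_blosum_rows, [(b.rows, cfg) for b in bacteria])
    for k, b in enumerate(bacteria):
        b.blosum = float(out.blosum[k])
    d2 = (out.blosum[:, None] - out.blosum[None, :]) ** 2
    out.attract[:] = -p.d_attr * np.exp(-p.w_attr * d2).sum(axis=1)
    out.repel[:] = p.h_repel * np.exp(-p.w_repel * d2).sum(axis=1)
    out.interaction[:] = out.attract + out.repel
    out.fitness[:] = out.blosum + out.interaction
    record_nfe(out, nfe_mode, S)
    return out
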