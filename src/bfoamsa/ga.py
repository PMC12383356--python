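"""Genetic Algorithm baseline for head-to-head comparison.

Individuals are the same feasible alignment matrices the foraging variants
use.  Selection is roulette-wheel on shifted fitness, recombination is a
two-point column-block crossover followed by a residue re-threading repair
(column swaps between differently gapped parents would otherwise corrupt
the sequences), and mutation inserts or deletes a single gap with
probability ``mutation_prob``.

Fitness is the normalized sum-of-pairs score alone — swarm interaction is a
foraging concept — and cross-algorithm comparison is done on z-scored
traces, which are scale-free.  The cumulative NFE counter includes the
extra evaluation the first selection requires, so for a population of 8 it
runs 16, 24, 32, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, Bacterium, clean_gap_columns, cuadra, tumble
from .optimizers import RunTrace
from .scoring import ScoringConfig
from .swarm import fitness_table, SwarmParams, ScoreTables

__all__ = ["GAConfig", "roulette_select", "two_point_crossover", "mutate", "run_ga"]


@dataclass(frozen=True)
class GAConfig:
    """GA parameters: population 8, 200 generations, mutation 0.3 by default.

    ``init_gaps`` controls how many gaps seed each initial individual; the
    default matches the elitist foraging variant's tumble parameter so both
    phase-3 algorithms start from comparably gapped populations.
    """

    population: int = 8
    generations: int = 200
    mutation_prob: float = 0.3
    crossover: str = "two_point"
    selection: str = "roulette"
    init_gaps: int = 100
    elitism: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be an even number >= 2")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.crossover != "two_point" or self.selection != "roulette":
            raise ValueError("only two_point crossover with roulette selection is supported")


def roulette_select(
    fitnesses, k: int, rng: np.random.Generator, delta: float = 1e-12
) -> list[int]:
    """Draw ``k`` parent indices with probability proportional to shifted fitness.

    Fitness is shifted by its minimum (plus a tiny ``delta``) so negative
    values are legal; an all-equal population degenerates to uniform
    selection.
    """
    f = np.asarray(fitnesses, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if f.size == 0 or not np.isfinite(f).any():
        raise ValueError("need at least one finite fitness")
    shifted = f - np.nanmin(f)
    shifted = np.where(np.isfinite(shifted), shifted, 0.0)
    if shifted.sum() == 0:
        p = np.full(f.size, 1.0 / f.size)
    else:
        p = shifted + delta * max(1.0, float(shifted.max()))
        p = p / p.sum()
    return [int(i) for i in rng.choice(f.size, size=k, p=p)]


def _rethread(pattern: str, residues: str) -> str:
    """Fill a gap pattern with the row's original residues, left to right.

    Surplus slots become gaps; surplus residues are appended at the end, so
    the repaired row always gap-strips back to ``residues``.
    """
    out = []
    pos = 0
    for ch in pattern:
        if ch != GAP and pos < len(residues):
            out.append(residues[pos])
            pos += 1
        else:
            out.append(GAP)
    out.append(residues[pos:])
    return "".join(out)


def two_point_crossover(
    a: Bacterium, b: Bacterium, rng: np.random.Generator
) -> tuple[Bacterium, Bacterium]:
    """Swap the column block [c1, c2) between two parents, then repair.

    Cut points ``c1 < c2`` are drawn uniformly from the common alignment
    width (parents are padded to it first).  Children are repaired by
    re-threading each row's original residues through the child's gap
    pattern, restoring residue conservation, then cleaned of all-gap
    columns.  Alignments narrower than 2 columns are returned unchanged.
    """
    m = max(a.width, b.width)
    pa = cuadra(Bacterium(a.rows + [GAP * m]))  # pad both to the common width
    pb = cuadra(Bacterium(b.rows + [GAP * m]))
    ra, rb = pa.rows[:-1], pb.rows[:-1]
    if m < 2:
        return a.copy(), b.copy()
    c1, c2 = sorted(int(x) for x in rng.choice(m + 1, size=2, replace=False))
    child1 = [x[:c1] + y[c1:c2] + x[c2:] for x, y in zip(ra, rb)]
    child2 = [y[:c1] + x[c1:c2] + y[c2:] for x, y in zip(ra, rb)]
    originals = a.gapstripped()
    kids = []
    for rows in (child1, child2):
        repaired = [_rethread(row, orig) for row, orig in zip(rows, originals)]
        kids.append(clean_gap_columns(cuadra(Bacterium(repaired))))
    return kids[0], kids[1]


def mutate(bact: Bacterium, p: float, rng: np.random.Generator) -> Bacterium:
    """With probability ``p``, insert or delete (coin flip) one random gap.

    The deletion branch falls back to insertion when the matrix holds no
    gaps.  Without mutation the individual is returned as an unmodified
    copy.
    """
    if not 0 <= p <= 1:
        raise ValueError("mutation probability must lie in [0, 1]")
    if rng.random() >= p:
        return bact.copy()
    do_delete = bool(rng.integers(2))
    if do_delete:
        coords = [
            (i, j)
            for i, row in enumerate(bact.rows)
            for j, ch in enumerate(row)
            if ch == GAP
        ]
        if coords:
            i, j = coords[int(rng.integers(len(coords)))]
            rows = list(bact.rows)
            rows[i] = rows[i][:j] + rows[i][j + 1 :]
            return clean_gap_columns(cuadra(Bacterium(rows)))
    return tumble(bact, 1, rng)


def run_ga(
    seqs,
    cfg: GAConfig,
    scoring: ScoringConfig | None = None,
    workers: int = 1,
) -> RunTrace:
    """Generational GA over alignment matrices; returns a per-generation trace."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    if scoring is None:
        scoring = ScoringConfig(normalize=True)
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, loop_ss = ss.spawn(2)
    base = [rec.residues for rec in seqs]
    pop = [
        tumble(Bacterium(list(base)), cfg.init_gaps, np.random.default_rng(child))
        for child in init_ss.spawn(cfg.population)
    ]
    rng = np.random.default_rng(loop_ss)
    # interaction-free evaluation: zero-width swarm terms cancel exactly
    null_swarm = SwarmParams(d_attr=0.0, w_attr=0.0, h_repel=0.0, w_repel=0.0)
    trace = RunTrace(label="ga")
    nfe = 0
    import multiprocessing as mp
    from contextlib import nullcontext
    import time

    if workers > 1:
        method = "fork" if "fork" in mp.get_all_start_methods() else None
        pool_cm = mp.get_context(method).Pool(workers)
    else:
        pool_cm = nullcontext(None)
    t0 = time.monotonic()
    with pool_cm as pool:
        for gen in range(cfg.generations):
            tables = fitness_table(
                pop,
                scoring,
                null_swarm,
                tables=ScoreTables.empty(cfg.population, nfe=nfe),
                pool=pool,
                nfe_mode="per_matrix",
            )
            nfe = tables.nfe
            if gen == 0:  # the initial selection costs one extra sweep
                nfe += cfg.population
            fitness = tables.blosum  # no swarm term in the GA objective
            bi = int(np.argmax(fitness))
            trace.best_fitness.append(float(fitness[bi]))
            trace.best_blosum.append(float(fitness[bi]))
            trace.best_interaction.append(0.0)
            trace.nfe.append(nfe)
            trace.elapsed_s.append(time.monotonic() - t0)
            if trace.best is None or float(fitness[bi]) >= max(trace.best_fitness):
                trace.best = pop[bi].copy()
            parents = roulette_select(fitness, cfg.population, rng)
            nxt: list[Bacterium] = []
            for i in range(0, cfg.population, 2):
                c1, c2 = two_point_crossover(pop[parents[i]], pop[parents[i + 1]], rng)
                nxt.append(mutate(c1, cfg.mutation_prob, rng))
                nxt.append(mutate(c2, cfg.mutation_prob, rng))
            if cfg.elitism:
                nxt[0] = pop[bi].copy()
            pop = nxt
    return trace
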