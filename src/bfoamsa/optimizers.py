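"""The three bacterial-foraging optimizer variants for alignment search.

* ``run_bfoa``   — base loop: tumble (gap insertion), evaluate, reproduce
  (copy the best bacterium over the worst).  The reported best is the best
  of *each iteration*, so the trace may worsen over time — gap load grows
  without bound and the non-elitist reporting exposes the decay.
* ``run_bfoad``  — adds a swim step (random gap deletion, 50 per move in
  the reference scheme K) after each tumble to counter gap saturation.
* ``run_bfoadtp`` — the elitist variant: normalized BLOSUM scores, the top
  ``elitism`` bacteria pass unchanged into the next population, the trace
  reports the global best so far (monotone non-decreasing), and the NFE
  counter advances once per bacterium matrix per iteration.

All randomness flows from ``SchemeConfig.seed`` through numpy seed
sequences; a fixed seed gives an identical trace for any worker count
(wall-clock ``elapsed_s`` excepted).
"""

from __future__ import annotations

import copy
import multiprocessing as mp
import time
from contextlib import nullcontext
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import Bacterium, clean_gap_columns, cuadra, swim, tumble
from .scoring import ScoringConfig
from .seqio import SequenceRecord
from .swarm import ScoreTables, SwarmParams, fitness_table

__all__ = ["SchemeConfig", "RunTrace", "run_bfoa", "run_bfoad", "run_bfoadtp"]


@dataclass(frozen=True)
class SchemeConfig:
    """Full parameterisation of one optimizer run.

    ``tumble`` gaps are inserted per bacterium per chemotaxis step;
    ``swim`` gaps are deleted afterwards (0 disables the swim phase);
    ``elitism`` and ``nfe_mode`` only change behaviour in the elitist
    variant.  ``tumble_each_iteration=False`` restricts gap insertion to
    initialization (an exploratory switch; chemotaxis is then frozen).
    """

    tumble: int = 100
    population: int = 22
    iterations: int = 100
    swim: int = 0
    swarm: SwarmParams = field(default_factory=SwarmParams)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    nfe_mode: str = "per_interaction"
    elitism: int = 1
    seed: int = 0
    tumble_each_iteration: bool = True
    replace_count: int = 1

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.tumble < 0 or self.swim < 0:
            raise ValueError("tumble and swim must be >= 0")
        if self.replace_count < 0:
            raise ValueError("replace_count must be >= 0")

    def with_(self, **kwargs) -> "SchemeConfig":
        return replace(self, **kwargs)


@dataclass
class RunTrace:
    """Per-iteration record of a single optimizer (or GA) run."""

    best_fitness: list[float] = field(default_factory=list)
    best_blosum: list[float] = field(default_factory=list)
    best_interaction: list[float] = field(default_factory=list)
    nfe: list[int] = field(default_factory=list)
    elapsed_s: list[float] = field(default_factory=list)
    best: Bacterium | None = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "best_fitness": self.best_fitness,
                "blosum_score": self.best_blosum,
                "interaction": self.best_interaction,
                "nfe": self.nfe,
                "elapsed_s": self.elapsed_s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "RunTrace":
        df = pd.read_csv(path)
        return cls(
            best_fitness=[float(x) for x in df["best_fitness"]],
            best_blosum=[float(x) for x in df["blosum_score"]],
            best_interaction=[float(x) for x in df["interaction"]],
            nfe=[int(x) for x in df["nfe"]],
            elapsed_s=[float(x) for x in df["elapsed_s"]],
            label=label,
        )


def _init_population(seqs: list[SequenceRecord], cfg: SchemeConfig, ss) -> list[Bacterium]:
    """One bacterium per population slot: inputs tumbled by the tumble parameter.

    Each bacterium draws from an independent stream spawned off the master
    seed, so initialization is reproducible and order-independent.
    """
    base = [rec.residues for rec in seqs]
    streams = ss.spawn(cfg.population)
    return [
        tumble(Bacterium(list(base)), cfg.tumble, np.random.default_rng(child))
        for child in streams
    ]


def _evolve(
    seqs: list[SequenceRecord], cfg: SchemeConfig, elitist: bool, workers: int
) -> RunTrace:
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, loop_ss = ss.spawn(2)
    pop = _init_population(seqs, cfg, init_ss)
    rng = np.random.default_rng(loop_ss)
    trace = RunTrace()
    elite: set[int] = set()
    best_global: tuple[float, float, float, Bacterium] | None = None
    nfe = 0
    t0 = time.monotonic()
    if workers > 1:
        method = "fork" if "fork" in mp.get_all_start_methods() else None
        ctx = mp.get_context(method)
        pool_cm = ctx.Pool(workers)
    else:
        pool_cm = nullcontext(None)
    with pool_cm as pool:
        for _ in range(cfg.iterations):
            for k in range(cfg.population):
                if k in elite:
                    continue
                b = pop[k]
                if cfg.tumble_each_iteration:
                    b = tumble(b, cfg.tumble, rng)
                if cfg.swim:
                    b = swim(b, cfg.swim, rng)
                pop[k] = clean_gap_columns(cuadra(b))
            tables = fitness_table(
                pop,
                cfg.scoring,
                cfg.swarm,
                tables=ScoreTables.empty(cfg.population, nfe=nfe),
                pool=pool,
                nfe_mode=cfg.nfe_mode,
            )
            nfe = tables.nfe
            bi = int(np.argmax(tables.fitness))  # ties -> lowest index
            it_best = (
                float(tables.fitness[bi]),
                float(tables.blosum[bi]),
                float(tables.interaction[bi]),
                pop[bi],
            )
            if elitist:
                if best_global is None or it_best[0] > best_global[0]:
                    best_global = (it_best[0], it_best[1], it_best[2], pop[bi].copy())
                rec = best_global
            else:
                rec = it_best
            trace.best_fitness.append(rec[0])
            trace.best_blosum.append(rec[1])
            trace.best_interaction.append(rec[2])
            trace.nfe.append(nfe)
            trace.elapsed_s.append(time.monotonic() - t0)
            # reproduction: copy the best over the worst (one-for-one default)
            order = np.argsort(tables.fitness, kind="stable")
            for wi in order[: cfg.replace_count]:
                if int(wi) != bi:
                    pop[int(wi)] = copy.deepcopy(pop[bi])
            if elitist and cfg.elitism > 0:
                ranked = np.argsort(-tables.fitness, kind="stable")
                elite = {int(i) for i in ranked[: cfg.elitism]}
        if elitist and best_global is not None:
            trace.best = best_global[3]
        else:
            trace.best = pop[bi].copy()
    return trace


def run_bfoa(seqs: list[SequenceRecord], cfg: SchemeConfig, workers: int = 1) -> RunTrace:
    """Base bacterial foraging run (no swim).  See the module docstring."""
    if cfg.swim != 0:
        raise ValueError("base BFOA requires cfg.swim == 0; use run_bfoad for swim > 0")
    trace = _evolve(seqs, cfg, elitist=False, workers=workers)
    trace.label = "bfoa"
    return trace


def run_bfoad(seqs: list[SequenceRecord], cfg: SchemeConfig, workers: int = 1) -> RunTrace:
    """Gap-deletion variant: swim removes ``cfg.swim`` random gaps per move."""
    if cfg.swim <= 0:
        raise ValueError("BFOAd requires cfg.swim > 0")
    trace = _evolve(seqs, cfg, elitist=False, workers=workers)
    trace.label = "bfoad"
    return trace


def run_bfoadtp(seqs: list[SequenceRecord], cfg: SchemeConfig, workers: int = 1) -> RunTrace:
    """Elitist variant: normalized scores, elitism, global-best reporting,
    per-matrix NFE counting.  The best-fitness trace is monotone
    non-decreasing by construction."""
    if not cfg.scoring.normalize:
        raise ValueError("BFOAdtp requires normalized scoring (cfg.scoring.normalize)")
    if cfg.elitism < 1:
        raise ValueError("BFOAdtp requires elitism >= 1")
    if cfg.nfe_mode != "per_matrix":
        raise ValueError("BFOAdtp counts NFE per matrix (cfg.nfe_mode='per_matrix')")
    trace = _evolve(seqs, cfg, elitist=True, workers=workers)
    trace.label = "bfoadtp"
    return trace
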