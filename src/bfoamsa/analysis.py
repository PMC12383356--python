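"""Post-run analysis: z-standardization, convergence, NFE-to-threshold, stats.

Raw fitness traces from different algorithms differ in magnitude and
variance, so each run k is standardized with its own mean and standard
deviation, z_{k,t} = (f_{k,t} - mu_k) / sigma_k, before overlaying or
averaging.  Convergence speed is summarised as the first iteration whose
running-best fitness reaches a fraction (typically 95%) of the run's best.
Two algorithms are compared on evaluations-to-quality by pooling all
per-run best fitnesses, taking the pooled median as the threshold of
interest (tHi) and reading off each run's cumulative NFE at first
threshold crossing; runs that never reach tHi are discarded.

The 30-run statistical comparison is a thin layer over scipy: Shapiro-Wilk
normality gates a Welch t-test versus Mann-Whitney U, and Cohen's d (pooled
SD) quantifies effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .optimizers import RunTrace

__all__ = [
    "RunSet",
    "ConstantTraceError",
    "ComparisonReport",
    "ThresholdResult",
    "zscore_trace",
    "mean_zcurve",
    "convergence_iteration",
    "threshold_nfe",
    "compare_runs",
    "plot_zcurves",
    "plot_nfe_boxplot",
]


class ConstantTraceError(ValueError):
    """Standardization is undefined for a zero-variance trace."""


def _values(trace) -> np.ndarray:
    if isinstance(trace, RunTrace) or hasattr(trace, "best_fitness"):
        return np.asarray(trace.best_fitness, dtype=float)
    return np.asarray(trace, dtype=float)


@dataclass
class RunSet:
    """A labelled collection of runs (typically 30) of one algorithm."""

    traces: list[RunTrace]
    label: str = ""
    scheme: object | None = None

    def __post_init__(self) -> None:
        if self.traces and len({len(t) for t in self.traces}) > 1:
            raise ValueError("all traces in a RunSet must have the same length")

    def __len__(self) -> int:
        return len(self.traces)

    def best_fitnesses(self) -> np.ndarray:
        """Per-run best (maximum) fitness."""
        return np.array([float(np.max(_values(t))) for t in self.traces])


def zscore_trace(trace, ddof: int = 0) -> np.ndarray:
    """Standardize one run with its own mean and (population) std.

    Raises :class:`ConstantTraceError` when the trace has zero variance.
    """
    f = _values(trace)
    if f.size < 2:
        raise ValueError("need at least 2 iterations to standardize")
    sigma = float(np.std(f, ddof=ddof))
    if sigma == 0:
        raise ConstantTraceError("constant trace: standard deviation is zero")
    return (f - float(np.mean(f))) / sigma


def mean_zcurve(runs: RunSet | Sequence, ddof: int = 0) -> np.ndarray:
    """Elementwise mean of the per-run z-curves."""
    traces = runs.traces if isinstance(runs, RunSet) else list(runs)
    if not traces:
        raise ValueError("need at least one run")
    curves = []
    for k, t in enumerate(traces):
        try:
            curves.append(zscore_trace(t, ddof=ddof))
        except ConstantTraceError as exc:
            raise ConstantTraceError(f"run {k}: {exc}") from exc
    return np.mean(np.stack(curves), axis=0)


def convergence_iteration(trace, frac: float = 0.95) -> int:
    """First iteration whose running-best fitness reaches ``frac`` of the best.

    Thresholding uses the running maximum, so later decay (the non-elitist
    variants routinely worsen past ~150 iterations) cannot undo a crossing.
    When the trace contains non-positive values the fitness is min-max
    normalized first — a 95%-of-best criterion is ill-defined for scores
    that cross zero.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    f = _values(trace)
    if f.size == 0:
        raise ValueError("empty trace")
    if f.min() <= 0:
        span = f.max() - f.min()
        if span == 0:
            return 0
        f = (f - f.min()) / span
    running = np.maximum.accumulate(f)
    return int(np.argmax(running >= frac * f.max()))


@dataclass
class ThresholdResult:
    """Outcome of the tHi evaluations-to-quality comparison."""

    thi: float
    nfe_a: list[int]
    nfe_b: list[int]
    discarded_a: int = 0
    discarded_b: int = 0


def _nfe_at_threshold(trace: RunTrace, thi: float) -> int | None:
    f = _values(trace)
    hit = np.nonzero(f >= thi)[0]
    if hit.size == 0:
        return None
    return int(trace.nfe[int(hit[0])])


def threshold_nfe(set_a: RunSet, set_b: RunSet) -> ThresholdResult:
    """Pooled-median threshold (tHi) and per-run NFE at first crossing.

    The threshold is the median of the pooled per-run best fitnesses of
    both sets (even pool -> midpoint of the two central order statistics).
    Runs whose best never reaches tHi are discarded and only counted.
    """
    if not len(set_a) or not len(set_b):
        raise ValueError("both run sets must be non-empty")
    pooled = np.concatenate([set_a.best_fitnesses(), set_b.best_fitnesses()])
    thi = float(np.median(pooled))
    out = ThresholdResult(thi=thi, nfe_a=[], nfe_b=[])
    for t in set_a.traces:
        nfe = _nfe_at_threshold(t, thi)
        if nfe is None:
            out.discarded_a += 1
        else:
            out.nfe_a.append(nfe)
    for t in set_b.traces:
        nfe = _nfe_at_threshold(t, thi)
        if nfe is None:
            out.discarded_b += 1
        else:
            out.nfe_b.append(nfe)
    return out


@dataclass
class ComparisonReport:
    """Two-sample comparison: normality gate, test choice, p-value, effect size."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    test: str
    p_value: float
    cohens_d: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["significant"] = self.significant
        return d


def cohens_d(a, b) -> float:
    """Effect size (mean_b - mean_a) / pooled sample SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0
        raise ValueError("Cohen's d undefined: zero variance in both samples")
    return float((np.mean(b) - np.mean(a)) / np.sqrt(pooled))


def compare_runs(a, b, alpha: float = 0.05) -> ComparisonReport:
    """Shapiro-gated two-sample comparison with Cohen's d.

    Both samples normal by Shapiro-Wilk (p > alpha) -> Welch t-test;
    otherwise Mann-Whitney U.  Cohen's d is always reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must have at least 3 observations")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # a constant sample is treated as non-normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > alpha and pb > alpha:
        test = "welch_t"
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test = "mann_whitney_u"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ComparisonReport(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        shapiro_p_a=pa,
        shapiro_p_b=pb,
        test=test,
        p_value=p,
        cohens_d=cohens_d(a, b),
        alpha=alpha,
    )


def plot_zcurves(runsets: Sequence[RunSet], path) -> None:
    """Overlay the mean z-curves of several run sets (convergence figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for rs in runsets:
        ax.plot(mean_zcurve(rs), label=rs.label or "runs")
    ax.set_xlabel("iteration / generation")
    ax.set_ylabel("mean standardized fitness (z)")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_nfe_boxplot(result: ThresholdResult, labels: tuple[str, str], path) -> None:
    """Boxplot of per-run NFE at the tHi crossing (one-sided boxes are legal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    data, ticks = [], []
    for vals, lab in zip((result.nfe_a, result.nfe_b), labels):
        if vals:
            data.append(vals)
            ticks.append(lab)
    if data:
        ax.boxplot(data, tick_labels=ticks)
        for i, vals in enumerate(data, start=1):
            ax.scatter([i] * len(vals), vals, s=12, alpha=0.6)
    ax.set_ylabel(f"NFE to reach tHi = {result.thi:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
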