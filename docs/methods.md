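# Methods

## Problem and representation

Multiple sequence alignment is treated as direct search over complete
alignment matrices: a candidate ("bacterium") is the list of input
sequences with gaps inserted, kept rectangular by trailing-gap padding
(`cuadra`) and stripped of all-gap columns (`clean_gap_columns`). All move
operators — tumble (gap insertion), swim (gap deletion), GA crossover with
re-threading repair, single-gap mutation — conserve each row's gap-stripped
residue string, so feasibility never needs checking downstream. No guide
tree or progressive decomposition is used; the whole matrix is the search
variable.

## Objective

The score of an alignment is the sum over columns of BLOSUM62 scores over
all unordered row pairs, with

* residue/gap (indel) pairs: −0.1 each,
* gap/gap pairs: 0 (such columns carry no pair information; fully gapped
  columns are removed anyway),
* ambiguity codes scored 0 against anything: `N` under the DNA alphabet,
  `B/Z/X` under protein. Protein `N` (asparagine) is a real residue and is
  scored from BLOSUM62.

DNA is scored with the same BLOSUM62 lookup on A/C/G/T — which are all
valid amino-acid codes — so one evaluator serves both sequence types. This
is a modelling quirk inherited from the algorithm family this package
implements, not a claim that BLOSUM62 is a sensible nucleotide model;
conclusions about DNA alignment quality should be drawn accordingly.

The "normalized" score used by the elitist variant is the mean per-pair
score (raw sum divided by m·C(n,2)). The mean is stable under alignment
widening, which matters because tumble grows m every iteration.

Scoring is vectorised through a 128×128 lookup table indexed by character
codes. Per-column scores are accumulated over row pairs in a fixed order
and reduced with one `np.sum`; when a process pool is supplied the column
range is chunked contiguously and the per-column arrays concatenated before
the same reduction, so parallel and serial results are bit-identical. The
population-level parallelism (one worker per bacterium, results written to
index-disjoint table slots) is likewise order-independent.

## Swarm interaction

Bacterium k receives

    g_k = Σ_i −d_attr·exp(−w_attr·D_ki) + Σ_i h_repel·exp(−w_repel·D_ki)

with the sums over the whole population including i = k; the self-term adds
the constant h_repel − d_attr and is retained so the implementation matches
the formula's stated bounds exactly (tests rely on this). The embedding of
an alignment into the distance computation is deliberately minimal: each
bacterium's coordinate is its scalar sum-of-pairs score (P = 1). The
interaction model was formulated for continuous search spaces and admits no
canonical alignment embedding; the scalar-score choice keeps the attraction
toward high-scoring regions and the crowding repulsion meaningful while
adding no arbitrary geometry. With w_attr = w_repel and d_attr = h_repel
the two sums cancel identically — a closed-form invariant used as a test.

Defaults (d_attr = 0.1, w_attr = 0.002, h_repel = 0.1) are shared by all
named schemes; w_repel is the scheme knob: 0.001 (schemes A–D), 0.002
(scheme K), 1 (elitist scheme), larger values narrowing the repulsion
kernel and so increasing dispersion.

## Optimizer loops

Initialization inserts `tumble` gaps into each bacterium (independent
per-bacterium seed streams spawned from the master seed). Each iteration:
fresh score tables (no stale data), tumble each bacterium by `tumble`
gaps, optionally swim (`swim` deletions), clean, evaluate, then copy the
best bacterium over the worst (one-for-one; the count is a config knob).
Ties in best/worst selection break toward the lowest index for
determinism. Tumbling is re-applied every iteration — chemotaxis must move
bacteria each step — with an `tumble_each_iteration=False` switch for
init-only exploration. No elimination–dispersal phase is implemented: the
developed algorithm this package follows has none.

The base loop (`run_bfoa`) reports each *iteration's* best. Because gap
load grows without bound and reporting is non-elitist, traces routinely
worsen after an early peak; this decay is a documented behaviour, not a
bug, and motivates the elitist variant.

`run_bfoad` adds the swim deletions (50 per move in scheme K), bounding
gap saturation at the cost of extra work per move.

`run_bfoadtp` changes four things: scores are normalized; the `elitism`
best bacteria (default 1) pass unchanged into the next population; the
reported best is the global best so far, so its trace is monotone
non-decreasing; and NFE is counted once per bacterium matrix per iteration
(+S per step) instead of once per attraction/repulsion term (+2·S² per
step). `Swim = 1` in its scheme is read as one gap deletion per move.

## Genetic Algorithm baseline

Population 8, 200 generations, roulette selection on min-shifted fitness
(a δ = 1e−12 floor makes zero-weight individuals selectable and degenerates
to uniform selection when all fitnesses tie), two-point column-block
crossover, mutation probability 0.3 (one gap insertion or deletion, coin
flip, deletion falling back to insertion on gap-free matrices),
generational replacement (elitism available behind a flag, off by
default). The chromosome encoding is this package's reconstruction: the
alignment matrix itself, with crossover swapping a column block and then
re-threading each row's original residues through the child's gap pattern —
surplus slots become gaps, surplus residues append at the end — which
restores feasibility exactly.

GA fitness is the normalized BLOSUM score alone; the swarm interaction is
a foraging concept. Cross-algorithm comparisons use z-standardized traces,
which are scale-free, so the differing fitness definitions do not bias the
overlay. GA initialization is not prescribed anywhere; individuals start
as the inputs with `init_gaps` (default 100, the elitist variant's tumble
value) random gap insertions so both phase-3 algorithms begin from
comparably gapped populations. The GA's cumulative NFE includes the extra
evaluation sweep the first selection requires: 16 → 24 → 32 → … for
population 8.

## Analysis layer

* `zscore_trace`: per-run standardization (f − μ)/σ with the *population*
  σ by default (ddof exposed); constant traces raise rather than return
  NaNs.
* `convergence_iteration`: first iteration whose running-best fitness
  reaches `frac` (default 0.95) of the run's best; when a trace contains
  non-positive values it is min-max normalized first, since a fractional
  threshold is ill-defined across zero.
* `threshold_nfe`: pools both algorithms' per-run best fitnesses, takes
  the median (even pool → midpoint of central order statistics) as the
  threshold of interest, and reports each run's cumulative NFE at first
  crossing; runs that never cross are discarded and counted. One-sided
  results (every run of one set discarded) are legal.
* `compare_runs`: Shapiro–Wilk on both samples gates Welch's t-test
  (both p > 0.05) versus Mann–Whitney U; Cohen's d with pooled sample SD
  is always reported; α = 0.05 throughout. A constant sample is treated as
  non-normal rather than letting Shapiro–Wilk fail.

## Synthetic families

`generate_family` draws one uniform-random ancestor and derives each
descendant independently: per-site substitution with probability
`substitution_rate` (resampling uniformly over the alphabet, so the
realised per-site change rate is rate·(|Σ|−1)/|Σ|), and indel events with
probability `indel_rate` per site, each a geometric-length (p = 0.5,
truncated at `max_indel_len`) insertion or deletion. Defaults — 4
sequences, 60-residue ancestor, 5% substitutions, 2% indels — give compact
families with enough shared signal for a gap-placement optimizer to climb.
There is no phylogeny, no rate heterogeneity and no domain structure, so
passing tests demonstrate the algorithms' mechanics and contracts, not
alignment quality on real homolog sets; absolute fitness values on real
data are outside what this generator can speak to. Three frozen families
(synthetic, generated by this module) ship under `bfoamsa/data/` for
quick-start examples.

## Numerical and reproducibility choices

* All randomness flows through numpy `SeedSequence` spawning; a fixed seed
  yields identical traces for any worker count. Wall-clock `elapsed_s` is
  recorded from a monotonic clock and is the one trace column excluded
  from determinism guarantees and tests.
* Gap insertion positions are uniform over (row, position 0..len
  inclusive); deletion positions uniform over existing gaps without
  replacement.
* The indel penalty is applied by subtraction (−0.1 per indel pair), the
  only reading consistent with a maximized score.
* Process pools use the fork start method where available and fall back to
  the platform default.

## Problem sizes used in tests and the acceptance script

The reference experiments behind the named schemes run for 10⁴–10⁵ seconds
on large NCBI homolog sets; this package's own validation uses the
synthetic families at reduced sizes chosen as its demonstration scale:
populations 4–8, 20–120 iterations, 6–12 runs per set. The acceptance
script's head-to-head uses the elitist scheme's Table-values (population 8,
tumble 100, swim 1, w_repel 1) with 120 iterations × 12 runs. At this
scale, on a 60-residue family, the GA reaches the pooled-median threshold
while the elitist forager — inserting 100 gaps per move and deleting one —
freezes on its early best and is discarded; the structural signatures
(monotone elitist traces, decaying non-elitist traces, the NFE ledgers,
z-curve shapes) are reproduced, but which algorithm wins the
evaluations-to-quality race at full scale on real homolog sets is not
decidable from this demo.

## Known limitations

* P = 1 coordinate embedding is a modelling choice; richer embeddings
  (e.g. per-column score vectors) would change interaction geometry.
* BLOSUM62-on-DNA is kept for fidelity, not recommended practice.
* The GA is intentionally un-tuned beyond its reference parameters.
* No affine gap penalties, alternative substitution matrices, or
  distributed (multi-node) execution.
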