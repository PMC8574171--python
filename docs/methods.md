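# Methods

This note records the models, numerical choices and open design decisions
behind `equiphen`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

A `CountMatrix` holds non-negative genes × cells copy numbers with a stage
tag (`raw` → `prenormalized` → `normalized`). A zero is interpreted as the
gene's OFF state at harvest time under bursting transcription, never as a
measured low level. Consequently every level estimate in the package is a
*non-zero mean* — the average over cells in which the gene is ON — and
every abundance statement is paired with the *ON-state frequency*, the
percentage of cells detecting the transcript. Printed percentages are
rounded half away from zero to one decimal. Gene symbols are matched
case-insensitively everywhere (reference lists are often human-cased while
matrices are murine); no ortholog mapping is attempted and unmatched
symbols are reported rather than dropped.

## Reference selection

The cascade takes the `k_frequent = 1000` genes with the highest ON count,
pre-normalizes cells against their non-zero averages with the same RMSD fit
used for final normalization, keeps the `k_stable = 500` genes with the
lowest cross-cell standard deviation, and retains those detected in both
groups with a group-wise non-zero-mean ratio strictly below
`fold_threshold = 10`. Deliberate choices:

- **Tie-breaking** in both top-k selections is by larger total expression,
  then lexicographic symbol, so output is deterministic.
- **Stability SD** is computed over non-zero values only by default,
  consistent with the non-zero averaging used everywhere else;
  `stability_mode="all"` includes zeros. Genes ON in fewer than 3 cells are
  excluded from the stability ranking (their SD estimate is meaningless).
- **"Less than tenfold"** is strict (`<`); a ratio of exactly 10 fails the
  balance filter, and genes absent from either group are excluded.
- The balance filter operates on the pre-normalized matrix, as it follows
  pre-normalization in the procedure.

## Normalization

The per-cell factor minimizes the root-mean-square deviation between the
scaled reference counts and the reference targets, restricted to reference
genes detected in the cell. Zeros carry no scale information (they are OFF
states), so they are excluded from the fit. The objective is least squares
through the origin — strictly convex with unique minimizer
`f = Σ x·μ / Σ x²` — computed in closed form; grid searches exist only as
independent test oracles. Cells detecting no reference gene default to
`policy="flag"` (kept, factor 1, reported) so cell counts match the input;
`policy="drop"` removes them.

Two properties worth knowing:

- The fit is unweighted, so reference genes with the largest counts
  dominate it. This is tolerable for the final fit (reference genes are
  selected for stability) but makes the *pre*-normalization factor noisy —
  a real limitation of the procedure, visible in the simulation.
- Targets are arithmetic cross-cell averages while the factor is an inverse
  scale, so the factors' geometric mean exceeds 1 by the Jensen gap
  AM/GM of the capture factors. The tests check that no drift occurs
  beyond that predictable gap.

The QC check computes the Pearson correlation between per-cell detected
gene counts (invariant under positive rescaling) and per-cell normalized
copy sums; a clearly positive value indicates the factors put cells on a
common scale. With zero variance in either vector the correlation is
reported as undefined rather than as a number.

## ON/OFF statistics

Frequency bins use unrounded frequencies with edges (50, 10): [50, 100],
[10, 50), (0, 10) — the only reading under which the three bands partition
detected genes; never-detected genes are counted separately. The two-group
comparison of per-cell gene-set counts uses the pooled-variance two-sample
t-test (Welch by option); each group's Shapiro–Wilk normality check at
α = 0.05 is recorded but never switches the test automatically. The
frequency/copy-number association uses Spearman rank correlation with
average ranks and the large-sample two-sided p. No multiple-testing
correction is applied to the per-gene summaries.

## Classification

Over the two groups a gene is *undetected* (ON in neither), *specific* (ON
in exactly one), *enriched* (ON in both, non-zero-mean ratio strictly
greater than 10), or *even* (otherwise). A ratio of exactly 10 is classed
even: "less than tenfold" defines even and "more than tenfold" defines
enriched, leaving the boundary to the weaker claim. No minimum ON-cell
support is imposed for specific labels, but support counts are always
reported so users can filter. Published per-column gene lists can be fed
through the same table builder via `classes_from_assignments`.

The reliability analysis shuffles cell group labels uniformly (preserving
group sizes, 1,000 permutations by default), recomputes the classification,
and reports per-label null distributions with add-one empirical p-values
`(1 + #{null ≥ observed}) / (1 + n)`, plus a combined `differential`
(specific + enriched) count. The exact construction of the original
randomized comparison is not published; this size-preserving label shuffle
is this package's documented reconstruction.

### Calibration experiment

`permutation_calibration` draws exchangeable data sets (both groups share
all gene parameters; unit size factor), runs the permutation analysis, and
collects the differential-count p-values, whose distance from uniformity is
summarized by the Kolmogorov–Smirnov statistic. Because the statistic is an
integer count, its p-values are slightly conservative and lattice-valued;
the experiment therefore uses many genes and few cells (default 1,500
genes, 10 + 10 cells, 399 permutations, 200 repeats) so the null count
spreads over enough values for the uniformity check to be meaningful.
Observed KS distances are ≈ 0.04–0.09.

## The synthetic-data generator

The generator emulates the statistical structure of two-group patch-seq
data at desk scale so the whole pipeline is testable with ground truth:

- **Bursting**: gene g in cell c of group t is ON with probability
  `p_on(g, t)`; an ON gene holds `L` transcripts, lognormal with mean
  `m(g, t)` and log-SD `burst_dispersion` (negative binomial by option).
- **Capture**: each transcript of an ON burst is recovered independently,
  so the observed count is `Poisson(s_c · L)`; an ON burst can be observed
  as zero. The capture factor `s_c` is lognormal (median 0.3, log-SD 0.5)
  times a deterministic 2× for the first group (pyramidal-like cells carry
  about twice the mRNA). Truth records both the drawn burst states and the
  effective (observed) ON states, which agree with observed zeros by
  construction.
- **Breadth**: a per-cell lognormal factor (unit mean, log-SD 0.35)
  multiplies every gene's ON probability (clipped at 1), reproducing the
  strong cell-to-cell variation in the number of detected genes seen in
  real data; the truth stores the realized per-gene marginal ON
  probabilities for calibration checks.
- **Planted classes** (default fractions): housekeeping 0.40, even 0.24,
  enriched 0.08, specific 0.08 + 0.05, rare 0.15. Housekeeping genes are
  near-constitutive (p_on 0.85–1), low-dispersion (log-SD 0.1), with means
  30–150 — the planted "equi-phenotype" core. For all other classes the
  burst mean is coupled to the ON probability on a log scale (range 5–1500,
  with scatter shrinking from 1.0 at p_on = 0 to 0.2 at p_on = 1): rarely
  bursting genes span orders of magnitude while frequently detected genes
  are invariably high-copy, giving the positive frequency/copy-number
  association characteristic of bursty transcriptomes. Enriched genes carry
  group mean ratios 15–100; even genes at most 3.
- **Scale**: 59 + 25 cells and 2,000 genes by default — a tractable
  stand-in for the real ~19,000-gene transcriptome. The published selection
  sizes (1,000 / 500) are kept, so the planted stable core (800 genes) is
  sized commensurately with them. The housekeeping means sit at the low end
  of the frequent genes' mean range deliberately: the unweighted RMSD
  pre-normalization leaves shared multiplicative noise that makes every
  gene's cross-cell SD roughly proportional to its mean, so under the
  absolute-SD stability criterion a recoverable stable core must also be
  the low-SD end of the frequent genes. This mirrors the real premise that
  the stable metabolic core is moderately high-copy while the extreme
  expressors are bursty and variable.
- **Randomness**: one counter-based stream (Philox) per (seed, gene), so
  subsetting or reordering genes never perturbs other genes' draws;
  cell-level factors and gene parameters use separate child streams of the
  master seed.

What the generator does **not** emulate: amplification chemistry and
read-level noise, spike-ins, batch or donor structure, gene–gene
correlation (co-regulation), ortholog mismatches, and any biological
pathway structure. Passing tests therefore demonstrate that the pipeline's
inference is correct under its own generative assumptions — not that those
assumptions capture every property of real patch-seq data.

## Problem sizes and numerics

Simulation-based checks run at 84–100 cells × 2,000 genes (selection,
normalization, classification recovery), 500 cells × 400 genes (size-effect
check, symmetric gene parameters to isolate the 2× factor), and 200
repeats × 1,500 genes × 20 cells (permutation calibration) — sizes chosen
so the full suite and the acceptance script each complete in about a minute
on one CPU. Grid-search oracles refine a 4,000-point coarse log grid to a
1e-4 step around the bracket. Degenerate inputs (all-zero matrices, cells
without reference genes, constant vectors in correlations, zero-variance
groups) raise informative errors or return flagged "undefined" results
rather than NaN.

## Known limitations

- The pre-normalization factor inherits the unweighted RMSD fit's
  sensitivity to the largest counts; a weighted or log-scale fit would be
  more robust but would depart from the published procedure.
- Symbol matching across species is by case-insensitive string equality
  only; genuinely diverged orthologs will be reported unmatched.
- The permutation reliability analysis calibrates label *counts*; it does
  not provide per-gene differential-expression p-values, and none are
  claimed.
- The packaged 186-entry antimicrobial-peptide reference list is a
  synthetic stand-in (100 published detected symbols plus 86 synthetic
  placeholders) preserving the list's size and coverage arithmetic; it is
  not the original database.
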