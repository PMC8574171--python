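# equiphen

Reference-gene normalization and ON/OFF-state expression analysis for
patch-seq single-cell count matrices.

## The problem

Patch-seq couples whole-cell electrophysiology with ultra-deep sequencing of
the harvested cytoplasm, yielding absolute-scale transcript copy numbers for
a small number of deeply characterized neurons (here: two cortical groups,
pyramidal cells and fast-spiking interneurons, 59 + 25 cells). Two features
make these matrices hostile to standard normalization: per-cell capture and
harvest efficiency vary strongly, and transcription is bursty, so most genes
show exact zeros in most cells — a zero is best read as the gene being in
its OFF state at harvest, not as a low expression level. Bulk-style size
factors and fixed housekeeping panels both fail here, because even classic
housekeeping genes are OFF in some cells.

`equiphen` implements the alternative: discover an "equi-phenotype"
reference set empirically, fit each cell's scale factor against it, and
summarize expression with ON-state statistics.

## Method

**Reference discovery** (`ReferenceGeneSelector`, `equiphen.reference`):

1. keep the $k_1 = 1000$ genes detected in the most cells;
2. pre-normalize each cell against those genes' cross-cell non-zero
   averages;
3. keep the $k_2 = 500$ genes with the lowest cross-cell standard
   deviation;
4. keep genes detected in both groups whose group-wise non-zero means
   differ by strictly less than tenfold.

**Normalization** (`RmsdNormalizer`, `equiphen.normalize`): for a cell with
reference counts $x_g$ and reference targets $\mu_g$ (averages of non-zero
values), the factor is the minimizer of

$$\mathrm{RMSD}(f) = \sqrt{\tfrac1n \sum_{g:\,x_g>0} (f x_g - \mu_g)^2},$$

restricted to reference genes detected in the cell. The objective is
strictly convex with the closed form $f = \sum x_g\mu_g / \sum x_g^2$. As a
quality check, the per-cell sum of normalized copies should correlate
positively with the number of detected transcripts.

**ON/OFF statistics and classification** (`equiphen.stats`,
`equiphen.classify`): per gene and group, the ON-state frequency (share of
cells detecting the transcript) and the non-zero mean (copy number in the
ON state). Genes of a study set are classed *even* (non-zero mean ratio
$\le 10$ between groups), *enriched* (ratio $> 10$, detected in both), or
*specific* (detected in exactly one group); a label-shuffling permutation
analysis calibrates how many such labels arise by chance.

**Gene-set coverage and networks** (`equiphen.genesets`): fraction of a
reference list (e.g. an antimicrobial-peptide database) detected anywhere
in the cells, frequency bins (≥50%, 10–49%, <10%), per-cell set counts
with a two-sample t-test between groups, and export of score-filtered
interaction networks with ON-frequency node attributes.

**Synthetic data** (`equiphen.simulate`): a telegraph-style generator —
per (gene, cell) Bernoulli ON states, lognormal burst sizes, Poisson
molecule capture with per-cell efficiency, a 2× cell-type size effect, and
planted housekeeping / even / enriched / specific / rare gene classes — so
every stage is testable with ground truth and no external data.

The selector and normalizer are scikit-learn estimators and compose with
`sklearn.pipeline.Pipeline`; everything is equally reachable through plain
functions and the `equiphen` command-line interface
(`simulate`, `select-refs`, `normalize`, `summarize`, `classify`,
`reliability`, `coverage`, `pipeline run`).

## Worked example

```python
import numpy as np
from equiphen import (default_paperlike_config, simulate, select_reference_genes,
                      normalize_matrix, qc_correlation, classify_genes,
                      build_classification_table, coverage, GeneSet)

config = default_paperlike_config(seed=1)
matrix, cells, truth = simulate(config)
print(f"simulated {matrix.n_genes} genes x {matrix.n_cells} cells "
      f"({(matrix.values == 0).mean():.0%} zeros)")

refs, _ = select_reference_genes(matrix, cells)
print(f"reference set: {len(refs)} genes")

result = normalize_matrix(matrix, refs)
qc = qc_correlation(result)
print(f"QC: Pearson r(detected, copy sum) = {qc.pearson_r:.3f}")

rng = np.random.default_rng(0)
study_set = GeneSet("study_set", list(rng.choice(matrix.gene_ids, 200, replace=False)))
table = build_classification_table(classify_genes(result.matrix, cells, study_set))
print(f"{table.n_detected} detected: even {table.even_pct}%, "
      f"enriched {table.enriched_pct}%, specific {table.specific_pct}%")
rep = coverage(result.matrix, study_set)
print(f"coverage: {rep.n_detected}/{rep.n_reference} = {rep.coverage_pct}%")
```

prints

```
simulated 2000 genes x 84 cells (52% zeros)
reference set: 500 genes
QC: Pearson r(detected, copy sum) = 0.745
192 detected: even 64.1%, enriched 7.8%, specific 28.1%
coverage: 192/200 = 96.0%
```

The 84 simulated cells carry bursty, zero-inflated counts; the cascade
recovers a 500-gene stable reference core; the positive QC correlation
shows the fitted factors put cells on a common copy-number scale; and the
random 200-gene study set splits into evenly expressed, cell-type-enriched
and cell-type-specific transcripts, with 96% of it detected somewhere in
the 84 cells even though each single cell transcribes far less.

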