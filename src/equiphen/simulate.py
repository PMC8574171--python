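"""Synthetic patch-seq count matrices from a two-state bursting model.

Each gene switches between a transcriptionally silent OFF state and an ON
state (telegraph-style kinetics observed at a single harvest time): in cell
``c`` of group ``t``, gene ``g`` is ON with probability ``p_on(g, t)`` and
then holds ``L`` transcripts, a positive burst-size draw with mean
``m(g, t)`` and configurable dispersion.  Harvest and amplification capture
each molecule independently, so the observed raw count is
``Poisson(s_c * L)`` where ``s_c`` is the cell's capture/size factor; an ON
burst whose molecules are all missed is observed as zero.  OFF genes
contribute exact zeros.  Together these produce the heavily zero-inflated
matrices characteristic of patch-seq data, with per-cell detection breadth
(genes detected per cell) varying with capture efficiency, as in the real
experiments.  The capture factor combines lognormal noise with a
deterministic cell-type size effect (the first group's cells yield
``type_size_factor`` times more captured mRNA, emulating the larger soma of
pyramidal cells).

Genes belong to planted classes so every downstream stage has ground truth:

* ``housekeeping`` — high ON probability, moderate-to-high mean, low
  dispersion, identical in both groups: the planted "equi-phenotype" core
  that reference selection should recover.
* ``even`` — balanced between groups (mean ratio below the fold threshold).
* ``enriched`` — ON in both groups with a mean ratio above the threshold.
* ``specific_a`` / ``specific_b`` — ON probability zero in the other group.
* ``rare`` — very low ON probability in both groups.

For the non-housekeeping classes the burst mean is coupled to the ON
probability on a log scale, with scatter shrinking as the ON probability
grows: rarely bursting genes span copy numbers from below one to hundreds,
while near-constitutive genes are invariably high-copy.  This reproduces
the positive frequency/copy-number association seen in real single-cell
data, where sustained ON states come from frequent bursting and therefore
high mean copy numbers.

Randomness is split by a counter-based generator keyed per (seed, gene), so
subsetting or reordering genes never perturbs other genes' draws.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix, GeneSet
from . import _tables

CLASSES = ("housekeeping", "even", "enriched", "specific_a", "specific_b", "rare")

_DEFAULT_FRACTIONS: dict[str, float] = {
    "housekeeping": 0.40,
    "even": 0.24,
    "enriched": 0.08,
    "specific_a": 0.08,
    "specific_b": 0.05,
    "rare": 0.15,
}

_DEFAULT_P_ON: dict[str, tuple[float, float]] = {
    "housekeeping": (0.85, 1.0),
    "even": (0.05, 0.6),
    "enriched": (0.1, 0.6),
    "specific_a": (0.1, 0.65),
    "specific_b": (0.1, 0.65),
    "rare": (0.005, 0.05),
}


@dataclasses.dataclass
class SimulationConfig:
    """Study-scale defaults: 59 + 25 cells, 2,000 genes, 2x cell-type size effect."""

    n_cells_a: int = 59
    n_cells_b: int = 25
    n_genes: int = 2000
    class_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    p_on_ranges: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_P_ON)
    )
    burst_mean_range: tuple[float, float] = (5.0, 1500.0)
    housekeeping_mean_range: tuple[float, float] = (30.0, 150.0)
    # log-scale scatter around the p_on/mean trend at p_on = 0 and p_on = 1:
    # rare genes span orders of magnitude, constitutive genes are tightly
    # high-copy.
    mean_coupling_sd: tuple[float, float] = (1.0, 0.2)
    burst_dispersion: float = 0.7  # log-scale SD of burst sizes
    housekeeping_dispersion: float = 0.1
    enrichment_ratio_range: tuple[float, float] = (15.0, 100.0)
    even_ratio_range: tuple[float, float] = (1.0, 3.0)
    type_size_factor: float = 2.0  # group A cells yield this much more mRNA
    capture_median: float = 0.3  # median per-cell capture fraction
    capture_sd: float = 0.5  # log-scale SD of per-cell capture factors
    # log-scale SD of the per-cell transcriptome-breadth factor multiplying
    # every gene's ON probability (clipped at 1): cells differ strongly in
    # how many genes they are found transcribing, as in the real data.
    breadth_sd: float = 0.35
    level_dist: str = "lognormal"  # or "negbin"
    # "poisson": each transcript of an ON burst is captured independently
    # (zero-truncation emerges naturally); "rounded": deterministic
    # round(s_c * L), useful for noiseless limits.
    capture_model: str = "poisson"
    group_labels: tuple[str, str] = ("Pyr", "FS")
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_cells_a < 1 or self.n_cells_b < 1:
            raise ValueError("cell counts must be positive")
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        for cls, (lo, hi) in self.p_on_ranges.items():
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"p_on range for {cls!r} outside [0, 1]")
        if self.capture_sd < 0:
            raise ValueError("capture_sd must be non-negative")
        if self.type_size_factor <= 0:
            raise ValueError("type_size_factor must be positive")
        if self.level_dist not in ("lognormal", "negbin"):
            raise ValueError("level_dist must be 'lognormal' or 'negbin'")
        if self.capture_model not in ("poisson", "rounded"):
            raise ValueError("capture_model must be 'poisson' or 'rounded'")
        if self.enrichment_ratio_range[0] <= 1:
            raise ValueError("enrichment ratios must exceed 1")


@dataclasses.dataclass
class SimulationTruth:
    """Planted ground truth of one simulated matrix."""

    gene_ids: list[str]
    cell_ids: list[str]
    classes: np.ndarray  # per-gene planted class label
    p_on: np.ndarray  # genes x 2 (groups a, b): base ON probability
    p_on_marginal: np.ndarray  # genes x 2: mean realized ON prob per group
    burst_mean: np.ndarray  # genes x 2
    capture: np.ndarray  # per-cell factor s_c (includes the type size effect)
    breadth: np.ndarray  # per-cell ON-probability multiplier b_c
    cell_groups: np.ndarray  # per-cell group label
    burst_on: np.ndarray  # genes x cells bool: burst state drawn ON
    effective_on: np.ndarray  # genes x cells bool: observed value > 0
    group_labels: tuple[str, str]

    def gene_frame(self) -> pd.DataFrame:
        a, b = self.group_labels
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "class": self.classes,
                f"p_on_{a}": self.p_on[:, 0],
                f"p_on_{b}": self.p_on[:, 1],
                f"burst_mean_{a}": self.burst_mean[:, 0],
                f"burst_mean_{b}": self.burst_mean[:, 1],
            }
        )

    def cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "group": self.cell_groups,
                "capture": self.capture,
            }
        )


def _class_counts(n_genes: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    raw = {c: fractions.get(c, 0.0) * n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_genes - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _coupled_mean(p_on, lo, hi, sd_at_0, sd_at_1, rng) -> np.ndarray:
    """Log-scale burst mean rising with ON probability.

    The scatter interpolates from ``sd_at_0`` (rare genes, wide) to
    ``sd_at_1`` (constitutive genes, tight)."""
    p = np.asarray(p_on)
    log_m = np.log(lo) + p * (np.log(hi) - np.log(lo))
    sd = sd_at_0 + p * (sd_at_1 - sd_at_0)
    return np.exp(log_m + rng.normal(0.0, 1.0, size=p.shape) * sd)


def _draw_gene_params(config: SimulationConfig, rng: np.random.Generator):
    counts = _class_counts(config.n_genes, config.class_fractions)
    classes = np.concatenate([[c] * counts[c] for c in CLASSES])
    n = config.n_genes
    p_on = np.zeros((n, 2))
    mean = np.zeros((n, 2))
    sigma = np.full(n, config.burst_dispersion)
    lo_m, hi_m = config.burst_mean_range
    i = 0
    for cls in CLASSES:
        k = counts[cls]
        if k == 0:
            continue
        sl = slice(i, i + k)
        p_lo, p_hi = config.p_on_ranges[cls]
        p = rng.uniform(p_lo, p_hi, size=k)
        if cls == "housekeeping":
            m = np.exp(rng.uniform(*np.log(config.housekeeping_mean_range), size=k))
            p_on[sl] = p[:, None]
            mean[sl] = m[:, None]
            sigma[sl] = config.housekeeping_dispersion
        elif cls == "even":
            base = _coupled_mean(p, lo_m, hi_m, *config.mean_coupling_sd, rng)
            r = rng.uniform(*config.even_ratio_range, size=k)
            direction = rng.integers(0, 2, size=k) * 2 - 1
            p_on[sl] = p[:, None]
            mean[sl, 0] = base * r ** (direction / 2)
            mean[sl, 1] = base * r ** (-direction / 2)
        elif cls == "enriched":
            base = _coupled_mean(p, lo_m, hi_m, *config.mean_coupling_sd, rng)
            lo_r, hi_r = config.enrichment_ratio_range
            r = np.exp(rng.uniform(np.log(lo_r), np.log(hi_r), size=k))
            toward_a = rng.integers(0, 2, size=k).astype(bool)
            p_on[sl] = p[:, None]
            mean[sl, 0] = np.where(toward_a, base * r, base)
            mean[sl, 1] = np.where(toward_a, base, base * r)
        elif cls in ("specific_a", "specific_b"):
            own = 0 if cls == "specific_a" else 1
            base = _coupled_mean(p, lo_m, hi_m, *config.mean_coupling_sd, rng)
            p_on[sl, own] = p
            mean[sl, own] = base
            mean[sl, 1 - own] = base  # unused: p_on is 0 there
        else:  # rare
            base = _coupled_mean(p, lo_m, hi_m, *config.mean_coupling_sd, rng)
            p_on[sl] = p[:, None]
            mean[sl] = base[:, None]
        i += k
    return classes, p_on, mean, sigma


def _gene_stream(seed: int, gene_index: int) -> np.random.Generator:
    key = np.array([np.uint64(seed & 0xFFFFFFFFFFFFFFFF), np.uint64(gene_index)])
    return np.random.Generator(np.random.Philox(key=key))


def simulate(
    config: SimulationConfig,
) -> tuple[CountMatrix, CellAnnotation, SimulationTruth]:
    """Draw a count matrix, cell annotation and ground truth from ``config``.

    Fully reproducible: identical configs (including ``seed``) give
    identical output.  The truth records both ``burst_on`` (the drawn burst
    states, exactly Bernoulli(p_on)) and ``effective_on`` (observed value
    > 0): an ON burst whose molecules are all missed by capture is observed
    as zero, so observed zeros and ``effective_on`` agree by construction.
    """
    config.validate()
    label_a, label_b = config.group_labels
    n_cells = config.n_cells_a + config.n_cells_b
    cell_groups = np.array(
        [label_a] * config.n_cells_a + [label_b] * config.n_cells_b
    )
    cell_ids = [
        f"{g}_{i + 1:03d}"
        for g, i in zip(
            cell_groups,
            list(range(config.n_cells_a)) + list(range(config.n_cells_b)),
        )
    ]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    rng_params = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1])
    )
    rng_cells = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    classes, p_on, mean, sigma = _draw_gene_params(config, rng_params)
    is_a = cell_groups == label_a
    capture = (
        np.where(is_a, config.type_size_factor, 1.0)
        * config.capture_median
        * np.exp(rng_cells.normal(0.0, config.capture_sd, size=n_cells))
    )
    # breadth has unit mean so gene-level marginal ON probabilities stay
    # centered on the base p_on
    breadth = np.exp(
        rng_cells.normal(-config.breadth_sd**2 / 2.0, config.breadth_sd, n_cells)
    )

    group_col = np.where(is_a, 0, 1)
    values = np.zeros((config.n_genes, n_cells))
    burst_on = np.zeros((config.n_genes, n_cells), dtype=bool)
    p_cells = np.empty(n_cells)
    p_on_marginal = np.zeros_like(p_on)
    for g in range(config.n_genes):
        rng = _gene_stream(config.seed, g)
        u = rng.random(n_cells)
        m_cell = mean[g, group_col]
        if config.level_dist == "lognormal":
            mu_log = np.log(m_cell) - sigma[g] ** 2 / 2.0
            levels = rng.lognormal(mean=mu_log, sigma=sigma[g])
        else:
            size = 1.0 / max(config.burst_dispersion, 1e-6) ** 2
            levels = rng.negative_binomial(size, size / (size + m_cell)).astype(float)
        np.minimum(breadth * p_on[g, group_col], 1.0, out=p_cells)
        on = u < p_cells
        burst_on[g] = on
        p_on_marginal[g, 0] = p_cells[is_a].mean()
        p_on_marginal[g, 1] = p_cells[~is_a].mean()
        if config.capture_model == "poisson":
            # molecule-level capture: each of the ~L transcripts of an ON
            # burst is recovered independently at the cell's capture rate
            values[g] = rng.poisson(capture * levels) * on
        else:
            values[g] = np.floor(capture * levels + 0.5) * on

    matrix = CountMatrix(values, gene_ids, cell_ids, stage="raw")
    ann = CellAnnotation.from_labels(cell_ids, cell_groups)
    truth = SimulationTruth(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        classes=classes,
        p_on=p_on,
        p_on_marginal=p_on_marginal,
        burst_mean=mean,
        capture=capture,
        breadth=breadth,
        cell_groups=cell_groups,
        burst_on=burst_on,
        effective_on=values > 0,
        group_labels=(label_a, label_b),
    )
    return matrix, ann, truth


def default_paperlike_config(seed: int = 0) -> SimulationConfig:
    """The study-condition configuration at desk scale.

    59 + 25 cells as sequenced, 2,000 genes (a tractable stand-in for the
    ~19,000-gene transcriptome), a 2x cell-type size effect, and burst
    means spanning roughly 0.1-1,000 normalized copies.  Two calls return
    identical configs.
    """
    return SimulationConfig(seed=seed)


def exchangeable_config(
    seed: int, n_genes: int = 1500, n_cells_per_group: int = 10
) -> SimulationConfig:
    """A configuration with no group structure (cells are exchangeable).

    Both groups share every gene's parameters (no enriched or specific
    classes, unit even-ratio, unit type size factor), so shuffling group
    labels leaves the data distribution unchanged — the null case for
    calibrating the randomized group comparison.  Many genes and few cells
    keep the permutation statistic finely grained.
    """
    return SimulationConfig(
        n_cells_a=n_cells_per_group,
        n_cells_b=n_cells_per_group,
        n_genes=n_genes,
        class_fractions={
            "housekeeping": 0.10,
            "even": 0.55,
            "enriched": 0.0,
            "specific_a": 0.0,
            "specific_b": 0.0,
            "rare": 0.35,
        },
        even_ratio_range=(1.0, 1.0),
        type_size_factor=1.0,
        seed=seed,
    )


def table_fixture(name: str) -> list[GeneSet]:
    """Published per-column gene lists as five GeneSets (``table1``/``table2``)."""
    tables = {"table1": _tables.TABLE1, "table2": _tables.TABLE2}
    if name not in tables:
        raise ValueError(f"unknown table {name!r}; expected 'table1' or 'table2'")
    return [
        GeneSet(name=f"{name}_{column}", symbols=list(symbols), source=name)
        for column, symbols in tables[name].items()
    ]


def table_columns(name: str) -> dict[str, list[str]]:
    """Published per-column gene lists keyed by generic class kind."""
    rename = {
        "even": "even",
        "enriched_pyr": "enriched_a",
        "enriched_fs": "enriched_b",
        "specific_pyr": "specific_a",
        "specific_fs": "specific_b",
    }
    tables = {"table1": _tables.TABLE1, "table2": _tables.TABLE2}
    if name not in tables:
        raise ValueError(f"unknown table {name!r}; expected 'table1' or 'table2'")
    return {rename[k]: list(v) for k, v in tables[name].items()}
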