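"""End-to-end orchestration: selection -> normalization -> summaries ->
classification -> coverage -> permutation reliability, from one config file.

Every stage output is a pure function of (inputs, config, seed); re-running
with identical inputs reproduces byte-identical TSVs.  On any stage
failure the partially written bundle is removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import sys
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classify, genesets, io, normalize, reference, stats
from .containers import CellAnnotation, CountMatrix, GeneSet


@dataclasses.dataclass
class PipelineConfig:
    counts: str
    meta: str
    sets: list[str] = dataclasses.field(default_factory=list)
    edges: str | None = None
    outdir: str = "equiphen_out"
    k_frequent: int = 1000
    k_stable: int = 500
    fold_threshold: float = 10.0
    bin_edges: tuple[float, float] = (50.0, 10.0)
    edge_threshold: float = 0.7
    n_permutations: int = 1000
    policy: str = "flag"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.bin_edges = tuple(float(e) for e in cfg.bin_edges)
        return cfg

    def validate_paths(self) -> None:
        for p in [self.counts, self.meta, *self.sets, *([self.edges] if self.edges else [])]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


ARTIFACTS = (
    "refs.tsv",
    "normalized.tsv",
    "qc.tsv",
    "summary.tsv",
    "classes.tsv",
    "coverage.tsv",
    "reliability.tsv",
)


def _write_summary(summaries, path) -> None:
    io.write_table(summaries, path)


def _write_classes(classes, path) -> None:
    rows = [
        {
            "gene": c.gene,
            "label": c.label,
            "ratio": "" if c.ratio is None else f"{c.ratio:.4g}",
            "on_count_a": c.support[0],
            "on_count_b": c.support[1],
        }
        for c in classes
    ]
    io.write_table(rows, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a small dict of headline numbers (reference-set size, QC
    correlation, per-set coverage).  Raises :class:`StageError` naming the
    failing stage; no partial bundle is left behind.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".equiphen_", dir=outdir))
    headline: dict = {}
    try:
        stage = "load"
        matrix = io.read_count_matrix(config.counts)
        ann = io.read_cell_annotation(config.meta)
        sets = [io.read_gene_set(p) for p in config.sets]

        stage = "refselect"
        sel = reference.SelectionConfig(
            k_frequent=min(config.k_frequent, matrix.n_genes),
            k_stable=min(config.k_stable, config.k_frequent, matrix.n_genes),
            fold_threshold=config.fold_threshold,
        )
        refs, _ = reference.select_reference_genes(matrix, ann, sel)
        refs.write(tmp / "refs.tsv")
        headline["n_reference_genes"] = len(refs)

        stage = "normalize"
        result = normalize.normalize_matrix(matrix, refs, policy=config.policy)
        io.write_count_matrix(result.matrix, tmp / "normalized.tsv")
        qc = normalize.qc_correlation(result)
        frame = qc.to_frame()
        frame["factor"] = result.factors
        frame["rmsd"] = result.rmsd
        frame["n_ref_used"] = result.n_ref_used
        frame.to_csv(tmp / "qc.tsv", sep="\t")
        headline["qc_pearson_r"] = qc.pearson_r

        stage = "summarize"
        union: list[str] = []
        seen: set[str] = set()
        for gs in sets:
            for s in gs.symbols:
                if s.lower() not in seen:
                    seen.add(s.lower())
                    union.append(s)
        target_genes = union or list(result.matrix.gene_ids)
        summaries = stats.summarize_genes(result.matrix, ann, target_genes)
        _write_summary(summaries, tmp / "summary.tsv")

        stage = "classify"
        classes = classify.classify_genes(
            result.matrix, ann, target_genes, config.fold_threshold
        )
        _write_classes(classes, tmp / "classes.tsv")

        stage = "coverage"
        if sets:
            report = genesets.multi_set_report(result.matrix, sets, ann)
            rows = []
            for rep in report.reports:
                comp = report.comparisons.get(rep.set_name)
                rows.append(
                    {
                        "set": rep.set_name,
                        "n_reference": rep.n_reference,
                        "n_detected": rep.n_detected,
                        "coverage_pct": rep.coverage_pct,
                        "t_p_value": "" if comp is None else f"{comp.p_value:.4g}",
                    }
                )
            io.write_table(rows, tmp / "coverage.tsv", sort=False)
            headline["union_detected"] = report.union_detected
            headline["mean_coverage_pct"] = report.mean_coverage_pct
        else:
            io.write_table([], tmp / "coverage.tsv")

        stage = "reliability"
        rel = classify.randomized_group_reliability(
            result.matrix,
            ann,
            target_genes,
            n_permutations=config.n_permutations,
            seed=config.seed,
            fold_threshold=config.fold_threshold,
        )
        io.write_table(
            [
                {
                    "label": lab,
                    "observed": rel.observed[lab],
                    "null_mean": float(rel.null_distribution[lab].mean()),
                    "empirical_p": rel.empirical_p[lab],
                }
                for lab in rel.labels
            ],
            tmp / "reliability.tsv",
            sort=False,
        )

        stage = "finalize"
        log = {
            "equiphen_version": __version__,
            "python": sys.version.split()[0],
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "config_hash": hashlib.sha256(
                json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
            ).hexdigest(),
        }
        (tmp / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        for name in (*ARTIFACTS, "run_log.json"):
            shutil.move(str(tmp / name), str(outdir / name))
    except StageError:
        raise
    except BaseException as exc:
        raise StageError(stage, exc) from exc
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return headline
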