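"""Per-cell RMSD-minimizing scale factors and the detected-vs-sum QC check.

For a cell with reference-gene counts :math:`x_g` and reference targets
:math:`\\mu_g` (cross-cell averages of non-zero values), the normalization
factor is the multiplier :math:`f` minimizing

.. math:: \\mathrm{RMSD}(f) = \\sqrt{\\tfrac{1}{n}\\sum_{g: x_g > 0} (f x_g - \\mu_g)^2}

restricted to the reference genes detected in the cell: zeros are gene OFF
states, not scale information.  The objective is a least-squares line
through the origin, strictly convex in :math:`f`, with the unique closed
form :math:`f = \\sum x_g \\mu_g / \\sum x_g^2`.

After normalization the sum of copy numbers should correlate positively
with the number of detected transcripts across cells;
:func:`qc_correlation` computes that Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountMatrix

if TYPE_CHECKING:  # avoid a cycle: reference.py uses scale_factors
    from .reference import ReferenceSet

logger = logging.getLogger(__name__)


class UnnormalizableCellError(ValueError):
    """Raised when a cell detects none of the reference genes."""


def fit_scale_factor(
    cell_values: np.ndarray, targets: np.ndarray
) -> tuple[float, float, int]:
    """Closed-form RMSD-minimizing factor for a single cell.

    Parameters
    ----------
    cell_values : array of shape (n_ref,)
        The cell's counts on the reference genes (zeros allowed).
    targets : array of shape (n_ref,)
        Positive per-gene targets.

    Returns
    -------
    factor, rmsd, n_used
        The minimizer ``sum(x * mu) / sum(x**2)`` over the genes with
        ``x > 0``, the objective value at the minimizer, and the number of
        reference genes used.
    """
    x = np.asarray(cell_values, dtype=float)
    mu = np.asarray(targets, dtype=float)
    if x.shape != mu.shape or x.ndim != 1:
        raise ValueError("cell_values and targets must be 1-D of equal length")
    if np.any(mu <= 0):
        raise ValueError("targets must be strictly positive")
    on = x > 0
    n_used = int(on.sum())
    if n_used == 0:
        raise UnnormalizableCellError(
            "cell detects none of the reference genes; factor undefined"
        )
    xs, ms = x[on], mu[on]
    factor = float(xs @ ms / (xs @ xs))
    rmsd = float(np.sqrt(np.mean((factor * xs - ms) ** 2)))
    return factor, rmsd, n_used


def scale_factors(
    ref_values: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_scale_factor` over the columns (cells).

    ``ref_values`` is reference-genes x cells.  Cells with no reference
    gene detected get ``factor = nan``, ``rmsd = nan``, ``n_used = 0``;
    callers decide the policy.
    """
    V = np.asarray(ref_values, dtype=float)
    mu = np.asarray(targets, dtype=float)
    on = V > 0
    n_used = on.sum(axis=0)
    denom = (V**2).sum(axis=0)  # zeros contribute nothing
    numer = V.T @ mu
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(n_used > 0, numer / denom, np.nan)
        resid = (factors[None, :] * V - mu[:, None]) * on
        rmsd = np.sqrt((resid**2).sum(axis=0) / np.where(n_used > 0, n_used, 1))
    rmsd = np.where(n_used > 0, rmsd, np.nan)
    return factors, rmsd, n_used.astype(int)


@dataclasses.dataclass
class NormalizationResult:
    """Normalized matrix plus per-cell fit diagnostics."""

    matrix: CountMatrix  # stage == "normalized"
    factors: pd.Series
    rmsd: pd.Series
    n_ref_used: pd.Series
    flagged_cells: list[str]
    dropped_cells: list[str]
    policy: str


def normalize_matrix(
    matrix: CountMatrix, refs: "ReferenceSet", policy: str = "flag"
) -> NormalizationResult:
    """Scale every cell of ``matrix`` by its fitted reference-gene factor.

    Cells detecting no reference gene are handled per ``policy``:
    ``"flag"`` (default) keeps them unscaled (factor 1) and lists them in
    ``flagged_cells``; ``"drop"`` removes them from the output.
    """
    if policy not in ("flag", "drop"):
        raise ValueError("policy must be 'flag' or 'drop'")
    pos, matched, unmatched = matrix.match_symbols(refs.symbols)
    if not matched:
        raise ValueError("reference set shares no genes with the matrix")
    if unmatched:
        logger.warning(
            "%d reference symbols absent from the matrix: %s",
            len(unmatched),
            unmatched[:5],
        )
    keep_target = [i for i, s in enumerate(refs.symbols) if s in set(matched)]
    targets = refs.targets[keep_target]
    factors, rmsd, n_used = scale_factors(matrix.values[pos], targets)

    unfit = n_used == 0
    flagged = [matrix.cell_ids[i] for i in np.flatnonzero(unfit)]
    dropped: list[str] = []
    if policy == "drop" and flagged:
        keep = np.flatnonzero(~unfit)
        dropped, flagged = flagged, []
        logger.info("dropped %d unnormalizable cell(s): %s", len(dropped), dropped)
        matrix = matrix.subset_cells(keep)
        factors, rmsd, n_used = factors[keep], rmsd[keep], n_used[keep]
        unfit = n_used == 0
    factors = np.where(unfit, 1.0, factors)

    normalized = matrix.with_values(matrix.values * factors[None, :], "normalized")
    cells = normalized.cell_ids
    return NormalizationResult(
        matrix=normalized,
        factors=pd.Series(factors, index=cells, name="factor"),
        rmsd=pd.Series(rmsd, index=cells, name="rmsd"),
        n_ref_used=pd.Series(n_used, index=cells, name="n_ref_used"),
        flagged_cells=flagged,
        dropped_cells=dropped,
        policy=policy,
    )


@dataclasses.dataclass
class QCReport:
    """Detected-transcripts vs copy-sum consistency check."""

    detected_genes: pd.Series
    copy_sum: pd.Series
    pearson_r: float | None
    p_value: float | None
    undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"detected_genes": self.detected_genes, "copy_sum": self.copy_sum}
        ).rename_axis("cell_id")


def qc_correlation(result: NormalizationResult) -> QCReport:
    """Pearson correlation between per-cell detected gene counts and copy sums.

    Detected counts are invariant under positive rescaling, so a positive
    correlation indicates the fitted factors put cells on a common copy
    number scale.  With zero variance in either vector the correlation is
    undefined and flagged rather than reported.
    """
    m = result.matrix
    if m.n_cells < 3:
        raise ValueError("QC correlation requires at least 3 cells")
    detected = pd.Series(
        (m.values > 0).sum(axis=0), index=m.cell_ids, name="detected_genes"
    )
    copy_sum = pd.Series(m.values.sum(axis=0), index=m.cell_ids, name="copy_sum")
    if detected.nunique() < 2 or copy_sum.nunique() < 2:
        return QCReport(detected, copy_sum, None, None, undefined=True)
    r, p = scipy.stats.pearsonr(detected.to_numpy(float), copy_sum.to_numpy(float))
    return QCReport(detected, copy_sum, float(r), float(p))
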