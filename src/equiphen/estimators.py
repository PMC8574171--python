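"""scikit-learn estimator wrappers around the selection/normalization core.

These adapt the genes x cells pipeline to the sklearn convention of
samples x features (cells x genes), so reference discovery and RMSD
normalization compose with :class:`sklearn.pipeline.Pipeline` and model
selection:

>>> pipe = Pipeline([
...     ("refs", ReferenceGeneSelector()),
...     ("norm", RmsdNormalizer()),
... ])
>>> normalized_refs = pipe.fit_transform(X, groups)

``ReferenceGeneSelector.transform`` restricts cells to the discovered
reference genes; ``RmsdNormalizer`` then rescales each cell by its
closed-form RMSD-minimizing factor.  To rescale a *full* matrix by factors
fitted on the reference genes, use :func:`equiphen.normalize.normalize_matrix`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import CellAnnotation, CountMatrix
from .normalize import scale_factors
from .reference import SelectionConfig, nonzero_row_means, select_reference_genes


def _as_array(X, estimator):
    feature_names = None
    if hasattr(X, "columns"):
        feature_names = np.asarray([str(c) for c in X.columns], dtype=object)
    arr = check_array(X, dtype=float, ensure_min_samples=1, estimator=estimator)
    return arr, feature_names


class ReferenceGeneSelector(SelectorMixin, BaseEstimator):
    """Discover equi-phenotype reference genes as a feature selector.

    Fit on a cells x genes matrix ``X`` with per-cell group labels ``y``
    (exactly two groups).  The cascade keeps the ``k_frequent`` most
    frequently detected genes, pre-normalizes cells against them, keeps the
    ``k_stable`` genes with the lowest cross-cell standard deviation, and
    retains those with group-wise non-zero means within ``fold_threshold``.

    Attributes
    ----------
    reference_symbols_ : list of str
        Selected gene names (column names when X is a DataFrame).
    targets_ : ndarray
        Per-reference-gene normalization targets (non-zero averages on the
        pre-normalized data).
    provenance_ : dict
        Selection sizes and thresholds actually applied.
    """

    def __init__(
        self,
        k_frequent: int = 1000,
        k_stable: int = 500,
        fold_threshold: float = 10.0,
        stability_mode: str = "nonzero",
    ):
        self.k_frequent = k_frequent
        self.k_stable = k_stable
        self.fold_threshold = fold_threshold
        self.stability_mode = stability_mode

    def fit(self, X, y):
        arr, feature_names = _as_array(X, self)
        if y is None:
            raise ValueError("ReferenceGeneSelector requires per-cell group labels y")
        y = np.asarray(y).ravel()
        if y.shape[0] != arr.shape[0]:
            raise ValueError("y must have one group label per cell (row of X)")
        self.n_features_in_ = arr.shape[1]
        if feature_names is not None:
            self.feature_names_in_ = feature_names
        gene_ids = (
            list(feature_names)
            if feature_names is not None
            else [f"g{j}" for j in range(arr.shape[1])]
        )
        cell_ids = [f"c{i}" for i in range(arr.shape[0])]
        matrix = CountMatrix(arr.T, gene_ids, cell_ids, stage="raw")
        ann = CellAnnotation.from_labels(cell_ids, [str(g) for g in y])
        config = SelectionConfig(
            k_frequent=min(self.k_frequent, arr.shape[1]),
            k_stable=min(self.k_stable, self.k_frequent, arr.shape[1]),
            fold_threshold=self.fold_threshold,
            stability_mode=self.stability_mode,
        )
        refs, _ = select_reference_genes(matrix, ann, config)
        index = {g: j for j, g in enumerate(gene_ids)}
        mask = np.zeros(arr.shape[1], dtype=bool)
        mask[[index[s] for s in refs.symbols]] = True
        # targets reordered to column order for transform composability
        order = np.argsort([index[s] for s in refs.symbols])
        self.reference_symbols_ = [refs.symbols[i] for i in order]
        self.targets_ = refs.targets[order]
        self.support_ = mask
        self.provenance_ = dict(refs.provenance)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class RmsdNormalizer(TransformerMixin, BaseEstimator):
    """Per-cell scaling by the closed-form RMSD-minimizing factor.

    ``fit`` learns per-gene targets: the supplied ``targets`` array, or the
    cross-cell averages of non-zero values of the fitted data.  ``transform``
    rescales each row (cell) by ``sum(x * mu) / sum(x ** 2)`` over its
    detected genes; rows detecting none of the target genes are left
    unscaled (factor 1).  ``fit_transform`` additionally records the
    training-cell diagnostics ``factors_``, ``rmsd_`` and ``n_ref_used_``.
    """

    def __init__(self, targets=None):
        self.targets = targets

    def fit(self, X, y=None):
        arr, _ = _as_array(X, self)
        self.n_features_in_ = arr.shape[1]
        if self.targets is not None:
            targets = np.asarray(self.targets, dtype=float)
            if targets.shape != (arr.shape[1],):
                raise ValueError("targets must have one entry per gene (column)")
        else:
            targets = nonzero_row_means(arr.T)
        if np.all(np.isnan(targets)):
            raise ValueError("no gene is detected in any cell; targets undefined")
        self.targets_ = targets
        self.usable_ = ~np.isnan(targets)
        return self

    def scale_factors(self, X):
        """Per-row ``(factor, rmsd, n_used)`` against the fitted targets."""
        check_is_fitted(self, "targets_")
        arr, _ = _as_array(X, self)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of genes than at fit time")
        factors, rmsd, n_used = scale_factors(
            arr.T[self.usable_], self.targets_[self.usable_]
        )
        return np.where(n_used == 0, 1.0, factors), rmsd, n_used

    def transform(self, X):
        arr, _ = _as_array(X, self)
        factors, _, _ = self.scale_factors(arr)
        return arr * factors[:, None]

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        arr, _ = _as_array(X, self)
        factors, rmsd, n_used = self.scale_factors(arr)
        self.factors_ = factors
        self.rmsd_ = rmsd
        self.n_ref_used_ = n_used
        return arr * factors[:, None]
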