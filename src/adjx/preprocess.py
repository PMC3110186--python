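"""Scale transformation, quantile normalization and SVD sample QC.

Quantile normalization forces every sample (column) onto a common
reference distribution — the across-sample mean of sorted values — so
that between-array intensity differences cancel. Sample-level
consistency is then assessed by singular value decomposition of the
row-centered matrix: the first few right singular vectors, scaled by
their singular values, place each array in a low-dimensional space where
treatment/control and timepoint structure (or array problems) are
visible.

The two operations are exposed both as functions on
:class:`~adjx.datatypes.ExpressionDataset` and as scikit-learn
estimators (:class:`QuantileNormalizer`, :class:`SVDSampleProjector`)
operating on plain samples × features arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datatypes import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "svd_projection",
    "SvdProjection",
    "QuantileNormalizer",
    "SVDSampleProjector",
]


def log2_transform(data: ExpressionDataset, offset: float = 1.0) -> ExpressionDataset:
    """Return log2(value + offset); all input values must be >= 0."""
    arr = data.values.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value at gene {data.values.index[i]!r}, "
            f"sample {data.values.columns[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(arr + offset), index=data.values.index, columns=data.values.columns
    )
    return ExpressionDataset(out, data.design.copy())


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Columns of *x* onto the mean-of-sorted-columns reference.

    Ties within a column receive the mean of the reference values their
    positions span (the common dialect)."""
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = reference
        # average reference over tie blocks
        sorted_col = col[order]
        block_start = 0
        for i in range(1, n + 1):
            if i == n or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    ranked[order[block_start:i]] = reference[block_start:i].mean()
                block_start = i
        out[:, j] = ranked
    return out


def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize all samples jointly.

    After normalization the sorted value vector of every column is
    identical (the across-sample mean of sorted columns). A single
    sample is returned unchanged with a warning.
    """
    if data.n_samples < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return data.copy()
    arr = _quantile_normalize_array(data.values.to_numpy(dtype=float))
    out = pd.DataFrame(arr, index=data.values.index, columns=data.values.columns)
    return ExpressionDataset(out, data.design.copy())


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer for quantile normalization.

    Follows the sklearn convention of samples × features input: here a
    "sample" is one array and features are genes, i.e. the transpose of
    the genes × samples layout used elsewhere. ``fit`` learns the
    reference distribution (mean of sorted rows); ``transform`` maps
    each row onto it, so the normalizer can be fit on one cohort and
    applied to another.

    Attributes
    ----------
    reference_ : ndarray of shape (n_features,)
        Sorted reference distribution learned in :meth:`fit`.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return _quantile_normalize_array(X.T).T


@dataclass
class SvdProjection:
    """Sample coordinates on the leading singular directions.

    ``coordinates`` is samples × n_components (right singular vectors
    scaled by singular values); ``singular_values`` are all singular
    values of the row-centered matrix; ``variance_fraction`` is
    sigma_k^2 / sum(sigma^2) for the retained components.
    """

    coordinates: pd.DataFrame
    singular_values: np.ndarray
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction)
        if ((vf < -1e-12) | (vf > 1 + 1e-12)).any():
            raise ValueError("variance fractions must lie in [0, 1]")
        if (np.diff(vf) > 1e-12).any():
            raise ValueError("variance fractions must be non-increasing")


def _centered_svd(arr: np.ndarray):
    centered = arr - arr.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| gene entry of each component positive
    for k in range(u.shape[1]):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    return centered, u, s, vt


def svd_projection(data: ExpressionDataset, n_components: int = 3) -> SvdProjection:
    """Project samples onto the leading singular directions of the
    row-centered matrix (genes centered to mean zero).

    Coordinates are the right singular vectors scaled by their singular
    values, so pairwise distances in the full component space equal
    distances between centered sample columns. Component signs are fixed
    so the largest-magnitude gene loading of each component is positive.
    """
    arr = data.values.to_numpy(dtype=float)
    if n_components > min(arr.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min matrix dimension {min(arr.shape)}"
        )
    _, u, s, vt = _centered_svd(arr)
    coords = (vt[:n_components].T * s[:n_components])
    total = float((s**2).sum())
    varfrac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    coords = pd.DataFrame(
        coords,
        index=data.sample_ids,
        columns=[f"dim{k + 1}" for k in range(n_components)],
    )
    return SvdProjection(coords, s, varfrac)


class SVDSampleProjector(BaseEstimator, TransformerMixin):
    """PCA-like estimator placing arrays in singular-direction space.

    Input is samples × genes (sklearn orientation). ``fit`` centers each
    gene and stores the loadings; ``transform`` returns the sample
    coordinates scaled by singular values.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.n_components > min(X.shape):
            raise ValueError("n_components exceeds min matrix dimension")
        # genes are features here -> transpose into genes × samples
        _, u, s, _ = _centered_svd(X.T)
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.components_ = u[:, : self.n_components].T  # (k, genes)
        self.singular_values_ = s
        total = float((s**2).sum())
        self.variance_fraction_ = (
            (s[: self.n_components] ** 2) / total if total > 0
            else np.zeros(self.n_components)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
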