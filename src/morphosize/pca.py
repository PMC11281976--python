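"""Covariance PCA morphospaces with a deterministic axis orientation.

Shape matrices are explored with principal component analysis on the
covariance matrix: columns are centered but not scaled to unit variance,
because within a treatment the variables are commensurate (all mm, or all
dimensionless log ratios).  Components come from the singular value
decomposition of the centered matrix; eigenvalues use the n-1 divisor.

The sign of every eigenvector is arbitrary, so axes are oriented by a
fixed convention — the loading of largest absolute value on each
component is made positive (ties broken by lowest variable index) — which
makes scores and loadings bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .transforms import ShapeMatrix


class OrientedPCA(TransformerMixin, BaseEstimator):
    """Covariance-matrix PCA with deterministic component signs.

    Parameters
    ----------
    scale : bool, default False
        If True, standardize columns to unit variance first
        (correlation-matrix PCA).  Never the default: the analyses run on
        commensurate variables.

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Column means removed before decomposition.
    loadings_ : ndarray of shape (n_features, n_components)
        Orthonormal eigenvectors, one column per component, oriented.
    eigenvalues_ : ndarray of shape (n_components,)
        Component variances (n-1 divisor), non-increasing.
    scores_ : ndarray of shape (n_samples, n_components)
        Projections of the training rows.
    pct_variance_ : ndarray of shape (n_components,)
        Percent of total variance per component; sums to 100.
    """

    def __init__(self, scale: bool = False):
        self.scale = scale

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, ensure_min_features=2)
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        if self.scale:
            self.scale_ = centered.std(axis=0, ddof=1)
            if np.any(self.scale_ == 0):
                raise ValueError("cannot scale: a column has zero variance")
            centered = centered / self.scale_
        else:
            self.scale_ = np.ones(p)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = s**2 / (n - 1)
        total = eigenvalues.sum()
        if total <= 0:
            raise ValueError(
                "total variance is zero (constant matrix); PCA undefined"
            )
        self.loadings_ = Vt.T
        self.eigenvalues_ = eigenvalues
        self.scores_ = U * s
        self.pct_variance_ = 100.0 * eigenvalues / total
        self.n_features_in_ = p
        self.n_samples_ = n
        self._orient()
        return self

    def _orient(self) -> None:
        """Make the largest-|loading| entry of each component positive."""
        for j in range(self.loadings_.shape[1]):
            col = self.loadings_[:, j]
            i = int(np.argmax(np.abs(col)))  # ties: lowest variable index
            if col[i] < 0:
                self.loadings_[:, j] = -col
                self.scores_[:, j] = -self.scores_[:, j]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} variables, got {X.shape[1]}"
            )
        return ((X - self.mean_) / self.scale_) @ self.loadings_

    def inverse_transform(self, scores) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        scores = check_array(scores)
        return scores @ self.loadings_.T * self.scale_ + self.mean_


class PCAModel(OrientedPCA):
    """An :class:`OrientedPCA` fitted to a :class:`ShapeMatrix`.

    Adds the treatment tag and variable names, and DataFrame views of the
    loadings and scores for reporting.
    """

    def fit_shape(self, shape: ShapeMatrix) -> "PCAModel":
        self.fit(shape.to_array())
        self.treatment_ = shape.treatment
        self.var_names_ = list(shape.values.columns)
        self.specimen_ids_ = shape.specimen_ids
        return self

    def loadings_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        comps = [f"PC{i + 1}" for i in range(self.loadings_.shape[1])]
        return pd.DataFrame(self.loadings_, index=self.var_names_, columns=comps)

    def scores_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        comps = [f"PC{i + 1}" for i in range(self.scores_.shape[1])]
        return pd.DataFrame(self.scores_, index=self.specimen_ids_, columns=comps)


def fit_pca(shape: ShapeMatrix, scale: bool = False) -> PCAModel:
    """Fit a covariance PCA (oriented axes) to a shape matrix."""
    try:
        return PCAModel(scale=scale).fit_shape(shape)
    except ValueError as err:
        raise ValueError(f"[treatment={shape.treatment}] {err}") from err


def orient_axes(model: OrientedPCA) -> OrientedPCA:
    """Re-apply the deterministic sign convention in place (idempotent)."""
    check_is_fitted(model, "loadings_")
    model._orient()
    return model


def project(model: OrientedPCA, shape: ShapeMatrix | np.ndarray) -> np.ndarray:
    """Project new rows into a fitted morphospace: (rows - mean) @ loadings."""
    if isinstance(shape, ShapeMatrix):
        treatment = getattr(model, "treatment_", None)
        if treatment is not None and shape.treatment != treatment:
            raise ValueError(
                f"treatment mismatch: model fitted on {treatment!r}, "
                f"rows are {shape.treatment!r}"
            )
        X = shape.to_array()
    else:
        X = np.asarray(shape, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    return model.transform(X)
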