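"""Size correction of measurement matrices: the three data treatments.

Traditional-morphometric measurement sets confound size and shape.  Three
treatments are offered, each producing a :class:`ShapeMatrix`:

``form``
    Raw measurements, carrying both size and shape.
``log_shape_ratio``
    Mosimann shape variables: each linear measurement x_j becomes
    ln(x_j / GM), where GM is the specimen's geometric mean over the
    linear variables — an overall-size proxy chosen so no single variable
    is privileged.  Angles are size-free by construction and pass through
    untouched.  The linear components of each row sum to zero exactly.
``allometry_free``
    Residuals of each raw variable regressed (OLS, intercept + slope) on
    GM across specimens — the residual matrix of the multivariate linear
    model of all variables on size, removing the size-predictable
    component of variation.

Both non-trivial treatments are exposed as scikit-learn transformers
(:class:`LogShapeRatios`, :class:`AllometryFreeResiduals`) operating on
plain arrays, and as table-level functions returning tagged
:class:`ShapeMatrix` objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .catalogs import VariableCatalog
from .table import MeasurementTable

TREATMENTS = ("form", "log_shape_ratio", "allometry_free")


@dataclass(frozen=True)
class SizeVector:
    """Per-specimen geometric-mean size proxy (mm) and its natural log."""

    specimen_ids: tuple[str, ...]
    gm: np.ndarray

    def __post_init__(self) -> None:
        gm = np.asarray(self.gm, dtype=float)
        if gm.ndim != 1 or len(gm) != len(self.specimen_ids):
            raise ValueError("gm must be 1-D, one entry per specimen")
        if not np.all(gm > 0):
            raise ValueError("geometric means must be strictly positive")
        object.__setattr__(self, "gm", gm)

    @property
    def log_gm(self) -> np.ndarray:
        return np.log(self.gm)

    def __len__(self) -> int:
        return len(self.gm)


@dataclass(frozen=True)
class ShapeMatrix:
    """A measurement matrix after one treatment, tagged with that treatment."""

    treatment: str
    values: pd.DataFrame
    catalog: VariableCatalog
    size: SizeVector | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def geometric_mean(x: Sequence[float] | np.ndarray, axis: int | None = None) -> np.ndarray:
    """Geometric mean, the nth root of the product of n values.

    Computed in log space for numerical stability.  All inputs must be
    strictly positive and non-missing; angle variables are the caller's
    responsibility to exclude.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty set is undefined")
    if np.isnan(x).any() or np.any(x <= 0):
        raise ValueError(
            "geometric mean requires strictly positive, non-missing inputs; "
            "filter incomplete specimens first"
        )
    return np.exp(np.mean(np.log(x), axis=axis))


def size_vector(table: MeasurementTable) -> SizeVector:
    """Geometric-mean size proxy per specimen, over the linear variables."""
    linear = table.values[table.catalog.linear_abbreviations].to_numpy(float)
    if linear.shape[1] == 0:
        raise ValueError("catalog has no linear variables; size proxy undefined")
    gm = geometric_mean(linear, axis=1)
    return SizeVector(tuple(table.specimen_ids), gm)


class LogShapeRatios(TransformerMixin, BaseEstimator):
    """Mosimann log-shape-ratio transformer.

    Each linear column x_j of a row becomes ln(x_j / GM) where GM is the
    row's geometric mean over the linear columns; angle columns (marked by
    ``angle_mask``) pass through unchanged.  Stateless: ``fit`` only
    records dimensions.

    Parameters
    ----------
    angle_mask : sequence of bool, optional
        True for columns that are angles.  Default: all linear.
    """

    def __init__(self, angle_mask: Sequence[bool] | None = None):
        self.angle_mask = angle_mask

    def _mask(self, n_features: int) -> np.ndarray:
        if self.angle_mask is None:
            return np.zeros(n_features, dtype=bool)
        mask = np.asarray(self.angle_mask, dtype=bool)
        if mask.shape != (n_features,):
            raise ValueError("angle_mask length must equal the number of columns")
        return mask

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        mask = self._mask(self.n_features_in_)
        if (~mask).sum() == 0:
            raise ValueError("at least one linear variable is required")
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        mask = self._mask(X.shape[1])
        linear = X[:, ~mask]
        if np.any(linear <= 0):
            raise ValueError("log shape ratios require strictly positive lengths")
        log_gm = np.mean(np.log(linear), axis=1)
        out = X.astype(float).copy()
        out[:, ~mask] = np.log(linear) - log_gm[:, None]
        return out

    def size_of(self, X) -> np.ndarray:
        """Geometric means of the linear columns of ``X`` (same rule as transform)."""
        X = check_array(X)
        mask = self._mask(X.shape[1])
        return np.exp(np.mean(np.log(X[:, ~mask]), axis=1))


class AllometryFreeResiduals(TransformerMixin, BaseEstimator):
    """Residualize every variable on a size covariate by per-column OLS.

    ``fit`` regresses each column of X on the fitted size values
    (intercept + slope) and stores the coefficients; ``transform`` returns
    observed minus predicted.  On the training data every residual column
    has mean zero and zero sample covariance with size — the residual
    matrix of the multivariate linear model of all variables on size,
    since such residuals are computed per response.

    Parameters
    ----------
    include_angles : bool, default True
        If False, columns flagged by ``angle_mask`` are centered only,
        not size-residualized.
    angle_mask : sequence of bool, optional
        Needed only when ``include_angles`` is False.
    """

    def __init__(
        self,
        include_angles: bool = True,
        angle_mask: Sequence[bool] | None = None,
    ):
        self.include_angles = include_angles
        self.angle_mask = angle_mask

    def fit(self, X, y=None, *, size: Sequence[float] | None = None):
        X = check_array(X)
        if size is None:
            raise ValueError("AllometryFreeResiduals.fit requires size=")
        size = np.asarray(size, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError(
                "allometry-free residuals need >= 3 specimens (a 2-point "
                "line fit leaves residuals identically zero)"
            )
        if np.ptp(size) == 0 or np.var(size) == 0:
            raise ValueError("size covariate has zero variance")
        design = np.column_stack([np.ones(n), size])
        coef, *_ = np.linalg.lstsq(design, X, rcond=None)
        if not self.include_angles and self.angle_mask is not None:
            mask = np.asarray(self.angle_mask, dtype=bool)
            # angles: keep the centering (intercept) but drop the size slope
            coef[0, mask] = X[:, mask].mean(axis=0)
            coef[1, mask] = 0.0
        self.coef_ = coef
        self.n_features_in_ = p
        return self

    def transform(self, X, *, size: Sequence[float] | None = None) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if size is None:
            raise ValueError("AllometryFreeResiduals.transform requires size=")
        size = np.asarray(size, dtype=float)
        design = np.column_stack([np.ones(len(size)), size])
        return X - design @ self.coef_

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y, **kwargs).transform(X, **kwargs)


def _require_complete(table: MeasurementTable) -> None:
    if not table.is_complete():
        raise ValueError(
            f"table has {table.n_missing} missing cell(s); apply "
            "filter_complete() before a shape treatment"
        )


def form(table: MeasurementTable) -> ShapeMatrix:
    """The identity treatment: raw measurements (size + shape together)."""
    _require_complete(table)
    return ShapeMatrix("form", table.values.copy(), table.catalog, size=None)


def log_shape_ratios(table: MeasurementTable) -> ShapeMatrix:
    """Mosimann log shape ratios of a complete table (angles pass through)."""
    _require_complete(table)
    est = LogShapeRatios(angle_mask=table.catalog.angle_mask)
    X = table.values.to_numpy(float)
    out = est.fit(X).transform(X)
    values = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return ShapeMatrix("log_shape_ratio", values, table.catalog, size=size_vector(table))


def allometry_free(table: MeasurementTable, include_angles: bool = True) -> ShapeMatrix:
    """Residuals of every raw variable on the geometric-mean size proxy."""
    _require_complete(table)
    size = size_vector(table)
    est = AllometryFreeResiduals(
        include_angles=include_angles, angle_mask=table.catalog.angle_mask
    )
    out = est.fit_transform(table.values.to_numpy(float), size=size.gm)
    values = pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    return ShapeMatrix("allometry_free", values, table.catalog, size=size)


def apply_treatment(table: MeasurementTable, treatment: str) -> ShapeMatrix:
    """Dispatch a treatment by name: form | log_shape_ratio | allometry_free."""
    if treatment == "form":
        return form(table)
    if treatment == "log_shape_ratio":
        return log_shape_ratios(table)
    if treatment == "allometry_free":
        return allometry_free(table)
    raise ValueError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
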