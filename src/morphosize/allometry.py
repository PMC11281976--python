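"""Multivariate allometry test: PC1 of the log-shape-ratio PCA on log size.

With many variables, allometry is assessed jointly rather than in a myriad
of bivariate fits (the Jolicoeur tradition): the first principal component
of the Mosimann log-shape-ratio matrix captures the dominant axis of shape
variation, and its scores are regressed on the log geometric mean.  A
significant slope (F test with (1, n-2) df, the single-covariate ANOVA)
means shape depends on size; R² quantifies how much of the PC1 shape
variation size explains.

R² is always computed and carried together with the significance flag, so
the convention of quoting R² only when the slope is significant remains
available as a view without losing information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .transforms import SizeVector

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AllometryFit:
    """Result of the PC1 ~ log(GM) regression for one structure."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    alpha: float = DEFAULT_ALPHA
    structure: str = ""
    treatment: str = "log_shape_ratio"
    canonical: bool = field(default=True)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def r_squared_pct(self) -> str:
        """R² rendered as a percentage with two decimals, e.g. '72.67%'."""
        return f"{100.0 * self.r_squared:.2f}%"

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "r_squared_pct": self.r_squared_pct,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "treatment": self.treatment,
        }
        if self.structure:
            out["structure"] = self.structure
        if not self.canonical:
            out["non_canonical"] = True
        return out


class AllometryRegression(RegressorMixin, BaseEstimator):
    """OLS of PC1 scores on log geometric mean, with the slope F test.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for the slope ANOVA.

    Attributes
    ----------
    slope_, intercept_ : float
        Regression coefficients of scores on log size.
    r_squared_ : float
        Squared Pearson correlation of scores and log size.
    f_stat_, p_value_ : float
        F statistic with (1, n-2) df and its p value.
    significant_ : bool
        ``p_value_ < alpha``.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        self.alpha = alpha

    def fit(self, X, y):
        log_gm = np.asarray(X, dtype=float).reshape(-1)
        scores = np.asarray(y, dtype=float).reshape(-1)
        if log_gm.shape != scores.shape:
            raise ValueError("log size and PC1 scores must have equal length")
        n = len(log_gm)
        if n < 3:
            raise ValueError("allometry test needs at least 3 specimens")
        if np.var(log_gm) == 0:
            raise ValueError("log size has zero variance; slope undefined")
        res = stats.linregress(log_gm, scores)
        r2 = float(res.rvalue**2)
        df_resid = n - 2
        if r2 < 1.0:
            f_stat = r2 / (1.0 - r2) * df_resid
        else:
            f_stat = float("inf")
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = r2
        self.f_stat_ = float(f_stat)
        self.p_value_ = float(stats.f.sf(f_stat, 1, df_resid)) if np.isfinite(f_stat) else 0.0
        self.n_ = n
        self.significant_ = bool(self.p_value_ < self.alpha)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        log_gm = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * log_gm

    def to_fit(self, structure: str = "", treatment: str = "log_shape_ratio") -> AllometryFit:
        check_is_fitted(self, "slope_")
        return AllometryFit(
            n=self.n_,
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            f_stat=self.f_stat_,
            p_value=self.p_value_,
            alpha=self.alpha,
            structure=structure,
            treatment=treatment,
            canonical=(treatment == "log_shape_ratio"),
        )


def allometry_test(
    scores_pc1: Sequence[float] | np.ndarray,
    size: SizeVector | Sequence[float] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    structure: str = "",
    treatment: str = "log_shape_ratio",
) -> AllometryFit:
    """Regress PC1 scores on the natural log of the geometric mean.

    ``size`` may be a :class:`SizeVector` (its log is taken) or a
    pre-computed log-size array.  Applying the test to PC1 of a treatment
    other than ``log_shape_ratio`` is allowed but labelled non-canonical
    in the result.
    """
    log_gm = size.log_gm if isinstance(size, SizeVector) else np.asarray(size, float)
    est = AllometryRegression(alpha=alpha).fit(log_gm, scores_pc1)
    return est.to_fit(structure=structure, treatment=treatment)


def allometry_report(
    fits: Mapping[str, AllometryFit] | Sequence[AllometryFit],
) -> tuple[pd.DataFrame, dict]:
    """Tabular + JSON-ready summary of one allometry fit per structure."""
    if isinstance(fits, Mapping):
        items = [(name, fit) for name, fit in fits.items()]
    else:
        items = [(fit.structure or f"fit{i}", fit) for i, fit in enumerate(fits)]
    if not items:
        raise ValueError("allometry_report needs at least one fit")
    rows = []
    payload = {}
    for name, fit in items:
        d = fit.to_dict()
        d.setdefault("structure", name)
        payload[name] = d
        rows.append(
            {
                "structure": name,
                "n": fit.n,
                "slope": fit.slope,
                "r_squared_pct": fit.r_squared_pct,
                "p_value": fit.p_value,
                "significant": fit.significant,
            }
        )
    return pd.DataFrame(rows), payload
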