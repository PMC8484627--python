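"""Ordinary least squares of mean valence ratings on contour features.

The analysis stage for rating data: mean valence (1-9 Likert) of each image
is regressed on the 23 square-root-transformed histogram features with an
intercept.  Collinear feature columns are detected by pivoted QR and
dropped with a by-name report, so the fit is deterministic whatever the
rank of the design.  Partial-regression (added-variable) series are exposed
for the diagnostic plots, and close/far subsets can be refit separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ValenceRegression",
    "RegressionResult",
    "UnderdeterminedError",
    "fit_valence_model",
    "partial_regression_data",
    "subset_analysis",
]

DISTANCE_CLASSES = ("close", "far", "unlabeled")


class UnderdeterminedError(ValueError):
    """Raised when a regression has too few rows for its retained predictors."""


@dataclass(frozen=True)
class RegressionResult:
    """Summary of one OLS fit (coefficients exclude the intercept)."""

    predictor_names: tuple[str, ...]
    coef: np.ndarray
    stderr: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    intercept: float
    fvalue: float
    f_pvalue: float
    df1: int
    df2: int
    rsquared: float
    n: int
    dropped: tuple[str, ...]

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.predictor_names),
                "beta": self.coef,
                "se": self.stderr,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "F": self.fvalue,
                    "f_pvalue": self.f_pvalue,
                    "df1": self.df1,
                    "df2": self.df2,
                    "rsquared": self.rsquared,
                    "n": self.n,
                    "n_dropped": len(self.dropped),
                }
            ]
        )


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR).

    The intercept is prepended by the caller; a column whose R diagonal falls
    below ``tol`` times the largest is treated as linearly dependent on the
    columns pivoted before it.
    """
    if X.shape[1] == 0:
        return np.empty(0, dtype=int)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        return np.empty(0, dtype=int)
    rank = int(np.sum(diag > tol * diag[0]))
    return np.sort(piv[:rank])


class ValenceRegression(RegressorMixin, BaseEstimator):
    """OLS of mean valence on contour features, with rank-deficiency handling.

    Fits ``y = b0 + X beta`` by ordinary least squares.  Columns that are
    (numerically) linear combinations of earlier-pivoted columns are removed
    before fitting and reported in ``dropped_``; the fitted values are then
    invariant to adding duplicated columns.

    Attributes
    ----------
    coef_ : (p,) ndarray
        Coefficients of the retained predictors (0 for dropped ones).
    intercept_ : float
    result_ : RegressionResult
        Full inferential summary (SEs, t, p, overall F, R^2).
    dropped_ : tuple of str
        Names of columns eliminated as collinear.
    """

    def __init__(self, rank_tol: float = 1e-8) -> None:
        self.rank_tol = rank_tol

    def fit(
        self,
        X: np.ndarray | pd.DataFrame,
        y: np.ndarray | pd.Series,
        feature_names: Sequence[str] | None = None,
    ) -> "ValenceRegression":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns.astype(str))
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = (
                list(feature_names)
                if feature_names is not None
                else [f"x{i}" for i in range(X.shape[1])]
            )
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per rating")
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

        centered = X - X.mean(axis=0)  # intercept handled separately
        keep = _independent_columns(centered, tol=self.rank_tol)
        dropped = tuple(names[j] for j in range(X.shape[1]) if j not in set(keep))
        p = len(keep)
        if len(y) < p + 2:
            raise UnderdeterminedError(
                f"need at least {p + 2} rows to fit {p} retained predictors "
                f"with an intercept, got {len(y)}"
            )

        design = sm.add_constant(X[:, keep], has_constant="add")
        res = sm.OLS(y, design).fit()

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.retained_idx_ = keep
        self.dropped_ = dropped
        self.intercept_ = float(res.params[0])
        coef_full = np.zeros(X.shape[1])
        coef_full[keep] = res.params[1:]
        self.coef_ = coef_full
        self.result_ = RegressionResult(
            predictor_names=tuple(names[j] for j in keep),
            coef=res.params[1:],
            stderr=res.bse[1:],
            tvalues=res.tvalues[1:],
            pvalues=res.pvalues[1:],
            intercept=float(res.params[0]),
            fvalue=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            df1=int(res.df_model),
            df2=int(res.df_resid),
            rsquared=float(res.rsquared),
            n=len(y),
            dropped=dropped,
        )
        self._X_retained = X[:, keep]
        self._y = y
        return self

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.intercept_ + np.asarray(X, float) @ self.coef_

    def partial_regression(self, predictor: str) -> pd.DataFrame:
        """Added-variable series for one retained predictor.

        Returns a DataFrame with ``x_resid`` (residuals of the predictor on
        the remaining predictors) and ``y_resid`` (residuals of the response
        on the remaining predictors); the OLS slope of ``y_resid`` on
        ``x_resid`` equals the predictor's multiple-regression coefficient.
        """
        check_is_fitted(self, "result_")
        names = list(self.result_.predictor_names)
        if predictor not in names:
            raise KeyError(
                f"predictor {predictor!r} is not among the retained predictors "
                f"(dropped: {list(self.dropped_)})"
            )
        j = names.index(predictor)
        others = np.delete(self._X_retained, j, axis=1)
        others = sm.add_constant(others, has_constant="add")
        xj = self._X_retained[:, j]
        x_resid = xj - others @ np.linalg.lstsq(others, xj, rcond=None)[0]
        y_resid = self._y - others @ np.linalg.lstsq(others, self._y, rcond=None)[0]
        slope = float(x_resid @ y_resid / (x_resid @ x_resid))
        out = pd.DataFrame({"x_resid": x_resid, "y_resid": y_resid})
        out.attrs["partial_slope"] = slope
        out.attrs["predictor"] = predictor
        return out


def _align(features: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    for col in ("image_id",):
        if col not in features.columns or col not in ratings.columns:
            raise ValueError("both tables need an 'image_id' column")
    if "valence" not in ratings.columns:
        raise ValueError("ratings table needs a 'valence' column")
    bad = ratings.loc[
        (ratings["valence"] < 1) | (ratings["valence"] > 9), "image_id"
    ]
    if len(bad):
        raise ValueError(f"valence ratings outside [1, 9] for images {list(bad)[:5]}")
    merged = features.merge(ratings, on="image_id", how="inner", validate="1:1")
    if len(merged) != len(features) or len(merged) != len(ratings):
        missing = set(features["image_id"]).symmetric_difference(ratings["image_id"])
        raise ValueError(
            f"feature and rating tables do not align on image_id; "
            f"{len(missing)} unmatched ids, e.g. {sorted(missing)[:5]}"
        )
    return merged


def fit_valence_model(
    features: pd.DataFrame, ratings: pd.DataFrame, rank_tol: float = 1e-8
) -> RegressionResult:
    """OLS of mean valence on the feature table, aligned by image_id."""
    merged = _align(features, ratings)
    cols = [c for c in features.columns if c != "image_id"]
    model = ValenceRegression(rank_tol=rank_tol).fit(merged[cols], merged["valence"])
    return model.result_


def partial_regression_data(
    features: pd.DataFrame, ratings: pd.DataFrame, predictor: str
) -> pd.DataFrame:
    """Added-variable series for one predictor of the full-sample fit."""
    merged = _align(features, ratings)
    cols = [c for c in features.columns if c != "image_id"]
    model = ValenceRegression().fit(merged[cols], merged["valence"])
    return model.partial_regression(predictor)


def subset_analysis(
    features: pd.DataFrame, ratings: pd.DataFrame, rank_tol: float = 1e-8
) -> dict[str, RegressionResult | Exception]:
    """Separate OLS fits for the close and far image subsets.

    Unlabeled images are excluded.  A subset with too few rows for its
    retained predictors yields the error object in its slot instead of a
    result, leaving the other subset's fit intact.
    """
    merged = _align(features, ratings)
    if "distance_class" not in merged.columns:
        raise ValueError("ratings table needs a 'distance_class' column")
    unknown = set(merged["distance_class"]) - set(DISTANCE_CLASSES)
    if unknown:
        raise ValueError(f"unknown distance_class values: {sorted(unknown)}")
    cols = [c for c in features.columns if c != "image_id"]
    out: dict[str, RegressionResult | Exception] = {}
    for cls in ("close", "far"):
        sub = merged[merged["distance_class"] == cls]
        try:
            if sub.empty:
                raise UnderdeterminedError(f"no rows labeled {cls!r}")
            out[cls] = (
                ValenceRegression(rank_tol=rank_tol)
                .fit(sub[cols], sub["valence"])
                .result_
            )
        except UnderdeterminedError as err:
            out[cls] = err
    return out
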