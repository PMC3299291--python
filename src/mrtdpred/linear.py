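"""Linear dose models: the published MLR equation and a from-scratch OLS refit.

The published multiple linear regression predicts MRTD (mg/kg/day) as

    MRTD = -34.3303 - 12.20*AlogP + 2.1249*ASol + 15.90*logBioHL
           + 0.2159*MW + 5.659*OxidHL + 46.5133*P[BD]

Predictions are a plain affine map of the six descriptors and may be
negative; no clipping is applied (the published external-test column
contains negative values).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import DESCRIPTOR_COLUMNS, descriptor_matrix, subset_frame

#: Eq.-style published coefficients, mg/kg/day per descriptor unit.
PUBLISHED_INTERCEPT = -34.3303
PUBLISHED_COEF = {
    "oxid_hl": 5.659,
    "p_bd": 46.5133,
    "log_bio_hl": 15.90,
    "alogp": -12.20,
    "asol": 2.1249,
    "mw": 0.2159,
}

# Number of estimated parameters: six slopes + intercept.
_N_PARAMS = len(DESCRIPTOR_COLUMNS) + 1


class DescriptorLinearRegression(RegressorMixin, BaseEstimator):
    """OLS regression of MRTD on the six molecular property descriptors.

    Follows the scikit-learn estimator protocol.  :meth:`fit` solves the
    least-squares problem by a numerically stable orthogonal
    decomposition (via statsmodels) and populates classical inference
    statistics with ``n - 7`` residual degrees of freedom.

    Fitted attributes
    -----------------
    intercept_ : float
    coef_ : ndarray of shape (6,)
        Slopes in the canonical descriptor order.
    coef_se_, t_values_, p_values_ : ndarray of shape (7,)
        Standard errors, t statistics and two-sided p-values for
        (intercept, slopes); ``p_values_`` uses Student's t with
        ``df = n - 7``.
    r2_, mcc_, rsd_, f_statistic_, f_pvalue_ : float
        Coefficient of determination, multiple correlation coefficient
        ``sqrt(R2)``, residual standard deviation ``sqrt(SSE/(n-7))``,
        ANOVA F ratio and its p-value.
    n_, df_resid_ : int
    """

    def __init__(self):
        pass

    # -- construction from published constants --------------------------------

    @classmethod
    def from_published(cls) -> "DescriptorLinearRegression":
        """The published dose equation as a ready-to-use (pre-fitted) model.

        Carries no inference statistics: only the printed intercept and
        six coefficients.
        """
        model = cls()
        model.intercept_ = PUBLISHED_INTERCEPT
        model.coef_ = np.array([PUBLISHED_COEF[c] for c in DESCRIPTOR_COLUMNS])
        model.n_features_in_ = len(DESCRIPTOR_COLUMNS)
        return model

    # -- sklearn protocol ------------------------------------------------------

    def fit(self, X, y):
        """Fit by ordinary least squares with coefficient inference.

        Parameters
        ----------
        X : dataset frame, mapping or (n, 6) array
        y : array of MRTD values, mg/kg/day

        Raises
        ------
        ValueError
            if ``n < 8`` (no residual degrees of freedom) or the design
            matrix is rank-deficient (the message names the collinear
            columns).
        """
        A = descriptor_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if A.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        n = A.shape[0]
        if n < _N_PARAMS + 1:
            raise ValueError(
                f"need at least {_N_PARAMS + 1} observations to fit "
                f"{_N_PARAMS} parameters with inference, got {n}"
            )
        design = sm.add_constant(A, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                "design matrix is rank-deficient; collinear column(s): "
                + ", ".join(self._collinear_columns(design))
            )

        res = sm.OLS(y, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.coef_se_ = np.asarray(res.bse, dtype=float)
        self.t_values_ = np.asarray(res.tvalues, dtype=float)
        self.p_values_ = np.asarray(res.pvalues, dtype=float)
        self.r2_ = float(res.rsquared)
        self.mcc_ = float(np.sqrt(res.rsquared))
        self.df_resid_ = int(res.df_resid)
        self.rsd_ = float(np.sqrt(res.ssr / res.df_resid))
        self.f_statistic_ = float(res.fvalue)
        self.f_pvalue_ = float(res.f_pvalue)
        self.n_ = n
        self.n_features_in_ = A.shape[1]
        self._cov_params = np.asarray(res.cov_params(), dtype=float)
        return self

    @staticmethod
    def _collinear_columns(design: np.ndarray) -> list[str]:
        names = ["intercept", *DESCRIPTOR_COLUMNS]
        flagged = []
        for j in range(1, design.shape[1]):
            others = np.delete(design, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
            resid = design[:, j] - others @ beta
            scale = np.linalg.norm(design[:, j]) or 1.0
            if np.linalg.norm(resid) / scale < 1e-10:
                flagged.append(names[j])
        return flagged or ["<unidentified>"]

    def predict(self, X) -> np.ndarray:
        """Predicted MRTD, mg/kg/day (may be negative; no clipping)."""
        A = descriptor_matrix(X)
        return self.intercept_ + A @ self.coef_

    # -- extras ----------------------------------------------------------------

    @property
    def coef_named_(self) -> dict[str, float]:
        return dict(zip(DESCRIPTOR_COLUMNS, map(float, self.coef_)))

    def coef_confint(self, alpha: float = 0.05) -> np.ndarray:
        """(7, 2) confidence bounds for (intercept, slopes) at level 1-alpha."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        est = np.concatenate([[self.intercept_], self.coef_])
        half = tcrit * self.coef_se_
        return np.column_stack([est - half, est + half])

    def to_dict(self) -> dict:
        """Flat key-value export (portable to the CLI and JSON files)."""
        doc = {
            "kind": "linear",
            "intercept": float(self.intercept_),
            "coef": self.coef_named_,
        }
        if hasattr(self, "coef_se_"):
            doc["coef_se"] = dict(
                zip(("intercept",) + DESCRIPTOR_COLUMNS, map(float, self.coef_se_))
            )
            doc["stats"] = {
                "n": self.n_,
                "r2": self.r2_,
                "mcc": self.mcc_,
                "rsd": self.rsd_,
                "f_statistic": self.f_statistic_,
                "f_pvalue": self.f_pvalue_,
                "p_values": dict(
                    zip(("intercept",) + DESCRIPTOR_COLUMNS, map(float, self.p_values_))
                ),
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "DescriptorLinearRegression":
        model = cls()
        model.intercept_ = float(doc["intercept"])
        model.coef_ = np.array([float(doc["coef"][c]) for c in DESCRIPTOR_COLUMNS])
        model.n_features_in_ = len(DESCRIPTOR_COLUMNS)
        if "coef_se" in doc:
            keys = ("intercept",) + DESCRIPTOR_COLUMNS
            model.coef_se_ = np.array([float(doc["coef_se"][k]) for k in keys])
        if "stats" in doc:
            s = doc["stats"]
            model.n_ = int(s["n"])
            model.r2_ = float(s["r2"])
            model.mcc_ = float(s["mcc"])
            model.rsd_ = float(s["rsd"])
            model.f_statistic_ = float(s["f_statistic"])
            model.f_pvalue_ = float(s["f_pvalue"])
            model.df_resid_ = model.n_ - _N_PARAMS
            keys = ("intercept",) + DESCRIPTOR_COLUMNS
            model.p_values_ = np.array([float(s["p_values"][k]) for k in keys])
        return model


def published_mlr() -> DescriptorLinearRegression:
    """The published multiple linear regression dose equation."""
    return DescriptorLinearRegression.from_published()


def predict_linear(model: DescriptorLinearRegression, descriptors) -> np.ndarray:
    """Evaluate a linear dose model on descriptor input."""
    return model.predict(descriptors)


def fit_ols(ds: pd.DataFrame, subset: str = "train") -> DescriptorLinearRegression:
    """Refit the six-descriptor OLS model on one subset of a dataset."""
    sub = subset_frame(ds, subset)
    if sub["mrtd"].isna().any():
        raise ValueError("cannot fit: subset contains rows without MRTD")
    return DescriptorLinearRegression().fit(sub, sub["mrtd"].to_numpy())


def univariate_screen(ds: pd.DataFrame, subset: str = "train") -> pd.DataFrame:
    """Pearson correlation of each descriptor with MRTD over one subset.

    Returns a frame indexed by descriptor with columns ``pearson_r``,
    ``r2`` (= pearson_r**2) and ``degenerate``.  A zero-variance
    descriptor column gets NaN correlation and ``degenerate=True`` with a
    warning rather than an exception.
    """
    sub = subset_frame(ds, subset)
    if len(sub) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    y = sub["mrtd"].to_numpy(dtype=float)
    rows = {}
    for col in DESCRIPTOR_COLUMNS:
        x = sub[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"correlation undefined for zero-variance column {col!r}",
                stacklevel=2,
            )
            rows[col] = {"pearson_r": np.nan, "r2": np.nan, "degenerate": True}
            continue
        r = float(stats.pearsonr(x, y)[0])
        rows[col] = {"pearson_r": r, "r2": r * r, "degenerate": False}
    return pd.DataFrame(rows).T
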