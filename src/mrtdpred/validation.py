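"""Model validation: error scoring, rank correlation, and Bland-Altman agreement.

These are the statistics used to compare the two published dose models on
the external test compounds: per-compound squared errors with RMSE
(divisor n), Kendall's tau-a with an exact small-sample p-value from the
inversion-count (Mahonian) distribution, and Bland-Altman limits of
agreement on the clinical-minus-predicted differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import subset_frame


# -- prediction scoring --------------------------------------------------------


@dataclass
class PredictionTable:
    """Per-compound predictions with squared errors and aggregates.

    ``rmse`` uses divisor n (the mean of the squared errors), matching
    the published error summaries.
    """

    table: pd.DataFrame  # columns: name, clinical, predicted, sq_error
    mean_clinical: float
    mean_predicted: float
    rmse: float
    max_sq_error: float

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def score_predictions(clinical, predicted, names=None) -> PredictionTable:
    """Square the per-compound errors and aggregate them.

    Differences are ``clinical - predicted``; RMSE is the root of their
    mean square (divisor n).
    """
    clinical = np.asarray(clinical, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if clinical.shape != predicted.shape:
        raise ValueError("clinical and predicted have different lengths")
    if clinical.size == 0:
        raise ValueError("need at least one pair")
    if names is None:
        names = [f"item{i + 1}" for i in range(clinical.size)]
    sq = (clinical - predicted) ** 2
    table = pd.DataFrame(
        {"name": list(names), "clinical": clinical, "predicted": predicted, "sq_error": sq}
    )
    return PredictionTable(
        table=table,
        mean_clinical=float(clinical.mean()),
        mean_predicted=float(predicted.mean()),
        rmse=float(np.sqrt(sq.mean())),
        max_sq_error=float(sq.max()),
    )


# -- Kendall rank correlation --------------------------------------------------


@dataclass
class RankCorrelation:
    tau: float
    n: int
    discordant: int
    p_two_sided: float
    method: str  # exact_enumeration | normal_approx | tau_b_normal_approx


def _inversion_count_pmf(n: int) -> np.ndarray:
    """Mahonian counts: number of permutations of n with k inversions.

    Classic DP over the triangle of inversion counts; index k runs from 0
    to n(n-1)/2.
    """
    counts = np.array([1], dtype=float)
    for m in range(2, n + 1):
        # convolve with the uniform kernel of length m
        kernel = np.ones(m)
        counts = np.convolve(counts, kernel)
    return counts


def _exact_two_sided_p(n: int, discordant: int) -> float:
    """P(|tau| >= observed) under the null, from the inversion distribution."""
    counts = _inversion_count_pmf(n)
    total = counts.sum()  # n!
    m = n * (n - 1) // 2
    d = discordant
    # distribution is symmetric about m/2; fold to the smaller tail
    lower = counts[: d + 1].sum()
    upper = counts[d:].sum()
    return float(min(1.0, 2.0 * min(lower, upper) / total))


def kendall_tau(x, y) -> RankCorrelation:
    """Kendall's tau between two paired value lists.

    For tie-free data this is tau-a, ``1 - 4 D / (n (n - 1))`` with D the
    number of discordant (inverted) pairs, and the two-sided p-value is
    exact for ``n <= 10`` (full inversion-count enumeration); larger
    samples use the normal approximation
    ``z = 3 tau sqrt(n (n - 1)) / sqrt(2 (2 n + 5))``.

    Ties are permitted but fall back to tau-b with a warning and a
    normal-approximation p-value; the ``method`` field records which
    procedure produced the p.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y have different lengths")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for a constant input vector")

    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    has_ties = bool(np.any(dx[iu] == 0) or np.any(dy[iu] == 0))

    npairs = n * (n - 1) // 2
    if has_ties:
        warnings.warn("ties present; falling back to tau-b", stacklevel=2)
        tx = npairs - int(np.sum(np.abs(dx[iu])))
        ty = npairs - int(np.sum(np.abs(dy[iu])))
        denom = math.sqrt((npairs - tx) * (npairs - ty))
        tau = (concordant - discordant) / denom
        method = "tau_b_normal_approx"
        z = 3 * tau * math.sqrt(n * (n - 1)) / math.sqrt(2 * (2 * n + 5))
        p = float(min(1.0, math.erfc(abs(z) / math.sqrt(2))))
    else:
        tau = 1.0 - 4.0 * discordant / (n * (n - 1))
        if n <= 10:
            method = "exact_enumeration"
            p = _exact_two_sided_p(n, discordant)
        else:
            method = "normal_approx"
            z = 3 * tau * math.sqrt(n * (n - 1)) / math.sqrt(2 * (2 * n + 5))
            p = float(min(1.0, math.erfc(abs(z) / math.sqrt(2))))
    return RankCorrelation(
        tau=float(tau), n=n, discordant=discordant, p_two_sided=p, method=method
    )


# -- Bland-Altman agreement ----------------------------------------------------


@dataclass
class AgreementReport:
    """Limits of agreement between clinical and predicted doses.

    Differences are taken as ``clinical - predicted``; limits sit at
    ``bias +/- multiplier * SD`` of the differences (sample SD, n-1).
    """

    bias: float
    sd_diff: float
    upper_loa: float
    lower_loa: float
    averages: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)
    all_within_limits: bool = True
    multiplier: float = 1.96


def bland_altman(clinical, predicted, multiplier: float = 1.96) -> AgreementReport:
    """Bland-Altman agreement of predicted against clinical doses."""
    clinical = np.asarray(clinical, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if clinical.shape != predicted.shape:
        raise ValueError("clinical and predicted have different lengths")
    if clinical.size < 2:
        raise ValueError("need at least 2 pairs for limits of agreement")
    diffs = clinical - predicted
    avgs = (clinical + predicted) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    upper = bias + multiplier * sd
    lower = bias - multiplier * sd
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        upper_loa=upper,
        lower_loa=lower,
        averages=avgs,
        differences=diffs,
        all_within_limits=bool(np.all((diffs >= lower) & (diffs <= upper))),
        multiplier=multiplier,
    )


# -- goodness of fit -----------------------------------------------------------


@dataclass
class GoodnessOfFit:
    """Training-fit summary reporting both common R-squared definitions.

    ``r2_sse`` is 1 - SSE/SST; ``r2_pearson`` is the squared Pearson
    correlation between clinical and predicted values.  The two coincide
    for a least-squares linear fit with intercept but differ for an
    arbitrary predictor, so both are reported.
    """

    r2_sse: float
    r2_pearson: float
    rmse: float
    max_abs_error: float
    n: int


def goodness_of_fit(clinical, predicted) -> GoodnessOfFit:
    clinical = np.asarray(clinical, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if clinical.shape != predicted.shape:
        raise ValueError("clinical and predicted have different lengths")
    n = clinical.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sst = float(np.sum((clinical - clinical.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero-variance clinical vector")
    resid = clinical - predicted
    sse = float(np.sum(resid**2))
    if np.ptp(predicted) == 0:
        r2p = math.nan
    else:
        r2p = float(np.corrcoef(clinical, predicted)[0, 1] ** 2)
    return GoodnessOfFit(
        r2_sse=1.0 - sse / sst,
        r2_pearson=r2p,
        rmse=float(np.sqrt(sse / n)),
        max_abs_error=float(np.max(np.abs(resid))),
        n=n,
    )


# -- two-model comparison ------------------------------------------------------


@dataclass
class ModelReport:
    label: str
    predictions: PredictionTable
    rank_correlation: RankCorrelation
    agreement: AgreementReport


@dataclass
class ModelComparison:
    """Side-by-side validation of two dose models on one subset."""

    reports: tuple[ModelReport, ModelReport]

    def to_frame(self) -> pd.DataFrame:
        """Per-compound layout: clinical dose plus each model's prediction
        and squared error."""
        a, b = self.reports
        out = a.predictions.table[["name", "clinical"]].copy()
        for rep in (a, b):
            out[rep.label] = rep.predictions.table["predicted"].to_numpy()
            out[f"{rep.label}_sq_error"] = rep.predictions.table["sq_error"].to_numpy()
        return out

    def to_dict(self) -> dict:
        doc = {}
        for rep in self.reports:
            doc[rep.label] = {
                "rmse": rep.predictions.rmse,
                "max_sq_error": rep.predictions.max_sq_error,
                "mean_clinical": rep.predictions.mean_clinical,
                "mean_predicted": rep.predictions.mean_predicted,
                "tau": rep.rank_correlation.tau,
                "tau_p_two_sided": rep.rank_correlation.p_two_sided,
                "tau_p_method": rep.rank_correlation.method,
                "bias": rep.agreement.bias,
                "upper_loa": rep.agreement.upper_loa,
                "lower_loa": rep.agreement.lower_loa,
                "all_within_limits": rep.agreement.all_within_limits,
                "predictions": {
                    str(r["name"]): float(r["predicted"])
                    for _, r in rep.predictions.table.iterrows()
                },
            }
        return doc


def compare_models(
    ds: pd.DataFrame,
    model_a,
    model_b,
    labels: tuple[str, str] = ("model_a", "model_b"),
    subset: str = "test",
) -> ModelComparison:
    """Score two fitted dose models on one subset of a dataset.

    Each model contributes a prediction table (RMSE, max squared error),
    a Kendall rank correlation against the clinical doses, and a
    Bland-Altman agreement report.
    """
    sub = subset_frame(ds, subset)
    if sub["mrtd"].isna().any():
        raise ValueError("comparison subset contains rows without clinical MRTD")
    clinical = sub["mrtd"].to_numpy(dtype=float)
    names = sub["name"].tolist()
    reports = []
    for label, model in zip(labels, (model_a, model_b)):
        predicted = np.asarray(model.predict(sub), dtype=float)
        reports.append(
            ModelReport(
                label=label,
                predictions=score_predictions(clinical, predicted, names),
                rank_correlation=kendall_tau(clinical, predicted),
                agreement=bland_altman(clinical, predicted),
            )
        )
    return ModelComparison(reports=(reports[0], reports[1]))
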