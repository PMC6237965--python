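"""Temperature anomalies, trend fitting, and proxy-year selection.

Anomalies are departures of monthly values from their calendar-month
climatological mean over a baseline window (default 1961-1990).  Candidate
study years (December-November spans) are compared against a reference
anomaly series with a trimmed-means heteroscedastic one-way test; the
candidate with the lowest annual anomaly that does not differ from the
reference becomes the baseline proxy, the one with the highest anomaly
that sits significantly above the reference becomes the warm proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

DEFAULT_BASELINE = (1961, 1990)


@dataclass
class TrendFit:
    degree: int
    coefficients: np.ndarray  # ascending powers of centered year
    center: float
    fitted: pd.Series  # year -> fitted value
    se_fit: pd.Series  # pointwise standard error
    residuals: pd.Series


@dataclass
class ProxyAssignment:
    baseline_year: int | None
    warm_year: int | None
    annual_means: dict[int, float] = field(default_factory=dict)
    annual_sds: dict[int, float] = field(default_factory=dict)
    p_values: dict[int, float] = field(default_factory=dict)
    omnibus_p: float = float("nan")


def monthly_anomalies(
    series: pd.DataFrame,
    baseline: tuple[int, int] = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Anomaly of each monthly value against its baseline calendar-month mean.

    *series* is a tidy frame with integer columns ``year``, ``month`` and a
    float ``value``.  Returns the same frame with ``value`` replaced by the
    anomaly.  Every calendar month must be observed at least once inside the
    baseline window.
    """
    need = {"year", "month", "value"}
    if not need.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(need)}")
    y0, y1 = baseline
    base = series[(series["year"] >= y0) & (series["year"] <= y1)]
    clim = base.groupby("month")["value"].mean()
    missing = sorted(set(range(1, 13)) - set(clim.index))
    if missing:
        raise ValueError(f"baseline window {baseline} has no data for months {missing}")
    out = series.copy()
    out["value"] = series["value"].to_numpy() - clim.reindex(series["month"]).to_numpy()
    return out


def annual_means(anomalies: pd.DataFrame) -> pd.Series:
    """Calendar-year means of a monthly anomaly frame."""
    return anomalies.groupby("year")["value"].mean()


def fit_anomaly_trend(annual: pd.Series, degree: int = 2) -> TrendFit:
    """Least-squares polynomial fit of annual anomalies on (centered) year.

    Returns coefficients in ascending powers, fitted values and the
    pointwise standard-error band of the mean curve.
    """
    years = np.asarray(annual.index, dtype=float)
    vals = np.asarray(annual.to_numpy(), dtype=float)
    if len(years) < degree + 2:
        raise ValueError(f"need at least {degree + 2} annual points for degree {degree}")
    center = years.mean()
    x = years - center
    X = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(vals, X).fit()
    pred = fit.get_prediction(X)
    return TrendFit(
        degree=degree,
        coefficients=fit.params.copy(),
        center=center,
        fitted=pd.Series(fit.fittedvalues, index=annual.index),
        se_fit=pd.Series(pred.se_mean, index=annual.index),
        residuals=pd.Series(fit.resid, index=annual.index),
    )


# -- trimmed-means heteroscedastic one-way comparison -----------------------

def _winsorized_var(x: np.ndarray, trim: float) -> float:
    n = len(x)
    g = int(np.floor(trim * n))
    xs = np.sort(x)
    w = xs.copy()
    w[:g] = xs[g]
    w[n - g:] = xs[n - g - 1]
    return float(np.var(w, ddof=1))


def trimmed_oneway(groups: list[np.ndarray], trim: float = 0.2) -> tuple[float, float]:
    """Heteroscedastic one-way comparison of trimmed means (Welch-type).

    Returns (F statistic, p-value).  With two groups this is equivalent to
    the two-sided Yuen test (F = t^2).
    """
    J = len(groups)
    if J < 2:
        raise ValueError("need at least two groups")
    h = np.empty(J)
    xbar = np.empty(J)
    d = np.empty(J)
    for j, x in enumerate(groups):
        x = np.asarray(x, dtype=float)
        n = len(x)
        g = int(np.floor(trim * n))
        h[j] = n - 2 * g
        if h[j] < 2:
            raise ValueError("group too small for trimming level")
        xbar[j] = st.trim_mean(x, trim)
        d[j] = (n - 1) * _winsorized_var(x, trim) / (h[j] * (h[j] - 1))
    w = 1.0 / d
    U = w.sum()
    xtilde = (w * xbar).sum() / U
    A = (w * (xbar - xtilde) ** 2).sum() / (J - 1)
    B = 2 * (J - 2) / (J**2 - 1) * ((1 - w / U) ** 2 / (h - 1)).sum()
    F = A / (1 + B)
    df2 = 1.0 / (3.0 / (J**2 - 1) * ((1 - w / U) ** 2 / (h - 1)).sum())
    p = float(st.f.sf(F, J - 1, df2))
    return float(F), p


def study_year_groups(anomalies: pd.DataFrame, years: list[int]) -> dict[int, np.ndarray]:
    """Monthly anomalies of each Dec-Nov study year (labelled by end year)."""
    out: dict[int, np.ndarray] = {}
    for y in years:
        sel = ((anomalies["year"] == y - 1) & (anomalies["month"] == 12)) | (
            (anomalies["year"] == y) & (anomalies["month"] <= 11)
        )
        vals = anomalies.loc[sel].sort_values(["year", "month"])["value"].to_numpy()
        if len(vals) != 12:
            raise ValueError(f"study year {y} has {len(vals)} months, expected 12")
        out[y] = vals
    return out


def classify_proxy_years(
    local: pd.DataFrame,
    reference: pd.DataFrame,
    candidate_years: list[int],
    alpha: float = 0.05,
    trim: float = 0.2,
) -> ProxyAssignment:
    """Pick baseline and warm proxy study years from local anomalies.

    Both inputs are monthly anomaly frames (year, month, value); study years
    run December-November and are labelled by the ending year.  Each
    candidate is compared against the reference anomalies of the same
    months.  An omnibus trimmed one-way comparison across all candidate
    groups plus the pooled reference gates the pairwise calls, so under a
    global null the warm declaration keeps its nominal type-I rate.
    Either role can come back ``None`` ("no proxy found").
    """
    if len(candidate_years) < 2:
        raise ValueError("need at least two candidate study years")
    local_groups = study_year_groups(local, candidate_years)
    ref_groups = study_year_groups(reference, candidate_years)

    means = {y: float(np.mean(v)) for y, v in local_groups.items()}
    sds = {y: float(np.std(v, ddof=1)) for y, v in local_groups.items()}

    pooled_ref = np.concatenate([ref_groups[y] for y in candidate_years])
    _, omnibus_p = trimmed_oneway(
        [local_groups[y] for y in candidate_years] + [pooled_ref], trim=trim
    )

    pvals: dict[int, float] = {}
    for y in candidate_years:
        res = st.ttest_ind(local_groups[y], ref_groups[y], equal_var=False, trim=trim)
        pvals[y] = float(res.pvalue)

    lo = min(candidate_years, key=lambda y: means[y])
    hi = max(candidate_years, key=lambda y: means[y])

    baseline = lo if pvals[lo] >= alpha else None
    warm = None
    if omnibus_p < alpha:
        diff = means[hi] - float(np.mean(ref_groups[hi]))
        if pvals[hi] < alpha and diff > 0:
            warm = hi
    if baseline is not None and warm is not None and baseline == warm:
        warm = None

    return ProxyAssignment(
        baseline_year=baseline,
        warm_year=warm,
        annual_means=means,
        annual_sds=sds,
        p_values=pvals,
        omnibus_p=omnibus_p,
    )
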