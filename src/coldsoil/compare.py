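"""Site classification, year x site mixed-model contrasts, and agreement
between sensor-derived and satellite-derived snow flags."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from sklearn.cluster import KMeans

from .sensors import Flag

SITE_CLASSES = ("open", "partially forested", "forested")


@dataclass
class SiteClassAssignment:
    classes: dict[str, str]  # plot_id -> class name
    centers: list[float]  # ascending LAI cluster centers


@dataclass
class ContrastReport:
    response: str
    fixed_effects: pd.DataFrame  # term -> estimate, se, p
    site_contrasts: pd.DataFrame  # site, estimate, se, p (year difference)
    log_transformed: bool
    random_variances: dict[str, float]
    converged: bool
    single_plot_fallback: bool = False


@dataclass
class AgreementMatrix:
    tp: int  # reference snow, predicted snow
    tn: int
    fp: int
    fn: int
    n_excluded: int = 0  # plot-days dropped because either flag was unknown

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def overall_accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def classify_sites_by_lai(lai: dict[str, float], k: int = 3,
                          seed: int = 0) -> SiteClassAssignment:
    """K-means (k=3) on plot LAI; classes named by ascending cluster center."""
    if len(lai) < k:
        raise ValueError(f"need at least {k} plots")
    values = np.array(list(lai.values()), dtype=float).reshape(-1, 1)
    if len(np.unique(values)) < k:
        raise ValueError(f"need at least {k} distinct LAI values")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values)
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    names = SITE_CLASSES if k == 3 else tuple(f"class_{i}" for i in range(k))
    classes = {p: names[rank[lbl]] for p, lbl in zip(lai, km.labels_)}
    centers = sorted(float(c) for c in km.cluster_centers_.ravel())
    return SiteClassAssignment(classes=classes, centers=centers)


def _residual_normality_ok(resid: np.ndarray, alpha: float = 0.01) -> bool:
    if len(resid) < 3 or np.ptp(resid) == 0:
        return True
    return scipy.stats.shapiro(resid).pvalue >= alpha


def fit_year_site_contrast(
    stats: pd.DataFrame,
    response: str = "value",
    log_transform: str = "auto",
    baseline_year: int | None = None,
    warm_year: int | None = None,
) -> ContrastReport:
    """Mixed model: year, site, year x site fixed; plot and sensor-in-plot
    random intercepts; per-site warm-minus-baseline contrasts.

    *stats* needs columns plot_id, sensor_id, year_label, site and the
    response.  ``log_transform="auto"`` logs a strictly positive response
    when an OLS residual normality check fails.  A single plot degrades the
    random structure to a sensor-only intercept (flagged in the report).
    """
    df = stats.copy()
    need = {"plot_id", "sensor_id", "year_label", "site", response}
    if not need.issubset(df.columns):
        raise ValueError(f"stats must have columns {sorted(need)}")
    years = sorted(df["year_label"].unique())
    if len(years) != 2:
        raise ValueError("exactly two study years are required for the contrast")
    if baseline_year is None or warm_year is None:
        baseline_year, warm_year = years
    sites = [s for s in SITE_CLASSES if s in set(df["site"])] or sorted(df["site"].unique())

    df["y"] = df[response].astype(float)
    logged = False
    if log_transform == "always" or (
        log_transform == "auto"
        and (df["y"] > 0).all()
        and not _residual_normality_ok(
            df["y"] - df.groupby(["year_label", "site"])["y"].transform("mean")
        )
    ):
        df["y"] = np.log(df["y"])
        logged = True

    df["year_f"] = pd.Categorical(df["year_label"], categories=[baseline_year, warm_year])
    df["site_f"] = pd.Categorical(df["site"], categories=sites)
    df["sensor_uid"] = df["plot_id"].astype(str) + ":" + df["sensor_id"].astype(str)

    single_plot = df["plot_id"].nunique() < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_plot:
            model = smf.mixedlm("y ~ year_f * site_f", df, groups=df["sensor_uid"])
            fit = model.fit(reml=True)
            rand = {"sensor": float(np.asarray(fit.cov_re).ravel()[0])}
        else:
            model = smf.mixedlm(
                "y ~ year_f * site_f",
                df,
                groups=df["plot_id"],
                re_formula="1",
                vc_formula={"sensor": "0 + C(sensor_uid)"},
            )
            fit = model.fit(reml=True)
            rand = {
                "plot": float(np.asarray(fit.cov_re).ravel()[0]),
                "sensor": float(fit.vcomp[0]) if len(fit.vcomp) else 0.0,
            }
    rand["residual"] = float(fit.scale)

    fe = pd.DataFrame(
        {"estimate": fit.fe_params, "se": fit.bse_fe, "p": fit.pvalues[fit.fe_params.index]}
    )

    # per-site warm-minus-baseline contrast: year main effect + interaction
    exog_names = model.exog_names
    year_term = f"year_f[T.{warm_year}]"
    rows = []
    for site in sites:
        contrast = np.zeros(len(exog_names))
        if year_term not in exog_names:
            raise RuntimeError("year term missing from design")
        contrast[exog_names.index(year_term)] = 1.0
        inter = f"{year_term}:site_f[T.{site}]"
        if inter in exog_names:
            contrast[exog_names.index(inter)] = 1.0
        tt = fit.t_test(contrast.reshape(1, -1))
        rows.append(
            {
                "site": site,
                "estimate": float(np.atleast_1d(tt.effect)[0]),
                "se": float(np.atleast_1d(tt.sd.ravel())[0]),
                "p": float(np.atleast_1d(tt.pvalue)[0]),
            }
        )
    return ContrastReport(
        response=response,
        fixed_effects=fe,
        site_contrasts=pd.DataFrame(rows),
        log_transformed=logged,
        random_variances=rand,
        converged=bool(fit.converged),
        single_plot_fallback=single_plot,
    )


def snow_agreement(reference: pd.Series, predicted: pd.Series) -> AgreementMatrix:
    """2x2 agreement counts between two plot-day flag series.

    Only dates present in both series with both flags known contribute;
    unknowns are excluded and counted separately.
    """
    joined = pd.concat({"ref": reference, "pred": predicted}, axis=1, join="inner")
    if joined.empty:
        raise ValueError("no overlapping dates between the two flag series")
    known = (joined != Flag.UNKNOWN).all(axis=1) & joined.notna().all(axis=1)
    sub = joined[known]
    ref_snow = sub["ref"] == Flag.SNOW
    pred_snow = sub["pred"] == Flag.SNOW
    return AgreementMatrix(
        tp=int((ref_snow & pred_snow).sum()),
        tn=int((~ref_snow & ~pred_snow).sum()),
        fp=int((~ref_snow & pred_snow).sum()),
        fn=int((ref_snow & ~pred_snow).sum()),
        n_excluded=int((~known).sum()),
    )


def pooled_agreement(matrices: list[AgreementMatrix]) -> AgreementMatrix:
    return AgreementMatrix(
        tp=sum(m.tp for m in matrices),
        tn=sum(m.tn for m in matrices),
        fp=sum(m.fp for m in matrices),
        fn=sum(m.fn for m in matrices),
        n_excluded=sum(m.n_excluded for m in matrices),
    )
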