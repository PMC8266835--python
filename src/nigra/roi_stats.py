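"""ROI-level statistics: skewness mixed model, demographics, correlations.

The subject-level ESNV skewness, one value per SN sub-ROI, is analysed
with a linear mixed model: fixed effects of group (PD vs HC), ROI (4 SN
tiers) and their interaction, and a random intercept per subject to
absorb between-subject level differences (fit by REML). Group comparisons
are reported as least-square means with a Tukey-adjusted contrast — which
for two groups reduces to the unadjusted t test, but the adjustment is
applied regardless.

Demographics use the Pearson chi-square (no continuity correction) for
sex counts and the pooled-variance two-sample t test for age. Clinical
correlations (skewness vs UPDRS III, disease duration, H&Y, LEDD) are
exploratory Pearson r with unadjusted p. A final ROI-level regression
tests whether the within-PD slope of putamen Ki on lateral-SN R2* differs
between pre- and post-commissural putamen (the group x R2* x ROI triple
interaction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "fit_lmm_skewness",
    "pearson_chi_square",
    "two_sample_t",
    "clinical_correlations",
    "roi_triple_interaction",
]


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame  # term, F, df_num, df_den, p
    ls_means: dict[str, float]  # group -> least-square mean
    group_contrast_t: float
    group_contrast_df: int
    group_contrast_p_tukey: float
    random_intercept_var: float
    residual_var: float
    converged: bool
    params: pd.Series = field(repr=False, default=None)


def _wald_f(params: np.ndarray, cov: np.ndarray, L: np.ndarray, df_den: float) -> tuple[float, int, float]:
    """Wald F test of L beta = 0 with a chosen denominator df."""
    L = np.atleast_2d(L)
    q = np.linalg.matrix_rank(L)
    lb = L @ params
    mid = np.linalg.pinv(L @ cov @ L.T)
    F = float(lb @ mid @ lb) / q
    p = float(stats.f.sf(F, q, df_den))
    return F, q, p


def fit_lmm_skewness(table: pd.DataFrame) -> MixedModelResult:
    """Mixed model of ESNV skewness on group, ROI and their interaction.

    ``table`` is long-format with columns subject_id, group ("PD"/"HC"),
    roi (4 levels), skewness. The model has a subject random intercept and
    is fit by REML. F tests use containment-style denominator degrees of
    freedom: the between-subject group effect uses n_subjects - 2 (so the
    group contrast is a t on n_subjects - 2 df); ROI and interaction terms
    use the within-subject residual df.
    """
    required = {"subject_id", "group", "roi", "skewness"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table misses columns {sorted(missing)}")
    groups = sorted(table["group"].unique())
    if set(groups) != {"HC", "PD"}:
        raise ValueError("expected exactly the groups HC and PD")
    rois = sorted(table["roi"].unique())
    n_subj = table["subject_id"].nunique()
    n_obs = len(table)
    k_roi = len(rois)
    per_group = table.groupby("group")["subject_id"].nunique()
    if (per_group < 2).any():
        raise ValueError("need >= 2 subjects per group")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "skewness ~ C(group, Treatment('HC')) * C(roi)",
            data=table,
            groups=table["subject_id"],
        )
        fit = model.fit(reml=True)

    fe_names = list(fit.fe_params.index)
    params = fit.fe_params.to_numpy()
    cov = fit.cov_params().to_numpy()[: len(fe_names), : len(fe_names)]

    def term_selector(predicate) -> np.ndarray:
        idx = [j for j, name in enumerate(fe_names) if predicate(name)]
        L = np.zeros((len(idx), len(fe_names)))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        return L

    is_group = lambda s: "C(group" in s and ":" not in s
    is_roi = lambda s: "C(roi)" in s and ":" not in s
    is_inter = lambda s: ":" in s

    df_between = n_subj - 2
    df_within = n_obs - n_subj - (k_roi - 1) * 2  # roi + interaction params

    # the group main effect is tested at its LS-mean contrast (averaged
    # over ROI levels), matching how a 2-group mixed ANOVA reports it
    L_group = np.zeros((1, len(fe_names)))
    for j, name in enumerate(fe_names):
        if is_group(name):
            L_group[0, j] = 1.0
        elif is_inter(name):
            L_group[0, j] = 1.0 / k_roi

    rows = []
    F, q, p = _wald_f(params, cov, L_group, df_between)
    rows.append({"term": "group", "F": F, "df_num": q, "df_den": df_between, "p": p})
    for term, pred, dfd in (("roi", is_roi, df_within), ("group:roi", is_inter, df_within)):
        L = term_selector(pred)
        F, q, p = _wald_f(params, cov, L, dfd)
        rows.append({"term": term, "F": F, "df_num": q, "df_den": dfd, "p": p})

    # least-square means: average the fitted cell means over ROI levels
    def ls_mean_vector(group: str) -> np.ndarray:
        v = np.zeros(len(fe_names))
        for j, name in enumerate(fe_names):
            if name == "Intercept":
                v[j] = 1.0
            elif is_group(name):
                v[j] = 1.0 if group == "PD" else 0.0
            elif is_roi(name):
                v[j] = 1.0 / k_roi
            elif is_inter(name):
                v[j] = (1.0 / k_roi) if group == "PD" else 0.0
        return v

    v_pd, v_hc = ls_mean_vector("PD"), ls_mean_vector("HC")
    ls_means = {"PD": float(v_pd @ params), "HC": float(v_hc @ params)}
    d = v_pd - v_hc
    se = float(np.sqrt(d @ cov @ d))
    t_val = (ls_means["PD"] - ls_means["HC"]) / se
    # Tukey (studentized range) over the 2 group means; reduces to the
    # two-sided t test when only two means are compared
    p_tukey = float(stats.studentized_range.sf(abs(t_val) * np.sqrt(2.0), 2, df_between))

    return MixedModelResult(
        fixed_effects=pd.DataFrame(rows),
        ls_means=ls_means,
        group_contrast_t=float(t_val),
        group_contrast_df=df_between,
        group_contrast_p_tukey=p_tukey,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        residual_var=float(fit.scale),
        converged=bool(fit.converged),
        params=fit.fe_params,
    )


def pearson_chi_square(table2x2) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction; returns (chi2, df, p)."""
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def two_sample_t(
    x=None,
    y=None,
    x_summary: tuple[float, float, int] | None = None,
    y_summary: tuple[float, float, int] | None = None,
    pooled: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t test from raw samples or (mean, SD, n) summaries.

    Pooled-variance by default (the Welch variant is available for raw
    and summary input alike). Returns (t, df, p) two-sided.
    """
    if x is not None:
        x = np.asarray(x, dtype=float)
        x_summary = (x.mean(), x.std(ddof=1), x.size)
    if y is not None:
        y = np.asarray(y, dtype=float)
        y_summary = (y.mean(), y.std(ddof=1), y.size)
    if x_summary is None or y_summary is None:
        raise ValueError("provide samples or summaries for both groups")
    m1, s1, n1 = x_summary
    m2, s2, n2 = y_summary
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance")
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
        if se == 0:
            raise ValueError("zero variance")
        df = (s1**2 / n1 + s2**2 / n2) ** 2 / (
            (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
        )
    t_val = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t_val), df)
    return float(t_val), float(df), float(p)


CLINICAL_SCORES = ("updrs3", "duration_years", "hy", "ledd")


def clinical_correlations(
    metric: np.ndarray, scores: pd.DataFrame, score_names=CLINICAL_SCORES
) -> pd.DataFrame:
    """Pearson correlations of a per-subject metric with clinical scores.

    PD subjects only; missing scores are dropped pairwise. p-values are
    unadjusted (exploratory). Columns: score, n, r, p.
    """
    metric = np.asarray(metric, dtype=float)
    if len(metric) != len(scores):
        raise ValueError("metric and score table lengths differ")
    rows = []
    for name in score_names:
        if name not in scores.columns:
            warnings.warn(f"score {name!r} absent; skipped")
            continue
        s = scores[name].to_numpy(dtype=float)
        ok = np.isfinite(metric) & np.isfinite(s)
        if ok.sum() < 4:
            warnings.warn(f"score {name!r}: fewer than 4 complete pairs; skipped")
            continue
        if np.std(s[ok]) == 0 or np.std(metric[ok]) == 0:
            warnings.warn(f"score {name!r}: constant; skipped")
            continue
        r, p = stats.pearsonr(metric[ok], s[ok])
        rows.append({"score": name, "n": int(ok.sum()), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["score", "n", "r", "p"])


def roi_triple_interaction(table: pd.DataFrame) -> dict:
    """ROI-level group x R2* x putamen-ROI interaction on Ki.

    ``table`` is long-format with columns subject_id, group ("PD"/"HC"),
    roi ("anterior"/"posterior"), ki, r2star_lat (per-subject lateral-SN
    R2*, repeated across the two rows). Fits an OLS with all main effects
    and interactions; returns the F test of the three-way term (1 df
    numerator for 2 groups x 2 ROIs x 1 slope).
    """
    required = {"subject_id", "group", "roi", "ki", "r2star_lat"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table misses columns {sorted(missing)}")
    df = table.copy()
    df["r2c"] = df["r2star_lat"] - df["r2star_lat"].mean()
    model = smf.ols(
        "ki ~ C(group, Treatment('HC')) * r2c * C(roi, Treatment('anterior'))", data=df
    )
    fit = model.fit()
    tri = [name for name in fit.params.index if name.count(":") == 2]
    if len(tri) != 1:
        raise ValueError("design is rank deficient for the triple interaction")
    name = tri[0]
    t_val = float(fit.tvalues[name])
    return {
        "coef": float(fit.params[name]),
        "t": t_val,
        "F": t_val**2,
        "df_num": 1,
        "df_den": int(fit.df_resid),
        "p": float(fit.pvalues[name]),
        "model": fit,
    }
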