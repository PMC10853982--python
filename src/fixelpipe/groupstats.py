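"""Tract-of-interest group statistics.

Cross-sectional comparisons use covariate-adjusted one-way ANOVA (ANCOVA):
the group factor enters a linear model next to age, sex and head-size scale
(plus education for cognitive-profile contrasts, or treatment for the
sensitivity reruns); the group F statistic is the nested-RSS partial F.
Post-hoc pairwise group contrasts are Bonferroni-corrected within the
tract's family of pairs. Longitudinal change is modelled with linear
mixed-effects models (random subject intercept, fixed group, time and
group-by-time effects); per-phenotype time slopes combine the time and
interaction terms, with large-sample normal inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from .errors import DegenerateFitError, RankError


def bonferroni(p_values, family_size: int):
    """Bonferroni adjustment: min(1, p * family_size), elementwise."""
    p = np.asarray(p_values, dtype=float)
    out = np.minimum(1.0, p * family_size)
    return float(out) if out.ndim == 0 else out


@dataclass
class AncovaResult:
    """Covariate-adjusted one-way ANOVA for one tract x metric."""

    tract: str
    metric: str
    F: float
    p: float
    df_num: int
    df_den: int
    adjusted_means: pd.DataFrame   # group, mean, ci_low, ci_high, n
    posthoc: pd.DataFrame          # group_a, group_b, diff, t, p_raw, p_adj
    bonferroni_family: int
    covariates: list[str] = field(default_factory=list)


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def ancova_tract(values, group, covariates: pd.DataFrame,
                 tract: str = "", metric: str = "",
                 bonferroni_family: int | None = None) -> AncovaResult:
    """Group comparison of one tract metric, adjusted for covariates.

    Parameters
    ----------
    values:
        outcome vector (tract-mean metric per subject).
    group:
        group label per subject (>= 2 levels, each with n >= 2).
    covariates:
        DataFrame of numeric covariates (e.g. age, sex, head_scale,
        optionally education_high and/or treatment dummies); complete cases
        only.
    bonferroni_family:
        family size for the post-hoc adjustment; defaults to the number of
        group pairs.
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    n = len(y)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (group == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    C = covariates.to_numpy(dtype=float)
    if np.any(~np.isfinite(C)) or np.any(~np.isfinite(y)):
        raise ValueError("covariates and values must be complete")
    cov_names = list(covariates.columns)

    dummies = np.column_stack([(group == g).astype(float)
                               for g in levels[1:]])
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, dummies, C])
    X_red = np.hstack([ones, C])
    p_full = X_full.shape[1]
    if np.linalg.matrix_rank(X_full) < p_full:
        # a group nested within a covariate level (or collinear covariates)
        names = ["intercept"] + [f"group[{g}]" for g in levels[1:]] + cov_names
        r = np.linalg.matrix_rank(X_full)
        bad = [names[j] for j in range(p_full)
               if np.linalg.matrix_rank(np.delete(X_full, j, axis=1)) == r]
        raise RankError(f"confounded/collinear design columns: {bad}")

    beta_full, rss_full = _lstsq_rss(X_full, y)
    _, rss_red = _lstsq_rss(X_red, y)
    q = len(levels) - 1
    df_den = n - p_full
    if rss_full <= 0:
        F = np.inf if rss_red > rss_full else 0.0
        p = 0.0 if np.isinf(F) else 1.0
    else:
        F = max(0.0, ((rss_red - rss_full) / q) / (rss_full / df_den))
        p = float(st.f.sf(F, q, df_den))
    sigma2 = rss_full / df_den if df_den > 0 else 0.0
    XtX_inv = np.linalg.inv(X_full.T @ X_full)

    cbar = C.mean(axis=0)
    rows = []
    for g in levels:
        w = np.zeros(p_full)
        w[0] = 1.0
        if g != levels[0]:
            w[1 + levels[1:].index(g)] = 1.0
        w[1 + q:] = cbar
        mu = float(w @ beta_full)
        se = float(np.sqrt(sigma2 * w @ XtX_inv @ w))
        tcrit = st.t.ppf(0.975, df_den) if df_den > 0 else np.nan
        rows.append({"group": g, "mean": mu,
                     "ci_low": mu - tcrit * se, "ci_high": mu + tcrit * se,
                     "n": int((group == g).sum())})
    adjusted_means = pd.DataFrame(rows)

    pairs = list(combinations(levels, 2))
    fam = bonferroni_family if bonferroni_family is not None else len(pairs)
    ph = []
    for ga, gb in pairs:
        w = np.zeros(p_full)
        if ga != levels[0]:
            w[1 + levels[1:].index(ga)] = 1.0
        if gb != levels[0]:
            w[1 + levels[1:].index(gb)] -= 1.0
        diff = float(w @ beta_full)
        se = float(np.sqrt(sigma2 * w @ XtX_inv @ w))
        tval = diff / se if se > 0 else np.sign(diff) * np.inf
        praw = float(2 * st.t.sf(abs(tval), df_den))
        ph.append({"group_a": ga, "group_b": gb, "diff": diff, "t": tval,
                   "p_raw": praw, "p_adj": bonferroni(praw, fam)})
    return AncovaResult(
        tract=tract, metric=metric, F=float(F), p=p, df_num=q, df_den=df_den,
        adjusted_means=adjusted_means, posthoc=pd.DataFrame(ph),
        bonferroni_family=fam, covariates=cov_names)


def posthoc_pairwise(result: AncovaResult) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise group contrasts of a fitted ANCOVA."""
    return result.posthoc.copy()


@dataclass
class LmmResult:
    """Longitudinal mixed-model fit for one tract x metric."""

    tract: str
    metric: str
    fixed_effects: pd.DataFrame     # term, estimate, se, z, p
    random_intercept_var: float
    residual_var: float
    slopes: pd.DataFrame            # group, slope, se, z, p  (per year)
    converged: bool


def lmm_longitudinal(data: pd.DataFrame, value_col: str,
                     subject_col: str = "subject_id",
                     group_col: str = "group",
                     time_col: str = "time_years",
                     covariate_cols: list[str] | None = None,
                     tract: str = "", metric: str = "") -> LmmResult:
    """Random-intercept linear mixed model of change over time.

    Fixed effects: group, time (years since baseline), group x time and the
    given covariates; random intercept per subject; REML variance
    components; Wald (normal-approximation) p-values. The per-phenotype
    annual slope is the time effect plus that phenotype's interaction term.
    """
    covariate_cols = covariate_cols if covariate_cols is not None \
        else ["age", "sex"]
    df = data[[subject_col, group_col, time_col, value_col]
              + covariate_cols].dropna().copy()
    counts = df.groupby(subject_col)[time_col].nunique()
    if (counts < 2).all():
        raise DegenerateFitError(
            "all subjects have a single timepoint: the random-intercept "
            "variance is unidentifiable; use a cross-sectional model")
    cov_terms = "".join(f" + {c}" for c in covariate_cols)
    formula = (f"{value_col} ~ C({group_col}) + {time_col} "
               f"+ C({group_col}):{time_col}{cov_terms}")
    model = smf.mixedlm(formula, df, groups=df[subject_col])
    fit = None
    last_err = None
    # boundary variance (sigma_b ~ 0) can make an optimizer's Hessian
    # singular; fall through a few optimizers before giving up
    for method in ("lbfgs", "bfgs", "powell", "cg"):
        try:
            fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError as err:
            last_err = err
    if fit is None:
        raise DegenerateFitError(f"mixed model failed to fit: {last_err}")
    fe = fit.fe_params
    se = fit.bse_fe
    z = fe / se
    pvals = 2 * st.norm.sf(np.abs(z))
    fixed = pd.DataFrame({
        "term": fe.index, "estimate": fe.to_numpy(),
        "se": se.to_numpy(), "z": z.to_numpy(), "p": pvals,
    })

    levels = sorted(df[group_col].unique().tolist())
    cov_fe = fit.cov_params().loc[fe.index, fe.index]
    slope_rows = []
    for g in levels:
        w = pd.Series(0.0, index=fe.index)
        w[time_col] = 1.0
        inter = f"C({group_col})[T.{g}]:{time_col}"
        if inter in w.index:
            w[inter] = 1.0
        est = float(w @ fe)
        sse = float(np.sqrt(w @ cov_fe @ w))
        zz = est / sse if sse > 0 else np.nan
        slope_rows.append({"group": g, "slope": est, "se": sse, "z": zz,
                           "p": float(2 * st.norm.sf(abs(zz)))})
    return LmmResult(
        tract=tract, metric=metric, fixed_effects=fixed,
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        slopes=pd.DataFrame(slope_rows),
        converged=bool(fit.converged))


# --------------------------------------------------------------------------
# Cohort-level drivers


def _treatment_covariates(subjects: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Treatment as confound: 'none', 'binary' (treated y/n) or 'category'."""
    if mode == "none":
        return pd.DataFrame(index=subjects.index)
    if mode == "binary":
        return pd.DataFrame(
            {"treated": (subjects["treatment"] != "none").astype(float)},
            index=subjects.index)
    if mode == "category":
        d = pd.get_dummies(subjects["treatment"], prefix="tx",
                           dtype=float)
        ref = "tx_none" if "tx_none" in d else d.columns[0]
        return d.drop(columns=[ref])
    raise ValueError("treatment mode must be none, binary or category")


def ancova_all_tracts(tract_table: pd.DataFrame, subjects: pd.DataFrame,
                      metric_cols: list[str] | None = None,
                      group_col: str = "group",
                      covariate_cols: list[str] | None = None,
                      treatment: str = "none",
                      timepoint: int = 1) -> pd.DataFrame:
    """Baseline ANCOVA across every tract and metric; tidy result table.

    The Bonferroni family is, per metric, the number of tracts tested in
    this analysis; the family size is recorded in every output row.
    """
    covariate_cols = covariate_cols if covariate_cols is not None \
        else ["age", "sex", "head_scale"]
    base = subjects[subjects["timepoint"] == timepoint]
    merged = tract_table.merge(base, on=["subject_id", "timepoint"])
    metric_cols = metric_cols or [c for c in tract_table.columns
                                  if c.startswith("mean_")]
    tracts = sorted(merged["tract"].unique().tolist())
    family = len(tracts)
    rows = []
    for metric in metric_cols:
        for tract in tracts:
            sub = merged[merged["tract"] == tract]
            cov = sub[covariate_cols].reset_index(drop=True)
            tx = _treatment_covariates(sub.reset_index(drop=True), treatment)
            if len(tx.columns):
                cov = pd.concat([cov, tx], axis=1)
            res = ancova_tract(sub[metric], sub[group_col], cov,
                               tract=tract, metric=metric)
            rows.append({
                "tract": tract, "metric": metric, "F": res.F, "p": res.p,
                "p_bonferroni": bonferroni(res.p, family),
                "family_size": family,
                **{f"mean_{r.group}": r.mean
                   for r in res.adjusted_means.itertuples()},
            })
    return pd.DataFrame(rows)


def lmm_all_tracts(tract_table: pd.DataFrame, subjects: pd.DataFrame,
                   metric_cols: list[str] | None = None,
                   covariate_cols: list[str] | None = None) -> pd.DataFrame:
    """Longitudinal mixed models across tracts/metrics; tidy slope table."""
    merged = tract_table.merge(subjects, on=["subject_id", "timepoint"])
    merged["time_years"] = np.where(merged["timepoint"] == 1, 0.0,
                                    merged["interval_years"])
    # age fixed at its baseline value so time captures within-subject change
    base_age = merged[merged["timepoint"] == 1][["subject_id", "age"]] \
        .rename(columns={"age": "age_baseline"})
    merged = merged.merge(base_age, on="subject_id")
    metric_cols = metric_cols or [c for c in tract_table.columns
                                  if c.startswith("mean_")]
    covariate_cols = covariate_cols if covariate_cols is not None \
        else ["age_baseline", "sex"]
    tracts = sorted(merged["tract"].unique().tolist())
    family = len(tracts)
    rows = []
    for metric in metric_cols:
        for tract in tracts:
            sub = merged[merged["tract"] == tract]
            res = lmm_longitudinal(sub, metric, covariate_cols=covariate_cols,
                                   tract=tract, metric=metric)
            for r in res.slopes.itertuples():
                rows.append({
                    "tract": tract, "metric": metric, "group": r.group,
                    "slope_per_year": r.slope, "se": r.se, "p": r.p,
                    "p_bonferroni": bonferroni(r.p, family),
                    "family_size": family,
                })
    return pd.DataFrame(rows)
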