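"""Normative cognitive scoring and impairment classification.

Raw scores on seven cognitive domains are converted to Z-scores against a
healthy-control reference corrected for age, sex and binary education level
(regression-based norms: per-domain linear model fitted on HC, residuals
scaled by the HC residual SD). Classification follows the standard two-of-
seven-domain rule: cognitively impaired (CI) if at least two domains have
Z <= -2; mildly impaired (MCI) if at least two have Z <= -1.5 without
meeting the CI rule; cognitively preserved (CP) otherwise. Thresholds are
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassificationError, DegenerateFitError, RankError

N_DOMAINS = 7
CLASSES = ("CP", "MCI", "CI")
COVARIATES = ("age", "sex", "education_high")


@dataclass
class NormativeModel:
    """HC-fitted per-domain linear norms.

    ``coefficients`` has shape (7, 4): intercept, age, sex (1 = male),
    education_high (1 = high) per domain. ``residual_sd`` uses the (n - p)
    denominator of the HC fit.
    """

    coefficients: np.ndarray
    residual_sd: np.ndarray
    n_reference: int

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        """Expected domain scores, covariates shape (n, 3) or (3,)."""
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        X = np.column_stack([np.ones(len(covariates)), covariates])
        return X @ self.coefficients.T


def _design(covariates: np.ndarray) -> np.ndarray:
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim != 2 or covariates.shape[1] != 3:
        raise ValueError("covariates must be (n, 3): age, sex, education_high")
    return np.column_stack([np.ones(len(covariates)), covariates])


def fit_normative(hc_scores: np.ndarray,
                  hc_covariates: np.ndarray) -> NormativeModel:
    """Fit the normative model on healthy controls only.

    Parameters
    ----------
    hc_scores:
        (n, 7) raw domain scores of >= 10 HC subjects, no missing values.
    hc_covariates:
        (n, 3) age (years), sex (0 = F, 1 = M), education_high (0/1).
    """
    hc_scores = np.asarray(hc_scores, dtype=float)
    X = _design(hc_covariates)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 HC subjects to fit norms")
    if hc_scores.shape != (n, N_DOMAINS):
        raise ValueError(f"hc_scores must be (n, {N_DOMAINS})")
    if np.any(~np.isfinite(hc_scores)) or np.any(~np.isfinite(X)):
        raise ValueError("missing values in the HC reference data")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify which covariate columns are collinear with the rest
        names = ("intercept",) + COVARIATES
        bad = [names[j] for j in range(p)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise RankError(f"collinear normative design columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, hc_scores, rcond=None)
    resid = hc_scores - X @ beta
    sd = np.sqrt((resid ** 2).sum(axis=0) / (n - p))
    if np.any(sd < 1e-10):
        raise DegenerateFitError(
            "near-zero HC residual SD: reference scores are an exact "
            "function of the covariates; Z-scores undefined")
    return NormativeModel(coefficients=beta.T, residual_sd=sd, n_reference=n)


def domain_z(raw_scores: np.ndarray, covariates: np.ndarray,
             model: NormativeModel) -> np.ndarray:
    """Covariate-corrected domain Z-scores.

    ``z_d = (observed_d - predicted_d) / residual_sd_d``. Missing raw scores
    propagate as NaN; they are never imputed.
    """
    raw = np.asarray(raw_scores, dtype=float)
    one = raw.ndim == 1
    raw = np.atleast_2d(raw)
    pred = model.predict(covariates)
    z = (raw - pred) / model.residual_sd
    return z[0] if one else z


def classify_cognition(z_scores, lenient: bool = False) -> str:
    """CP / MCI / CI classification from 7 domain Z-scores.

    CI iff at least two domains have Z <= -2; else MCI iff at least two have
    Z <= -1.5; else CP. With ``lenient=False`` (default) any missing domain
    refuses classification; ``lenient=True`` classifies anyway when the
    criteria are already met on the observed domains (a missing domain can
    only move a subject away from CP, never toward it).
    """
    z = np.asarray(z_scores, dtype=float)
    if z.shape != (N_DOMAINS,):
        raise ClassificationError(f"expected {N_DOMAINS} domain Z-scores")
    missing = ~np.isfinite(z)
    if missing.any() and not lenient:
        raise ClassificationError(
            f"{missing.sum()} missing domain Z-score(s); cannot classify "
            "(use lenient mode to classify on observed domains)")
    obs = z[~missing]
    if (obs <= -2.0).sum() >= 2:
        return "CI"
    if (obs <= -1.5).sum() >= 2:
        return "MCI"
    if missing.any():
        raise ClassificationError(
            "criteria not met on observed domains and some are missing; "
            "classification would be ambiguous")
    return "CP"


def classify_many(z_matrix: np.ndarray) -> np.ndarray:
    """Vectorized classification of an (n, 7) complete Z matrix.

    Returns int ranks 0 = CP, 1 = MCI, 2 = CI (index into CLASSES).
    """
    z = np.asarray(z_matrix, dtype=float)
    ci = (z <= -2.0).sum(axis=-1) >= 2
    mci = (z <= -1.5).sum(axis=-1) >= 2
    return np.where(ci, 2, np.where(mci, 1, 0))


def average_cognition(z_scores) -> float:
    """Arithmetic mean of the 7 domain Z-scores."""
    z = np.asarray(z_scores, dtype=float)
    if z.shape != (N_DOMAINS,):
        raise ClassificationError(f"expected {N_DOMAINS} domain Z-scores")
    return float(z.mean())


def average_subtest_z(subtest_z: np.ndarray) -> float:
    """Collapse several sub-test Z-scores into one domain Z (their mean)."""
    return float(np.asarray(subtest_z, dtype=float).mean())


def score_cohort(cognition_raw: pd.DataFrame, subjects: pd.DataFrame,
                 domain_columns: list[str],
                 per_timepoint_norms: bool = True) -> pd.DataFrame:
    """Build cognitive profiles for a whole cohort table.

    Fits the normative model on the HC rows (per timepoint by default, so
    follow-up scores are normed against follow-up controls and learning
    effects cancel; set ``per_timepoint_norms=False`` to norm every visit
    against baseline HC) and returns one profile row per subject/timepoint
    with columns ``z_<domain>``, ``average_z`` and ``cognitive_class``.
    """
    merged = cognition_raw.merge(
        subjects[["subject_id", "timepoint", "group", "age", "sex",
                  "education_high"]],
        on=["subject_id", "timepoint"], validate="one_to_one")
    out_rows = []
    timepoints = sorted(merged["timepoint"].unique())
    models: dict[int, NormativeModel] = {}
    for tp in timepoints:
        ref_tp = tp if per_timepoint_norms else timepoints[0]
        if ref_tp not in models:
            hc = merged[(merged["group"] == "HC")
                        & (merged["timepoint"] == ref_tp)]
            models[ref_tp] = fit_normative(
                hc[domain_columns].to_numpy(),
                hc[list(COVARIATES)].to_numpy())
        model = models[ref_tp]
        block = merged[merged["timepoint"] == tp]
        z = domain_z(block[domain_columns].to_numpy(),
                     block[list(COVARIATES)].to_numpy(), model)
        ranks = classify_many(z)
        for i, (_, row) in enumerate(block.iterrows()):
            out_rows.append({
                "subject_id": row["subject_id"], "timepoint": tp,
                "group": row["group"],
                **{f"z_{c}": float(z[i, d])
                   for d, c in enumerate(domain_columns)},
                "average_z": float(z[i].mean()),
                "cognitive_class": CLASSES[ranks[i]],
            })
    return pd.DataFrame(out_rows)
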