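"""Single-subject pattern expression scoring and its evaluation.

The trained pattern is turned into a per-subject expression score by
regressing disease status (control = 0, disease = 1) on the training
factor scores: the regression coefficients beta are the per-component
weighting factors, and a subject's raw expression score is the
beta-weighted sum of their factor scores.  Prospective use is simulated by
leave-one-in scoring: the test subject is added to the training set, the
PCA is re-run, rerun components are matched back to the training
components by loading correlation, and the test subject's matched factor
scores are combined with the fixed beta weights.  Scores are z-scored
against the healthy-control scores of the same run; score stability
across runs is summarized as a per-control coefficient of variation, and
discrimination is evaluated by ROC analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CohortMatrix
from .ssm import SSMModel, fit_ssm_pca, log_and_double_center

logger = logging.getLogger(__name__)

__all__ = [
    "fit_weights",
    "ExpressionResult",
    "leave_one_in_score",
    "score_cohort",
    "zscore_expression",
    "StabilityReport",
    "stability_cov",
    "roc_auc",
    "correlate_expression",
    "fdr_adjust",
    "batch_effect_check",
]


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]

#: Below this |loading correlation| a rerun component match is flagged.
MATCH_WARN = 0.5


def _training_factor_scores(model: SSMModel) -> np.ndarray:
    Y, _, _ = log_and_double_center(model.training_values, model.region_names)
    Z = Y / model.col_sds[None, :]
    return model.factor_scores(Z)


def fit_weights(
    model: SSMModel,
    train: CohortMatrix,
    positive_group: str = "DLB_DATPOS",
    include_covariates: bool = True,
) -> SSMModel:
    """Determine the per-component weighting factors beta.

    Ordinary least squares of disease status (0 = HC, 1 = ``positive_group``)
    on the K training factor scores, with age and sex as additional
    covariate adjusters when available.  The covariate coefficients adjust
    the regression but do not enter the summed expression score; the raw
    score is the beta-weighted sum of factor scores alone (the intercept
    cancels in HC-referenced z-scores).
    """
    if model.training_values is None:
        raise ValueError("model carries no training values")
    F = _training_factor_scores(model)
    sub = train.subset(model.training_ids)
    status = (sub.meta["group"] == positive_group).to_numpy(dtype=float)
    if status.min() == status.max():
        raise ValueError("training cohort must contain both status classes")
    X = [np.ones(len(status)), *F.T]
    names = ["const"] + [f"PC{k + 1}" for k in range(F.shape[1])]
    cov_names: list[str] = []
    if include_covariates:
        if "age" in sub.meta:
            a = sub.meta["age"].to_numpy(dtype=float)
            if a.std() > 0:
                X.append(a - a.mean())
                cov_names.append("age")
        if "sex" in sub.meta:
            s = sub.meta["sex"].to_numpy()
            s = (s == np.sort(pd.unique(s))[-1]).astype(float)
            if s.std() > 0:
                X.append(s)
                cov_names.append("sex")
    Xm = np.column_stack(X)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient design in weighting-factor regression")
    coef, *_ = np.linalg.lstsq(Xm, status, rcond=None)
    model.intercept = float(coef[0])
    model.beta = coef[1 : 1 + F.shape[1]]
    model.covariate_names = cov_names
    model.covariate_coefs = coef[1 + F.shape[1] :]
    model.training_groups = sub.meta["group"].tolist()

    raw = F @ model.beta
    hc_mask = sub.meta["group"].to_numpy() == "HC"
    if hc_mask.sum() >= 2:
        hc_scores = raw[hc_mask]
        model.hc_ref_mean = float(hc_scores.mean())
        model.hc_ref_sd = float(hc_scores.std(ddof=1))
    _ = names  # kept for readable debugging
    return model


@dataclass
class ExpressionResult:
    """One subject's pattern expression from one scoring run."""

    subject_id: str
    raw_score: float
    z_score: float
    run_id: str
    run_hc_scores: np.ndarray = field(repr=False)
    match_quality: np.ndarray = field(repr=False)
    n_components_run: int = 0


def _match_components(train_loadings: np.ndarray, rerun_loadings: np.ndarray):
    """Greedy matching of training to rerun components by |loading correlation|.

    Returns (match index per training component or -1, sign, |r| quality).
    """
    kt, kr = train_loadings.shape[1], rerun_loadings.shape[1]
    C = np.zeros((kt, kr))
    for a in range(kt):
        for b in range(kr):
            C[a, b] = np.corrcoef(train_loadings[:, a], rerun_loadings[:, b])[0, 1]
    match = np.full(kt, -1)
    sign = np.ones(kt)
    quality = np.zeros(kt)
    absC = np.abs(C.copy())
    for _ in range(min(kt, kr)):
        a, b = np.unravel_index(np.argmax(absC), absC.shape)
        match[a] = b
        sign[a] = 1.0 if C[a, b] >= 0 else -1.0
        quality[a] = absC[a, b]
        absC[a, :] = -1.0
        absC[:, b] = -1.0
    return match, sign, quality


def leave_one_in_score(
    train: CohortMatrix, model: SSMModel, test_id: str, test_values: np.ndarray
) -> ExpressionResult:
    """Score one held-out subject by re-running the PCA with them included.

    The test subject's 77-region SUVr profile joins the training matrix,
    the full log/double-centre/PCA/varimax pipeline is re-run, rerun
    components are matched to the training components (greedy, by maximal
    absolute loading correlation, sign-aligned), and the raw score is the
    beta-weighted sum of the matched, sign-aligned test factor scores.
    The z-score is referenced to the healthy-control scores of this run.
    """
    if model.beta is None:
        raise ValueError("model has no weighting factors; call fit_weights first")
    test_values = np.asarray(test_values, dtype=float).ravel()
    if test_values.size != len(model.region_names) or not np.isfinite(test_values).all():
        raise ValueError("test subject must provide all 77 finite region values")
    combined = np.vstack([model.training_values, test_values[None, :]])
    ids = list(model.training_ids) + [test_id]
    rerun = fit_ssm_pca(combined, ids, model.region_names, eigen_cut=model.eigen_cut)
    match, sign, quality = _match_components(model.loadings, rerun.loadings)
    unmatched = np.where(match < 0)[0]
    if unmatched.size:
        logger.warning(
            "run %s: %d training component(s) unmatched (rerun retained %d)",
            test_id,
            unmatched.size,
            rerun.n_components,
        )
    weak = quality[(match >= 0)] < MATCH_WARN
    if weak.any():
        logger.warning(
            "run %s: %d component match(es) with |loading r| < %.2f: %s",
            test_id,
            int(weak.sum()),
            MATCH_WARN,
            np.round(quality, 3).tolist(),
        )
    Y, _, _ = log_and_double_center(combined, model.region_names)
    F = rerun.factor_scores(Y / rerun.col_sds[None, :])

    def raw_of(i: int) -> float:
        total = 0.0
        for k in range(model.n_components):
            if match[k] >= 0:
                total += model.beta[k] * sign[k] * F[i, match[k]]
        return float(total)

    groups = train.subset(model.training_ids).meta["group"].to_numpy()
    hc_rows = np.where(groups == "HC")[0]
    hc_scores = np.array([raw_of(i) for i in hc_rows])
    raw = raw_of(len(ids) - 1)
    z = zscore_expression(raw, hc_scores)
    return ExpressionResult(
        subject_id=test_id,
        raw_score=raw,
        z_score=z,
        run_id=f"loi_{test_id}",
        run_hc_scores=hc_scores,
        match_quality=quality,
        n_components_run=rerun.n_components,
    )


def _projection_score(model: SSMModel, test_values: np.ndarray) -> tuple[float, float]:
    """Fast scoring path: project onto the frozen training pattern."""
    logv = np.log(np.asarray(test_values, dtype=float))
    prof = (logv - logv.mean() - model.col_means) / model.col_sds
    raw = float(prof @ model.score_weights @ model.beta)
    if model.hc_ref_sd is None or model.hc_ref_sd <= 0:
        raise ValueError("model has no healthy-control reference distribution")
    return raw, (raw - model.hc_ref_mean) / model.hc_ref_sd


def score_cohort(
    train: CohortMatrix,
    model: SSMModel,
    test: CohortMatrix,
    method: str = "leave_one_in",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every test subject; returns (scores table, per-run HC score table).

    ``method='leave_one_in'`` re-runs the PCA once per test subject
    (prospective simulation); ``method='projection'`` projects onto the
    frozen training pattern (no per-run HC scores).
    """
    rows = []
    hc_rows = {}
    for sid in test.subject_ids:
        vals = test.values.loc[sid].to_numpy(dtype=float)
        if method == "leave_one_in":
            res = leave_one_in_score(train, model, sid, vals)
            rows.append(
                {
                    "subject_id": sid,
                    "group": test.meta.loc[sid, "group"],
                    "raw_score": res.raw_score,
                    "z_score": res.z_score,
                    "n_components_run": res.n_components_run,
                    "min_match_quality": float(res.match_quality.min()),
                }
            )
            hc_rows[res.run_id] = res.run_hc_scores
        elif method == "projection":
            raw, z = _projection_score(model, vals)
            rows.append(
                {"subject_id": sid, "group": test.meta.loc[sid, "group"], "raw_score": raw, "z_score": z}
            )
        else:
            raise ValueError(f"unknown scoring method {method!r}")
    scores = pd.DataFrame(rows).set_index("subject_id")
    if hc_rows:
        hc_ids = [i for i, g in zip(model.training_ids, model.training_groups or []) if g == "HC"]
        run_hc = pd.DataFrame.from_dict(hc_rows, orient="index", columns=hc_ids)
    else:
        run_hc = pd.DataFrame()
    return scores, run_hc


def zscore_expression(raw: float, hc_scores_of_reference) -> float:
    """z-score an expression value against a healthy-control reference."""
    ref = np.asarray(hc_scores_of_reference, dtype=float)
    sd = ref.std(ddof=1)
    if sd <= 0:
        raise ValueError("reference SD must be positive")
    return float((raw - ref.mean()) / sd)


@dataclass
class StabilityReport:
    """Per-control CoV of expression scores across scoring runs (percent)."""

    per_subject_cov: pd.Series
    summary_cov: float
    excluded: list[str]


def stability_cov(run_hc_scores: pd.DataFrame | np.ndarray) -> StabilityReport:
    """Coefficient of variation of each control's score across runs.

    CoV = sample SD across runs / |mean across runs|, in percent; the
    summary is the mean over controls.  Controls with mean zero across
    runs have undefined CoV and are excluded with a warning.
    """
    table = pd.DataFrame(run_hc_scores)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 runs for a stability analysis")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    excluded = [str(c) for c in table.columns[np.isclose(means, 0.0, atol=1e-12)]]
    if excluded:
        logger.warning("CoV undefined (mean 0 across runs) for control(s) %s; excluded", excluded)
    ok = ~np.isclose(means, 0.0, atol=1e-12)
    cov = (sds[ok] / means[ok].abs()) * 100.0
    return StabilityReport(per_subject_cov=cov, summary_cov=float(cov.mean()), excluded=excluded)


def roc_auc(scores_positive, scores_negative) -> dict:
    """ROC of positive-class vs negative-class scores (higher = positive).

    AUC is the Mann-Whitney probability (ties count 1/2), computed by
    midranks; the curve is a threshold sweep over the unique scores.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u / (pos.size * neg.size)
    thresholds = np.concatenate([[np.inf], np.unique(combined)[::-1]])
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})
    return {"auc": float(auc), "curve": curve, "n_positive": int(pos.size), "n_negative": int(neg.size)}


def correlate_expression(z_scores, covariate) -> dict[str, float]:
    """Pearson correlation of expression z-scores with a clinical covariate."""
    z = np.asarray(z_scores, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if z.size != c.size or z.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if z.std() == 0 or c.std() == 0:
        raise ValueError("inputs must be non-constant")
    r, p = stats.pearsonr(z, c)
    return {"r": float(r), "r2": float(r**2), "p": float(p)}


def batch_effect_check(z_scores, site_labels, group_labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Site/scanner comparisons of expression z-scores with FDR correction.

    Welch two-sample t-tests between every pair of sites (within each
    cohort when ``group_labels`` is given); sites with n < 2 are excluded
    with a warning.  Raw p-values are Benjamini-Hochberg adjusted across
    all comparisons.
    """
    z = np.asarray(z_scores, dtype=float)
    site = np.asarray(site_labels)
    grp = np.asarray(group_labels) if group_labels is not None else np.array(["all"] * z.size)
    rows = []
    for g in pd.unique(grp):
        gm = grp == g
        sites = pd.unique(site[gm])
        usable = []
        for s in sites:
            n = int((gm & (site == s)).sum())
            if n < 2:
                logger.warning("site %s in cohort %s has n=%d < 2; excluded", s, g, n)
            else:
                usable.append(s)
        for i, sa in enumerate(usable):
            for sb in usable[i + 1 :]:
                a = z[gm & (site == sa)]
                b = z[gm & (site == sb)]
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append({"cohort": g, "site_a": sa, "site_b": sb, "t": float(t), "p_raw": float(p)})
    if not rows:
        raise ValueError("fewer than 2 usable sites in every cohort")
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_fdr"] < alpha
    return table
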