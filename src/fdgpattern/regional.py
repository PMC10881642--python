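"""Region-wise comparison of relative glucose metabolism.

Global-mean scaling, composite means, ANCOVA (age/sex-adjusted) with
Bonferroni-corrected pairwise contrasts, Cohen's d effect sizes, effect-size
correlation between contrasts, and single-subject abnormality flags
(|z| >= 2 SD of controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .atlas import AtlasDefinition
from .io import CohortMatrix

__all__ = [
    "global_mean_scale",
    "composite_means",
    "cohens_d",
    "ancova_region",
    "AncovaResult",
    "bonferroni_adjust",
    "effect_size_correlation",
    "subject_abnormality",
    "regional_effect_table",
]


def global_mean_scale(raw_values: np.ndarray, volumes: np.ndarray | None = None) -> np.ndarray:
    """Scale a regional profile to a (volume-weighted) whole-brain mean of one.

    ``output = raw / (sum(v_r * raw_r) / sum(v_r))``; with ``volumes=None``
    the plain arithmetic mean is used.
    """
    raw = np.asarray(raw_values, dtype=float)
    if (raw <= 0).any():
        raise ValueError("regional values must be strictly positive")
    if volumes is None:
        wb = raw.mean()
    else:
        v = np.asarray(volumes, dtype=float)
        if (v <= 0).any():
            raise ValueError("volumes must be strictly positive")
        wb = np.average(raw, weights=v)
    return raw / wb


def composite_means(suvr: np.ndarray, atlas: AtlasDefinition) -> pd.Series:
    """Volume-weighted mean SUVr per composite region (unweighted if no volumes)."""
    suvr = np.asarray(suvr, dtype=float)
    out = {}
    vols = np.asarray(atlas.volumes, dtype=float) if atlas.volumes is not None else None
    for comp in atlas.composites:
        idx = atlas.composite_indices(comp)
        if not idx:
            raise ValueError(f"composite {comp!r} is empty")
        if vols is None:
            out[comp] = float(suvr[idx].mean())
        else:
            out[comp] = float(np.average(suvr[idx], weights=vols[idx]))
    return pd.Series(out)


def cohens_d(group_a, group_b) -> float:
    """Classical pooled-SD Cohen's d, ``(mean_a - mean_b) / s_pooled``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if pooled_var <= 0:
        raise ValueError("pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class AncovaResult:
    """Omnibus and pairwise-contrast p-values from one region's ANCOVA."""

    omnibus_p: float
    contrasts: dict[tuple[str, str], float]
    adjusted_means: dict[str, float]


def ancova_region(values, group, age=None, sex=None) -> AncovaResult:
    """Age/sex-adjusted group comparison for one region.

    Fits ``value ~ group + age_centred + sex`` by OLS and tests all pairwise
    group contrasts on the adjusted means (two-sided t-tests on the group
    coefficients), plus the omnibus F-test for any group effect.  Covariates
    with zero variance are dropped from the design.
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: int((group == g).sum()) for g in levels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"group(s) with n < 2: {small}")

    cols = {}
    for g in levels[1:]:
        cols[f"group[{g}]"] = (group == g).astype(float)
    if age is not None:
        a = np.asarray(age, dtype=float)
        if a.std() > 0:
            cols["age"] = a - a.mean()
    if sex is not None:
        s = np.asarray(sex)
        if s.dtype.kind in "OUS":
            s = (s == np.sort(pd.unique(s))[-1]).astype(float)
        else:
            s = s.astype(float)
        if s.std() > 0:
            cols["sex"] = s
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()

    # omnibus: joint test that all group dummies are zero
    r_names = [c for c in X.columns if c.startswith("group[")]
    omnibus_p = float(fit.f_test(" = 0, ".join(r_names) + " = 0").pvalue)

    contrasts = {}
    for i, ga in enumerate(levels):
        for gb in levels[i + 1 :]:
            vec = np.zeros(X.shape[1])
            if ga != levels[0]:
                vec[X.columns.get_loc(f"group[{ga}]")] = 1.0
            if gb != levels[0]:
                vec[X.columns.get_loc(f"group[{gb}]")] = -1.0
            tt = fit.t_test(vec)
            contrasts[(ga, gb)] = float(tt.pvalue)

    covar_adjust = 0.0  # adjusted means at covariate means (age centred, sex at sample mean)
    if "sex" in X.columns:
        covar_adjust = float(fit.params["sex"] * X["sex"].mean())
    base = float(fit.params["const"]) + covar_adjust
    adjusted = {levels[0]: base}
    for g in levels[1:]:
        adjusted[g] = base + float(fit.params[f"group[{g}]"])
    return AncovaResult(omnibus_p=omnibus_p, contrasts=contrasts, adjusted_means=adjusted)


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: ``min(1, p * m)``; m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.minimum(1.0, p * m)


def effect_size_correlation(d_vector_a, d_vector_b) -> dict[str, float]:
    """OLS of one regional effect-size vector on another.

    Returns slope, intercept, R^2 (squared Pearson r) and the two-sided
    p-value of the correlation test.
    """
    a = np.asarray(d_vector_a, dtype=float)
    b = np.asarray(d_vector_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("effect-size vectors must be non-constant")
    res = stats.linregress(a, b)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def subject_abnormality(
    suvr: np.ndarray,
    hc_region_means: np.ndarray,
    hc_region_sds: np.ndarray,
    atlas: AtlasDefinition | None = None,
    threshold: float = 2.0,
) -> dict:
    """Per-region z-scores vs controls and >= threshold-SD abnormality flags.

    The subject-level "abnormal" call requires at least one composite-level
    |z| at or above the threshold when an atlas is given, otherwise any
    regional flag.
    """
    suvr = np.asarray(suvr, dtype=float)
    mu = np.asarray(hc_region_means, dtype=float)
    sd = np.asarray(hc_region_sds, dtype=float)
    if (sd <= 0).any():
        raise ValueError("control SDs must be positive")
    z = (suvr - mu) / sd
    # closed threshold, robust to float round-off at exactly +/- threshold SD
    flags = (np.abs(z) >= threshold) | np.isclose(np.abs(z), threshold, rtol=1e-9, atol=1e-12)
    if atlas is not None:
        comp_z = {}
        for comp in atlas.composites:
            idx = atlas.composite_indices(comp)
            vols = (
                np.asarray(atlas.volumes, dtype=float)[idx]
                if atlas.volumes is not None
                else np.ones(len(idx))
            )
            comp_z[comp] = float(np.average(z[idx], weights=vols))
        abnormal = any(abs(v) >= threshold for v in comp_z.values())
        return {"z": z, "flags": flags, "composite_z": comp_z, "abnormal": bool(abnormal)}
    return {"z": z, "flags": flags, "abnormal": bool(flags.any())}


def regional_effect_table(
    cohort: CohortMatrix,
    groups: tuple[str, str, str] = ("HC", "DLB_DATNEG", "DLB_DATPOS"),
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-region group means, Cohen's d vs the reference group, and ANCOVA p-values.

    ``groups[0]`` is the reference (control) group.  The Bonferroni family
    defaults to 77 regions x number of pairwise contrasts; pass
    ``bonferroni_m`` to override.
    """
    sub = cohort.select(*groups)
    present = set(sub.meta["group"])
    missing_groups = [g for g in groups if g not in present]
    if missing_groups:
        raise ValueError(f"cohort has no subjects in group(s) {missing_groups}")
    gl = sub.meta["group"].to_numpy()
    age = sub.meta["age"].to_numpy(dtype=float) if "age" in sub.meta else None
    sex = sub.meta["sex"].to_numpy() if "sex" in sub.meta else None
    ref = groups[0]
    n_contrasts = len(groups) * (len(groups) - 1) // 2
    m = bonferroni_m if bonferroni_m is not None else len(cohort.atlas.names) * n_contrasts

    rows = []
    for region in cohort.atlas.names:
        y = sub.values[region].to_numpy(dtype=float)
        res = ancova_region(y, gl, age, sex)
        row = {"region": region}
        for g in groups:
            row[f"mean_{g}"] = float(y[gl == g].mean())
        for g in groups[1:]:
            row[f"cohens_d_{g}_vs_{ref}"] = cohens_d(y[gl == g], y[gl == ref])
        row["ancova_omnibus_p"] = res.omnibus_p
        for (ga, gb), p in res.contrasts.items():
            row[f"p_raw_{ga}_vs_{gb}"] = p
            row[f"p_bonferroni_{ga}_vs_{gb}"] = float(min(1.0, p * m))
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
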