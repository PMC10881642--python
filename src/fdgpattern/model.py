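"""Model/Results interface for the metabolic covariance pattern analysis.

``PatternModel`` is built from a cohort (or a plain DataFrame) and its
``fit()`` returns a ``PatternResults`` object that carries the retained
components, weighting factors, the healthy-control reference distribution
and diagnostics, and exposes scoring, stability and ROC evaluation::

    model = PatternModel(cohort)              # trains on HC + DLB_DATPOS
    res = model.fit()
    print(res.summary())
    scores, run_hc = res.score(test_cohort)   # leave-one-in scoring
    auc = res.roc(scores, positive="DLB_DATNEG", negative=("AD", "PD", "MSA"))
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition, load_default_atlas
from .io import CohortMatrix
from . import expression as expr
from .ssm import SSMModel, fit_ssm_pca, save_model

__all__ = ["PatternModel", "PatternResults"]


class PatternModel:
    """SSM/PCA disease-pattern model specification.

    Parameters
    ----------
    cohort
        Cohort containing at least the two training groups.
    training_groups
        ``(control, disease)`` labels; the PCA is trained on their union
        and status is coded control = 0, disease = 1.
    eigen_cut
        Kaiser criterion threshold on correlation-matrix eigenvalues.
    include_covariates
        Include age and sex as adjusters in the weighting-factor regression.
    """

    def __init__(
        self,
        cohort: CohortMatrix,
        training_groups: tuple[str, str] = ("HC", "DLB_DATPOS"),
        eigen_cut: float = 1.0,
        use_correlation: bool = True,
        include_covariates: bool = True,
    ):
        self.cohort = cohort
        self.training_groups = training_groups
        self.eigen_cut = eigen_cut
        self.use_correlation = use_correlation
        self.include_covariates = include_covariates
        train = cohort.select(*training_groups)
        if train.n_subjects < 10:
            raise ValueError(f"need >= 10 training subjects, got {train.n_subjects}")
        for g in training_groups:
            if (train.meta["group"] == g).sum() == 0:
                raise ValueError(f"training cohort has no {g} subjects")
        self.train = train

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, atlas: AtlasDefinition | None = None, **kwargs):
        """Build from a DataFrame with metadata columns plus the 77 region columns."""
        atlas = atlas or load_default_atlas()
        frame = frame.copy()
        if "subject_id" in frame.columns:
            frame = frame.set_index("subject_id")
        meta_cols = [c for c in frame.columns if c not in atlas.names]
        cohort = CohortMatrix(meta=frame[meta_cols], values=frame[atlas.names].astype(float), atlas=atlas)
        return cls(cohort, **kwargs)

    def fit(self) -> "PatternResults":
        """Extract components, rotate, and estimate the weighting factors."""
        ssm = fit_ssm_pca(
            self.train.matrix(),
            self.train.subject_ids,
            self.train.atlas.names,
            eigen_cut=self.eigen_cut,
            use_correlation=self.use_correlation,
        )
        ssm = expr.fit_weights(
            ssm, self.train, positive_group=self.training_groups[1], include_covariates=self.include_covariates
        )
        return PatternResults(self, ssm)


class PatternResults:
    """Fitted pattern: components, weighting factors, reference, scoring."""

    def __init__(self, model: PatternModel, ssm: SSMModel):
        self.model = model
        self.ssm = ssm

    # ---- estimates -------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.ssm.n_components

    @property
    def eigenvalues(self) -> pd.Series:
        return pd.Series(self.ssm.eigenvalues, index=[f"PC{k+1}" for k in range(self.n_components)])

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ssm.loadings, index=self.ssm.region_names, columns=[f"PC{k+1}" for k in range(self.n_components)]
        )

    @property
    def params(self) -> pd.Series:
        """Weighting factors beta (status-regression coefficients per component)."""
        return pd.Series(self.ssm.beta, index=[f"PC{k+1}" for k in range(self.n_components)])

    @property
    def explained_variance_ratio(self) -> pd.Series:
        return self.eigenvalues / len(self.ssm.region_names)

    def training_expression(self) -> pd.DataFrame:
        """Raw and HC-referenced z expression scores of the training subjects."""
        F = expr._training_factor_scores(self.ssm)
        raw = F @ self.ssm.beta
        groups = self.model.train.meta["group"]
        hc = raw[(groups == "HC").to_numpy()]
        z = (raw - hc.mean()) / hc.std(ddof=1)
        return pd.DataFrame(
            {"group": groups.to_numpy(), "raw_score": raw, "z_score": z}, index=self.ssm.training_ids
        )

    # ---- scoring ---------------------------------------------------
    def score(self, test: CohortMatrix, method: str = "leave_one_in"):
        """Score held-out subjects; see :func:`fdgpattern.expression.score_cohort`."""
        return expr.score_cohort(self.model.train, self.ssm, test, method=method)

    def stability(self, run_hc_scores: pd.DataFrame) -> expr.StabilityReport:
        return expr.stability_cov(run_hc_scores)

    def roc(self, scores: pd.DataFrame, positive: str, negative) -> dict:
        if isinstance(negative, str):
            negative = (negative,)
        pos = scores.loc[scores["group"] == positive, "z_score"].to_numpy()
        neg = scores.loc[scores["group"].isin(negative), "z_score"].to_numpy()
        return expr.roc_auc(pos, neg)

    def save(self, path) -> None:
        save_model(self.ssm, path)

    # ---- reporting -------------------------------------------------
    def loading_report(self, suppress_below: float = 0.1) -> pd.DataFrame:
        """Display-style loading table: small coefficients suppressed, sorted by size.

        Purely presentational; computations always use the full loadings.
        """
        table = self.loadings.copy()
        order = table.abs().max(axis=1).sort_values(ascending=False).index
        table = table.loc[order]
        return table.where(table.abs() >= suppress_below)

    def summary(self) -> str:
        groups = self.model.train.meta["group"]
        lines = [
            "Metabolic covariance pattern model (SSM/PCA)",
            "=" * 52,
            f"Training subjects:        {len(self.ssm.training_ids)} "
            f"({(groups == self.model.training_groups[0]).sum()} {self.model.training_groups[0]}, "
            f"{(groups == self.model.training_groups[1]).sum()} {self.model.training_groups[1]})",
            f"Regions:                  {len(self.ssm.region_names)}",
            f"Retained components:      {self.n_components} (eigenvalue > {self.ssm.eigen_cut:g}, varimax-rotated)",
            f"Explained variance:       {100 * self.explained_variance_ratio.sum():.1f}%",
            f"HC reference (raw score): mean {self.ssm.hc_ref_mean:.4f}, SD {self.ssm.hc_ref_sd:.4f}",
            "",
            "Weighting factors (beta):",
        ]
        for name, (ev, b) in enumerate(zip(self.ssm.eigenvalues, self.ssm.beta), start=1):
            lines.append(f"  PC{name:<3d} eigenvalue {ev:7.3f}   beta {b:+.4f}")
        if len(self.ssm.covariate_names):
            covs = ", ".join(
                f"{n} = {c:+.4f}" for n, c in zip(self.ssm.covariate_names, self.ssm.covariate_coefs)
            )
            lines.append(f"Covariate adjusters: {covs} (not part of the summed score)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PatternResults: {self.n_components} components, {len(self.ssm.training_ids)} training subjects>"
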