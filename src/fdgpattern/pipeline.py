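"""End-to-end study pipeline.

From one config (YAML/JSON dict): cohort input (table or synthetic) ->
DaT stratification -> regional metabolism analysis -> metabolic
connectivity -> pattern training on HC + DLB-DaT(+) -> leave-one-in
scoring of every DLB-DaT(-)/AD/PD/MSA subject -> stability report, ROC
per contrast, covariate correlations and site checks -> tables, model
JSON and a run manifest.  All randomness flows from the single config
seed, so a run is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import load_default_atlas
from .connectivity import connectivity_similarity, delta_matrix, icc_matrix
from .dat import DatNormative, stratify_cohort
from .expression import batch_effect_check, correlate_expression, stability_cov
from .io import CohortMatrix, read_cohort_table, write_cohort_table, write_matrix, write_report
from .model import PatternModel
from .regional import effect_size_correlation, regional_effect_table
from .synthetic import SyntheticCohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

TEST_GROUPS = ("DLB_DATNEG", "AD", "PD", "MSA")
ROC_CONTRASTS = {
    "DLB_DATNEG_vs_all": ("AD", "PD", "MSA"),
    "DLB_DATNEG_vs_PD": ("PD",),
    "DLB_DATNEG_vs_MSA": ("MSA",),
    "DLB_DATNEG_vs_AD": ("AD",),
}


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""


@dataclass
class PipelineConfig:
    """One run's full configuration.

    Exactly one of ``input_table`` / ``synthetic`` must be set.  Threshold
    defaults are the analysis constants: DaT z cut -2, abnormality cut
    2 SD, eigenvalue cut 1.0, loading display cut 0.1.
    """

    input_table: str | None = None
    synthetic: dict = field(default_factory=dict)
    use_synthetic: bool = True
    dat_normative: dict | None = None
    analyses: tuple[str, ...] = ("regional", "connectivity", "expression")
    dat_z_cut: float = -2.0
    abnormality_sd: float = 2.0
    eigen_cut: float = 1.0
    coefficient_display_cut: float = 0.1
    make_plots: bool = False
    seed: int = 0
    outdir: str = "fdgpattern_out"

    def validate(self) -> None:
        if (self.input_table is None) == (not self.use_synthetic):
            raise ValueError("config must select exactly one input mode (table or synthetic)")
        unknown = set(self.analyses) - {"regional", "connectivity", "expression"}
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if not (-10 <= self.dat_z_cut <= 0 and 0 < self.abnormality_sd <= 10 and 0 < self.eigen_cut <= 10):
            raise ValueError("threshold outside documented range")


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc = doc or {}
    inp = doc.pop("input", {})
    cfg = PipelineConfig(
        input_table=inp.get("table"),
        synthetic=inp.get("synthetic") or {},
        use_synthetic="table" not in inp,
        **{k: tuple(v) if k == "analyses" else v for k, v in doc.items()},
    )
    cfg.validate()
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


@_stage("input")
def _load_cohort(config: PipelineConfig) -> CohortMatrix:
    atlas = load_default_atlas()
    if config.input_table:
        return read_cohort_table(config.input_table, atlas)
    spec_dict = dict(config.synthetic)
    spec_dict.setdefault("seed", config.seed)
    spec = SyntheticCohortSpec.from_config(spec_dict)
    return simulate_cohort(spec, atlas)


@_stage("stratify")
def _stratify(cohort: CohortMatrix, config: PipelineConfig) -> CohortMatrix:
    norm = DatNormative(**config.dat_normative) if config.dat_normative else None
    return stratify_cohort(cohort, norm)


@_stage("regional")
def _regional(cohort: CohortMatrix, outdir: Path) -> dict:
    table = regional_effect_table(cohort)
    table.to_csv(outdir / "regional_effects.tsv", sep="\t")
    sim = effect_size_correlation(
        table["cohens_d_DLB_DATPOS_vs_HC"], table["cohens_d_DLB_DATNEG_vs_HC"]
    )
    return {
        "n_regions": int(len(table)),
        "effect_size_correlation_datpos_vs_datneg": sim,
        "n_significant_bonferroni_DATPOS_vs_HC": int(
            (table["p_bonferroni_DLB_DATPOS_vs_HC"] < 0.05).sum()
        ),
    }


@_stage("connectivity")
def _connectivity(cohort: CohortMatrix, outdir: Path, seed: int, make_plots: bool = False) -> dict:
    mats = {g: icc_matrix(cohort, g) for g in ("HC", "DLB_DATPOS", "DLB_DATNEG")}
    for g, m in mats.items():
        write_matrix(m.z_values, m.region_names, outdir / f"connectivity_z_{g}.tsv")
        if make_plots:
            from .plots import plot_connectivity_heatmap

            plot_connectivity_heatmap(
                m.z_values, f"ICC (Fisher z), {g}", outdir / f"connectivity_z_{g}.png", vlim=2.0
            )
    d_pos = delta_matrix(mats["DLB_DATPOS"], mats["HC"])
    d_neg = delta_matrix(mats["DLB_DATNEG"], mats["HC"])
    if make_plots:
        from .plots import plot_connectivity_heatmap

        plot_connectivity_heatmap(d_pos.dz, "dz DaT(+) - HC", outdir / "delta_z_DATPOS_minus_HC.png")
        plot_connectivity_heatmap(d_neg.dz, "dz DaT(-) - HC", outdir / "delta_z_DATNEG_minus_HC.png")
    write_matrix(d_pos.dz, d_pos.region_names, outdir / "delta_z_DATPOS_minus_HC.tsv")
    write_matrix(d_neg.dz, d_neg.region_names, outdir / "delta_z_DATNEG_minus_HC.tsv")
    # long format for heatmap tooling
    iu = np.triu_indices(len(d_pos.region_names), k=1)
    long = pd.DataFrame(
        {
            "region_i": np.asarray(d_pos.region_names)[iu[0]],
            "region_j": np.asarray(d_pos.region_names)[iu[1]],
            "r_HC": mats["HC"].r_values[iu],
            "z_HC": mats["HC"].z_values[iu],
            "dz_DATPOS": d_pos.dz[iu],
            "dz_DATNEG": d_neg.dz[iu],
        }
    )
    long.to_csv(outdir / "connectivity_pairs.tsv", sep="\t", index=False)
    sim = connectivity_similarity(d_pos, d_neg, n_permutations=500, seed=seed)
    return {"delta_similarity_DATPOS_vs_DATNEG": sim, "n_subjects": {g: m.n_subjects for g, m in mats.items()}}


@_stage("expression")
def _expression(cohort: CohortMatrix, config: PipelineConfig, outdir: Path) -> dict:
    model = PatternModel(cohort, eigen_cut=config.eigen_cut)
    res = model.fit()
    res.save(outdir / "pattern_model.json")
    (outdir / "pattern_summary.txt").write_text(res.summary() + "\n")
    res.loading_report(config.coefficient_display_cut).to_csv(outdir / "loadings_display.tsv", sep="\t")

    test = cohort.select(*TEST_GROUPS)
    if test.n_subjects == 0:
        raise ValueError("no test subjects (DLB_DATNEG/AD/PD/MSA) to score")
    scores, run_hc = res.score(test, method="leave_one_in")
    train_expr = res.training_expression()
    train_expr.to_csv(outdir / "expression_training.tsv", sep="\t")
    scores.to_csv(outdir / "expression_scores.tsv", sep="\t")
    stability = stability_cov(run_hc)
    run_hc.to_csv(outdir / "run_hc_scores.tsv", sep="\t")

    rocs = {}
    for name, negs in ROC_CONTRASTS.items():
        r = res.roc(scores, positive="DLB_DATNEG", negative=negs)
        r["curve"].to_csv(outdir / f"roc_{name}.tsv", sep="\t", index=False)
        rocs[name] = {"auc": r["auc"], "n_positive": r["n_positive"], "n_negative": r["n_negative"]}
        if config.make_plots:
            from .plots import plot_roc_curve

            plot_roc_curve(r["curve"], r["auc"], name.replace("_", " "), outdir / f"roc_{name}.png")
    if config.make_plots:
        from .plots import plot_expression_distribution

        plot_expression_distribution(scores, outdir / "expression_scores.png")

    correlations = {}
    dlb = pd.concat([train_expr[train_expr["group"] == "DLB_DATPOS"], scores[scores["group"] == "DLB_DATNEG"]])
    meta = cohort.meta.loc[dlb.index]
    if "mmse" in meta and meta["mmse"].notna().all():
        correlations["mmse_all_dlb"] = correlate_expression(dlb["z_score"], meta["mmse"])
    if {"dat_z_left", "dat_z_right"} <= set(meta.columns):
        dat_mean = (meta["dat_z_left"] + meta["dat_z_right"]) / 2
        correlations["dat_z_all_dlb"] = correlate_expression(dlb["z_score"], dat_mean)

    batch = None
    if "site" in cohort.meta.columns:
        all_scores = pd.concat([train_expr, scores])
        site = cohort.meta.loc[all_scores.index, "site"]
        grp = all_scores["group"]
        batch_table = batch_effect_check(all_scores["z_score"], site, grp)
        batch_table.to_csv(outdir / "site_checks.tsv", sep="\t", index=False)
        batch = {
            "n_comparisons": int(len(batch_table)),
            "n_significant_fdr": int(batch_table["significant"].sum()),
        }

    group_means = scores.groupby("group")["z_score"].agg(["mean", "std", "count"])
    return {
        "n_components": res.n_components,
        "training_n": len(res.ssm.training_ids),
        "stability_cov_percent": stability.summary_cov,
        "stability_max_cov_percent": float(stability.per_subject_cov.max()),
        "min_match_quality": float(scores["min_match_quality"].min()),
        "roc": rocs,
        "expression_by_group": json.loads(group_means.to_json(orient="index")),
        "correlations": correlations,
        "site_checks": batch,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    cohort = _load_cohort(config)
    cohort = _stratify(cohort, config)
    write_cohort_table(cohort, outdir / "cohort_stratified.csv")
    counts = cohort.meta["group"].value_counts().to_dict()
    report["stages"]["input"] = {"n_subjects": cohort.n_subjects, "group_counts": counts}
    logger.info("cohort: %s", counts)

    if "regional" in config.analyses:
        report["stages"]["regional"] = _regional(cohort, outdir)
    if "connectivity" in config.analyses:
        report["stages"]["connectivity"] = _connectivity(cohort, outdir, config.seed, config.make_plots)
    if "expression" in config.analyses:
        report["stages"]["expression"] = _expression(cohort, config, outdir)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if not k.startswith("_")
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["manifest"] = manifest
    write_report(report, outdir / "report.json")
    return report
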