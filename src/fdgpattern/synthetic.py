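"""Synthetic FDG-PET cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes: per-group multivariate-normal regional log-SUVr profiles with a
planted disease covariance pattern (parieto-occipital/frontal
hypometabolism, basal-ganglia/limbic/motor hypermetabolism), planted
block-covariance (metabolic connectivity) increases in the disease groups,
group-specific putaminal DaT z-score distributions, and age/sex/site
metadata.  Profiles are generated in log space because the pattern model
works on log-transformed data, so the planted mean shift is exactly the
model's working quantity; after exponentiation every subject is scaled to
a volume-weighted whole-brain mean of one, which removes the global level
and makes only relative contrasts identifiable.

Default cohort sizes and the DLB DaT z distributions reproduce the
demographics of a typical multicentre DLB study (HC 23, DLB with
dopaminergic deficit 86, DLB without 22, AD 49, PD 33, MSA 19).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition, load_default_atlas
from .io import CohortMatrix
from .regional import global_mean_scale

__all__ = [
    "SyntheticCohortSpec",
    "GROUP_ORDER",
    "default_pattern",
    "disease_control_pattern",
    "default_base_cov",
    "build_covariance",
    "simulate_cohort",
]

#: Fixed group order; per-group RNG substreams are spawned in this order so
#: changing one group's size never perturbs the other groups' draws.
GROUP_ORDER = ("HC", "DLB_DATPOS", "DLB_DATNEG", "AD", "PD", "MSA")

_EIG_FLOOR = 1e-6
_MAX_ABS_R = 0.99


def default_pattern(atlas: AtlasDefinition) -> np.ndarray:
    """The planted DLB-like covariance pattern as signed log-space mean shifts.

    Hypometabolism (negative) in parieto-occipital and frontal cortex,
    hypermetabolism (positive) in motor cortex, basal ganglia, limbic
    system and cerebellum; near zero in precuneus and posterior cingulate
    (the "cingulate island" sparing).  Re-centred to mean zero because
    global-mean scaling leaves only relative contrasts identifiable.
    """
    v = np.zeros(len(atlas.names))
    assign = {
        "occipital": -0.08,
        "parietal": -0.06,
        "frontal": -0.03,
        "temporal": -0.01,
        "insula": 0.02,
        "limbic": 0.05,
        "basal_ganglia": 0.06,
        "cerebellum": 0.06,
    }
    for comp, val in assign.items():
        v[atlas.composite_indices(comp)] = val
    for name in ("precentral_gyrus_L", "precentral_gyrus_R"):  # motor cortex
        v[atlas.index_of(name)] = 0.05
    for name in (
        "precuneus_L",
        "precuneus_R",
        "posterior_cingulate_gyrus_L",
        "posterior_cingulate_gyrus_R",
    ):
        v[atlas.index_of(name)] = 0.0
    for name in ("thalamus_L", "thalamus_R"):
        v[atlas.index_of(name)] = 0.02
    return v - v.mean()


def disease_control_pattern(atlas: AtlasDefinition, disease: str) -> np.ndarray:
    """Simple mean-shift profiles for the disease-control groups.

    AD: temporo-parietal and posterior-cingulate/precuneus hypometabolism.
    MSA: subcortical (striatal) and cerebellar/brainstem hypometabolism.
    PD: mild diffuse posterior hypometabolism.  Magnitudes are generator
    conventions chosen to make discrimination exercises non-trivial, not
    literature effect sizes.
    """
    v = np.zeros(len(atlas.names))
    if disease == "AD":
        for comp, val in (("temporal", -0.05), ("parietal", -0.07), ("frontal", -0.02), ("occipital", -0.01)):
            v[atlas.composite_indices(comp)] = val
        for name in ("posterior_cingulate_gyrus_L", "posterior_cingulate_gyrus_R"):
            v[atlas.index_of(name)] = -0.06
        for name in ("precuneus_L", "precuneus_R"):
            v[atlas.index_of(name)] = -0.08
    elif disease == "MSA":
        for comp, val in (("basal_ganglia", -0.07), ("cerebellum", -0.08)):
            v[atlas.composite_indices(comp)] = val
        v[atlas.index_of("brainstem")] = -0.05
    elif disease == "PD":
        for comp, val in (("occipital", -0.03), ("parietal", -0.02), ("frontal", -0.01), ("basal_ganglia", 0.02)):
            v[atlas.composite_indices(comp)] = val
    else:
        raise ValueError(f"no control pattern for {disease!r}")
    return v - v.mean()


def _base_log_mean(atlas: AtlasDefinition) -> np.ndarray:
    """Plausible relative regional SUVr levels (log scale)."""
    level = np.full(len(atlas.names), 1.0)
    by_comp = {
        "frontal": 1.15,
        "parietal": 1.15,
        "temporal": 1.05,
        "occipital": 1.20,
        "insula": 1.10,
        "limbic": 0.95,
        "basal_ganglia": 1.25,
        "cerebellum": 1.00,
    }
    for comp, val in by_comp.items():
        level[atlas.composite_indices(comp)] = val
    for name in ("thalamus_L", "thalamus_R"):
        level[atlas.index_of(name)] = 1.15
    level[atlas.index_of("brainstem")] = 0.85
    return np.log(level)


def _region_family(atlas: AtlasDefinition) -> list[str]:
    fam = []
    comp_of = {}
    for comp, members in atlas.composites.items():
        for m in members:
            comp_of[m] = comp
    for name in atlas.names:
        fam.append(comp_of.get(name, "other"))
    return fam


def default_base_cov(atlas: AtlasDefinition, region_sd: float = 0.06) -> np.ndarray:
    """Default positive-definite covariance of regional log-SUVr.

    Correlation structure: 0.1 background, +0.3 within a composite, +0.2
    extra for homologous left/right pairs; per-region SD 6% (log scale),
    a typical between-subject regional variability after global scaling.
    """
    n = len(atlas.names)
    fam = _region_family(atlas)
    corr = np.full((n, n), 0.1)
    for i in range(n):
        for j in range(n):
            if i != j and fam[i] == fam[j] and fam[i] != "other":
                corr[i, j] += 0.3
    stems = [name[:-2] if name.endswith(("_L", "_R")) else name for name in atlas.names]
    for i in range(n):
        for j in range(n):
            if i != j and stems[i] == stems[j]:
                corr[i, j] += 0.2
    np.fill_diagonal(corr, 1.0)
    corr = _repair_spd(corr)
    sd = np.full(n, region_sd)
    return corr * np.outer(sd, sd)


def _repair_spd(corr: np.ndarray) -> np.ndarray:
    """Floor eigenvalues at 1e-6 and rescale to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= _EIG_FLOOR:
        return corr
    w = np.maximum(w, _EIG_FLOOR)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return (fixed + fixed.T) / 2


def build_covariance(
    base_cov: np.ndarray,
    cov_boost: dict[tuple[str, str], float] | None,
    atlas: AtlasDefinition,
) -> np.ndarray:
    """Apply additive correlation increments to composite blocks of a covariance.

    Entries of the correlation matrix belonging to the named
    (composite_A, composite_B) blocks (off-diagonal only) are incremented,
    clipped to ``|r| <= 0.99``, and the result is repaired to positive
    definiteness by eigenvalue flooring with the original variances
    restored on the diagonal.
    """
    base_cov = np.asarray(base_cov, dtype=float)
    sd = np.sqrt(np.diag(base_cov))
    if (sd <= 0).any():
        raise ValueError("base covariance has non-positive variances")
    corr = base_cov / np.outer(sd, sd)
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 0:
        raise ValueError("base covariance is not positive definite")
    if not cov_boost:
        return base_cov.copy()
    corr = corr.copy()
    n = corr.shape[0]
    for (comp_a, comp_b), inc in cov_boost.items():
        ia = atlas.composite_indices(comp_a)
        ib = atlas.composite_indices(comp_b)
        mask = np.zeros((n, n), dtype=bool)
        mask[np.ix_(ia, ib)] = True
        mask |= mask.T  # each unordered pair boosted once, symmetrically
        np.fill_diagonal(mask, False)
        corr[mask] += inc
    off = ~np.eye(corr.shape[0], dtype=bool)
    corr[off] = np.clip(corr[off], -_MAX_ABS_R, _MAX_ABS_R)
    corr = _repair_spd((corr + corr.T) / 2)
    return corr * np.outer(sd, sd)


def _default_n() -> dict[str, int]:
    return {"HC": 23, "DLB_DATPOS": 86, "DLB_DATNEG": 22, "AD": 49, "PD": 33, "MSA": 19}


def _default_effect() -> dict[str, float]:
    # DLB pattern expression: full strength with dopaminergic deficit,
    # attenuated without ("similar, overall less pronounced").
    return {"HC": 0.0, "DLB_DATPOS": 1.0, "DLB_DATNEG": 0.6, "AD": 0.0, "PD": 0.0, "MSA": 0.0}


def _default_dat() -> dict[str, tuple[float, float]]:
    return {
        "HC": (0.0, 1.0),
        "DLB_DATPOS": (-3.7, 0.9),
        "DLB_DATNEG": (-1.1, 0.7),
        "AD": (-0.3, 1.1),
        "PD": (-3.5, 1.2),
        "MSA": (-3.0, 1.4),
    }


def _default_age() -> dict[str, tuple[float, float]]:
    return {
        "HC": (68.0, 8.0),
        "DLB_DATPOS": (72.8, 7.7),
        "DLB_DATNEG": (73.5, 6.8),
        "AD": (69.7, 8.0),
        "PD": (77.7, 6.0),
        "MSA": (63.8, 7.0),
    }


def _default_mmse() -> dict[str, tuple[float, float]]:
    return {
        "HC": (29.0, 1.0),
        "DLB_DATPOS": (22.6, 4.8),
        "DLB_DATNEG": (22.0, 4.8),
        "AD": (21.0, 5.0),
        "PD": (27.0, 2.5),
        "MSA": (27.0, 2.5),
    }


def _default_sex() -> dict[str, float]:
    return {"HC": 0.5, "DLB_DATPOS": 0.63, "DLB_DATNEG": 0.55, "AD": 0.5, "PD": 0.6, "MSA": 0.5}


def _default_boost() -> dict[tuple[str, str], float]:
    # Connectivity increases within basal ganglia, frontal cortex and
    # limbic system, and between limbic system and basal ganglia.
    return {
        ("basal_ganglia", "basal_ganglia"): 0.15,
        ("limbic", "limbic"): 0.15,
        ("frontal", "frontal"): 0.10,
        ("limbic", "basal_ganglia"): 0.15,
    }


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a synthetic cohort.

    All defaults encode the reference cohort structure; pass ``atlas=None``
    fields as None to have them derived from the default atlas at
    simulation time.  The same seed always yields the identical cohort.
    """

    n_per_group: dict[str, int] = field(default_factory=_default_n)
    base_log_mean: np.ndarray | None = None
    pattern: np.ndarray | None = None
    effect_scale: dict[str, float] = field(default_factory=_default_effect)
    base_cov: np.ndarray | None = None
    cov_boost: dict[tuple[str, str], float] = field(default_factory=_default_boost)
    boosted_groups: tuple[str, ...] = ("DLB_DATPOS", "DLB_DATNEG")
    dat_params: dict[str, tuple[float, float]] = field(default_factory=_default_dat)
    age_params: dict[str, tuple[float, float]] = field(default_factory=_default_age)
    mmse_params: dict[str, tuple[float, float]] = field(default_factory=_default_mmse)
    sex_ratio: dict[str, float] = field(default_factory=_default_sex)
    site_labels: tuple[str, ...] = ("site_A", "site_B", "site_C")
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be non-negative")
        unknown = set(self.n_per_group) - set(GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown group(s) in n_per_group: {sorted(unknown)}")
        if any(d < 0 for d in self.effect_scale.values()):
            raise ValueError("effect scales must be non-negative")

    @classmethod
    def from_config(cls, config: dict) -> "SyntheticCohortSpec":
        """Build a spec from a plain dict (e.g. parsed YAML/JSON).

        Recognised keys are the scalar/dict fields of this class;
        ``cov_boost`` keys may be given as "compA:compB" strings.
        """
        kwargs = {}
        names = {f.name for f in dc_fields(cls)}
        for key, val in config.items():
            if key not in names:
                raise KeyError(f"unknown synthetic-spec key {key!r}")
            if key == "cov_boost" and val is not None:
                val = {tuple(k.split(":")) if isinstance(k, str) else tuple(k): float(v) for k, v in val.items()}
            if key in ("dat_params", "age_params", "mmse_params") and val is not None:
                val = {g: (float(p[0]), float(p[1])) for g, p in val.items()}
            if key in ("site_labels", "boosted_groups") and val is not None:
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


def simulate_cohort(spec: SyntheticCohortSpec, atlas: AtlasDefinition | None = None) -> CohortMatrix:
    """Draw a full synthetic cohort.

    Per group ``g``, log-SUVr profiles are drawn from
    ``MVN(base_log_mean + delta_g * pattern [+ control pattern], cov_g)``,
    exponentiated and scaled to a volume-weighted whole-brain mean of one.
    DaT z-scores, ages, MMSE, sex and site are drawn from the group's
    metadata distributions.  Deterministic under ``spec.seed``.
    """
    spec.validate()
    atlas = atlas or load_default_atlas()
    volumes = np.asarray(atlas.volumes, dtype=float)
    base_mu = spec.base_log_mean if spec.base_log_mean is not None else _base_log_mean(atlas)
    pattern = spec.pattern if spec.pattern is not None else default_pattern(atlas)
    base_cov = spec.base_cov if spec.base_cov is not None else default_base_cov(atlas)
    boosted_cov = build_covariance(base_cov, spec.cov_boost, atlas)

    streams = np.random.SeedSequence(spec.seed).spawn(len(GROUP_ORDER))
    frames_meta, frames_vals, ids = [], [], []
    for gi, group in enumerate(GROUP_ORDER):
        n = int(spec.n_per_group.get(group, 0))
        if n == 0:
            continue
        rng = np.random.default_rng(streams[gi])
        mu = base_mu + spec.effect_scale.get(group, 0.0) * pattern
        if group in ("AD", "PD", "MSA"):
            mu = mu + disease_control_pattern(atlas, group)
        cov = boosted_cov if group in spec.boosted_groups else base_cov
        chol = np.linalg.cholesky(cov)
        logs = mu + rng.standard_normal((n, len(atlas.names))) @ chol.T
        raw = np.exp(logs)
        suvr = np.vstack([global_mean_scale(row, volumes) for row in raw])

        mu_z, sd_z = spec.dat_params[group]
        z_mean = rng.normal(mu_z, sd_z, size=n)
        asym = rng.normal(0.0, 0.25, size=n)
        age_m, age_s = spec.age_params[group]
        mmse_m, mmse_s = spec.mmse_params[group]
        sexes = np.where(rng.random(n) < spec.sex_ratio[group], "M", "F")
        sites = rng.choice(np.asarray(spec.site_labels), size=n)
        gids = [f"{group}_{i:03d}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "group": group,
                "age": np.clip(rng.normal(age_m, age_s, size=n), 40, 95),
                "sex": sexes,
                "site": sites,
                "scanner": [f"scanner_{s[-1]}" for s in sites],
                "mmse": np.clip(rng.normal(mmse_m, mmse_s, size=n), 0, 30),
                "dat_z_left": z_mean + asym,
                "dat_z_right": z_mean - asym,
            },
            index=gids,
        )
        frames_meta.append(meta)
        frames_vals.append(pd.DataFrame(suvr, index=gids, columns=atlas.names))
        ids.extend(gids)

    if not frames_meta:
        raise ValueError("no subjects requested")
    meta = pd.concat(frames_meta)
    meta.index.name = "subject_id"
    values = pd.concat(frames_vals)
    values.index.name = "subject_id"
    return CohortMatrix(meta=meta, values=values, atlas=atlas)
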