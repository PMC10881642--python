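"""DaT-SPECT putaminal z-scores and DaT(+)/DaT(-) stratification.

Putaminal DaT binding ratios (putamen-to-occipital) are expressed in SD
units of a healthy-control normative sample, per hemisphere; the average
of the two hemispheric z-scores classifies DLB subjects into those with
significant dopaminergic deficit (z_mean <= -2, DaT(+)) and those without
(z_mean > -2, DaT(-)).  The boundary is closed: exactly -2 is DaT(+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = ["DatNormative", "DatResult", "putaminal_z", "stratify_cohort", "DAT_THRESHOLD"]

DAT_THRESHOLD = -2.0


@dataclass(frozen=True)
class DatNormative:
    """Healthy-control putaminal DaT-ratio statistics (per hemisphere).

    The packaged defaults are for synthetic use only and are not a
    clinically normative sample.
    """

    hc_mean_left: float
    hc_sd_left: float
    hc_mean_right: float
    hc_sd_right: float

    def __post_init__(self) -> None:
        if self.hc_sd_left <= 0 or self.hc_sd_right <= 0:
            raise ValueError("normative SDs must be positive")


#: Synthetic-use-only defaults (plausible putamen/occipital ratio scale).
SYNTHETIC_NORMATIVE = DatNormative(hc_mean_left=2.6, hc_sd_left=0.35, hc_mean_right=2.6, hc_sd_right=0.35)


@dataclass(frozen=True)
class DatResult:
    z_left: float
    z_right: float

    @property
    def z_mean(self) -> float:
        return (self.z_left + self.z_right) / 2.0

    @property
    def stratum(self) -> str:
        return "DATPOS" if self.z_mean <= DAT_THRESHOLD else "DATNEG"


def putaminal_z(ratio_left: float, ratio_right: float, norm: DatNormative) -> DatResult:
    """Hemispheric putaminal DaT z-scores against the normative sample."""
    return DatResult(
        z_left=(ratio_left - norm.hc_mean_left) / norm.hc_sd_left,
        z_right=(ratio_right - norm.hc_mean_right) / norm.hc_sd_right,
    )


def stratify_cohort(cohort: CohortMatrix, norm: DatNormative | None = None) -> CohortMatrix:
    """Relabel DLB rows as DLB_DATPOS / DLB_DATNEG by mean putaminal z.

    DLB subjects carrying precomputed ``dat_z_left/right`` are used as is;
    otherwise ``dat_ratio_putamen_L/R`` are converted with ``norm``.  DLB
    rows with neither are excluded with a warning (imaging-arm inclusion
    criteria).  Counts per stratum are logged.
    """
    out = cohort.copy()
    meta = out.meta
    dlb_mask = meta["group"].isin(["DLB", "DLB_DATPOS", "DLB_DATNEG"])
    drop: list[str] = []
    n_pos = n_neg = 0
    for sid in meta.index[dlb_mask]:
        row = meta.loc[sid]
        if "dat_z_left" in meta.columns and np.isfinite(row.get("dat_z_left", np.nan)) and np.isfinite(
            row.get("dat_z_right", np.nan)
        ):
            res = DatResult(z_left=float(row["dat_z_left"]), z_right=float(row["dat_z_right"]))
        elif (
            "dat_ratio_putamen_L" in meta.columns
            and np.isfinite(row.get("dat_ratio_putamen_L", np.nan))
            and np.isfinite(row.get("dat_ratio_putamen_R", np.nan))
        ):
            if norm is None:
                raise ValueError("DaT ratios present but no normative statistics supplied")
            res = putaminal_z(float(row["dat_ratio_putamen_L"]), float(row["dat_ratio_putamen_R"]), norm)
        else:
            logger.warning("DLB subject %s lacks DaT data; excluded from stratified cohort", sid)
            drop.append(sid)
            continue
        meta.loc[sid, "group"] = f"DLB_{res.stratum}"
        if res.stratum == "DATPOS":
            n_pos += 1
        else:
            n_neg += 1
    if drop:
        keep = meta.index.difference(drop, sort=False)
        out = out.subset(keep)
    logger.info("DaT stratification: %d DaT(+), %d DaT(-), %d excluded", n_pos, n_neg, len(drop))
    return out
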