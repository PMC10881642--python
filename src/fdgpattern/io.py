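"""Cohort tables and matrix/report serialization.

The pipeline's central container is :class:`CohortMatrix`: per-subject
metadata plus a subjects x 77 matrix of global-mean-scaled SUVr values in
atlas region order.  Tables are plain delimited text (comma or tab,
auto-detected); square matrices are TSV with region-name headers; reports
are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "CohortMatrix",
    "VALID_GROUPS",
    "read_cohort_table",
    "write_cohort_table",
    "write_matrix",
    "read_matrix",
    "write_report",
]

#: Accepted cohort labels.  "DLB" is the pre-stratification label; the DaT
#: stratification step relabels it to DLB_DATPOS / DLB_DATNEG.
VALID_GROUPS = ("HC", "DLB", "DLB_DATPOS", "DLB_DATNEG", "AD", "PD", "MSA")

METADATA_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "site",
    "scanner",
    "mmse",
    "dat_ratio_putamen_L",
    "dat_ratio_putamen_R",
    "dat_z_left",
    "dat_z_right",
)


@dataclass
class CohortMatrix:
    """Subjects x regions SUVr matrix plus per-subject metadata.

    ``meta`` and ``values`` share an index of unique subject ids; ``values``
    columns are the 77 atlas region names in atlas order and are strictly
    positive with no missing entries.
    """

    meta: pd.DataFrame
    values: pd.DataFrame
    atlas: AtlasDefinition

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.values.index):
            raise ValueError("meta and values must share the same subject index")
        if self.meta.index.has_duplicates:
            dup = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject id(s): {dup}")
        if list(self.values.columns) != self.atlas.names:
            raise ValueError("value columns must be the atlas regions in atlas order")
        if self.values.isna().any().any():
            raise ValueError("values contain missing entries after listwise exclusion")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("SUVr values must be strictly positive")
        bad = set(self.meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def select(self, *groups: str) -> "CohortMatrix":
        """Sub-cohort restricted to the given group labels (kept in row order)."""
        mask = self.meta["group"].isin(groups)
        return replace(self, meta=self.meta.loc[mask].copy(), values=self.values.loc[mask].copy())

    def subset(self, subject_ids) -> "CohortMatrix":
        return replace(
            self, meta=self.meta.loc[subject_ids].copy(), values=self.values.loc[subject_ids].copy()
        )

    def matrix(self) -> np.ndarray:
        """The subjects x 77 value matrix as a float array."""
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "CohortMatrix":
        return replace(self, meta=self.meta.copy(), values=self.values.copy())


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_cohort_table(path, atlas: AtlasDefinition) -> CohortMatrix:
    """Read a delimited cohort table into a :class:`CohortMatrix`.

    The file must contain ``subject_id`` and ``group`` columns and all 77
    atlas region columns (any order; reordered to atlas order).  Rows with
    any missing region value are dropped (listwise exclusion) and counted
    in the log.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_detect_sep(path))
    missing = [name for name in atlas.names if name not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing region column(s): {missing}")
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dup}")
    bad = set(table["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")

    values = table[atlas.names].astype(float)
    keep = ~values.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "listwise exclusion: dropped %d subject(s) with missing region values: %s",
            n_dropped,
            table.loc[~keep, "subject_id"].tolist(),
        )
    table = table.loc[keep]
    meta_cols = [c for c in METADATA_COLUMNS if c in table.columns and c != "subject_id"]
    meta = table.set_index("subject_id")[meta_cols]
    values = table.set_index("subject_id")[atlas.names].astype(float)
    return CohortMatrix(meta=meta, values=values, atlas=atlas)


def write_cohort_table(cohort: CohortMatrix, path, sep: str = ",") -> None:
    out = pd.concat([cohort.meta, cohort.values], axis=1)
    out.index.name = "subject_id"
    out.to_csv(path, sep=sep)


def write_matrix(matrix: np.ndarray, labels, path) -> None:
    """Write a labelled square matrix as TSV; asymmetry is flagged in a comment."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels do not match matrix shape")
    finite = np.isfinite(matrix)
    sym = bool(
        np.allclose(np.where(finite, matrix, 0.0), np.where(finite, matrix, 0.0).T, atol=0)
        and (finite == finite.T).all()
    )
    with open(path, "w") as fh:
        fh.write(f"# symmetric: {sym}\n")
        pd.DataFrame(matrix, index=labels, columns=labels).to_csv(fh, sep="\t", float_format="%.17g")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return table.to_numpy(dtype=float), list(table.index)


def write_report(tables: dict, path) -> None:
    """Serialize a report bundle (nested dicts/lists/scalars) as JSON."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return json.loads(obj.to_json(orient="split"))
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(tables, fh, indent=2, default=_default)
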