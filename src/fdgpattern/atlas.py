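"""Atlas definition: the 77 grey-matter volumes of interest and their composites.

The canonical parcellation used throughout the package is a 77-region
grey-matter subset of the Hammers adult maximum-probability atlas
(38 bilateral pairs plus the brainstem).  Eight composite regions group
the individual VOIs into lobar/functional units: frontal, parietal,
temporal, occipital, insula, limbic, basal_ganglia and cerebellum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["AtlasDefinition", "load_default_atlas", "COMPOSITE_NAMES", "N_REGIONS"]

N_REGIONS = 77
COMPOSITE_NAMES = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "insula",
    "limbic",
    "basal_ganglia",
    "cerebellum",
)


@dataclass(frozen=True)
class AtlasDefinition:
    """An ordered 77-region grey-matter parcellation.

    Parameters
    ----------
    regions
        Ordered ``(label, name)`` pairs; exactly 77, labels and names unique.
    composites
        Mapping from the eight composite names to subsets of region names.
    volumes
        Optional per-region volumes (mm^3) in region order, used as weights
        for volume-weighted means.  Strictly positive when present.
    """

    regions: tuple[tuple[int, str], ...]
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)
    volumes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.regions) != N_REGIONS:
            raise ValueError(
                f"atlas must define exactly {N_REGIONS} regions, got {len(self.regions)}"
            )
        labels = [lab for lab, _ in self.regions]
        names = [name for _, name in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("atlas labels are not unique")
        if len(set(names)) != len(names):
            raise ValueError("atlas region names are not unique")
        name_set = set(names)
        for comp, members in self.composites.items():
            if not members:
                raise ValueError(f"composite {comp!r} is empty")
            unknown = set(members) - name_set
            if unknown:
                raise ValueError(f"composite {comp!r} has unknown regions: {sorted(unknown)}")
        if self.volumes is not None:
            if len(self.volumes) != N_REGIONS:
                raise ValueError("volumes must have one entry per region")
            if any(v <= 0 for v in self.volumes):
                raise ValueError("volumes must be strictly positive")

    @property
    def labels(self) -> list[int]:
        return [lab for lab, _ in self.regions]

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.regions]

    def index_of(self, name: str) -> int:
        """Position of a region name in atlas order."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def composite_members(self, composite: str) -> list[str]:
        if composite not in self.composites:
            raise KeyError(f"unknown composite {composite!r}")
        return list(self.composites[composite])

    def composite_indices(self, composite: str) -> list[int]:
        return [self.index_of(n) for n in self.composite_members(composite)]


def load_default_atlas() -> AtlasDefinition:
    """Load the packaged canonical 77-region atlas with composites and volumes."""
    with resources.files("fdgpattern.data").joinpath("hammers77.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    regions = tuple(zip(table["label"].astype(int), table["name"]))
    composites: dict[str, list[str]] = {c: [] for c in COMPOSITE_NAMES}
    for _, row in table.iterrows():
        comp = row["composite"]
        if isinstance(comp, str) and comp:
            composites[comp].append(row["name"])
    return AtlasDefinition(
        regions=regions,
        composites={c: tuple(m) for c, m in composites.items()},
        volumes=tuple(table["volume_mm3"].astype(float)),
    )
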