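"""Group-level metabolic connectivity.

Metabolic connectivity is the matrix of inter-region correlation
coefficients (Pearson, across the subjects of one group) of global-mean
scaled regional FDG-PET values, Fisher-transformed (z = atanh r) to
stabilise the variance.  Between-group differences of the Fisher-z
matrices quantify connectivity alterations; the similarity of two such
delta matrices is assessed by regression over the off-diagonal
upper-triangle pairs, with a region-label permutation test alongside the
parametric p-value (pairs sharing a region are not independent, so the
parametric p is anti-conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "DeltaConnectivity",
    "fisher_z",
    "icc_matrix",
    "icc_from_matrix",
    "delta_matrix",
    "connectivity_similarity",
]

#: Correlations are clipped to this magnitude before atanh.
R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher transformation z = atanh(r) = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("|r| must be < 1 after clipping")
    return np.arctanh(r)


@dataclass
class ConnectivityMatrix:
    """One group's 77x77 inter-region correlation matrix (r and Fisher z).

    Symmetric by construction (upper triangle computed once and mirrored);
    the diagonal is excluded from all summaries.
    """

    group: str
    n_subjects: int
    region_names: list[str]
    r_values: np.ndarray
    z_values: np.ndarray

    @property
    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(len(self.region_names), dtype=bool)

    def upper_triangle(self, of: str = "z") -> np.ndarray:
        """Off-diagonal upper-triangle entries (n*(n-1)/2 values)."""
        m = self.z_values if of == "z" else self.r_values
        iu = np.triu_indices(len(self.region_names), k=1)
        return m[iu]


def icc_matrix(cohort: CohortMatrix, group: str | None = None) -> ConnectivityMatrix:
    """Inter-region correlation matrix of one group.

    ``r[i, j]`` is the Pearson correlation across subjects of region i vs
    region j.  Requires at least 4 subjects and non-constant regions; |r|
    is clipped to ``1 - 1e-7`` before the Fisher transform.
    """
    sub = cohort.select(group) if group is not None else cohort
    label = group if group is not None else "/".join(sorted(set(sub.meta["group"])))
    return icc_from_matrix(sub.matrix(), sub.atlas.names, group=label)


def icc_from_matrix(X: np.ndarray, region_names, group: str = "") -> ConnectivityMatrix:
    """Inter-region correlation (and Fisher z) of a raw subjects x regions matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError(f"group {group!r} has n={n} < 4 subjects")
    sd = X.std(axis=0, ddof=1)
    const = np.where(sd == 0)[0]
    if const.size:
        names = [region_names[i] for i in const]
        raise ValueError(f"constant region column(s): {names}")
    r_full = np.corrcoef(X, rowvar=False)
    # mirror the upper triangle for exact symmetry despite float non-associativity
    r = np.triu(r_full, k=1)
    r = r + r.T
    np.fill_diagonal(r, 1.0)
    clipped = np.abs(r) > R_CLIP
    off = ~np.eye(p, dtype=bool)
    if (clipped & off).any():
        logger.warning("clipped %d correlation(s) at |r| = 1 - 1e-7", int((clipped & off).sum() // 2))
    r_c = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r_c)
    np.fill_diagonal(z, np.arctanh(R_CLIP))
    return ConnectivityMatrix(
        group=group, n_subjects=n, region_names=list(region_names), r_values=r, z_values=z
    )


@dataclass
class DeltaConnectivity:
    """Elementwise difference of two groups' Fisher-z connectivity matrices."""

    contrast: tuple[str, str]
    region_names: list[str]
    dz: np.ndarray

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.region_names), k=1)
        return self.dz[iu]


def delta_matrix(a: ConnectivityMatrix, b: ConnectivityMatrix) -> DeltaConnectivity:
    """``dz = z_a - z_b`` on the off-diagonal entries; antisymmetric in (a, b)."""
    if a.region_names != b.region_names:
        raise ValueError("connectivity matrices use different atlas orderings")
    dz = a.z_values - b.z_values
    np.fill_diagonal(dz, 0.0)
    return DeltaConnectivity(contrast=(a.group, b.group), region_names=list(a.region_names), dz=dz)


def connectivity_similarity(
    delta_a: DeltaConnectivity,
    delta_b: DeltaConnectivity,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> dict[str, float]:
    """Regression of one delta-connectivity matrix on another.

    Uses the off-diagonal upper triangle (2926 pairs for 77 regions).
    Returns slope, intercept, R^2 and the parametric two-sided p, plus a
    region-label permutation p (rows/columns of ``delta_b`` permuted
    jointly), which respects the dependence among pairs sharing a region.
    """
    if delta_a.region_names != delta_b.region_names:
        raise ValueError("delta matrices use different atlas orderings")
    p = len(delta_a.region_names)
    iu = np.triu_indices(p, k=1)
    x = delta_a.dz[iu]
    y = delta_b.dz[iu]
    if x.size < 3:
        raise ValueError("need at least 3 region pairs")
    if x.std() == 0:
        raise ValueError("constant predictor delta matrix")
    res = stats.linregress(x, y)
    out = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_parametric": float(res.pvalue),
        "n_pairs": int(x.size),
    }
    if n_permutations and n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = res.rvalue**2
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(p)
            yp = delta_b.dz[np.ix_(perm, perm)][iu]
            r = np.corrcoef(x, yp)[0, 1]
            if r * r >= obs:
                count += 1
        out["p_permutation"] = float((count + 1) / (n_permutations + 1))
        out["n_permutations"] = int(n_permutations)
    return out
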