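"""Scaled-subprofile-model (SSM) style PCA of regional FDG-PET profiles.

The subjects x regions SUVr matrix is log-transformed and double centred
(each subject's row mean, then each region's column mean are removed), so
that residual covariance rather than global level drives the components.
Principal components are extracted from the region x region correlation
matrix, retained by the Kaiser criterion (eigenvalue > 1), varimax-rotated
with Kaiser normalization, and subject factor scores are computed by the
regression method and standardized to unit variance — the conventions of
classic factor-analysis software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "log_and_double_center",
    "varimax_rotate",
    "varimax_criterion",
    "fit_ssm_pca",
    "SSMModel",
    "save_model",
    "load_model",
]

#: Guard band on the Kaiser criterion: retain eigenvalues > 1 + this, so
#: numerically-1 eigenvalues of near-independent data are not retained.
EIGEN_GUARD = 1e-8


def log_and_double_center(values: np.ndarray, region_names=None):
    """Log-transform and double centre a subjects x regions matrix.

    Subtracts each subject's row mean from ``ln(values)``, then each
    region's column mean of the row-centred matrix; the result has all row
    and column means zero (to float precision) and the operation is
    idempotent.

    Returns ``(centred, row_means, col_means)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a subjects x regions matrix")
    if (v <= 0).any() or not np.isfinite(v).all():
        i, j = np.argwhere(~((v > 0) & np.isfinite(v)))[0]
        region = region_names[j] if region_names is not None else f"column {j}"
        raise ValueError(f"non-positive value for subject row {i}, region {region}")
    L = np.log(v)
    row_means = L.mean(axis=1)
    L = L - row_means[:, None]
    col_means = L.mean(axis=0)
    L = L - col_means[None, :]
    return L, row_means, col_means


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """The (optionally Kaiser-normalized) raw varimax criterion.

    ``V = sum_k [ p * sum_j b_jk^4 - (sum_j b_jk^2)^2 ] / p^2`` where the
    ``b`` are the (row-normalized) loadings.  Both the production rotation
    and any independent oracle should be compared on this value.
    """
    A = np.asarray(loadings, dtype=float)
    p = A.shape[0]
    if kaiser:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    b2 = A**2
    return float(((p * (b2**2).sum(axis=0) - b2.sum(axis=0) ** 2) / p**2).sum())


def varimax_rotate(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-10, max_iter: int = 1000):
    """Varimax rotation (orthogonal), SVD-update algorithm.

    Maximises the varimax criterion on Kaiser-normalized loadings;
    communalities (row sums of squared loadings) are preserved and the
    returned rotation matrix is orthonormal.  Each rotated component is
    sign-oriented so its largest-magnitude loading is positive.

    Returns ``(rotated_loadings, rotation)`` with ``rotated = loadings @ rotation``.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k == 1:
        rot = np.ones((1, 1))
        rotated = A.copy()
    else:
        if kaiser:
            h = np.sqrt((A**2).sum(axis=1))
            h_safe = np.where(h == 0, 1.0, h)
            B = A / h_safe[:, None]
        else:
            B = A
        T = np.eye(k)
        d = 0.0
        for _ in range(max_iter):
            L = B @ T
            grad = B.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
            u, s, vt = np.linalg.svd(grad)
            T = u @ vt
            d_new = s.sum()
            if d_new <= d * (1 + tol):
                break
            d = d_new
        rot = T
        rotated = A @ rot
    # deterministic sign orientation
    for j in range(rotated.shape[1]):
        i_max = np.argmax(np.abs(rotated[:, j]))
        if rotated[i_max, j] < 0:
            rotated[:, j] *= -1
            rot[:, j] *= -1
    return rotated, rot


@dataclass
class SSMModel:
    """A trained metabolic covariance pattern model.

    Holds everything needed to score new subjects: centering statistics,
    retained (rotated) loadings, regression-method score weights, the
    status-regression weighting factors beta, and the training-run
    healthy-control expression reference.
    """

    region_names: list[str]
    training_ids: list[str]
    n_components: int
    eigenvalues: np.ndarray  # retained, unrotated, descending
    loadings: np.ndarray  # regions x K, varimax-rotated
    rotation: np.ndarray  # K x K orthonormal
    score_weights: np.ndarray  # regions x K, standardized-score weights
    col_means: np.ndarray  # region means of row-centred log data
    col_sds: np.ndarray  # region SDs of centred log data
    eigen_cut: float = 1.0
    beta: np.ndarray | None = None  # K weighting factors
    intercept: float | None = None
    covariate_names: list[str] = field(default_factory=list)
    covariate_coefs: np.ndarray | None = None
    hc_ref_mean: float | None = None
    hc_ref_sd: float | None = None
    training_values: np.ndarray | None = None  # subjects x regions SUVr, for leave-one-in
    training_groups: list[str] | None = None

    def factor_scores(self, centred_std: np.ndarray) -> np.ndarray:
        """Standardized regression-method factor scores for standardized profiles."""
        return centred_std @ self.score_weights


def fit_ssm_pca(
    values: np.ndarray,
    subject_ids,
    region_names,
    eigen_cut: float = 1.0,
    use_correlation: bool = True,
    preprocess: str = "ssm",
) -> SSMModel:
    """Extract the SSM/PCA pattern model from a training SUVr matrix.

    Eigendecomposition of the region x region correlation matrix of the
    log-transformed, double-centred data (covariance matrix when
    ``use_correlation=False``); components with eigenvalue > ``eigen_cut``
    are retained, varimax-rotated, and regression-method score weights are
    derived so training factor scores have zero mean and unit variance per
    component.

    ``preprocess='ssm'`` is the canonical log + double-centre path;
    ``preprocess='center'`` only removes column means (for generic numeric
    matrices, e.g. closed-form checks on small correlation structures).
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 training subjects")
    if preprocess == "ssm":
        Y, _, col_means = log_and_double_center(values, region_names)
    elif preprocess == "center":
        col_means = values.mean(axis=0)
        Y = values - col_means[None, :]
    else:
        raise ValueError(f"unknown preprocess {preprocess!r}")
    col_sds = Y.std(axis=0, ddof=1)
    if (col_sds == 0).any():
        bad = [region_names[i] for i in np.where(col_sds == 0)[0]]
        raise ValueError(f"constant region(s) in training data: {bad}")
    Z = Y / col_sds[None, :] if use_correlation else Y
    R = (Z.T @ Z) / (n - 1)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > eigen_cut + EIGEN_GUARD
    K = int(keep.sum())
    if K == 0:
        raise ValueError("no components retained (no eigenvalue exceeds the cut)")
    if n <= K:
        raise ValueError(f"need more subjects ({n}) than retained components ({K})")
    wk, Vk = w[:K], V[:, :K]
    # deterministic sign: largest-|.| loading element positive
    A = Vk * np.sqrt(wk)[None, :]
    for j in range(K):
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] *= -1
    loadings, rot = varimax_rotate(A)
    # regression-method weights via the eigen pseudo-inverse of R
    pos = w > 1e-10
    R_pinv = (V[:, pos] / w[pos]) @ V[:, pos].T
    W = R_pinv @ loadings
    F = Z @ W
    sds = F.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError("degenerate factor scores")
    W = W / sds[None, :]
    return SSMModel(
        region_names=list(region_names),
        training_ids=list(subject_ids),
        n_components=K,
        eigenvalues=wk,
        loadings=loadings,
        rotation=rot,
        score_weights=W,
        col_means=col_means,
        col_sds=col_sds,
        eigen_cut=eigen_cut,
        training_values=values,
    )


def save_model(model: SSMModel, path) -> None:
    """Serialize a trained model (including the training matrix) to JSON."""
    doc = {
        "format": "fdgpattern-ssm-model",
        "version": 1,
        "region_names": model.region_names,
        "training_ids": model.training_ids,
        "n_components": model.n_components,
        "eigen_cut": model.eigen_cut,
        "eigenvalues": model.eigenvalues.tolist(),
        "loadings": model.loadings.tolist(),
        "rotation": model.rotation.tolist(),
        "score_weights": model.score_weights.tolist(),
        "col_means": model.col_means.tolist(),
        "col_sds": model.col_sds.tolist(),
        "beta": None if model.beta is None else model.beta.tolist(),
        "intercept": model.intercept,
        "covariate_names": model.covariate_names,
        "covariate_coefs": None if model.covariate_coefs is None else model.covariate_coefs.tolist(),
        "hc_ref_mean": model.hc_ref_mean,
        "hc_ref_sd": model.hc_ref_sd,
        "training_values": None if model.training_values is None else model.training_values.tolist(),
        "training_groups": model.training_groups,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SSMModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "fdgpattern-ssm-model":
        raise ValueError("not a pattern model file")

    def arr(key):
        return None if doc[key] is None else np.asarray(doc[key], dtype=float)

    return SSMModel(
        region_names=doc["region_names"],
        training_ids=doc["training_ids"],
        n_components=doc["n_components"],
        eigen_cut=doc["eigen_cut"],
        eigenvalues=arr("eigenvalues"),
        loadings=arr("loadings"),
        rotation=arr("rotation"),
        score_weights=arr("score_weights"),
        col_means=arr("col_means"),
        col_sds=arr("col_sds"),
        beta=arr("beta"),
        intercept=doc["intercept"],
        covariate_names=doc["covariate_names"],
        covariate_coefs=arr("covariate_coefs"),
        hc_ref_mean=doc["hc_ref_mean"],
        hc_ref_sd=doc["hc_ref_sd"],
        training_values=arr("training_values"),
        training_groups=doc["training_groups"],
    )
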