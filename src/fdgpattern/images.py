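"""Optional image-space ingestion: smoothing and VOI mean extraction.

The pipeline's canonical input is the regional table; this module is a
convenience path for atlas-space NIfTI volumes.  No spatial normalization
is performed — image and label map are assumed to be in the same space.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .atlas import AtlasDefinition

__all__ = ["gaussian_smooth", "extract_voi_means", "fwhm_to_sigma", "regional_means_from_nifti"]

#: FWHM = sigma * 2*sqrt(2 ln 2)
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian kernel full-width-at-half-maximum to sigma (same units)."""
    return fwhm_mm / FWHM_FACTOR


def gaussian_smooth(image: np.ndarray, fwhm_mm: float, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Separable 3-D Gaussian smoothing with FWHM given in millimetres.

    Uses reflect padding at the boundary, which preserves total mass for
    interior impulses.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size.shape != (3,) or (voxel_size <= 0).any():
        raise ValueError("voxel_size_mm must be three positive values")
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be a 3-D array")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size
    return ndimage.gaussian_filter(image, sigma=sigma_vox, mode="reflect")


def extract_voi_means(
    image: np.ndarray, labels: np.ndarray, atlas: AtlasDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Mean image value and voxel count per atlas VOI.

    Returns ``(means, counts)``, both of length 77 in atlas order.  Every
    atlas label must occur in the label map.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"image shape {image.shape} != label map shape {labels.shape}")
    atlas_labels = np.asarray(atlas.labels)
    present = np.unique(labels)
    missing = np.setdiff1d(atlas_labels, present)
    if missing.size:
        names = [name for lab, name in atlas.regions if lab in set(missing.tolist())]
        raise ValueError(f"label map lacks atlas label(s) {missing.tolist()} ({names})")
    counts = ndimage.sum_labels(np.ones_like(image), labels, atlas_labels)
    sums = ndimage.sum_labels(image, labels, atlas_labels)
    return sums / counts, counts.astype(int)


def regional_means_from_nifti(image_path, label_path, atlas: AtlasDefinition, fwhm_mm: float | None = 8.0):
    """Load NIfTI image + label map, optionally smooth, and extract VOI means."""
    import nibabel as nib

    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(lab.dataobj).astype(int)
    if fwhm_mm is not None:
        voxdim = img.header.get_zooms()[:3]
        data = gaussian_smooth(data, fwhm_mm, voxdim)
    return extract_voi_means(data, labels, atlas)
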