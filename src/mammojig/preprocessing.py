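"""Image-selection and cropping rules.

Implements the dataset curation steps of the classification study:
manifest-level exclusions (radiological exclusion flags), breast-area
segmentation by Otsu thresholding, 512x512 lesion-centred crops, and
randomly placed normal-tissue crops restricted to the bottom 80% of the
breast-area rows — the restriction that keeps the pectoral-muscle wedge,
which sits at the top of the breast region in MLO views, out of the
normal crops.

Conventions: row/column coordinates, 0-based, half-open crop windows;
crops near the border are clamped to image bounds (never padded), so a
crop always consists of real pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .records import EXCLUSION_FLAGS, ImageRecord, Manifest

__all__ = [
    "BreastSegmentation",
    "apply_exclusions",
    "segment_breast",
    "crop_lesion_centered",
    "crop_normal_region",
]


class SegmentationError(ValueError):
    """Thresholding produced an empty breast foreground."""


@dataclass
class BreastSegmentation:
    """Binary breast-area mask with its boundary contour and row extent."""

    breast_mask: np.ndarray
    outline: np.ndarray  # (n, 2) ordered boundary pixel coordinates
    row_extent: tuple[int, int]  # (top_row, bottom_row), inclusive

    def __post_init__(self) -> None:
        if not self.breast_mask.any():
            raise SegmentationError("breast mask is empty")
        top, bottom = self.row_extent
        if top >= bottom:
            raise ValueError("row extent must satisfy top_row < bottom_row")


def apply_exclusions(manifest: Manifest) -> tuple[Manifest, dict]:
    """Drop flagged records; report how many each flag removed.

    Keeps exactly the records with ``exclusion_flag == "none"``, in their
    original order. The report maps every non-``none`` flag to its removal
    count and carries ``kept`` / ``total`` entries, so removed + kept
    always equals the input size.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    counts = {flag: 0 for flag in EXCLUSION_FLAGS if flag != "none"}
    kept: list[ImageRecord] = []
    for rec in manifest:
        if rec.exclusion_flag == "none":
            kept.append(rec)
        elif rec.exclusion_flag in counts:
            counts[rec.exclusion_flag] += 1
        else:  # pragma: no cover - ImageRecord already validates flags
            raise ValueError(f"unknown exclusion flag {rec.exclusion_flag!r}")
    report = dict(counts)
    report["kept"] = len(kept)
    report["total"] = len(manifest)
    out = Manifest.from_records(kept, provenance=manifest.provenance)
    return out, report


def segment_breast(image: np.ndarray) -> BreastSegmentation:
    """Binarize into breast area and background; extract the outline.

    Otsu's threshold on the gray histogram separates tissue from the dark
    background; the breast area is the largest connected foreground
    component and the outline is its longest boundary contour.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if np.ptp(img) == 0:
        raise SegmentationError("image is constant; nothing to segment")
    thresh = filters.threshold_otsu(img)
    fg = img > thresh
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len)
    rows = np.flatnonzero(mask.any(axis=1))
    return BreastSegmentation(
        breast_mask=mask,
        outline=outline,
        row_extent=(int(rows[0]), int(rows[-1])),
    )


def _clamped_window(center: int, size: int, limit: int) -> tuple[int, int]:
    start = center - size // 2
    start = max(0, min(start, limit - size))
    return start, start + size


def crop_lesion_centered(image: np.ndarray, mask: np.ndarray, crop: int = 512
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Crop a ``crop``-sized window centred on the lesion-mask centroid.

    The window is clamped so it never leaves the image; the returned mask
    is the lesion mask translated into crop coordinates.
    """
    image = np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if image.shape[0] < crop or image.shape[1] < crop:
        raise ValueError(f"image smaller than {crop}x{crop} crop")
    cy, cx = ndimage.center_of_mass(mask)
    r0, r1 = _clamped_window(int(round(cy)), crop, image.shape[0])
    c0, c1 = _clamped_window(int(round(cx)), crop, image.shape[1])
    return image[r0:r1, c0:c1], mask[r0:r1, c0:c1]


def normal_crop_center(image: np.ndarray, seg: BreastSegmentation,
                       crop: int = 512, seed: int = 0) -> tuple[int, int]:
    """Sampled centre of a normal-tissue crop (see
    :func:`crop_normal_region`), drawn uniformly over the admissible
    pixels: inside the breast mask, below the top 20% of the breast's
    row extent, and far enough from the borders that the window fits."""
    image = np.asarray(image)
    if image.shape[0] < crop or image.shape[1] < crop:
        raise ValueError(f"image smaller than {crop}x{crop} crop")
    top, bottom = seg.row_extent
    row_cut = top + 0.2 * (bottom - top)
    admissible = seg.breast_mask.copy()
    rows = np.arange(image.shape[0])
    admissible[rows < row_cut, :] = False
    # window must fit: centre at c gives window [c - crop//2, c - crop//2 + crop)
    half = crop // 2
    admissible[: half, :] = False
    admissible[image.shape[0] - (crop - half) + 1:, :] = False
    admissible[:, : half] = False
    admissible[:, image.shape[1] - (crop - half) + 1:] = False
    coords = np.argwhere(admissible)
    if len(coords) == 0:
        raise ValueError("no admissible crop centre inside the breast area")
    rng = np.random.default_rng(seed)
    cy, cx = coords[rng.integers(len(coords))]
    return int(cy), int(cx)


def crop_normal_region(image: np.ndarray, seg: BreastSegmentation,
                       crop: int = 512, seed: int = 0) -> np.ndarray:
    """Random ``crop``-sized window from the bottom 80% of the breast area.

    The crop centre is drawn uniformly over pixels that lie inside the
    breast mask, below the top 20% of the breast's row extent (excluding
    the pectoral wedge, which sits at the top of the breast in MLO
    views), and far enough from the borders that the window stays inside
    the image. Seeded and reproducible.
    """
    image = np.asarray(image)
    cy, cx = normal_crop_center(image, seg, crop, seed)
    r0, r1 = _clamped_window(cy, crop, image.shape[0])
    c0, c1 = _clamped_window(cx, crop, image.shape[1])
    return image[r0:r1, c0:c1]
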