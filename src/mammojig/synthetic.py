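"""Seeded synthetic mammogram phantoms with lesion masks and manifests.

The generator emulates the statistical structure of a lesion-centred
mammography crop dataset: a bright breast-tissue field over a dark
background, fibroglandular texture whose amplitude depends on the breast
density category (dense breasts are brighter, noisier and hide lesions),
and three lesion classes — mass, calcification and architectural
distortion — each with a ground-truth mask whose area fraction is drawn
from a configurable range. Cancer-positive lesions differ systematically
from benign ones (spiculated mass margins, tight irregular calcification
clusters, strong swirls) so that a classifier can in principle separate
the classes.

Two positional cues are built into every phantom so the jigsaw pretext
task is solvable: fibrous streaks radiate from a per-image focus point
(mimicking ductal structure converging on the nipple), and a smooth
illumination falloff centred off-image. Both cues survive per-patch
intensity standardization because they change local texture orientation,
not just brightness.

Images use the 16-bit gray range of digital mammography and are written
as 16-bit PNG; masks as 8-bit binary (0/255) PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .records import EXCLUSION_FLAGS, FINDINGS, ImageRecord, Manifest

__all__ = [
    "SyntheticConfig",
    "generate_record",
    "build_dataset",
    "generate_fullfield",
    "total_images",
]

GRAY_MAX = 65535.0

# Category proportions of the study population the generator emulates
# (lesion-centred crops plus normal-tissue crops; rates derived from the
# 2824-image breakdown: 1140 mass, 570 calcification, 60 distortion,
# 1054 normal; 2377 dense).
_DEFAULT_FINDING_MIX = {
    "mass": 1140 / 2824,
    "calcification": 570 / 2824,
    "distortion": 60 / 2824,
    "normal": 1054 / 2824,
}
_DEFAULT_CANCER_RATE = {
    "mass": 954 / 1140,
    "calcification": 508 / 570,
    "distortion": 53 / 60,
    "normal": 0.0,
}
# Mask area fraction of the 512x512 crop per finding; uniform ranges
# centred on the reference means 0.207 / 0.252 / 0.575.
_DEFAULT_AREA_RANGE = {
    "mass": (0.157, 0.257),
    "calcification": (0.202, 0.302),
    "distortion": (0.475, 0.675),
}
# Exclusion-flag rates per image (radiological exclusion causes, relative
# to a 2601-image population: 6, 2, 1, 8, 5, 3, 140).
_DEFAULT_EXCLUSION_RATES = {
    "phyllodes": 6 / 2601,
    "neurofibromatosis": 2 / 2601,
    "lymphedema": 1 / 2601,
    "venous_port": 8 / 2601,
    "foreign_body": 5 / 2601,
    "artifact": 3 / 2601,
    "lesion_unidentifiable": 140 / 2601,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic phantom population.

    ``density_mix`` is the probability of the dense-breast (DB) category;
    ``two_image_rate`` the probability a synthetic patient contributes two
    images instead of one (826 of 1775 reference patients were bilateral).
    ``noise_sd`` is additive Gaussian pixel noise in 16-bit gray units.
    """

    n_patients: int = 100
    finding_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FINDING_MIX)
    )
    density_mix: float = 2377 / 2824
    cancer_rate_per_finding: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CANCER_RATE)
    )
    image_size: int = 512
    lesion_area_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_AREA_RANGE)
    )
    noise_sd: float = 600.0
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSION_RATES)
    )
    two_image_rate: float = 826 / 1775
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        mix_sum = sum(self.finding_mix.get(f, 0.0) for f in FINDINGS)
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"finding_mix must sum to 1, got {mix_sum}")
        if any(v < 0 for v in self.finding_mix.values()):
            raise ValueError("finding_mix proportions must be nonnegative")
        if not 0.0 <= self.density_mix <= 1.0:
            raise ValueError("density_mix must be a probability")
        if not 0.0 <= self.two_image_rate <= 1.0:
            raise ValueError("two_image_rate must be a probability")
        excl_sum = sum(self.exclusion_rates.values())
        if excl_sum > 1.0 + 1e-9 or any(v < 0 for v in self.exclusion_rates.values()):
            raise ValueError("exclusion_rates must be probabilities summing to <= 1")
        unknown = set(self.exclusion_rates) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        for f, (lo, hi) in self.lesion_area_range.items():
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"bad lesion_area_range for {f}: ({lo}, {hi})")


# ---------------------------------------------------------------------------
# Deterministic index bookkeeping
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def _patient_image_counts(config: SyntheticConfig) -> np.ndarray:
    """Number of images (1 or 2) each synthetic patient contributes."""
    r = _rng(config, 0xBEE)
    return 1 + (r.random(config.n_patients) < config.two_image_rate).astype(int)


def total_images(config: SyntheticConfig) -> int:
    """Total image count implied by the configuration."""
    return int(_patient_image_counts(config).sum())


def _index_to_patient(config: SyntheticConfig, index: int) -> tuple[int, int]:
    counts = _patient_image_counts(config)
    bounds = np.cumsum(counts)
    total = int(bounds[-1])
    if not 0 <= index < total:
        raise IndexError(f"index {index} out of range for {total} images")
    p = int(np.searchsorted(bounds, index, side="right"))
    within = index - (int(bounds[p - 1]) if p else 0)
    return p, within


# ---------------------------------------------------------------------------
# Texture and lesion rendering
# ---------------------------------------------------------------------------

def _smooth_noise_1d(rng: np.random.Generator, n: int, sigma: float,
                     periodic: bool) -> np.ndarray:
    x = rng.standard_normal(n)
    mode = "wrap" if periodic else "reflect"
    x = ndimage.gaussian_filter1d(x, sigma, mode=mode)
    return x / (np.abs(x).max() + 1e-12)

def _fibrous_texture(rng: np.random.Generator, shape: tuple[int, int],
                     focus: tuple[float, float]) -> np.ndarray:
    """Streaks radiating from ``focus``: product of smooth angular and
    radial noise profiles evaluated in polar coordinates about the focus."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - focus[0], cc - focus[1]
    theta = np.arctan2(dr, dc)  # [-pi, pi)
    rad = np.hypot(dr, dc)
    n_theta = 1440
    gtab = _smooth_noise_1d(rng, n_theta, sigma=7.0, periodic=True)
    htab = _smooth_noise_1d(rng, 512, sigma=12.0, periodic=False)
    ti = ((theta + np.pi) / (2 * np.pi) * n_theta).astype(int) % n_theta
    ri = np.clip(rad / (rad.max() + 1e-9) * 511, 0, 511).astype(int)
    return gtab[ti] * (0.6 + 0.4 * htab[ri])

def _parenchyma(rng: np.random.Generator, shape: tuple[int, int],
                sigma: float = 4.0) -> np.ndarray:
    x = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return x / (np.abs(x).max() + 1e-12)


def _crop_background(rng: np.random.Generator, size: int, dense: bool
                     ) -> np.ndarray:
    """Breast-tissue field filling a lesion-centred crop."""
    h = w = size
    # illumination falloff toward a random off-image point (breast edge side)
    ang = rng.uniform(0, 2 * np.pi)
    cen = (h / 2 + 0.8 * h * np.sin(ang), w / 2 + 0.8 * w * np.cos(ang))
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dist = np.hypot(rr - cen[0], cc - cen[1])
    dist = (dist - dist.min()) / (dist.max() - dist.min() + 1e-12)
    base_mean = 24000.0 if dense else 17000.0
    fib_amp = 5200.0 if dense else 3400.0
    par_amp = 3000.0 if dense else 1900.0
    # fibrous focus just outside the crop: streak orientation then varies
    # strongly across the field, the positional cue the pretext task needs
    focus = (h / 2 + 0.75 * h * np.sin(ang + np.pi), w / 2 + 0.75 * w * np.cos(ang + np.pi))
    img = (
        base_mean
        + 6000.0 * (1.0 - dist)
        + fib_amp * _fibrous_texture(rng, (h, w), focus)
        + par_amp * _parenchyma(rng, (h, w))
    )
    return img


def _tissue_convergence(img: np.ndarray, center: tuple[float, float],
                        radius: float, strength: float) -> np.ndarray:
    """Desmoplastic retraction: warp the surrounding fibrous texture so
    strands converge toward the lesion. Each pixel samples from slightly
    farther out along the radial direction; displacement peaks at
    ``strength`` pixels near ``radius`` and decays beyond."""
    h, w = img.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    rad = np.hypot(dr, dc) + 1e-9
    x = rad / radius
    disp = strength * x * np.exp(1.0 - x)  # 0 at centre, peak at radius, decays
    src_r = rr + disp * dr / rad
    src_c = cc + disp * dc / rad
    return ndimage.map_coordinates(img, [src_r, src_c], order=1, mode="reflect")


def _render_mass(rng: np.random.Generator, img: np.ndarray, cancer: bool,
                 area_frac: float, dense: bool) -> np.ndarray:
    h, w = img.shape
    area = area_frac * h * w
    ecc = rng.uniform(1.35, 1.9) if cancer else rng.uniform(1.0, 1.25)
    b = np.sqrt(area / (np.pi * ecc))
    a = ecc * b
    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    cx = w / 2 + rng.uniform(-0.04, 0.04) * w
    phi = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    u = (rr - cy) * np.cos(phi) + (cc - cx) * np.sin(phi)
    v = -(rr - cy) * np.sin(phi) + (cc - cx) * np.cos(phi)
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    contrast = rng.uniform(10000, 14000) * (0.62 if dense else 1.0)
    if cancer:
        # sharp-edged, high-contrast core with radial spicules beyond the margin
        img = img + contrast * np.exp(-(d ** 6))
        theta = np.arctan2(v, u)
        n_sp = rng.integers(9, 16)
        centers = rng.uniform(-np.pi, np.pi, n_sp)
        widths = rng.uniform(0.09, 0.2, n_sp)
        spik = np.zeros_like(img)
        for t0, wd in zip(centers, widths):
            dtheta = np.angle(np.exp(1j * (theta - t0)))
            spik += np.exp(-(dtheta / wd) ** 2)
        ring = np.exp(-(((d - 1.3) / 0.5) ** 2))
        img = img + 0.8 * contrast * np.clip(spik, 0, 1) * ring
    else:
        img = img + 0.7 * contrast * np.exp(-3.0 * d ** 2)
    mask = d <= 1.0
    return img, mask


def _render_calcification(rng: np.random.Generator, img: np.ndarray,
                          cancer: bool, area_frac: float, dense: bool
                          ) -> np.ndarray:
    h, w = img.shape
    radius = np.sqrt(area_frac * h * w / np.pi)
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    mask = d2 <= radius ** 2
    n_dots = int(2 + rng.poisson(26 if cancer else 6))
    spread = (0.45 if cancer else 0.95) * radius
    contrast = rng.uniform(16000, 24000) * (0.62 if dense else 1.0)
    for _ in range(n_dots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = spread * np.sqrt(rng.random())
        dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        sy = rng.uniform(1.6, 3.4)
        sx = sy * (rng.uniform(1.3, 2.6) if cancer else rng.uniform(0.9, 1.2))
        rot = rng.uniform(0, np.pi)
        u = (rr - dy) * np.cos(rot) + (cc - dx) * np.sin(rot)
        v = -(rr - dy) * np.sin(rot) + (cc - dx) * np.cos(rot)
        img = img + contrast * np.exp(-((u / sx) ** 2 + (v / sy) ** 2))
    return img, mask


def _render_distortion(rng: np.random.Generator, img: np.ndarray,
                       cancer: bool, area_frac: float, dense: bool
                       ) -> np.ndarray:
    h, w = img.shape
    side = np.sqrt(area_frac * h * w)
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    strength = rng.uniform(5.0, 8.0) if cancer else rng.uniform(1.5, 3.0)
    swirl_r = 0.62 * side
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - cy, cc - cx
    rad = np.hypot(dr, dc)
    # inverse swirl map: rotate source coordinates by an angle decaying with radius
    ang = strength * np.exp(-rad / (swirl_r / 2.5))
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    src_r = cy + cos_a * dr - sin_a * dc
    src_c = cx + sin_a * dr + cos_a * dc
    img = ndimage.map_coordinates(img, [src_r, src_c], order=1, mode="reflect")
    if cancer:
        img = img + 2500.0 * (0.62 if dense else 1.0) * np.exp(-(rad / (0.2 * side)) ** 2)
    half = side / 2
    mask = (np.abs(dr) <= half) & (np.abs(dc) <= half)
    return img, mask


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------

def _sample_labels(config: SyntheticConfig, rng: np.random.Generator
                   ) -> tuple[str, str, int, str]:
    findings = list(FINDINGS)
    probs = np.array([config.finding_mix.get(f, 0.0) for f in findings])
    finding = findings[int(rng.choice(len(findings), p=probs / probs.sum()))]
    density = "DB" if rng.random() < config.density_mix else "Not-DB"
    rate = config.cancer_rate_per_finding.get(finding, 0.0)
    cancer = int(finding != "normal" and rng.random() < rate)
    u, flag = rng.random(), "none"
    acc = 0.0
    for name in EXCLUSION_FLAGS[1:]:
        acc += config.exclusion_rates.get(name, 0.0)
        if u < acc:
            flag = name
            break
    return finding, density, cancer, flag


def generate_record(config: SyntheticConfig, index: int
                    ) -> tuple[np.ndarray, np.ndarray | None, ImageRecord]:
    """Generate the ``index``-th phantom crop of the configured population.

    Returns the 16-bit image, the binary lesion mask (``None`` for normal
    findings) and the metadata record. Fully deterministic in
    ``(config, index)``: the same pair always yields identical arrays.
    """
    patient, within = _index_to_patient(config, index)
    rng = _rng(config, 1, index)
    finding, density, cancer, flag = _sample_labels(config, rng)
    size = int(config.image_size)
    dense = density == "DB"

    img = _crop_background(rng, size, dense)
    mask = None
    if finding != "normal":
        lo, hi = config.lesion_area_range[finding]
        area_frac = rng.uniform(lo, hi)
        if cancer:
            # malignant lesions retract the surrounding fibrous tissue:
            # strands converge toward the lesion, so texture orientation
            # around the lesion carries the cancer signal
            radius = np.sqrt(area_frac * size * size / np.pi)
            strength = rng.uniform(6.0, 11.0)
            img = _tissue_convergence(img, (size / 2, size / 2), 1.6 * radius,
                                      strength)
        renderer = {
            "mass": _render_mass,
            "calcification": _render_calcification,
            "distortion": _render_distortion,
        }[finding]
        img, mask = renderer(rng, img, bool(cancer), area_frac, dense)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, GRAY_MAX).astype(np.uint16)

    record = ImageRecord(
        patient_id=f"P{patient:05d}",
        image_id=f"I{index:06d}",
        view="MLO",
        cancer=cancer,
        finding=finding,
        density=density,
        exclusion_flag=flag,
    )
    return img, (mask.astype(bool) if mask is not None else None), record


def generate_fullfield(config: SyntheticConfig, index: int,
                       shape: tuple[int, int] = (1024, 768)
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-field MLO-style phantom: breast half-ellipse against the left
    image edge with a pectoral-muscle wedge in the top-left corner.

    Returns ``(image, breast_mask, pectoral_mask)``; the pectoral wedge is
    part of the breast foreground (it is tissue, and brighter), so
    ``pectoral_mask ⊂ breast_mask``.
    """
    h, w = shape
    rng = _rng(config, 2, index)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h * rng.uniform(0.48, 0.55)
    ay = h * rng.uniform(0.38, 0.46)
    ax = w * rng.uniform(0.58, 0.72)
    breast = ((rr - cy) / ay) ** 2 + (cc / ax) ** 2 <= 1.0
    # pectoral wedge: triangle from the top-left corner
    wedge_rows = h * rng.uniform(0.30, 0.42)
    wedge_cols = w * rng.uniform(0.25, 0.38)
    pectoral = (cc < wedge_cols * (1.0 - rr / wedge_rows)) & (rr < wedge_rows) & breast

    dense = rng.random() < config.density_mix
    focus = (cy, ax)  # streaks converge toward the nipple side
    tissue = (
        (21000.0 if dense else 15000.0)
        + (4600.0 if dense else 2600.0) * _fibrous_texture(rng, (h, w), focus)
        + (3200.0 if dense else 1900.0) * _parenchyma(rng, (h, w))
    )
    img = np.full((h, w), 1200.0)
    img[breast] = tissue[breast]
    img[pectoral] += 9000.0
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, GRAY_MAX).astype(np.uint16)
    return img, breast, pectoral


# ---------------------------------------------------------------------------
# Dataset writing
# ---------------------------------------------------------------------------

def build_dataset(config: SyntheticConfig, out_dir: str | Path) -> Manifest:
    """Write the full phantom dataset (images, masks, manifest CSV).

    Layout: ``images/<image_id>.png`` (16-bit gray), ``masks/<image_id>.png``
    (8-bit, 0/255) for lesion findings, and ``manifest.csv`` with the
    standard column set. Returns the manifest with paths filled in.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    n = total_images(config)
    records = []
    for i in range(n):
        img, mask, rec = generate_record(config, i)
        img_path = out / "images" / f"{rec.image_id}.png"
        iio.imwrite(img_path, img)
        mask_path = ""
        if mask is not None:
            mpath = out / "masks" / f"{rec.image_id}.png"
            iio.imwrite(mpath, (mask.astype(np.uint8) * 255))
            mask_path = str(mpath)
        records.append(
            ImageRecord(
                patient_id=rec.patient_id,
                image_id=rec.image_id,
                view=rec.view,
                cancer=rec.cancer,
                finding=rec.finding,
                density=rec.density,
                image_path=str(img_path),
                mask_path=mask_path,
                exclusion_flag=rec.exclusion_flag,
            )
        )
    manifest = Manifest.from_records(
        records, provenance=f"synthetic phantoms, seed={config.seed}"
    )
    manifest.to_csv(out / "manifest.csv")
    return manifest
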