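"""Pyramid-of-HOG image measures: self-similarity, complexity, anisotropy.

The image is resized to ~100,000 pixels, luminance gradients are taken with
central differences, and gradient magnitudes are accumulated into 16
orientation bins covering the full 360-degree circle (signed orientations).
Histograms are computed for the whole image (level 0) and for a 4-way
recursive subdivision into 4, 16 and 64 rectangular sections (levels 1-3).

self-similarity
    mean histogram-intersection (HIK) between each section's sum-normalized
    histogram at levels 1-3 and the normalized level-0 histogram; in [0, 1],
    1 = parts distributed like the whole.
complexity
    total gradient magnitude at level 0 per gradient pixel (mean gradient
    magnitude) — linear in image contrast.
anisotropy
    mean over the 64 level-3 sections of the population variance of the 16
    normalized bin strengths; 0 = orientations uniformly represented.

The concrete low-level choices (central differences, hard bin assignment,
sum normalization, per-pixel complexity normalization) are fixed and
documented here; absolute values depend on them, so cross-dataset
comparisons should use one configuration throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import GreyImage, resize_bicubic
from .spectral import SpectralConfig, fit_image_slope

__all__ = [
    "PhogConfig",
    "PhogPyramid",
    "SIPRecord",
    "gradient_field",
    "build_pyramid",
    "self_similarity",
    "complexity",
    "anisotropy",
    "compute_sips",
]


@dataclass(frozen=True)
class PhogConfig:
    """16 orientation bins over 360 degrees, a 4-level pyramid (levels 0-3,
    i.e. 1/4/16/64 sections), computed at ~100,000 pixels."""

    n_orientation_bins: int = 16
    levels: int = 3
    target_pixels: int = 100_000
    orientation_range: float = 360.0

    def __post_init__(self) -> None:
        if self.n_orientation_bins < 2 or self.levels < 1:
            raise ValueError("need >= 2 orientation bins and >= 1 pyramid level")


@dataclass
class PhogPyramid:
    """Per-level grids of orientation histograms.

    ``levels[l]`` has shape (2**l, 2**l, n_bins): one histogram per section.
    ``n_pixels`` is the number of gradient pixels (the 1-pixel image border
    is excluded from the gradient field).
    """

    levels: list[np.ndarray]
    n_pixels: int
    config: PhogConfig

    @property
    def degenerate(self) -> bool:
        """True when the level-0 histogram is all zero (constant image)."""
        return not np.any(self.levels[0])


@dataclass
class SIPRecord:
    """The four per-image statistical image properties."""

    image_id: str
    fourier_slope: float
    self_similarity: float
    complexity: float
    anisotropy: float
    flags: tuple[str, ...] = ()


def gradient_field(img: GreyImage) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient magnitude and orientation.

    gx(r, c) = (I(r, c+1) - I(r, c-1)) / 2 and likewise gy along rows;
    magnitude is sqrt(gx^2 + gy^2) and orientation atan2(gy, gx) in degrees,
    in (-180, 180].  The 1-pixel border is excluded.  Note the operator's
    known blind spot: a period-2 checkerboard has zero central-difference
    response.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError(f"image too small for gradient analysis: {img.shape}")
    gx = (img[1:-1, 2:] - img[1:-1, :-2]) / 2.0
    gy = (img[2:, 1:-1] - img[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    ori = np.degrees(np.arctan2(gy, gx))
    return mag, ori


def build_pyramid(img: GreyImage, config: PhogConfig | None = None) -> PhogPyramid:
    """Accumulate gradient magnitudes into per-section orientation histograms.

    Hard assignment: each gradient pixel's full magnitude goes to the single
    bin containing its orientation.  Section borders are at multiples of
    floor(dim / 2**level); remainder rows/columns belong to the last section,
    so child sections always partition their parent exactly.
    """
    if config is None:
        config = PhogConfig()
    mag, ori = gradient_field(img)
    h, w = mag.shape
    nb = config.n_orientation_bins
    width = config.orientation_range / nb
    # map (-180, 180] -> [0, 360) -> bin index, with 180 wrapping onto -180
    bins = (np.floor((ori + 180.0) / width).astype(np.intp)) % nb

    levels = []
    for lev in range(config.levels + 1):
        ns = 2**lev
        row_sec = np.minimum(np.arange(h) // max(h // ns, 1), ns - 1)
        col_sec = np.minimum(np.arange(w) // max(w // ns, 1), ns - 1)
        sec = row_sec[:, None] * ns + col_sec[None, :]
        flat = (sec * nb + bins).ravel()
        hist = np.bincount(flat, weights=mag.ravel(), minlength=ns * ns * nb)
        levels.append(hist.reshape(ns, ns, nb))
    return PhogPyramid(levels, mag.size, config)


def _hik(a: np.ndarray, b: np.ndarray) -> float:
    """Histogram intersection kernel of two sum-normalized histograms."""
    return float(np.minimum(a, b).sum())


def self_similarity(pyr: PhogPyramid) -> float:
    """Mean HIK agreement of section histograms (levels 1-3) with level 0.

    All histograms are sum-normalized; an all-zero section contributes 0 and
    raises a warning; a constant image (all-zero level 0) returns 0 by
    convention.
    """
    h0 = pyr.levels[0].reshape(-1)
    total0 = h0.sum()
    if total0 == 0:
        warnings.warn("constant image: self-similarity degenerate, returning 0")
        return 0.0
    h0n = h0 / total0
    level_means = []
    for lev in range(1, len(pyr.levels)):
        hists = pyr.levels[lev].reshape(-1, pyr.config.n_orientation_bins)
        sums = hists.sum(axis=1)
        vals = np.zeros(len(hists))
        nz = sums > 0
        if not np.all(nz):
            warnings.warn(
                f"{np.count_nonzero(~nz)} all-zero section(s) at level {lev} "
                "contribute 0 to self-similarity"
            )
        vals[nz] = np.minimum(hists[nz] / sums[nz, None], h0n).sum(axis=1)
        level_means.append(vals.mean())
    return float(np.mean(level_means))


def complexity(pyr: PhogPyramid) -> float:
    """Total level-0 gradient strength per gradient pixel (mean gradient
    magnitude); 0 for a constant image, linear in contrast."""
    return float(pyr.levels[0].sum() / pyr.n_pixels)


def anisotropy(pyr: PhogPyramid) -> float:
    """Mean population variance of the normalized orientation-bin strengths
    over the deepest-level sections; 0 when orientations are uniformly
    represented (or when every section is empty)."""
    hists = pyr.levels[-1].reshape(-1, pyr.config.n_orientation_bins)
    sums = hists.sum(axis=1)
    nz = sums > 0
    if not np.any(nz):
        warnings.warn("constant image: anisotropy degenerate, returning 0")
        return 0.0
    normed = hists[nz] / sums[nz, None]
    return float(np.var(normed, axis=1).mean())


def compute_sips(
    img: GreyImage,
    image_id: str = "",
    spectral_config: SpectralConfig | None = None,
    phog_config: PhogConfig | None = None,
) -> SIPRecord:
    """All four statistical image properties of one source image.

    The spectral pipeline runs on a 512 x 512 resample and the PHOG pipeline
    on a ~100,000-pixel resample of the SAME source image.  A fully constant
    image raises a spectral error (no off-DC power); PHOG degeneracies are
    recorded in ``flags`` instead.
    """
    if phog_config is None:
        phog_config = PhogConfig()
    slope_fit = fit_image_slope(img, spectral_config)
    small = resize_bicubic(img, "area_100k", target=phog_config.target_pixels)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pyr = build_pyramid(small, phog_config)
        ss = self_similarity(pyr)
        comp = complexity(pyr)
        aniso = anisotropy(pyr)
    if pyr.degenerate:
        flags.append("phog_degenerate")
    elif caught:
        flags.append("phog_empty_sections")
    return SIPRecord(image_id, slope_fit.slope, ss, comp, aniso, tuple(flags))
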