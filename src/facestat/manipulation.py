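"""Phase-preserving modification of an image's power-spectrum slope.

To move an image from its measured slope m to a target slope t, every
off-DC Fourier coefficient at radial frequency f is multiplied by
f**((t - m) / 2) — half the exponent, because slopes live in the power
domain while coefficients are amplitudes.  A single global rescale then
restores the original total off-DC power, so the manipulation changes the
relative weight of high and low spatial frequencies only: phases and total
spectral power are untouched, and the DC coefficient (mean luminance) is
kept as is.

Returned images are floating point and may leave [0, 255]; clipping happens
only on export (``imaging.to_uint8``), which slightly perturbs the spectrum.
Tests that need exactness therefore run on the pre-clip image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import GreyImage
from .spectral import SpectralConfig, fit_image_slope

__all__ = ["SlopeTarget", "shift_slope", "make_variants", "slope_ladder"]

_SANITY_BOUNDS = (-6.0, 0.5)


class DegenerateSpectrumError(ValueError):
    """Raised when an image has no off-DC power to redistribute."""


@dataclass(frozen=True)
class SlopeTarget:
    """Absolute target slope (``mode="absolute"``) or slope change
    (``mode="delta"``, positive = shallower); ``preserve_power`` keeps the
    total off-DC power equal to the original's."""

    mode: str
    value: float
    preserve_power: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "delta"):
            raise ValueError(f"mode must be 'absolute' or 'delta', got {self.mode!r}")

    def resolve(self, measured: float) -> float:
        t = self.value if self.mode == "absolute" else measured + self.value
        lo, hi = _SANITY_BOUNDS
        if not lo <= t <= hi:
            raise ValueError(f"target slope {t:.3f} outside sanity bounds [{lo}, {hi}]")
        return t


def _measure(img: GreyImage, config: SpectralConfig | None) -> float:
    if config is None:
        config = SpectralConfig()
    return fit_image_slope(img, config).slope


def shift_slope(
    img: GreyImage,
    target: SlopeTarget,
    reference_slope: float | None = None,
    config: SpectralConfig | None = None,
) -> GreyImage:
    """Return a copy of ``img`` whose power-spectrum slope is moved to the
    target, with phases and (optionally) total off-DC power preserved.

    The current slope m is measured with the binned log-log estimator so the
    procedure is self-consistent with it; for pure power-law textures the
    nominal slope can be passed as ``reference_slope`` to skip measurement.
    The result is unclipped floating point.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"shift_slope needs a square image, got {img.shape}")
    m = _measure(img, config) if reference_slope is None else float(reference_slope)
    t = target.resolve(m)

    n = img.shape[0]
    f = np.fft.fft2(img)
    dc = f[0, 0]
    k = np.fft.fftfreq(n) * n
    r = np.hypot(k[:, None], k[None, :])
    r[0, 0] = 1.0  # placeholder; DC is restored below
    out_f = f * r ** ((t - m) / 2.0)

    if target.preserve_power:
        p_in = np.sum(np.abs(f) ** 2) - np.abs(dc) ** 2
        p_out = np.sum(np.abs(out_f) ** 2) - np.abs(out_f[0, 0]) ** 2
        if p_in <= 0 or p_out <= 0:
            raise DegenerateSpectrumError("image has no off-DC power")
        out_f *= np.sqrt(p_in / p_out)
    out_f[0, 0] = dc
    return np.fft.ifft2(out_f).real


def make_variants(
    img: GreyImage,
    delta_shallow: float = 0.25,
    delta_steep: float = -0.20,
    config: SpectralConfig | None = None,
) -> tuple[GreyImage, GreyImage]:
    """The shallow/steep pair used for pairwise attractiveness comparisons.

    ``delta_shallow`` must be positive (toward zero) and ``delta_steep``
    negative; the defaults reproduce the magnitude of the measured shifts in
    the original stimulus set (about +0.26 / -0.19 around a -2.85 original).
    Measured slopes always order steep < original < shallow.
    """
    if not (delta_shallow > 0 > delta_steep):
        raise ValueError(
            "delta_shallow must be > 0 and delta_steep < 0 "
            f"(got {delta_shallow}, {delta_steep})"
        )
    m = _measure(img, config)
    shallow = shift_slope(img, SlopeTarget("delta", delta_shallow), reference_slope=m,
                          config=config)
    steep = shift_slope(img, SlopeTarget("delta", delta_steep), reference_slope=m,
                        config=config)
    return shallow, steep


def slope_ladder(
    img: GreyImage,
    lo: float = -4.0,
    hi: float = -1.0,
    steps: int = 100,
    reference_slope: float | None = None,
    config: SpectralConfig | None = None,
) -> tuple[np.ndarray, list[GreyImage]]:
    """Sequence of absolute-slope variants, steep to shallow.

    Targets are linearly spaced from ``lo`` to ``hi``; every image is
    produced from the ORIGINAL (never chained), so clip artifacts do not
    compound.  Returns (targets, images) sorted steepest first.
    """
    if steps < 2:
        raise ValueError("need at least 2 ladder steps")
    m = _measure(img, config) if reference_slope is None else float(reference_slope)
    targets = np.linspace(lo, hi, steps)
    images = [
        shift_slope(img, SlopeTarget("absolute", float(t)), reference_slope=m,
                    config=config)
        for t in targets
    ]
    return targets, images
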