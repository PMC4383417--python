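"""Radially averaged Fourier power spectra and the log-log slope estimator.

The central statistic of the package: the slope of a least-squares line
fitted to log10(radially averaged power) versus log10(spatial frequency), on
data binned into 33 equal-width bins in log frequency over 10-255
cycles/image, measured on a 512 x 512 bicubic-resampled copy of the image.
Natural scenes sit near slope -2 in the power domain (-1 in the amplitude
domain); face photographs are steeper, around -2.8 to -3.

Frequencies are in cycles per image, never cycles per face width.  No window
or taper is applied before the FFT; boundary leakage is part of the measured
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import GreyImage, resize_bicubic

__all__ = [
    "SpectralConfig",
    "RadialSpectrum",
    "SlopeFit",
    "SpectralError",
    "power_spectrum",
    "radial_average",
    "estimate_slope",
    "fit_image_slope",
]


class SpectralError(ValueError):
    """Raised when a spectrum cannot be estimated (degenerate input)."""


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the slope fit.

    ``analysis_size``: side of the square analysis raster (pixels).
    ``fit_min``/``fit_max``: fitted frequency range, cycles/image.
    ``n_bins``: number of equal-width bins in log10 frequency.
    ``domain``: ``"power"`` fits log10 P(f); ``"amplitude"`` fits
    log10 sqrt(P(f)), which halves the slope exactly.
    ``bin_statistic``: ``"mean_log"`` averages log10-power within each bin
    (default); ``"log_mean"`` takes log10 of the mean power instead — both
    readings of "binned in the log-log plane" are available.
    """

    analysis_size: int = 512
    fit_min: float = 10.0
    fit_max: float = 255.0
    n_bins: int = 33
    domain: str = "power"
    bin_statistic: str = "mean_log"

    def __post_init__(self) -> None:
        if not 0 < self.fit_min < self.fit_max <= self.analysis_size / 2:
            raise ValueError(
                f"need 0 < fit_min < fit_max <= {self.analysis_size // 2}; "
                f"got [{self.fit_min}, {self.fit_max}]"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.domain not in ("power", "amplitude"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.bin_statistic not in ("mean_log", "log_mean"):
            raise ValueError(f"unknown bin_statistic {self.bin_statistic!r}")


@dataclass
class RadialSpectrum:
    """Mean power per integer radial frequency (DC excluded).

    ``frequency``: strictly increasing integer frequencies, cycles/image.
    ``mean_power``: arithmetic mean of |F|^2 over each annulus.
    ``count``: number of 2-D frequency samples in each annulus.
    """

    frequency: np.ndarray
    mean_power: np.ndarray
    count: np.ndarray


@dataclass
class SlopeFit:
    """A fitted log-log line: slope, intercept (log10 power at log10 f = 0),
    r-squared, and the binned points it was fitted to."""

    slope: float
    intercept: float
    r_squared: float
    config: SpectralConfig
    bin_centers: np.ndarray = field(repr=False)
    bin_means: np.ndarray = field(repr=False)

    @property
    def n_bins_used(self) -> int:
        return len(self.bin_centers)


def power_spectrum(img: GreyImage) -> np.ndarray:
    """|FFT|^2 of a square image, DC shifted to the grid center.

    The input must be square; resize first with
    ``imaging.resize_bicubic(img, "square_512")``.  The underlying transform
    of a real image is Hermitian, so the returned power grid is point
    symmetric about DC.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(
            f"power_spectrum needs a square image, got {img.shape}; "
            "resize first (imaging.resize_bicubic, mode='square_512')"
        )
    f = np.fft.fftshift(np.fft.fft2(img))
    return np.abs(f) ** 2


def radial_average(power: np.ndarray) -> RadialSpectrum:
    """Average a centered 2-D power grid over integer-frequency annuli.

    Each off-DC sample at centered coordinates (u, v) is assigned to the
    annulus f = round(sqrt(u^2 + v^2)); annulus means are arithmetic.  The
    annuli partition the grid: counts sum to N^2 - 1.
    """
    power = np.asarray(power, dtype=np.float64)
    n = power.shape[0]
    c = n // 2  # index of DC after fftshift (even n)
    ky = np.arange(n) - c
    r = np.rint(np.hypot(ky[:, None], ky[None, :])).astype(np.intp)
    flat_r = r.ravel()
    flat_p = power.ravel()
    sums = np.bincount(flat_r, weights=flat_p)
    counts = np.bincount(flat_r)
    # drop DC (f = 0) and any empty annuli
    freq = np.nonzero(counts)[0]
    freq = freq[freq > 0]
    return RadialSpectrum(
        frequency=freq,
        mean_power=sums[freq] / counts[freq],
        count=counts[freq],
    )


def estimate_slope(spec: RadialSpectrum, config: SpectralConfig | None = None) -> SlopeFit:
    """Least-squares line through log-log binned radial power.

    Bin edges are equally spaced in log10 f over [fit_min, fit_max]; within
    each bin the fitted point is (mean log10 f, mean log10 P) over the
    integer-frequency samples it contains (see ``bin_statistic``); empty bins
    are dropped; ordinary least squares gives slope and intercept.  In the
    amplitude domain the ordinate is halved before fitting, so the slope is
    exactly half the power-domain slope.
    """
    if config is None:
        config = SpectralConfig()
    in_range = (spec.frequency >= config.fit_min) & (spec.frequency <= config.fit_max)
    f = spec.frequency[in_range].astype(np.float64)
    p = spec.mean_power[in_range]
    if np.any(p <= 0):
        bad = f[np.asarray(p) <= 0]
        raise SpectralError(
            f"zero power inside the fit range at f = {bad[:5].astype(int).tolist()}"
            " (log undefined); the spectrum is degenerate there"
        )
    logf = np.log10(f)
    logp = np.log10(p)

    edges = np.linspace(np.log10(config.fit_min), np.log10(config.fit_max),
                        config.n_bins + 1)
    idx = np.searchsorted(edges, logf, side="right") - 1
    idx = np.clip(idx, 0, config.n_bins - 1)

    xs, ys = [], []
    for b in range(config.n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        xs.append(logf[sel].mean())
        if config.bin_statistic == "mean_log":
            ys.append(logp[sel].mean())
        else:
            ys.append(np.log10(p[sel].mean()))
    if len(xs) < 2:
        raise SpectralError("fewer than 2 non-empty bins; cannot fit a line")
    x = np.array(xs)
    y = np.array(ys)
    if config.domain == "amplitude":
        y = 0.5 * y  # exact halving: log10 sqrt(P) = 0.5 log10 P

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(float(slope), float(intercept), float(r2), config, x, y)


def fit_image_slope(img: GreyImage, config: SpectralConfig | None = None) -> SlopeFit:
    """Full pipeline: bicubic resize to the analysis raster, FFT, radial
    average, binned log-log fit."""
    if config is None:
        config = SpectralConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.shape != (config.analysis_size, config.analysis_size):
        img = resize_bicubic(img, "square_512", target=config.analysis_size)
    return estimate_slope(radial_average(power_spectrum(img)), config)
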