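"""Random-phase patterns with a prescribed power-spectrum slope, and the
mask / background stimulus assembly.

A pattern is built directly in the Fourier domain: the amplitude at radial
frequency f is set to f**(s/2) — s/2, not s, because s is the slope of the
POWER spectrum and power is amplitude squared (the classic off-by-two
pitfall) — phases are i.i.d. uniform with Hermitian symmetry enforced, and
the inverse FFT yields a real image which is then linearly rescaled to
[0, 255].  The rescale is affine and therefore leaves the measured slope
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import (
    CompositeSpec,
    GreyImage,
    OvalSpec,
    composite_overlay,
    embed_on_background,
)

__all__ = [
    "SynthesisSpec",
    "random_phase_pattern",
    "grey_mask",
    "make_masked_stimulus",
    "make_background_stimulus",
]

#: The five nominal mask/background power-spectrum slopes used in the
#: overlay and background studies, steepest to shallowest.
NOMINAL_SLOPES = (-4.0, -3.0, -2.0, -1.0, 0.0)

#: "Medium grey" control value (midpoint of the 0-255 display range).
MID_GREY = 128.0


@dataclass(frozen=True)
class SynthesisSpec:
    """Target power slope, raster size, seed, and rescale flag for one
    random-phase pattern.  ``size`` must be even (Hermitian pairing of
    Nyquist bins)."""

    nominal_slope: float = -2.0
    size: int = 1024
    seed: int | None = None
    rescale: bool = True

    def __post_init__(self) -> None:
        if self.size % 2 != 0 or self.size <= 0:
            raise ValueError(f"size must be a positive even number, got {self.size}")


def _hermitian_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    """Antisymmetric phase grid: theta(-k) = -theta(k) (mod 2*pi).

    Built as the difference of an i.i.d. uniform draw and its conjugate-index
    flip; the difference of independent uniform angles is again uniform, and
    self-conjugate bins (DC and the Nyquist axes' fixed points) come out 0.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
    idx = (-np.arange(n)) % n
    return phi - phi[np.ix_(idx, idx)]


def random_phase_pattern(
    slope: float = -2.0,
    size: int = 1024,
    seed: int | None = None,
    rescale: bool = True,
    phases: np.ndarray | None = None,
) -> GreyImage:
    """Synthesize a power-law texture: power ∝ f**slope, random phases.

    ``phases`` overrides the random phase grid (in FFT index order) — a test
    hook; an all-zero grid yields a real even spectrum and hence an image
    symmetric under 180-degree rotation.  With ``rescale`` (default) the
    image is mapped linearly onto [0, 255], which leaves the slope unchanged;
    otherwise the raw zero-mean inverse transform is returned.
    """
    spec = SynthesisSpec(slope, size, seed, rescale)  # validates size
    n = spec.size
    k = np.fft.fftfreq(n) * n  # integer frequencies in FFT order
    r = np.hypot(k[:, None], k[None, :])
    with np.errstate(divide="ignore"):
        amp = r ** (slope / 2.0)
    amp[0, 0] = 0.0  # DC: set by the final rescale, not the power law

    if phases is None:
        rng = np.random.default_rng(seed)
        theta = _hermitian_phases(n, rng)
    else:
        theta = np.asarray(phases, dtype=np.float64)
        if theta.shape != (n, n):
            raise ValueError(f"phases must have shape {(n, n)}, got {theta.shape}")
    f = amp * np.exp(1j * theta)
    img = np.fft.ifft2(f).real
    if rescale:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo) * 255.0
        else:
            img = np.full_like(img, MID_GREY)
    return img


def grey_mask(size: int, value: float = MID_GREY) -> GreyImage:
    """Homogeneous medium-grey control mask."""
    return np.full((size, size), float(value))


def make_masked_stimulus(
    face: GreyImage,
    condition: str | float,
    seed: int | None = None,
    opacity: float = 0.15,
    oval: OvalSpec | None = None,
) -> tuple[GreyImage, dict]:
    """One overlay-study stimulus: mask blended at 15% opacity, oval window.

    ``condition`` is either the string ``"grey"`` (mid-grey control) or a
    nominal power-spectrum slope for a freshly synthesized random-phase mask.
    Returns the stimulus and a manifest record (condition, nominal slope,
    opacity, seed).
    """
    face = np.asarray(face, dtype=np.float64)
    if face.ndim != 2 or face.shape[0] != face.shape[1]:
        raise ValueError(f"face must be square, got {face.shape}")
    n = face.shape[0]
    if isinstance(condition, str):
        if condition != "grey":
            raise ValueError(f"unknown condition {condition!r}")
        mask = grey_mask(n)
        nominal = None
    else:
        nominal = float(condition)
        mask = random_phase_pattern(nominal, size=n, seed=seed)
    if oval is None:
        oval = OvalSpec()
    out = composite_overlay(face, mask, CompositeSpec(opacity=opacity, window=oval))
    record = {
        "condition": "grey" if nominal is None else f"slope{nominal:g}",
        "mask_or_background_nominal_slope": nominal,
        "opacity": opacity,
        "seed": seed,
    }
    return out, record


def make_background_stimulus(
    face: GreyImage,
    slope: float,
    seed: int | None = None,
    canvas_size: int = 1536,
    layout: tuple[float, float] | None = None,
    oval: OvalSpec | None = None,
) -> tuple[GreyImage, dict]:
    """One background-study stimulus: a face oval on a random-phase canvas.

    The background fills the whole canvas at the requested nominal slope; the
    face's oval interior is pasted centered, covering the layout fractions
    (default: 1/3 of the canvas width, ~0.49 of its height).
    """
    background = random_phase_pattern(float(slope), size=canvas_size, seed=seed)
    spec = CompositeSpec() if layout is None else CompositeSpec(layout=layout)
    out = embed_on_background(face, background, spec, oval)
    record = {
        "condition": f"background{slope:g}",
        "mask_or_background_nominal_slope": float(slope),
        "opacity": None,
        "seed": seed,
    }
    return out, record
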