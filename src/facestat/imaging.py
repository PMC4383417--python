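"""Image I/O, grey conversion, resizing, windowing and compositing.

All routines operate on ``GreyImage``: a 2-D ``float64`` array of luminance
values in display units.  Values are nominally in [0, 255] but intermediates
(blends, slope-shifted images) may leave that range; clipping happens only on
export (:func:`to_uint8` / :func:`save_png`).

Coordinates are row-major with the origin at the top-left pixel, 0-based.
Colour is collapsed to luminance with the Rec. 601 weights
(0.299 R + 0.587 G + 0.114 B), one fixed convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "GreyImage",
    "OvalSpec",
    "CompositeSpec",
    "load_image",
    "save_png",
    "to_uint8",
    "resize_bicubic",
    "apply_oval_window",
    "oval_mask",
    "composite_overlay",
    "embed_on_background",
]

#: 2-D float64 luminance raster (display units, 0-255 on export).
GreyImage = np.ndarray

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Raised for unsupported image formats or bit depths."""


@dataclass(frozen=True)
class OvalSpec:
    """Hard elliptical window, in fractions of the image size.

    ``center`` is (row, col) as fractions of (height, width); ``semi_axes``
    is (vertical, horizontal) as fractions of (height, width).  Pixels whose
    centers fall outside the ellipse are set to ``outside_value`` (default
    black).  There is no feathering: the mask is binary.
    """

    center: tuple[float, float] = (0.5, 0.5)
    semi_axes: tuple[float, float] = (0.45, 0.35)
    outside_value: float = 0.0

    def __post_init__(self) -> None:
        for a in self.semi_axes:
            if not 0.0 < a <= 0.5:
                raise ValueError(f"semi-axis fraction {a} not in (0, 0.5]")


@dataclass(frozen=True)
class CompositeSpec:
    """How a mask pattern is blended onto a face and framed.

    ``opacity`` is the blend weight alpha of the mask:
    ``out = (1 - alpha) * face + alpha * mask``, computed before any
    windowing.  ``window`` (if given) is applied after blending.  ``layout``
    gives the (width, height) fractions of a background canvas that the face
    oval covers when the face is embedded on a larger background; the default
    reproduces a face spanning 5.7 deg x 8.4 deg of a 17.1 deg square display.
    """

    opacity: float = 0.15
    window: OvalSpec | None = None
    layout: tuple[float, float] = (5.7 / 17.1, 8.4 / 17.1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError(f"opacity {self.opacity} not in [0, 1]")


def load_image(path: str | Path) -> GreyImage:
    """Read a PNG/TIFF/JPEG image as a float64 luminance array in [0, 255].

    8-bit colour inputs are converted with the Rec. 601 luma weights; 16-bit
    greyscale inputs are rescaled so that full scale (65535) maps to 255.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGB")
            mode = im.mode
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"could not read image file {path}: {exc}") from exc

    if mode in ("RGB", "RGBA"):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ _LUMA_WEIGHTS
    if mode == "L":
        return arr.astype(np.float64)
    if mode in ("I;16", "I;16B", "I;16L", "I"):
        arr = arr.astype(np.float64)
        if mode == "I" and arr.max() > 65535:
            raise ImageFormatError(f"{path}: 32-bit integer images are not supported")
        return arr / 65535.0 * 255.0
    raise ImageFormatError(f"{path}: unsupported image mode {mode!r}")


def to_uint8(img: GreyImage) -> np.ndarray:
    """Clip to [0, 255] and round to 8-bit — the only place clipping happens."""
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def save_png(img: GreyImage, path: str | Path) -> None:
    """Export as 8-bit greyscale PNG (the canonical output format)."""
    Image.fromarray(to_uint8(img), mode="L").save(Path(path), format="PNG")


def resize_bicubic(
    img: GreyImage, mode: str = "square_512", target: int | None = None
) -> GreyImage:
    """Bicubic resize in one of the two geometries the analyses use.

    ``square_512``
        Resize to ``target`` x ``target`` pixels (default 512), the geometry
        of the spectral analysis.
    ``area_100k``
        Isotropic rescale to ~``target`` pixels total (default 100,000),
        preserving the aspect ratio to within one pixel — the geometry of the
        PHOG analysis.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D luminance array")
    h, w = img.shape
    if mode == "square_512":
        n = 512 if target is None else int(target)
        shape = (n, n)
    elif mode == "area_100k":
        area = 100_000 if target is None else int(target)
        s = np.sqrt(area / (h * w))
        # Round the larger dimension first, then pick the other to land as
        # close to the target pixel count as possible (still within 1 px of
        # the exact isotropic size, so the aspect ratio is preserved).
        if h >= w:
            nh = max(1, round(h * s))
            nw = max(1, round(area / nh))
        else:
            nw = max(1, round(w * s))
            nh = max(1, round(area / nw))
        shape = (nh, nw)
    else:
        raise ValueError(f"unknown resize mode {mode!r}")
    if shape == img.shape:
        return img.copy()
    return _sk_resize(img, shape, order=3, preserve_range=True, anti_aliasing=None)


def oval_mask(shape: tuple[int, int], oval: OvalSpec) -> np.ndarray:
    """Boolean mask, True inside the ellipse (pixel-center geometry)."""
    h, w = shape
    # pixel centers in fractional coordinates
    y = (np.arange(h) + 0.5) / h
    x = (np.arange(w) + 0.5) / w
    cy, cx = oval.center
    ay, ax = oval.semi_axes
    yy = ((y - cy) / ay) ** 2
    xx = ((x - cx) / ax) ** 2
    return yy[:, None] + xx[None, :] <= 1.0


def apply_oval_window(img: GreyImage, oval: OvalSpec | None = None) -> GreyImage:
    """Set pixels outside the ellipse to ``outside_value``; idempotent."""
    if oval is None:
        oval = OvalSpec()
    img = np.asarray(img, dtype=np.float64)
    out = np.full_like(img, oval.outside_value)
    inside = oval_mask(img.shape, oval)
    out[inside] = img[inside]
    return out


def composite_overlay(
    face: GreyImage, mask: GreyImage, spec: CompositeSpec | None = None
) -> GreyImage:
    """Alpha-blend a mask pattern onto a face, then apply the oval window.

    ``out = (1 - alpha) * face + alpha * mask``; with the default 15% opacity
    the face keeps 85% weight.  Blending comes first and the (optional) black
    oval second, so the surround stays strictly black.
    """
    if spec is None:
        spec = CompositeSpec()
    face = np.asarray(face, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if face.shape != mask.shape:
        raise ValueError(f"face {face.shape} and mask {mask.shape} shapes differ")
    out = (1.0 - spec.opacity) * face + spec.opacity * mask
    if spec.window is not None:
        out = apply_oval_window(out, spec.window)
    return out


def embed_on_background(
    face: GreyImage,
    background: GreyImage,
    spec: CompositeSpec | None = None,
    oval: OvalSpec | None = None,
) -> GreyImage:
    """Paste the oval interior of a face onto a larger background canvas.

    The face is rescaled so that its elliptical window covers
    ``spec.layout`` = (width, height) fractions of the canvas (default:
    1/3 of the width and ~0.491 of the height), centered.  Only interior
    pixels are pasted, so the background — not a black surround — is visible
    around the oval.
    """
    if spec is None:
        spec = CompositeSpec()
    if oval is None:
        oval = OvalSpec()
    face = np.asarray(face, dtype=np.float64)
    canvas = np.asarray(background, dtype=np.float64).copy()
    ch, cw = canvas.shape
    wfrac, hfrac = spec.layout
    # The oval spans 2*semi_axis of the face image in each direction.
    fh = round(ch * hfrac / (2 * oval.semi_axes[0]))
    fw = round(cw * wfrac / (2 * oval.semi_axes[1]))
    if fh > ch or fw > cw:
        raise ValueError("scaled face oval does not fit on the background canvas")
    if (fh, fw) != face.shape:
        face = _sk_resize(face, (fh, fw), order=3, preserve_range=True,
                          anti_aliasing=None)
    inside = oval_mask((fh, fw), oval)
    r0 = (ch - fh) // 2
    c0 = (cw - fw) // 2
    region = canvas[r0:r0 + fh, c0:c0 + fw]
    region[inside] = face[inside]
    return canvas
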