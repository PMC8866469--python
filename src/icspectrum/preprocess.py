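"""Preprocessing of en-face OCTA slabs into binary vessel maps.

The analysis chain mirrors the standard OCTA workflow for capillary
quantification: intensity normalization, optional frame averaging,
Gaussian denoising, Phansalkar adaptive local thresholding (white =
flow signal / vessel) and restriction to a central circular region of
interest (2 mm diameter by default, within a nominal 3 x 3 mm field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "EnFaceImage",
    "CircularROI",
    "ThresholdParams",
    "BinaryVesselMap",
    "normalize_intensity",
    "average_frames",
    "gaussian_blur",
    "phansalkar_threshold",
    "make_circular_roi",
    "transient_loss_map",
    "register_shift",
]


@dataclass(frozen=True)
class EnFaceImage:
    """A normalized 2D en-face angiography frame.

    Attributes
    ----------
    data:
        ``(H, W)`` float array with intensities in ``[0, 1]``.
    pitch_mm:
        Physical size of one pixel in millimetres (field width divided by
        raster size, e.g. 3 mm / 1024 px).
    provenance:
        ``"single"`` for a raw frame, ``"averaged"`` for a multi-frame mean.
    """

    data: np.ndarray
    pitch_mm: float
    provenance: str = "single"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.size == 0:
            raise ValueError("EnFaceImage requires a non-empty 2D grid")
        if self.pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if data.min() < -1e-9 or data.max() > 1 + 1e-9:
            raise ValueError("EnFaceImage intensities must lie in [0, 1]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def fov_mm(self) -> float:
        return self.data.shape[1] * self.pitch_mm


@dataclass(frozen=True)
class CircularROI:
    """Circular analysis region, in pixel coordinates.

    ``center`` is (row, col) of the circle center; membership uses the
    center-of-pixel rule ``(r - cy)**2 + (c - cx)**2 <= radius_px**2``.
    """

    center: tuple
    radius_px: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0 or self.diameter_mm <= 0:
            raise ValueError("ROI radius and diameter must be positive")

    @property
    def pitch_mm(self) -> float:
        return self.diameter_mm / (2.0 * self.radius_px)

    def mask(self, shape: tuple) -> np.ndarray:
        cy, cx = self.center
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - cy) ** 2 + (cc - cx) ** 2 <= self.radius_px**2

    def area_mm2(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class ThresholdParams:
    """Constants of the Phansalkar local threshold.

    The decision surface is ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))``
    with ``m``/``s`` the local mean and standard deviation over a circular
    window.  Defaults follow the common reference implementation of the
    method for images normalized to ``[0, 1]``.
    """

    window_radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass(frozen=True)
class BinaryVesselMap:
    """Boolean vessel map (True = flow signal) with an optional ROI."""

    vessel: np.ndarray
    pitch_mm: float
    roi: Optional[CircularROI] = None

    def __post_init__(self) -> None:
        vessel = np.asarray(self.vessel, dtype=bool)
        if vessel.ndim != 2:
            raise ValueError("vessel map must be 2D")
        object.__setattr__(self, "vessel", vessel)

    @property
    def shape(self) -> tuple:
        return self.vessel.shape

    def with_roi(self, roi: CircularROI) -> "BinaryVesselMap":
        return replace(self, roi=roi)


def normalize_intensity(
    image: np.ndarray, pitch_mm: float, provenance: str = "single"
) -> EnFaceImage:
    """Min-max rescale a raw grid of any depth to ``[0, 1]``.

    A constant image maps to all zeros (documented convention for
    degenerate input).
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    lo = float(arr.min())
    hi = float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return EnFaceImage(arr, pitch_mm, provenance)


def average_frames(stack) -> EnFaceImage:
    """Pixel-wise arithmetic mean of co-registered repeat frames.

    Averaging restores vessels with transient flow-signal loss that are
    blanked in individual frames; the result carries provenance
    ``"averaged"``.  ``stack`` may be a FrameStack, a sequence of
    :class:`EnFaceImage`, or an ``(n, H, W)`` array plus implicit pitch
    from the first EnFaceImage.
    """
    frames, pitch = _coerce_frames(stack)
    if len(frames) < 2:
        raise ValueError("averaging requires at least 2 frames")
    shape = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape:
            raise ValueError("frame shape mismatch")
    mean = np.mean(np.stack(frames, axis=0), axis=0)
    return EnFaceImage(np.clip(mean, 0.0, 1.0), pitch, provenance="averaged")


def _coerce_frames(stack):
    # FrameStack duck-typing avoids a circular import with synthetic.
    if hasattr(stack, "frames") and hasattr(stack, "pitch_mm"):
        return [np.asarray(f, float) for f in stack.frames], stack.pitch_mm
    if isinstance(stack, np.ndarray):
        raise TypeError("pass EnFaceImage sequence or FrameStack (pitch needed)")
    frames = list(stack)
    if frames and isinstance(frames[0], EnFaceImage):
        return [f.data for f in frames], frames[0].pitch_mm
    raise TypeError("unsupported frame container")


def gaussian_blur(image: EnFaceImage, radius_px: float = 2.0) -> EnFaceImage:
    """Gaussian denoising with sigma = radius (ImageJ-style convention).

    The kernel is the sampled, normalized Gaussian truncated at 3 sigma,
    applied with reflective boundary handling, so constant images pass
    through unchanged (unit DC gain).  ``radius_px = 0`` is the identity.
    """
    if radius_px < 0:
        raise ValueError("blur radius must be >= 0")
    if radius_px == 0:
        return image
    out = ndi.gaussian_filter(image.data, sigma=radius_px, mode="reflect", truncate=3.0)
    return EnFaceImage(np.clip(out, 0.0, 1.0), image.pitch_mm, image.provenance)


def _disk_footprint(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (x * x + y * y) <= radius * radius


def _disk_window_sum(data: np.ndarray, radius: int) -> np.ndarray:
    """Sum of ``data`` over a circular window clipped at the image border.

    The disk decomposes into horizontal runs, one per row offset, so the
    2D sum is a stack of shifted 1D box sums -- exact and O(R) passes.
    """
    h = data.shape[0]
    out = np.zeros_like(data)
    for dy in range(-radius, radius + 1):
        half = int(math.floor(math.sqrt(radius * radius - dy * dy)))
        width = 2 * half + 1
        row = ndi.uniform_filter1d(
            data, size=width, axis=1, mode="constant", cval=0.0
        ) * width
        if dy >= 0:
            out[: h - dy] += row[dy:]
        else:
            out[-dy:] += row[: h + dy]
    return out


def phansalkar_surface(image: EnFaceImage, params: ThresholdParams) -> np.ndarray:
    """Per-pixel Phansalkar threshold surface t(m, s).

    Local statistics use the circular window clipped at image borders
    (mean and population standard deviation over the in-image part).
    """
    data = image.data
    R = params.window_radius_px
    if 2 * R + 1 > min(data.shape):
        raise ValueError("threshold window larger than image")
    cnt = _disk_window_sum(np.ones_like(data), R)
    s1 = _disk_window_sum(data, R)
    s2 = _disk_window_sum(data * data, R)
    # Round-off could leave tiny negative moments in exactly-zero areas,
    # which would flip the strict ">" comparison there; clamp to the valid
    # range of [0,1]-image statistics.
    m = np.clip(s1 / cnt, 0.0, 1.0)
    var = np.maximum(s2 / cnt - m * m, 0.0)
    s = np.sqrt(var)
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0))


def phansalkar_threshold(
    image: EnFaceImage, params: ThresholdParams = ThresholdParams()
) -> BinaryVesselMap:
    """Binarize an en-face image; a pixel is vessel iff intensity > t.

    ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))`` with m, s computed over a
    circular window of ``window_radius_px`` clipped at the image border.
    """
    t = phansalkar_surface(image, params)
    return BinaryVesselMap(image.data > t, image.pitch_mm)


def make_circular_roi(image: EnFaceImage, diameter_mm: float = 2.0) -> CircularROI:
    """Central circular ROI of the given physical diameter.

    The circle is centered at the grid center; ``radius_px =
    diameter_mm / (2 * pitch)``.
    """
    h, w = image.shape
    if h != w:
        raise ValueError("ROI selection expects a square image")
    fov = w * image.pitch_mm
    if diameter_mm > fov + 1e-9:
        raise ValueError(
            f"ROI diameter {diameter_mm} mm exceeds the {fov:.3f} mm field"
        )
    radius_px = diameter_mm / (2.0 * image.pitch_mm)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    return CircularROI(center=center, radius_px=radius_px, diameter_mm=diameter_mm)


def transient_loss_map(
    single: BinaryVesselMap, averaged: BinaryVesselMap
) -> np.ndarray:
    """Pixels where the averaged map shows vessel but the raw frame does not.

    These mark capillaries with transient flow-signal loss: perfused
    across repeat frames yet blanked in the single acquisition.
    """
    if single.shape != averaged.shape:
        raise ValueError("shape mismatch between single and averaged maps")
    if (single.roi is None) != (averaged.roi is None) or (
        single.roi is not None and single.roi != averaged.roi
    ):
        raise ValueError("ROI mismatch between single and averaged maps")
    out = averaged.vessel & ~single.vessel
    if single.roi is not None:
        out &= single.roi.mask(single.shape)
    return out


def register_shift(reference: EnFaceImage, moving: EnFaceImage) -> tuple:
    """Integer (dy, dx) shift aligning ``moving`` onto ``reference``.

    Maximal cross-correlation; intended for optional rigid pre-alignment
    of repeat frames (off by default in the pipeline: frames from the
    device are assumed co-registered).
    """
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        reference.data, moving.data, upsample_factor=1
    )
    return int(shift[0]), int(shift[1])
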