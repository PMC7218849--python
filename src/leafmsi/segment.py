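"""NDVI segmentation, leaf orientation, rotation and petiole removal.

The leaf is separated from the bright diffuse chamber background by
thresholding the per-pixel NDVI, ``(NIR − red) / (NIR + red)``: plant tissue
absorbs red and transmits NIR so its NDVI is high, while the white diffuser
background stays below the threshold (default 0.2).  The leaf is then
rotated so its fitted major axis is horizontal, and the petiole — imaged
along the major axis — is cut off at the first column right of the widest
column whose leaf width drops below ``t_petiole`` pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology, transform

from .stack import CalibratedStack, FormatError

log = logging.getLogger(__name__)


class NoLeafError(RuntimeError):
    """Raised when segmentation finds no leaf-like region."""


@dataclass
class NdviMap:
    """Per-pixel NDVI with a validity mask for zero-denominator pixels."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise FormatError("NDVI values and validity mask shapes differ")


@dataclass
class SegmentationParams:
    """Thresholds of the segmentation stage.

    ``t`` is the NDVI threshold separating leaf from background; ``t_petiole``
    the leaf-width threshold (pixels) locating the petiole cutting line;
    ``min_component_px`` the smallest hole filled during mask cleanup.
    """

    t: float = 0.2
    t_petiole: int = 50
    min_component_px: int = 64

    def __post_init__(self) -> None:
        if not -1.0 < self.t < 1.0:
            raise ValueError(f"NDVI threshold must be in (-1, 1), got {self.t}")
        if self.t_petiole < 1:
            raise ValueError(f"t_petiole must be >= 1, got {self.t_petiole}")


@dataclass
class SegmentedLeaf:
    """A segmented (and possibly rotated / petiole-free) leaf.

    ``stack`` is the calibrated stack with non-leaf pixels zeroed; ``mask``
    the binary leaf mask; ``theta_deg`` the cumulative rotation applied
    (degrees, counter-clockwise positive); ``cut_col`` the petiole cutting
    column, or None if no cut was made.
    """

    stack: CalibratedStack
    mask: np.ndarray
    theta_deg: float = 0.0
    cut_col: int | None = None
    degenerate_orientation: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.stack.shape:
            raise FormatError("mask shape does not match stack shape")


def compute_ndvi(stack: CalibratedStack, *, denom_eps: float = 1e-9) -> NdviMap:
    """Per-pixel NDVI from the calibrated NIR and red bands.

    Pixels with |NIR + red| below ``denom_eps``, or flagged invalid by
    calibration, get value 0 and valid=False.  Valid values are clipped to
    [−1, 1] (slightly negative calibrated intensities can otherwise push the
    ratio out of range).
    """
    nir = stack.band("nir").astype(float)
    red = stack.band("red").astype(float)
    denom = nir + red
    valid = (np.abs(denom) >= denom_eps) & stack.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / denom
    ndvi[~valid] = 0.0
    ndvi[valid] = np.clip(ndvi[valid], -1.0, 1.0)
    return NdviMap(ndvi, valid)


def threshold_segment(
    stack: CalibratedStack, ndvi: NdviMap, params: SegmentationParams | None = None
) -> SegmentedLeaf:
    """Threshold the NDVI map and keep the largest 8-connected component.

    The mask is ``ndvi >= t`` on valid pixels (the boundary value t itself is
    included).  Small holes (< ``min_component_px``) are filled.  The
    returned stack has non-mask pixels set to 0 in every band.
    """
    params = params or SegmentationParams()
    if ndvi.values.shape != stack.shape:
        raise FormatError("NDVI map shape does not match stack shape")

    raw_mask = (ndvi.values >= params.t) & ndvi.valid
    if not raw_mask.any():
        raise NoLeafError("no leaf detected: no pixel reaches the NDVI threshold")

    labels = measure.label(raw_mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    if params.min_component_px > 0:
        # fill holes strictly smaller than min_component_px
        mask = morphology.remove_small_holes(mask, max_size=params.min_component_px - 1)

    masked = stack.copy()
    masked.data[:, ~mask] = 0.0
    return SegmentedLeaf(masked, mask)


def fit_orientation(mask: np.ndarray, *, degenerate_tol: float = 1e-3) -> tuple[float, bool]:
    """Major-axis angle of the mask from second-order central moments.

    Returns ``(theta_deg, degenerate)`` with theta in (−90, 90], measured
    counter-clockwise from the image x-axis (y up).  Near-circular masks,
    whose principal direction is numerically meaningless, return 0 with the
    degenerate flag set.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size < 5:
        raise ValueError(f"mask has only {xs.size} pixels; need >= 5 to fit an orientation")
    x = xs - xs.mean()
    y = -(ys - ys.mean())  # image rows increase downward; flip to y-up
    mxx = float(np.mean(x * x))
    myy = float(np.mean(y * y))
    mxy = float(np.mean(x * y))
    anisotropy = math.hypot(mxx - myy, 2 * mxy)
    if anisotropy < degenerate_tol * (mxx + myy):
        return 0.0, True
    theta = 0.5 * math.degrees(math.atan2(2 * mxy, mxx - myy))
    if theta <= -90.0:
        theta += 180.0
    return theta, False


def rotate_to_horizontal(seg: SegmentedLeaf, theta_deg: float | None = None) -> SegmentedLeaf:
    """Rotate the leaf so its major axis is horizontal.

    Intensity bands are resampled bilinearly, the mask with nearest
    neighbour; the canvas is expanded so no leaf pixel is lost.  If
    ``theta_deg`` is omitted it is fitted from the mask.
    """
    if theta_deg is None:
        theta_deg, degenerate = fit_orientation(seg.mask)
    else:
        degenerate = False
    # skimage rotates counter-clockwise in (x right, y up) terms for
    # positive angles; rotating by -theta brings the axis to horizontal.
    angle = -theta_deg
    bands = [
        transform.rotate(b, angle, resize=True, order=1, preserve_range=True)
        for b in seg.stack.data
    ]
    mask = transform.rotate(
        seg.mask.astype(float), angle, resize=True, order=0, preserve_range=True
    ) > 0.5
    valid = transform.rotate(
        seg.stack.valid.astype(float), angle, resize=True, order=0, preserve_range=True
    ) > 0.5
    data = np.stack(bands)
    data[:, ~mask] = 0.0
    stack = CalibratedStack(data, list(seg.stack.manifest), valid)
    return SegmentedLeaf(stack, mask, seg.theta_deg + theta_deg, seg.cut_col, degenerate)


def width_profile(mask: np.ndarray) -> np.ndarray:
    """Leaf width (pixel count) per image column."""
    return np.asarray(mask, dtype=bool).sum(axis=0)


def remove_petiole(seg: SegmentedLeaf, params: SegmentationParams | None = None) -> SegmentedLeaf:
    """Cut the petiole off a horizontally oriented leaf.

    Scanning rightward from the column of maximum leaf width, the first
    column whose width drops below ``t_petiole`` becomes the cutting line;
    that column and everything right of it is zeroed in mask and stack.  If
    no in-leaf column qualifies the leaf is returned unchanged (cut_col
    None).  A tapering blade tip can be clipped by this rule; the cut column
    is recorded so callers can flag it.
    """
    params = params or SegmentationParams()
    widths = width_profile(seg.mask)
    occupied = np.nonzero(widths > 0)[0]
    if occupied.size == 0:
        raise NoLeafError("cannot remove petiole from an empty mask")
    rightmost = occupied[-1]
    c_max = int(np.argmax(widths))

    cut_col: int | None = None
    for c in range(c_max + 1, rightmost + 1):
        if widths[c] < params.t_petiole:
            cut_col = c
            break
    if cut_col is None:
        return SegmentedLeaf(
            seg.stack, seg.mask, seg.theta_deg, None, seg.degenerate_orientation
        )

    mask = seg.mask.copy()
    mask[:, cut_col:] = False
    stack = seg.stack.copy()
    stack.data[:, ~mask] = 0.0
    log.debug("remove_petiole: cutting at column %d (max width col %d)", cut_col, c_max)
    return SegmentedLeaf(stack, mask, seg.theta_deg, cut_col, seg.degenerate_orientation)
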