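"""Spectral (flat-field) and spatial (undistortion, metric scale) calibration.

Spectral calibration normalises raw counts by white and dark reference
frames, ``I_cal = (I_raw − I_dark) / (I_white − I_dark)``, which cancels any
illumination field shared by the raw and white captures and removes the
sensor dark level.  Spatial calibration removes lens distortion with the
standard Brown–Conrady radial/tangential model and converts pixel geometry
to millimetres with a fixed chamber scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack import CalibratedStack, FormatError, MultispectralStack

log = logging.getLogger(__name__)

#: calibrated values are clipped to this range; transmittance can slightly
#: exceed 1 near reference noise, but unbounded values break NDVI.
CLIP_RANGE = (-0.05, 1.5)

#: |white − dark| below this is an unusable flat-field denominator
DENOM_EPS = 1e-9


class ValidationError(ValueError):
    """Raised when a calibration bundle violates its invariants."""


@dataclass
class CalibrationBundle:
    """White/dark reference stacks plus spatial calibration parameters.

    ``distortion_coeffs`` follow the (k1, k2, p1, p2, k3) convention.
    ``mm_per_px`` is the metric scale at the imaging platform; it is derived
    once from the platform distance and intrinsics and stored, never
    re-derived per image.
    """

    white_ref: MultispectralStack
    dark_ref: MultispectralStack
    intrinsic_matrix: np.ndarray
    distortion_coeffs: np.ndarray
    mm_per_px: float
    platform_distance_mm: float = 0.0

    def __post_init__(self) -> None:
        self.intrinsic_matrix = np.asarray(self.intrinsic_matrix, dtype=float)
        self.distortion_coeffs = np.asarray(self.distortion_coeffs, dtype=float)
        if self.intrinsic_matrix.shape != (3, 3):
            raise ValidationError("intrinsic matrix must be 3x3")
        if not np.all(np.isfinite(self.distortion_coeffs)):
            raise ValidationError("distortion coefficients must be finite")
        if self.mm_per_px <= 0:
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if not self.white_ref.same_geometry(self.dark_ref):
            raise ValidationError("white and dark reference stacks disagree in geometry")
        self._validate_references()

    def _validate_references(self) -> None:
        # flat-field denominator must be positive almost everywhere per band
        for i, band in enumerate(self.white_ref.manifest):
            w = self.white_ref.data[i].astype(float)
            d = self.dark_ref.data[i].astype(float)
            frac = float(np.mean(w > d))
            if frac < 0.99:
                raise ValidationError(
                    f"white reference not above dark reference on {frac:.1%} of "
                    f"pixels in band {band.wavelength_nm:g} nm (need >= 99%)"
                )


def derive_mm_per_px(intrinsic_matrix: np.ndarray, platform_distance_mm: float) -> float:
    """Pinhole scale at the platform plane: distance / focal length (px)."""
    fx = float(np.asarray(intrinsic_matrix)[0, 0])
    if fx <= 0 or platform_distance_mm <= 0:
        raise ValidationError("focal length and platform distance must be positive")
    return platform_distance_mm / fx


def spectral_calibrate(
    raw: MultispectralStack,
    bundle: CalibrationBundle,
    *,
    invalid_warn_fraction: float = 0.01,
) -> CalibratedStack:
    """Flat-field calibrate a raw stack against the bundle's references.

    Per pixel and band, ``(raw − dark) / (white − dark)``.  Pixels whose
    denominator is degenerate in any band are flagged invalid (value 0), not
    infinite.  Output is clipped to :data:`CLIP_RANGE`; the clip count is
    logged.

    Raises
    ------
    FormatError
        If raw and reference stacks disagree in shape or manifest.
    """
    if not raw.same_geometry(bundle.white_ref):
        raise FormatError("raw stack geometry/manifest does not match calibration references")

    white = bundle.white_ref.data.astype(float)
    dark = bundle.dark_ref.data.astype(float)
    denom = white - dark
    bad = np.abs(denom) < DENOM_EPS          # per band
    valid = ~np.any(bad, axis=0)             # per pixel, all bands usable

    with np.errstate(divide="ignore", invalid="ignore"):
        cal = (raw.data.astype(float) - dark) / denom
    cal[np.broadcast_to(~valid, cal.shape)] = 0.0

    n_clip = int(np.sum((cal < CLIP_RANGE[0]) | (cal > CLIP_RANGE[1])))
    if n_clip:
        log.info("spectral_calibrate: clipped %d values to %s", n_clip, CLIP_RANGE)
    cal = np.clip(cal, *CLIP_RANGE)

    frac_invalid = 1.0 - float(np.mean(valid))
    if frac_invalid > invalid_warn_fraction:
        log.warning(
            "spectral_calibrate: %.2f%% of pixels have unusable flat-field denominators",
            100 * frac_invalid,
        )
    return CalibratedStack(cal, list(raw.manifest), valid)


# ---------------------------------------------------------------------------
# lens distortion


def _distort_normalized(x: np.ndarray, y: np.ndarray, coeffs: np.ndarray):
    """Forward Brown–Conrady model on normalized camera coordinates."""
    k1, k2, p1, p2, k3 = (list(coeffs) + [0.0] * 5)[:5]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return xd, yd


def _pixel_grid_normalized(shape, K):
    fy, fx = float(K[1, 1]), float(K[0, 0])
    cy, cx = float(K[1, 2]), float(K[0, 2])
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (cols - cx) / fx, (rows - cy) / fy


def undistort(image: np.ndarray, bundle: CalibrationBundle, *, interpolation: str = "bilinear") -> np.ndarray:
    """Remove lens distortion by inverse remapping.

    For every output (ideal) pixel the forward distortion model gives the
    source location in the distorted input, which is then sampled.  With all
    coefficients zero the mapping is the identity.

    ``interpolation`` is 'bilinear' for intensity images or 'nearest' for
    masks (masks must stay binary).
    """
    image = np.asarray(image)
    K = bundle.intrinsic_matrix
    x, y = _pixel_grid_normalized(image.shape, K)
    xd, yd = _distort_normalized(x, y, bundle.distortion_coeffs)
    src_cols = xd * K[0, 0] + K[0, 2]
    src_rows = yd * K[1, 1] + K[1, 2]
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(
        image.astype(float), [src_rows, src_cols], order=order, mode="constant", cval=0.0
    )
    if image.dtype == bool:
        return out > 0.5
    return out


def distort_image(image: np.ndarray, bundle: CalibrationBundle, *, iterations: int = 8) -> np.ndarray:
    """Synthesize a lens-distorted view of an ideal image (inverse of
    :func:`undistort`); the inverse distortion is found by fixed-point
    iteration.  Intended for simulation and round-trip testing."""
    image = np.asarray(image, dtype=float)
    K = bundle.intrinsic_matrix
    xd, yd = _pixel_grid_normalized(image.shape, K)
    # invert: find (x, y) with distort(x, y) = (xd, yd)
    x, y = xd.copy(), yd.copy()
    for _ in range(iterations):
        xt, yt = _distort_normalized(x, y, bundle.distortion_coeffs)
        x += xd - xt
        y += yd - yt
    src_cols = x * K[0, 0] + K[0, 2]
    src_rows = y * K[1, 1] + K[1, 2]
    return ndimage.map_coordinates(image, [src_rows, src_cols], order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# metric scaling


def px_to_mm(length_px: float, bundle: CalibrationBundle) -> float:
    """Linear pixel length to millimetres."""
    return float(length_px) * bundle.mm_per_px


def area_px_to_mm2(count_px: float, bundle: CalibrationBundle) -> float:
    """Pixel area (count) to square millimetres."""
    return float(count_px) * bundle.mm_per_px**2
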