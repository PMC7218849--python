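"""Contour-scaling ring sectioning of a leaf and per-section NDVI means.

The leaf outline is shrunk toward a scaling center — the point at a fixed
fraction (default 2/3) of the major axis from the leaf tip, where the
midrib is taken as the major-axis chord — producing nested contour rings.
The region between successive rings is one section; with the default scale
factors (0.9 … 0.3) a convex leaf is partitioned into eight sections,
ordered outermost (edge) to innermost (center).  Mean NDVI per section
profiles the edge-to-center colour gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

from .features import leaf_contour

DEFAULT_SCALE_FACTORS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3)


@dataclass
class SectioningParams:
    """Ring-sectioning parameters.

    ``scale_factors`` must be strictly descending in (0, 1);
    ``center_fraction`` positions the scaling center along the major axis,
    measured from the leaf tip.  ``tip_side`` states which image side the
    tip is on after rotation and petiole removal (the petiole is cut on the
    right, so the tip defaults to the left).
    """

    scale_factors: tuple[float, ...] = DEFAULT_SCALE_FACTORS
    center_fraction: float = 2.0 / 3.0
    tip_side: str = "left"

    def __post_init__(self) -> None:
        f = tuple(self.scale_factors)
        if any(not 0 < s < 1 for s in f):
            raise ValueError(f"scale factors must lie in (0, 1): {f}")
        if any(a <= b for a, b in zip(f, f[1:])):
            raise ValueError(f"scale factors must be strictly descending: {f}")
        if not 0 < self.center_fraction < 1:
            raise ValueError(f"center_fraction must be in (0, 1), got {self.center_fraction}")
        if self.tip_side not in {"left", "right"}:
            raise ValueError(f"tip_side must be 'left' or 'right', got {self.tip_side!r}")
        self.scale_factors = f

    @property
    def n_sections(self) -> int:
        return len(self.scale_factors) + 1


def scaling_center(mask: np.ndarray, params: SectioningParams | None = None) -> tuple[float, float]:
    """Scaling center (row, col) on the major axis of a horizontal leaf.

    The column lies at ``center_fraction`` of the leaf's column extent,
    measured from the tip side; the row is the mask centroid row (the
    midrib of a roughly symmetric leaf).  If the point falls outside the
    mask it is snapped to the nearest mask pixel.
    """
    params = params or SectioningParams()
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    c0, c1 = xs.min(), xs.max()
    if params.tip_side == "left":
        col = c0 + params.center_fraction * (c1 - c0)
    else:
        col = c1 - params.center_fraction * (c1 - c0)
    row = float(ys.mean())
    r_i, c_i = int(round(row)), int(round(col))
    r_i = min(max(r_i, 0), mask.shape[0] - 1)
    c_i = min(max(c_i, 0), mask.shape[1] - 1)
    if not mask[r_i, c_i]:
        d2 = (ys - row) ** 2 + (xs - col) ** 2
        j = int(np.argmin(d2))
        return float(ys[j]), float(xs[j])
    return row, col


def scaled_contours(
    contour: np.ndarray, center: tuple[float, float], params: SectioningParams | None = None
) -> list[np.ndarray]:
    """Shrink a closed (row, col) contour toward the center.

    Each vertex v maps to ``center + s · (v − center)`` for every scale
    factor s, in the given (descending) order.
    """
    params = params or SectioningParams()
    contour = np.asarray(contour, dtype=float)
    c = np.asarray(center, dtype=float)
    return [c + s * (contour - c) for s in params.scale_factors]


def section_partition(
    mask: np.ndarray, contours: list[np.ndarray], params: SectioningParams | None = None
) -> np.ndarray:
    """Label each mask pixel with its section, 1 (edge) .. K (center).

    Contours must be ordered by descending scale factor.  Labels are
    assigned by successive even-odd polygon rasterisation, innermost wins,
    so every mask pixel receives exactly one label even for concave or
    self-intersecting scaled contours.
    """
    params = params or SectioningParams()
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = 1
    for k, contour in enumerate(contours, start=2):
        inside = draw.polygon2mask(mask.shape, contour)
        labels[mask & inside] = k
    return labels


def section_means(ndvi: np.ndarray, labels: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Mean NDVI per section, ordered edge → center; empty sections are NaN."""
    ndvi = np.asarray(ndvi, dtype=float)
    labels = np.asarray(labels)
    n = int(labels.max())
    if valid is None:
        valid = np.ones(ndvi.shape, dtype=bool)
    out = np.full(n, np.nan)
    for k in range(1, n + 1):
        sel = (labels == k) & valid
        if sel.any():
            out[k - 1] = float(ndvi[sel].mean())
    return out


def section_leaf(
    mask: np.ndarray, ndvi: np.ndarray, params: SectioningParams | None = None,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: contour → center → partition → per-section means.

    Returns ``(label_map, means)`` for a horizontal, petiole-free leaf mask.
    """
    params = params or SectioningParams()
    contour = leaf_contour(mask)
    # point-in-polygon cost is linear in vertex count; ~150 vertices keep
    # section areas within ~0.1% for leaf-like outlines
    if len(contour) > 150:
        contour = contour[:: len(contour) // 150]
    center = scaling_center(mask, params)
    rings = scaled_contours(contour, center, params)
    labels = section_partition(mask, rings, params)
    return labels, section_means(ndvi, labels, valid)
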