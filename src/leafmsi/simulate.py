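"""Synthetic back-lit leaf scenes with full ground truth.

Emulates what a chamber-based multispectral transmittance imager captures:
a leaf pressed flat on a bright diffuse (Teflon-like) background, imaged in
four LED bands (NIR, red, green, blue capture order), with a petiole along
the major axis, a branching vein network that is darker in NDVI than the
lamina, an edge-to-midrib NDVI gradient, smooth vignetting and additive
dark noise.  Every scene comes with analytic ground truth: lamina, petiole
and vein masks, the vein graph, the applied orientation and closed-form
morphology, so each downstream stage can be scored exactly.

The leaf silhouette is a superellipse |u/a|^e + |v/b|^e = 1 whose exponent
controls tip sharpness; e = 2 gives an exact ellipse with closed-form area
πab.  Raw counts follow ``dark + illum · τ · (white_plateau − dark) + noise``;
the white reference shares the same illumination field, so flat-field
calibration recovers the scene transmittance τ exactly in the noiseless
case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.special import gamma

from .stack import MultispectralStack, default_manifest
from .venation import VenationGraph


@dataclass
class BandTransmittance:
    """Per-band transmittance triplet (lamina, vein, background), each [0,1]."""

    lamina: float
    vein: float
    background: float

    def __post_init__(self) -> None:
        for name in ("lamina", "vein", "background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} transmittance must be in [0, 1], got {v}")


def default_band_transmittance() -> dict[int, BandTransmittance]:
    """Transmittances emulating a healthy soybean leaflet on a Teflon diffuser.

    Lamina NDVI (0.8 − 0.1)/(0.8 + 0.1) ≈ 0.78, vein ≈ 0.45, background
    ≈ 0.01 — plant tissue far above and the diffuser far below the 0.2
    segmentation threshold.
    """
    return {
        880: BandTransmittance(0.80, 0.75, 0.97),
        660: BandTransmittance(0.10, 0.28, 0.95),
        560: BandTransmittance(0.30, 0.25, 0.96),
        405: BandTransmittance(0.05, 0.08, 0.93),
    }


@dataclass
class LeafShape:
    a_px: float = 180.0          # semi-major axis
    b_px: float = 100.0          # semi-minor axis
    tip_sharpness: float = 2.0   # superellipse exponent


@dataclass
class Petiole:
    length_px: float = 90.0
    width_px: float = 14.0


@dataclass
class VeinSpec:
    n_primary: int = 6           # primary vein pairs off the midrib
    branching_depth: int = 2
    vein_width_px: float = 5.0


@dataclass
class SceneParams:
    """Full description of one synthetic scene.

    Defaults emulate the imaging chamber at desk scale: a 620 × 400 px field
    at 0.2 mm/px (124 × 80 mm, the chamber's leaf capacity), a leaflet with
    a 72 × 40 mm blade, a ~3 mm petiole, a mild positive edge-to-center NDVI
    gradient, 30% corner vignetting and ~0.5% dark noise.
    """

    image_size: tuple[int, int] = (400, 620)      # (height, width) px
    mm_per_px: float = 0.2
    leaf_shape: LeafShape = field(default_factory=LeafShape)
    orientation_deg: float = 0.0
    petiole: Petiole = field(default_factory=Petiole)
    vein_spec: VeinSpec = field(default_factory=VeinSpec)
    band_transmittance: dict[int, BandTransmittance] = field(
        default_factory=default_band_transmittance
    )
    ndvi_gradient: float = 0.10     # center NDVI minus edge NDVI, >= 0
    illum_falloff: float = 0.30     # vignetting strength, [0, 1)
    dark_level: float = 100.0       # counts
    white_plateau: float = 3000.0   # counts at full illumination
    noise_sd: float = 15.0          # counts
    quantize: bool = False          # round to integer counts (uint16 range)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if not -90.0 < self.orientation_deg <= 90.0:
            raise ValueError(f"orientation_deg must be in (-90, 90], got {self.orientation_deg}")
        if self.ndvi_gradient < 0:
            raise ValueError("ndvi_gradient must be >= 0")
        if not 0.0 <= self.illum_falloff < 1.0:
            raise ValueError("illum_falloff must be in [0, 1)")
        if self.dark_level < 0 or self.noise_sd < 0:
            raise ValueError("dark_level and noise_sd must be >= 0")
        if self.white_plateau <= self.dark_level:
            raise ValueError("white_plateau must exceed dark_level")
        tau = self.band_transmittance
        nir, red = tau[880], tau[660]
        bg_ndvi = (nir.background - red.background) / (nir.background + red.background)
        if bg_ndvi >= 0.2:
            raise ValueError(f"background NDVI {bg_ndvi:.3f} must be < 0.2")
        if nir.lamina <= red.lamina:
            raise ValueError("lamina NIR transmittance must exceed red so lamina NDVI > 0.2")


@dataclass
class TrueMorphology:
    """Closed-form morphology of the generated silhouette (mm units)."""

    area_mm2: float
    perimeter_mm: float
    major_axis_mm: float
    minor_axis_mm: float
    roundness: float


@dataclass
class GroundTruth:
    leaf_mask: np.ndarray        # lamina only
    petiole_mask: np.ndarray
    vein_mask: np.ndarray
    vein_graph: VenationGraph
    true_features: TrueMorphology
    theta_deg: float
    ndvi_field: np.ndarray       # per-pixel NDVI the scene realises (noise-free)
    scaling_center_gradient: float  # center-minus-edge NDVI actually applied


# ---------------------------------------------------------------------------
# silhouette geometry


def superellipse_area(a: float, b: float, e: float) -> float:
    """Area of |x/a|^e + |y/b|^e <= 1 (πab when e = 2)."""
    return 4.0 * a * b * gamma(1 + 1 / e) ** 2 / gamma(1 + 2 / e)


def superellipse_perimeter(a: float, b: float, e: float, n: int = 20000) -> float:
    """Boundary length by dense polyline integration."""
    t = np.linspace(0, math.pi / 2, n)
    ct, st = np.cos(t), np.sin(t)
    x = a * ct ** (2 / e)
    y = b * st ** (2 / e)
    quarter = float(np.hypot(np.diff(x), np.diff(y)).sum())
    return 4.0 * quarter


def _leaf_frame(params: SceneParams):
    """(u, v) leaf-frame coordinate grids: u along major axis (+u = base)."""
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dx = cols - cx
    dy_up = -(rows - cy)
    th = math.radians(params.orientation_deg)
    u = dx * math.cos(th) + dy_up * math.sin(th)
    v = -dx * math.sin(th) + dy_up * math.cos(th)
    return u, v, (cy, cx)


def _check_bounds(params: SceneParams) -> None:
    a = params.leaf_shape.a_px + params.petiole.length_px
    b = params.leaf_shape.b_px
    th = math.radians(params.orientation_deg)
    half_w = abs(a * math.cos(th)) + abs(b * math.sin(th))
    half_h = abs(a * math.sin(th)) + abs(b * math.cos(th))
    h, w = params.image_size
    margin = 4
    if 2 * half_w > w - 2 * margin:
        raise ValueError(
            f"leaf geometry exceeds image width: needs {2 * half_w:.0f} px, image is {w} px wide"
        )
    if 2 * half_h > h - 2 * margin:
        raise ValueError(
            f"leaf geometry exceeds image height: needs {2 * half_h:.0f} px, image is {h} px tall"
        )


# ---------------------------------------------------------------------------
# vein network construction


def _superellipse_radius(phi: float, a: float, b: float, e: float) -> float:
    """Distance from center to the boundary along direction phi."""
    c, s = abs(math.cos(phi)), abs(math.sin(phi))
    return (c**e / a**e + s**e / b**e) ** (-1.0 / e)


def _build_vein_segments(params: SceneParams):
    """Segments [(p0, p1, width), ...] in leaf-frame (u, v) coordinates, and
    the ground-truth graph over their junctions."""
    shape, spec = params.leaf_shape, params.vein_spec
    a, b, e = shape.a_px, shape.b_px, shape.tip_sharpness
    wv = spec.vein_width_px
    segments: list[tuple[tuple, tuple, float]] = []
    g: nx.MultiGraph = nx.MultiGraph()
    nid = [0]

    def add_node(pt):
        g.add_node(nid[0], pos=pt)
        nid[0] += 1
        return nid[0] - 1

    tip = (-0.97 * a, 0.0)
    base = (0.97 * a, 0.0)
    n_tip, n_base = add_node(tip), add_node(base)

    # attachment points of the primary pairs along the midrib
    n_pairs = max(spec.n_primary, 1)
    attach_u = np.linspace(-0.7 * a, 0.6 * a, n_pairs)
    attach_ids = []
    prev = n_tip
    for ua in attach_u:
        node = add_node((float(ua), 0.0))
        seg_len = abs(ua - g.nodes[prev]["pos"][0])
        g.add_edge(prev, node, length=seg_len, width=wv + 2)
        segments.append((g.nodes[prev]["pos"], (float(ua), 0.0), wv + 2))
        attach_ids.append(node)
        prev = node
    g.add_edge(prev, n_base, length=abs(base[0] - g.nodes[prev]["pos"][0]), width=wv + 2)
    segments.append((g.nodes[prev]["pos"], base, wv + 2))

    def grow(node, origin, direction, length, width, depth):
        end = (origin[0] + length * math.cos(direction), origin[1] + length * math.sin(direction))
        # keep inside the blade
        phi = math.atan2(end[1], end[0])
        r_max = 0.93 * _superellipse_radius(phi, a, b, e)
        r_end = math.hypot(*end)
        if r_end > r_max:
            scale = r_max / r_end
            end = (end[0] * scale, end[1] * scale)
            length *= scale
        child = add_node(end)
        g.add_edge(node, child, length=math.hypot(end[0] - origin[0], end[1] - origin[1]), width=width)
        segments.append((origin, end, width))
        if depth > 1 and length > 6 * width:
            for sgn in (-1.0, 1.0):
                grow(child, end, direction + sgn * math.radians(30), 0.5 * length, max(width - 1, 2), depth - 1)

    for k, (node, ua) in enumerate(zip(attach_ids, attach_u)):
        for side in (1.0, -1.0):
            # primaries angle toward the tip, reaching for the margin
            direction = side * math.radians(55)
            phi = direction
            reach = 0.80 * _superellipse_radius(phi, a, b, e)
            grow(node, (float(ua), 0.0), direction, reach * 0.6, wv, spec.branching_depth)

    return segments, g


def _rasterize_segments(segments, params: SceneParams, lamina: np.ndarray) -> np.ndarray:
    """Draw widths-aware strokes (leaf frame) into an image-frame mask."""
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(params.orientation_deg)
    cth, sth = math.cos(th), math.sin(th)
    mask = np.zeros((h, w), dtype=bool)

    def to_image(u, v):
        dx = u * cth - v * sth
        dy_up = u * sth + v * cth
        return cy - dy_up, cx + dx  # (row, col)

    by_width: dict[float, list] = {}
    for p0, p1, width in segments:
        by_width.setdefault(width, []).append((p0, p1))
    for width, segs in by_width.items():
        lines = np.zeros((h, w), dtype=bool)
        for (u0, v0), (u1, v1) in segs:
            r0, c0 = to_image(u0, v0)
            r1, c1 = to_image(u1, v1)
            n = int(max(abs(r1 - r0), abs(c1 - c0)) * 2) + 2
            rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, h - 1)
            cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, w - 1)
            lines[rr, cc] = True
        radius = max(int(round((width - 1) / 2)), 0)
        if radius:
            from skimage import morphology as _m

            lines = _m.dilation(lines, _m.disk(radius))
        mask |= lines
    return mask & lamina


def _graph_in_image_frame(g: nx.MultiGraph, params: SceneParams) -> nx.MultiGraph:
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(params.orientation_deg)
    out = nx.MultiGraph()
    for n, d in g.nodes(data=True):
        u, v = d["pos"]
        dx = u * math.cos(th) - v * math.sin(th)
        dy_up = u * math.sin(th) + v * math.cos(th)
        deg = g.degree(n)
        out.add_node(
            n,
            pos=(cy - dy_up, cx + dx),
            degree=deg,
            kind="endpoint" if deg <= 1 else ("junction" if deg >= 3 else "bend"),
        )
    for u_, v_, d in g.edges(data=True):
        out.add_edge(u_, v_, **d)
    return out


# ---------------------------------------------------------------------------
# scene assembly


def _illumination(params: SceneParams) -> np.ndarray:
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    r2 = ((rows - cy) ** 2 + (cols - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - params.illum_falloff * r2


def _band_rngs(params: SceneParams, n_draws: int) -> list[np.random.Generator]:
    """One deterministic child stream per band (stable under band-order use)."""
    root = np.random.SeedSequence(params.seed)
    return [np.random.default_rng(s) for s in root.spawn(n_draws)]


def generate_scene(
    params: SceneParams,
) -> tuple[MultispectralStack, MultispectralStack, MultispectralStack, GroundTruth]:
    """Generate one scene: (raw, white_ref, dark_ref, ground_truth).

    All three stacks share the band order NIR, red, green, blue (the
    device's capture order, recorded in the manifest).  Identical params +
    seed give bit-identical outputs.
    """
    _check_bounds(params)
    h, w = params.image_size
    shape = params.leaf_shape
    a, b, e = shape.a_px, shape.b_px, shape.tip_sharpness

    u, v, _ = _leaf_frame(params)
    lamina = (np.abs(u / a) ** e + np.abs(v / b) ** e) <= 1.0

    pet = params.petiole
    petiole = (
        (u >= 0.0)
        & (u <= a + pet.length_px)
        & (np.abs(v) <= pet.width_px / 2.0)
        & ~lamina
    )

    segments, g_leafframe = _build_vein_segments(params)
    vein_mask = _rasterize_segments(segments, params, lamina)
    vein_graph = VenationGraph(_graph_in_image_frame(g_leafframe, params))

    # NDVI target field on the lamina: rises from the margin to the interior
    tau = params.band_transmittance
    n_center = (tau[880].lamina - tau[660].lamina) / (tau[880].lamina + tau[660].lamina)
    depth = ndimage.distance_transform_edt(lamina)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth_norm = depth / depth.max() if depth.max() > 0 else depth
    ndvi_field = np.where(
        lamina, n_center - params.ndvi_gradient * (1.0 - depth_norm), 0.0
    )

    n_vein = (tau[880].vein - tau[660].vein) / (tau[880].vein + tau[660].vein)
    n_bg = (tau[880].background - tau[660].background) / (
        tau[880].background + tau[660].background
    )
    ndvi_field = np.where(vein_mask, n_vein, ndvi_field)
    ndvi_field = np.where(petiole, n_vein, ndvi_field)
    ndvi_field = np.where(~(lamina | petiole), n_bg, ndvi_field)

    # per-band transmittance maps; red is derived from the NDVI field so the
    # gradient is realised exactly with a fixed NIR transmittance
    manifest = default_manifest()
    tau_maps = []
    for band in manifest:
        wl = int(band.wavelength_nm)
        t = tau[wl]
        base = np.where(lamina, t.lamina, np.where(petiole | vein_mask, t.vein, t.background))
        base = np.where(vein_mask, t.vein, base)
        tau_maps.append(base)
    # overwrite red on the lamina from the NDVI field: τr = τn (1−n)/(1+n)
    i_nir = next(i for i, bnd in enumerate(manifest) if bnd.role == "nir")
    i_red = next(i for i, bnd in enumerate(manifest) if bnd.role == "red")
    interior = lamina & ~vein_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_red_field = tau[880].lamina * (1.0 - ndvi_field) / (1.0 + ndvi_field)
    tau_maps[i_red] = np.where(interior, tau_red_field, tau_maps[i_red])

    illum = _illumination(params)
    span = params.white_plateau - params.dark_level
    rngs = _band_rngs(params, 3 * len(manifest))

    def counts(tau_map, rng):
        img = params.dark_level + illum * tau_map * span
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 65535.0)
        if params.quantize:
            img = np.round(img).astype(np.uint16)
        return img

    raw = np.stack([counts(tm, rngs[i]) for i, tm in enumerate(tau_maps)])
    nb = len(manifest)
    white = np.stack(
        [counts(np.ones((h, w)), rngs[nb + i]) for i in range(nb)]
    )
    dark_imgs = []
    for i in range(nb):
        img = np.full((h, w), params.dark_level)
        if params.noise_sd > 0:
            img = img + rngs[2 * nb + i].normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 65535.0)
        if params.quantize:
            img = np.round(img).astype(np.uint16)
        dark_imgs.append(img)
    dark = np.stack(dark_imgs)

    area_px2 = superellipse_area(a, b, e)
    perim_px = superellipse_perimeter(a, b, e)
    s = params.mm_per_px
    true_features = TrueMorphology(
        area_mm2=area_px2 * s * s,
        perimeter_mm=perim_px * s,
        major_axis_mm=2 * a * s,
        minor_axis_mm=2 * b * s,
        roundness=4 * math.pi * area_px2 / perim_px**2,
    )

    gt = GroundTruth(
        leaf_mask=lamina,
        petiole_mask=petiole,
        vein_mask=vein_mask,
        vein_graph=vein_graph,
        true_features=true_features,
        theta_deg=params.orientation_deg,
        ndvi_field=ndvi_field,
        scaling_center_gradient=params.ndvi_gradient,
    )
    mk = lambda data: MultispectralStack(data, default_manifest())
    return mk(raw), mk(white), mk(dark), gt


# ---------------------------------------------------------------------------
# analytic vein lattice fixture


def generate_vein_lattice(
    rows: int, cols: int, spacing_px: int, width_px: int, seed: int = 0
) -> tuple[np.ndarray, VenationGraph]:
    """A rectangular grid-graph of strokes with known topology.

    The lattice is the grid graph on ``rows × cols`` nodes spaced
    ``spacing_px`` apart, drawn as strokes of ``width_px``.  Corner nodes
    have degree 2 and are contracted (a skeleton tracer sees them as bends),
    so the ground-truth counts are: cycles = (rows−1)(cols−1); for
    rows, cols ≥ 2, junctions = rows·cols − 4 and endpoints = 0; a single
    row or column is a path with 2 endpoints and no junction.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if rows * cols < 2:
        raise ValueError("lattice needs at least two nodes")
    if spacing_px <= width_px:
        raise ValueError(
            f"spacing ({spacing_px}) must exceed stroke width ({width_px}): strokes would merge"
        )

    margin = spacing_px // 2 + width_px
    h = (rows - 1) * spacing_px + 2 * margin
    w = (cols - 1) * spacing_px + 2 * margin
    img = np.zeros((max(h, 1), max(w, 1)), dtype=bool)

    def node_pos(i, j):
        return margin + i * spacing_px, margin + j * spacing_px

    half = max(int(round((width_px - 1) / 2)), 0)

    def stroke(r0, c0, r1, c1):
        # width is applied only perpendicular to the stroke axis, so the
        # drawn centerline length matches the node-to-node distance
        rr0, rr1 = sorted((r0, r1))
        cc0, cc1 = sorted((c0, c1))
        if rr0 == rr1:  # horizontal
            img[max(rr0 - half, 0) : rr1 + half + 1, cc0 : cc1 + 1] = True
        else:  # vertical
            img[rr0 : rr1 + 1, max(cc0 - half, 0) : cc1 + half + 1] = True

    g = nx.MultiGraph()
    for i in range(rows):
        for j in range(cols):
            g.add_node((i, j), pos=node_pos(i, j))
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                stroke(*node_pos(i, j), *node_pos(i, j + 1))
                g.add_edge((i, j), (i, j + 1), length=float(spacing_px), width=float(width_px))
            if i + 1 < rows:
                stroke(*node_pos(i, j), *node_pos(i + 1, j))
                g.add_edge((i, j), (i + 1, j), length=float(spacing_px), width=float(width_px))

    _contract_path_nodes(g)
    for n in g.nodes:
        deg = g.degree(n)
        g.nodes[n]["degree"] = deg
        g.nodes[n]["kind"] = "endpoint" if deg <= 1 else ("junction" if deg >= 3 else "bend")
    return img, VenationGraph(g)


def _contract_path_nodes(g: nx.MultiGraph) -> None:
    """Remove degree-2 nodes, merging their incident edges."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2 or g.number_of_edges(n, n):
                continue
            (u1, v1, d1), (u2, v2, d2) = list(g.edges(n, data=True))
            a = v1 if u1 == n else u1
            b2 = v2 if u2 == n else u2
            if a == n or b2 == n:
                continue
            g.remove_node(n)
            g.add_edge(a, b2, length=d1["length"] + d2["length"], width=d1["width"])
            changed = True
            break
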