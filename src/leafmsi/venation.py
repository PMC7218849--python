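"""Vein extraction from NDVI images and venation-graph features.

Veins transmit less NIR relative to red than the surrounding lamina, so
they appear dark in the NDVI image.  The extraction pipeline is: Gaussian
smoothing (kernel 5) → adaptive local-mean threshold (block 51, keeping
pixels below the local mean) → restriction to the leaf mask → removal of
8-connected components smaller than 71 px.  The vein mask is thinned to a
one-pixel skeleton and converted to a planar graph whose nodes are
junctions (degree ≥ 3) and endpoints (degree 1); edges carry a centerline
length (subsampled-polyline Euclidean length, exact for straight and 45°
strokes) and a mean width from the distance transform.  The eight summary features are: number of junctions, number of
endpoints, number of cycles (E − V + components), total length, network
area, convex-hull area, average edge length and average edge width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import morphology

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class VenationParams:
    """Vein-extraction parameters (smoothing, adaptive threshold, denoise)."""

    gaussian_kernel: int = 5
    adaptive_block: int = 51
    min_object_px: int = 71
    #: subtracted from the local mean before comparison.  A zero offset
    #: classifies arbitrarily faint smoothing halos around each vein as
    #: vein (precision collapses to ~w/(w+4) for veins of width w); 0.08
    #: NDVI units is about a quarter of the typical lamina-vein contrast
    #: and well above the per-pixel NDVI noise floor.
    adaptive_offset: float = 0.08

    def __post_init__(self) -> None:
        for name in ("gaussian_kernel", "adaptive_block"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 3, got {v}")
        if self.min_object_px < 1:
            raise ValueError(f"min_object_px must be >= 1, got {self.min_object_px}")


@dataclass
class VenationGraph:
    """Planar skeleton graph of a vein network.

    ``graph`` is a networkx MultiGraph whose nodes carry ``pos`` (row, col),
    and whose edges carry ``length`` (px, centerline), ``width`` (px) and
    ``path`` (list of skeleton pixels).
    """

    graph: nx.MultiGraph

    @property
    def n_components(self) -> int:
        if self.graph.number_of_nodes() == 0:
            return 0
        return nx.number_connected_components(self.graph)

    def nodes_of_kind(self, kind: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind]

    @property
    def n_junctions(self) -> int:
        return len(self.nodes_of_kind("junction"))

    @property
    def n_endpoints(self) -> int:
        return len(self.nodes_of_kind("endpoint"))

    @property
    def n_cycles(self) -> int:
        """Independent cycles via Euler's formula E − V + components."""
        return self.graph.number_of_edges() - self.graph.number_of_nodes() + self.n_components

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for *_, d in self.graph.edges(data=True)))


@dataclass
class VenationFeatures:
    """The eight venation summary features; averages are NaN when E = 0."""

    n_junctions: int
    n_endpoints: int
    n_cycles: int
    total_length_px: float
    network_area_px: int
    convex_hull_area_px: float
    avg_edge_length_px: float
    avg_edge_width_px: float


def _gaussian_kernel_smooth(image: np.ndarray, ksize: int) -> np.ndarray:
    """Gaussian smoothing with a ksize×ksize kernel (sigma from the usual
    0.3·((k−1)/2 − 1) + 0.8 rule)."""
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    radius = (ksize - 1) // 2
    return ndimage.gaussian_filter(image, sigma=sigma, truncate=radius / sigma)


def extract_vein_mask(
    ndvi_image: np.ndarray,
    leaf_mask: np.ndarray,
    params: VenationParams | None = None,
) -> np.ndarray:
    """Binary vein mask: NDVI-dark structures inside the leaf.

    The local mean for the adaptive threshold is computed over leaf pixels
    only (normalized box filter), so the zero background outside the lamina
    does not depress the threshold near the leaf margin.  Components
    strictly smaller than ``min_object_px`` are removed.
    """
    params = params or VenationParams()
    ndvi = np.asarray(ndvi_image, dtype=float)
    mask = np.asarray(leaf_mask, dtype=bool)
    if not mask.any():
        log.warning("extract_vein_mask: empty leaf mask")
        return np.zeros_like(mask)

    smoothed = _gaussian_kernel_smooth(np.where(mask, ndvi, 0.0), params.gaussian_kernel)
    weight = _gaussian_kernel_smooth(mask.astype(float), params.gaussian_kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(weight > 1e-9, smoothed / weight, 0.0)

    size = params.adaptive_block
    local_sum = ndimage.uniform_filter(np.where(mask, smoothed, 0.0), size=size)
    local_n = ndimage.uniform_filter(mask.astype(float), size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(local_n > 1e-9, local_sum / local_n, 0.0)

    veins = mask & (smoothed < local_mean - params.adaptive_offset)
    # strict inequality: components of exactly min_object_px survive
    veins = morphology.remove_small_objects(
        veins, max_size=params.min_object_px - 1, connectivity=2
    )
    if not veins.any():
        log.warning("extract_vein_mask: no vein structures found")
    return veins


# ---------------------------------------------------------------------------
# skeleton graph tracing


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def skeleton_graph(vein_mask: np.ndarray, *, merge_radius: int = 2) -> VenationGraph:
    """Thin a vein mask and trace its topology into a graph.

    Nodes sit at skeleton pixels with ≠ 2 neighbours; adjacent node pixels
    (within ``merge_radius``) are merged into one node to avoid
    double-counting the pixel clusters thinning produces at Y-junctions.
    Pure loops with no node get one artificial anchor node and a self-loop
    edge so component and cycle counts stay correct.  Edge width is
    ``2 · mean(EDT along centerline) − 1`` pixels.
    """
    mask = np.asarray(vein_mask, dtype=bool)
    g: nx.MultiGraph = nx.MultiGraph()
    if not mask.any():
        return VenationGraph(g)

    skel = morphology.skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)
    nbr = _neighbor_count(skel)
    node_mask = skel & (nbr != 2)

    # merge nearby node pixels into clusters
    if node_mask.any():
        grown = morphology.dilation(node_mask, morphology.disk(merge_radius - 1))
        cluster_labels, _ = ndimage.label(grown, structure=np.ones((3, 3)))
        cluster_labels = np.where(node_mask, cluster_labels, 0)
    else:
        cluster_labels = np.zeros(mask.shape, dtype=int)

    cluster_of: dict[tuple[int, int], int] = {}
    cluster_pixels: dict[int, list[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero(node_mask)):
        cid = int(cluster_labels[r, c])
        cluster_of[(r, c)] = cid
        cluster_pixels.setdefault(cid, []).append((int(r), int(c)))

    for cid, px in cluster_pixels.items():
        rr = float(np.mean([p[0] for p in px]))
        cc = float(np.mean([p[1] for p in px]))
        g.add_node(cid, pos=(rr, cc), pixels=px)

    skel_set = {(int(r), int(c)) for r, c in zip(*np.nonzero(skel))}

    def neighbors(p):
        r, c = p
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in skel_set:
                yield q

    def step(a, b):
        return _SQRT2 if a[0] != b[0] and a[1] != b[1] else 1.0

    visited: set[tuple[int, int]] = set()  # non-node pixels consumed by an edge

    def centroid_offset(cid, px):
        """Distance from a cluster's centroid to one of its pixels; keeps
        edge lengths honest when junction clusters span several pixels."""
        rr, cc = g.nodes[cid]["pos"]
        return math.hypot(rr - px[0], cc - px[1])

    def polyline_length(points, subsample=5, closed=False):
        """Centerline length by Euclidean distance over a subsampled
        polyline.  Per-pixel √2/1 step weighting overestimates oblique
        lines by up to ~8%; sampling every few pixels removes that bias
        while following curvature at the vein scale."""
        if len(points) < 2:
            return 0.0
        pts = list(points[::subsample])
        if points[-1] != pts[-1]:
            pts.append(points[-1])
        if closed:
            pts.append(points[0])
        arr = np.asarray(pts, dtype=float)
        d = np.diff(arr, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    # trace paths leaving every node pixel
    done_pairs: set[frozenset] = set()
    for start_px, cid in cluster_of.items():
        for nxt in neighbors(start_px):
            if nxt in cluster_of:
                # direct contact between node pixels
                other = cluster_of[nxt]
                if other == cid and nxt == start_px:
                    continue
                key = frozenset([start_px, nxt])
                if key in done_pairs:
                    continue
                done_pairs.add(key)
                if other != cid:  # intra-cluster contacts are the cluster itself
                    w = 2.0 * float((edt[start_px] + edt[nxt]) / 2.0) - 1.0
                    length = (
                        step(start_px, nxt)
                        + centroid_offset(cid, start_px)
                        + centroid_offset(other, nxt)
                    )
                    g.add_edge(cid, other, length=length, width=w, path=[])
                continue
            if nxt in visited:
                continue
            # walk along degree-2 pixels
            path = [nxt]
            visited.add(nxt)
            prev, cur = start_px, nxt
            end_cluster = None
            terminal_px = cur
            while True:
                candidates = [q for q in neighbors(cur) if q != prev]
                # prefer node pixels as termination
                node_hits = [q for q in candidates if q in cluster_of]
                if node_hits:
                    q = node_hits[0]
                    end_cluster = cluster_of[q]
                    terminal_px = q
                    break
                candidates = [q for q in candidates if q not in visited]
                if not candidates:
                    break  # dead end (shouldn't happen on clean skeletons)
                q = candidates[0]
                visited.add(q)
                path.append(q)
                prev, cur = cur, q
            full = [start_px] + path
            length = centroid_offset(cid, start_px)
            if end_cluster is None:
                # path ended without reaching a node: attach back to start
                end_cluster = cid
            else:
                full.append(terminal_px)
                length += centroid_offset(end_cluster, terminal_px)
            length += polyline_length(full)
            width = 2.0 * float(np.mean([edt[p] for p in path])) - 1.0 if path else float("nan")
            g.add_edge(cid, end_cluster, length=length, width=width, path=path)

    # pure cycles: remaining degree-2 loops with no node pixel
    remaining = skel_set - visited - set(cluster_of)
    while remaining:
        seed = next(iter(remaining))
        anchor_id = (g.number_of_nodes() and max(n for n in g.nodes if isinstance(n, int)) + 1) or 1
        g.add_node(anchor_id, pos=(float(seed[0]), float(seed[1])), pixels=[seed])
        path = [seed]
        prev, cur = None, seed
        while True:
            candidates = [q for q in neighbors(cur) if q != prev and q in remaining and q not in path[1:]]
            nxt_opts = [q for q in candidates if q != seed]
            if not nxt_opts:
                break
            q = nxt_opts[0]
            path.append(q)
            prev, cur = cur, q
        length = polyline_length(path, closed=True)
        width = 2.0 * float(np.mean([edt[p] for p in path])) - 1.0
        g.add_edge(anchor_id, anchor_id, length=length, width=width, path=path[1:])
        remaining -= set(path)

    _classify_nodes(g)
    _contract_degree2(g)
    return VenationGraph(g)


def _classify_nodes(g: nx.MultiGraph) -> None:
    for n in g.nodes:
        deg = g.degree(n)
        g.nodes[n]["degree"] = deg
        g.nodes[n]["kind"] = "endpoint" if deg <= 1 else ("junction" if deg >= 3 else "bend")


def _contract_degree2(g: nx.MultiGraph) -> None:
    """Merge the two edges of any degree-2 node (a bend, not a feature)."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2 and not (g.degree(n) == 2 and g.number_of_edges(n, n) == 1):
                continue
            if g.number_of_edges(n, n) == 1 and g.degree(n) == 2:
                continue  # pure self-loop anchor: keep
            edges = list(g.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            length = d1["length"] + d2["length"]
            path = list(d1.get("path", [])) + [tuple(map(int, map(round, g.nodes[n]["pos"])))] + list(
                d2.get("path", [])
            )
            widths = [w for w in (d1.get("width"), d2.get("width")) if w == w]
            width = float(np.mean(widths)) if widths else float("nan")
            g.remove_node(n)
            g.add_edge(a, b, length=length, width=width, path=path)
            changed = True
            break
    _classify_nodes(g)


def convex_hull_area(mask: np.ndarray) -> float:
    """Convex-hull area (px²) of the mask's pixel set."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    hull = morphology.convex_hull_image(mask)
    return float(hull.sum())


def venation_features(vg: VenationGraph, vein_mask: np.ndarray) -> VenationFeatures:
    """The eight venation summary features from graph and mask."""
    g = vg.graph
    E = g.number_of_edges()
    total = vg.total_length
    widths = [d["width"] for *_, d in g.edges(data=True) if d["width"] == d["width"]]
    return VenationFeatures(
        n_junctions=vg.n_junctions,
        n_endpoints=vg.n_endpoints,
        n_cycles=vg.n_cycles,
        total_length_px=total,
        network_area_px=int(np.asarray(vein_mask, dtype=bool).sum()),
        convex_hull_area_px=convex_hull_area(vein_mask),
        avg_edge_length_px=total / E if E else float("nan"),
        avg_edge_width_px=float(np.mean(widths)) if widths else float("nan"),
    )


def graph_to_json(vg: VenationGraph) -> dict:
    """JSON-serialisable dict of nodes/edges with coordinates."""
    nodes = [
        {"id": int(n), "row": d["pos"][0], "col": d["pos"][1], "kind": d.get("kind", ""), "degree": d.get("degree", 0)}
        for n, d in vg.graph.nodes(data=True)
    ]
    edges = [
        {"u": int(u), "v": int(v), "length_px": d["length"], "width_px": d["width"]}
        for u, v, d in vg.graph.edges(data=True)
    ]
    return {"nodes": nodes, "edges": edges, "n_components": vg.n_components}
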