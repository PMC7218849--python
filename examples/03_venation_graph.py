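"""Venation extraction: from NDVI image to a skeleton graph.

Runs the vein-extraction chain (Gaussian smoothing, adaptive local-mean
threshold, small-object removal, thinning, graph tracing) on a simulated
leaf, and prints the eight venation summary features together with the
recall/precision of the vein mask against the simulator's ground truth.
"""

import numpy as np

from leafmsi import (
    SceneParams,
    compute_ndvi,
    extract_vein_mask,
    generate_scene,
    skeleton_graph,
    spectral_calibrate,
    venation_features,
)
from leafmsi.calibrate import CalibrationBundle

params = SceneParams(seed=3, noise_sd=0.0, orientation_deg=0.0)
raw, white, dark, truth = generate_scene(params)
h, w = params.image_size
K = np.array([[1000.0, 0, (w - 1) / 2], [0, 1000.0, (h - 1) / 2], [0, 0, 1.0]])
cal = spectral_calibrate(raw, CalibrationBundle(white, dark, K, np.zeros(5), params.mm_per_px))
ndvi = compute_ndvi(cal)

vein_mask = extract_vein_mask(ndvi.values, truth.leaf_mask)
graph = skeleton_graph(vein_mask)
f = venation_features(graph, vein_mask)

tp = (vein_mask & truth.vein_mask).sum()
print(f"vein mask recall    : {tp / truth.vein_mask.sum():.3f}")
print(f"vein mask precision : {tp / vein_mask.sum():.3f}")
print()
print(f"junctions           : {f.n_junctions}")
print(f"endpoints           : {f.n_endpoints}")
print(f"cycles (areoles)    : {f.n_cycles}")
print(f"total length        : {f.total_length_px:.0f} px")
print(f"network area        : {f.network_area_px} px^2")
print(f"convex hull area    : {f.convex_hull_area_px:.0f} px^2")
print(f"avg edge length     : {f.avg_edge_length_px:.1f} px")
print(f"avg edge width      : {f.avg_edge_width_px:.1f} px")
print()
print("Junctions are skeleton nodes of degree >= 3, endpoints degree 1;")
print("cycles come from the Euler identity E - V + connected components.")
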