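# leafmsi

Multispectral leaf image analysis for chamber-based transmittance imagers.

Plant phenotyping devices that press a living leaf flat inside a dark
chamber and image it through four LED bands (405, 560, 660, 880 nm) produce
a co-registered monochrome stack from which colour, shape and venation
traits of the whole leaf can be measured — information a SPAD-style dot
meter cannot see. `leafmsi` implements the full analysis chain for such
captures, plus a seeded scene simulator that provides analytic ground truth
for every stage:

1. **Flat-field calibration** — `I_cal = (I_raw − I_dark) / (I_white − I_dark)`,
   cancelling illumination nonuniformity and sensor dark level.
2. **NDVI segmentation** — per-pixel `NDVI = (I_NIR − I_red) / (I_NIR + I_red)`;
   leaf = pixels with `NDVI ≥ t` (default t = 0.2, the bright diffuse
   background stays below it).
3. **Orientation and petiole removal** — the major axis from second-order
   moments, rotation to horizontal, then a cut at the first column right of
   the widest column whose leaf width drops below `t_petiole` (default 50 px).
4. **Spatial calibration** — Brown–Conrady undistortion and a fixed mm/px
   scale.
5. **Morphometrics** — area A and perimeter P from the sub-pixel contour,
   ellipse axes from moments, roundness `R = 4πA / P²`.
6. **Ring sectioning** — the outline scaled by 0.9 … 0.3 toward a center at
   two-thirds of the major axis from the tip, partitioning the blade into
   eight sections whose NDVI means profile the edge-to-center gradient.
7. **Venation** — Gaussian smoothing (kernel 5), adaptive local-mean
   threshold (block 51), removal of objects under 71 px, thinning, and a
   skeleton graph with junctions (degree ≥ 3), endpoints (degree 1), cycles
   (`E − V + components`), lengths and distance-transform widths.
8. **SPAD regression** — simple NDVI regression and four-band multiple
   linear regression with pairwise interactions under leave-one-out
   cross-validation.

## Worked example

```sh
python examples/01_simulate_and_process.py
```

```
fitted orientation :   14.99 deg (true 15.00)
petiole cut column : 525
mean NDVI          :  0.6781
area               :   2253.8 mm^2 (true 2261.9)
perimeter          :    180.6 mm   (true 179.5)
major / minor axis : 71.6 / 40.1 mm (true 72.0 / 40.0)
roundness          :   0.868      (true 0.882)
```

The scene is a simulated 72 × 40 mm leaflet imaged at 0.2 mm/px and tilted
15°; the left column is what the pipeline measured from the images alone,
the right what the simulator actually drew. Orientation is recovered to
0.01°, axes to ≲ 0.6%, area to 0.4% — the pixel-scale measurement error of
the method. The other examples demonstrate ring sectioning (a simulated
+0.10 edge-to-center NDVI gradient recovered as strictly increasing section
means, 0.687 → 0.763), venation-graph extraction (vein mask recall/precision
≈ 0.99 against ground truth) and the LOOCV interaction regression.

A thin CLI wraps the same pipeline for shell use:

```sh
leafmsi simulate scenes/ --seed 3 --n-scenes 2
leafmsi process scenes/scene_0003 --out out/
leafmsi report out/features.csv
```

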