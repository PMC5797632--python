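# canopy3d

Plot-level canopy phenotyping from nadir RGB-D imagery for row crops such as
cotton. A camera-over-canopy rig (a time-of-flight RGB-D camera ~2.4 m above
ground, driven along the row at ~1 m/s with a GPS receiver) produces a stream
of depth/color frames. `canopy3d` turns those frames into per-plot colorized
point clouds, isolates the crop canopy from ground and weeds, and extracts
static and dynamic canopy-size traits that can be regressed against yield.

## Pipeline

**Reconstruction.** GPS fixes are projected to UTM and rotated into a
plot-local frame: for frame *i*, the local position is

    p_i = R(θ) · (e_i − e_1, n_i − n_1, a_i − a_1)ᵀ

where θ is the angle between the fitted travel line and grid north, chosen so
travel maps to +y. Each depth frame is back-projected through the pinhole
model (X = (u − c_x)·d/f_x, z = H_cam − d for a nadir camera at height
H_cam), cropped to a per-frame region of interest (±W/2 across-row, half the
inter-frame gap along-row, 0…H_cam vertically), leveled by a MLESAC ground
plane fit (rotations about y and x removing the tilt seen in the X-Z and Y-Z
planes), and translated by p_i − p_1, which stitches the frames into one plot
cloud.

**Segmentation.** The excess green index on chromatic coordinates,
ExG = 2g − r − b with r = R/(R+G+B) etc., separates vegetation from soil
(threshold 0.15). The vegetation cloud is rasterized to a max-height grid
(cell 0.05 m), binarized at the 30th height percentile (drops short in-row
weeds), and its 8-connected components are filtered by area (≥ 15 cells) and
by centroid distance to the largest component (≤ its bounding-box extent
along the row; drops tall between-plot weeds). Surviving cells back-project
to the canopy point cloud. Segmentations are scored against truth masks by
accuracy / FPR / FNR and the categories clean (accuracy ≥ 95%),
weed-under-removal (FPR ≥ 10%) and canopy-over-removal (FNR ≥ 10%).

**Traits.** Per plot and date: max/mean height, the cumulative height
profile (5th–95th percentile in 5% steps), max/mean width over ten along-row
segments, projected canopy area (2D alpha shape / convex hull), and convex
and concave (3D alpha shape) hull volumes. Growth rates between consecutive
observation dates are G = (T(d₂) − T(d₁))/(d₂ − d₁), with the first period
anchored at planting.

**Statistics.** Simple and multiple (height-profile) linear regressions of
fiber yield on traits with adjusted R² and RMSE, and nested-model F-tests
F = ((RSS_s − RSS_b)/df₁)/(RSS_b/df₂).

A fully synthetic virtual field (closed-form plant and weed solids rendered
through the same pinhole geometry, with exact ground truth) ships in
`canopy3d.synthetic` and drives the test suite.

## Worked example

```python
import canopy3d as c3
from canopy3d.synthetic import scene_config

spec = c3.default_field_scene(seed=0)          # two weedy 3.05 m plots
c3.render_frames(spec, "session/")             # depth/color PNGs + gps.csv

frames = c3.load_session("session/")
groups = c3.group_frames_by_plot(frames, c3.scene_layout(spec))
cfg = scene_config(spec)
intr = c3.CameraIntrinsics.from_config(cfg)

for plot_id, plot_frames in groups.items():
    cloud = c3.reconstruct_plot(plot_frames, intr, cfg)
    canopy = c3.segment_canopy(cloud, cfg)
    t = c3.compute_static_traits(canopy, plot_id=plot_id, dap=74)
    print(f"{plot_id}: {len(canopy):6d} canopy points | "
          f"max height {t['max_height']:.2f} m | "
          f"projected area {t['projected_area']:.2f} m2 | "
          f"convex volume {t['convex_volume']:.2f} m3")
```

prints

```
plot01:   5792 canopy points | max height 0.81 m | projected area 1.29 m2 | convex volume 0.68 m3
plot02:   6143 canopy points | max height 0.78 m | projected area 1.43 m2 | convex volume 0.72 m3
```

The canopy points are what survived the weed/ground removal; max height is
the tallest canopy point above ground (the generating plants are 0.5–0.8 m
domes, plus ~5 mm depth noise), projected area the alpha-shape footprint of
the stand, and convex volume the hull of the top-view surface (a nadir
camera sees no undersides, so hull volumes underestimate whole-plant volume
but track it).

The same chain is available from the shell:

```
canopy3d simulate --seed 0 --out session/
canopy3d reconstruct --session session/ --layout layout.json --out recon/
canopy3d segment --ply recon/plot01.ply --out canopy.ply
canopy3d traits --ply canopy.ply --plot-id plot01 --dap 74 --out traits.csv
```

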