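"""Virtual-field generator: rendered RGB-D sessions with exact ground truth.

Emulates the field protocol the pipeline targets: plots of 3.05 m separated
by 1.83 m alleys on 1.52 m rows, imaged by a nadir RGB-D camera 2.4 m above
ground moving at ~1 m/s along the row.  A scene is a set of closed-form
solids (cones and dome-shaped half-ellipsoids) standing on the ground:

* **plants** — 15 half-ellipsoid canopies per plot at 0.15 m in-row spacing,
  overlapping into a continuous canopy ridge;
* **in-row weeds** — short, small solids scattered beside the row inside the
  enclosure (removed by the height/area rules downstream);
* **between-plot weeds** — tall, large solids in the alleys (removed by the
  position rule when the canopy stand is short, otherwise only their sliver
  inside the plot ROI survives).

Frames are rendered by exact per-pixel ray casting against the analytic
surface (bracketing march plus bisection on the pinhole ray), so a noise-free
scene reconstructs to points lying on the generating surfaces.  Depth noise
is added before millimeter quantization; GPS jitter perturbs the logged
fixes.  Every run is bit-reproducible for a fixed seed.

Ground truth comes in three forms: per-pixel class maps (ground / canopy /
weed) per frame, closed-form per-plot traits of the generating solids, and a
point/cell labeling helper for scoring segmentations of reconstructed clouds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image

from .frame_io import GPS_FILENAME, PlotLayout, geographic_to_utm, utm_to_geographic
from .reconstruction import PointCloud
from .segmentation import DepthRaster

logger = logging.getLogger("canopy3d")

LABEL_GROUND, LABEL_CANOPY, LABEL_WEED = 0, 1, 2

# mean vegetation / soil colors (RGB); per-pixel jitter is added at render time
_COLOR_CANOPY = np.array([62, 150, 70], dtype=float)
_COLOR_WEED = np.array([80, 158, 66], dtype=float)
_COLOR_GROUND = np.array([135, 120, 100], dtype=float)


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass
class Solid:
    """One closed-form solid standing on the ground.

    shape 'cone': z = h·(1 − d/r); 'ellipsoid' (dome, half-ellipsoid of
    revolution): z = h·sqrt(1 − (d/r)²); 'hemisphere': dome with h = r.
    ``label`` is 'canopy' or 'weed'.
    """

    shape: str
    x: float
    y: float
    height: float
    radius: float
    label: str = "canopy"

    def __post_init__(self) -> None:
        if self.shape == "hemisphere":
            self.shape = "ellipsoid"
            self.height = self.radius
        if self.shape not in ("cone", "ellipsoid"):
            raise ValueError(f"unsupported shape {self.shape!r}")
        if self.height <= 0 or self.radius <= 0:
            raise ValueError("solid dimensions must be positive")

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Height contribution above local ground; 0 outside the footprint."""
        d2 = (np.asarray(x) - self.x) ** 2 + (np.asarray(y) - self.y) ** 2
        u2 = d2 / self.radius**2
        if self.shape == "cone":
            return self.height * np.clip(1.0 - np.sqrt(u2), 0.0, None)
        return self.height * np.sqrt(np.clip(1.0 - u2, 0.0, None))

    @property
    def volume(self) -> float:
        if self.shape == "cone":
            return math.pi * self.radius**2 * self.height / 3.0
        return 2.0 * math.pi * self.radius**2 * self.height / 3.0

    @property
    def footprint_area(self) -> float:
        return math.pi * self.radius**2


@dataclass
class PlotSpec:
    plot_id: str
    row_index: int
    start: float      # along-row (y) world meters
    end: float
    row_x: float      # across-row (x) world meters of the row line


@dataclass
class CameraSpec:
    fx: float = 130.0
    fy: float = 130.0
    cx: float = 79.5
    cy: float = 59.5
    width: int = 160
    height: int = 120
    camera_height: float = 2.4


@dataclass
class SceneSpec:
    """Full description of a virtual scanning session.

    World frame: x across-row (east), y along-row (north), z up; the GPS
    track runs north along each row.  Defaults reproduce the target field
    protocol: 3.05 m plots, 1.83 m alleys, 1.52 m rows, camera at 2.4 m
    traveling 1 m/s, 5 mm depth noise and 2 cm GPS jitter.
    """

    plots: list[PlotSpec] = field(default_factory=list)
    solids: list[Solid] = field(default_factory=list)
    camera: CameraSpec = field(default_factory=CameraSpec)
    frame_spacing: float = 0.4     # m between acquisitions (~2.5 Hz at 1 m/s)
    speed: float = 1.0             # m/s
    ground_tilt_deg: float = 0.0   # tilt about the x axis
    depth_sigma: float = 0.005     # m
    gps_sigma: float = 0.02       # m
    base_latitude: float = 33.727239
    base_longitude: float = -83.299097
    base_altitude: float = 230.0
    seed: int = 0

    def __post_init__(self) -> None:
        by_row: dict[int, list[PlotSpec]] = {}
        for p in self.plots:
            by_row.setdefault(p.row_index, []).append(p)
        for plots in by_row.values():
            plots = sorted(plots, key=lambda p: p.start)
            for a, b in zip(plots, plots[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"plots {a.plot_id} and {b.plot_id} overlap")
        tallest = max((s.height for s in self.solids), default=0.0)
        if tallest >= self.camera.camera_height:
            raise ValueError("camera below the tallest solid")

    def base_utm(self) -> tuple[float, float, str]:
        return geographic_to_utm(self.base_latitude, self.base_longitude)

    def ground_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # tilt about the x axis, referenced to the scene's along-row midpoint
        t = math.tan(math.radians(self.ground_tilt_deg))
        y_mid = 0.0
        if self.plots:
            y_mid = 0.5 * (min(p.start for p in self.plots)
                           + max(p.end for p in self.plots))
        return t * (np.asarray(y, dtype=float) - y_mid) + 0.0 * np.asarray(x)

    def surface(self, x: np.ndarray, y: np.ndarray,
                solids: Sequence[Solid] | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
        """(surface z, class label) of the top surface at world (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        best = np.zeros_like(x, dtype=float)
        labels = np.full(x.shape, LABEL_GROUND, dtype=np.uint8)
        for s in (self.solids if solids is None else solids):
            z = s.surface(x, y)
            take = z > best
            best = np.where(take, z, best)
            labels = np.where(
                take, LABEL_CANOPY if s.label == "canopy" else LABEL_WEED,
                labels)
        return self.ground_z(x, y) + best, labels

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        d = json.loads(Path(path).read_text())
        d["plots"] = [PlotSpec(**p) for p in d.get("plots", [])]
        d["solids"] = [Solid(**s) for s in d.get("solids", [])]
        if "camera" in d:
            d["camera"] = CameraSpec(**d["camera"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Default study-condition scene
# ---------------------------------------------------------------------------

def default_field_scene(seed: int = 0, n_plots: int = 2,
                        plants_per_plot: int = 15,
                        inrow_weeds_per_plot: int = 25,
                        alley_weeds: bool = True,
                        noise: bool = True,
                        ground_tilt_deg: float = 0.0) -> SceneSpec:
    """One row of plots under the default field conditions.

    Plants are dome canopies (height 0.5–0.8 m, radius 0.25–0.35 m) at
    0.15 m spacing, the first 0.15 m from the plot start (the 15-plant stand
    occupies 2.4 m of the 3.05 m plot).  In-row weeds are short and small
    (0.08–0.28 m tall, 0.05–0.10 m radius) scattered beside the row; each
    alley carries one tall weed (0.9–1.1 m) near its upstream plot.  The
    weed pressure is deliberately heavy (~a third of the vegetated area) —
    the segmentation's weed-removal rules are the subject under test.
    """
    rng = np.random.default_rng(seed)
    plot_len, alley = 3.05, 1.83
    plots: list[PlotSpec] = []
    solids: list[Solid] = []
    for k in range(n_plots):
        start = k * (plot_len + alley)
        end = start + plot_len
        plots.append(PlotSpec(f"plot{k + 1:02d}", 0, start, end, 0.0))
        for p in range(plants_per_plot):
            y = start + 0.15 + 0.15 * p + rng.normal(0.0, 0.01)
            solids.append(Solid(
                "ellipsoid", rng.normal(0.0, 0.02), y,
                height=rng.uniform(0.5, 0.8),
                radius=rng.uniform(0.25, 0.35), label="canopy"))
        for _ in range(inrow_weeds_per_plot):
            side = rng.choice([-1.0, 1.0])
            solids.append(Solid(
                "ellipsoid", side * rng.uniform(0.38, 0.68),
                rng.uniform(start, end),
                height=rng.uniform(0.08, 0.28),
                radius=rng.uniform(0.05, 0.10), label="weed"))
        if alley_weeds and k < n_plots - 1:
            solids.append(Solid(
                "ellipsoid", rng.uniform(-0.3, 0.3),
                end + rng.uniform(0.25, 0.45),
                height=rng.uniform(0.9, 1.1),
                radius=rng.uniform(0.2, 0.3), label="weed"))
    return SceneSpec(plots=plots, solids=solids,
                     depth_sigma=0.005 if noise else 0.0,
                     gps_sigma=0.02 if noise else 0.0,
                     ground_tilt_deg=ground_tilt_deg, seed=seed)


def scene_config(spec: SceneSpec, **overrides) -> "PipelineConfig":
    """A pipeline configuration whose intrinsics match the scene's camera."""
    from .config import IntrinsicsConfig, PipelineConfig

    cam = spec.camera
    cfg = PipelineConfig(
        intrinsics=IntrinsicsConfig(cam.fx, cam.fy, cam.cx, cam.cy,
                                    cam.width, cam.height),
        camera_height=cam.camera_height, seed=spec.seed)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def scene_layout(spec: SceneSpec) -> list[PlotLayout]:
    """The scene's plot layout in the UTM frame, for frame grouping."""
    e0, n0, _ = spec.base_utm()
    return [PlotLayout(p.plot_id, p.row_index,
                       start=n0 + p.start, end=n0 + p.end,
                       row_center=e0 + p.row_x) for p in spec.plots]


# ---------------------------------------------------------------------------
# Scene sampling (dense labeled point set)
# ---------------------------------------------------------------------------

@dataclass
class LabeledPoints:
    points: np.ndarray   # (N, 3)
    labels: np.ndarray   # (N,) LABEL_*


def build_scene(spec: SceneSpec, density: float = 2000.0,
                rng: np.random.Generator | None = None) -> LabeledPoints:
    """Sample the scene's top surface at ``density`` points per m².

    Solids are sampled uniformly over their footprints (apex/axis included),
    ground over each plot interval; labels follow the surface owner at the
    sample location so occluded solids do not leak points.
    """
    rng = rng or np.random.default_rng(spec.seed)
    xs, ys = [], []
    for s in spec.solids:
        n = max(16, int(density * s.footprint_area))
        r = s.radius * np.sqrt(rng.uniform(0, 1, n))
        t = rng.uniform(0, 2 * np.pi, n)
        xs.append(np.concatenate([[s.x], s.x + r * np.cos(t)]))
        ys.append(np.concatenate([[s.y], s.y + r * np.sin(t)]))
    for p in spec.plots:
        length = p.end - p.start
        n = max(16, int(density * length * 1.52))
        xs.append(p.row_x + rng.uniform(-0.76, 0.76, n))
        ys.append(rng.uniform(p.start, p.end, n))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z, labels = spec.surface(x, y)
    return LabeledPoints(np.column_stack([x, y, z]), labels)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _render_depth(spec: SceneSpec, cam_x: float, cam_y: float,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Exact pinhole ray casting against the analytic surface.

    For pixel (u, v) the ray at z-depth d passes through world
    (cam_x + (u−cx)·d/fx, cam_y + (v−cy)·d/fy, H − d); the first surface
    crossing is bracketed by a coarse march in d and refined by bisection.
    Returns (depth in meters, per-pixel class labels).
    """
    cam = spec.camera
    H = cam.camera_height
    v, u = np.indices((cam.height, cam.width))
    ax = (u - cam.cx) / cam.fx
    ay = (v - cam.cy) / cam.fy

    near = [s for s in spec.solids
            if abs(s.y - cam_y) < 2.5 and abs(s.x - cam_x) < 2.5]

    def above(d):
        wx = cam_x + ax * d
        wy = cam_y + ay * d
        z, _ = spec.surface(wx, wy, solids=near)
        return (H - d) - z

    tallest = max((s.height for s in near), default=0.0)
    d_lo = np.full(ax.shape, max(H - tallest - 0.3, 0.1))
    d_hi = np.full(ax.shape, H + 0.5)
    # coarse march to bracket the first crossing
    step = 0.02
    d = d_lo.copy()
    bracket_lo = d_lo.copy()
    bracket_hi = d_hi.copy()
    found = np.zeros(ax.shape, dtype=bool)
    while (~found).any() and d.min() < H + 0.5:
        d_next = d + step
        below = above(d_next) <= 0
        new = below & ~found
        bracket_lo[new] = d[new]
        bracket_hi[new] = d_next[new]
        found |= below
        d = d_next
    lo, hi = bracket_lo, bracket_hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        pos = above(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    depth = 0.5 * (lo + hi)
    _, labels = spec.surface(cam_x + ax * depth, cam_y + ay * depth,
                             solids=near)
    return depth, labels


def render_frames(spec: SceneSpec, out_dir: str | Path) -> dict:
    """Render the session: depth/color PNGs, gps.csv, and ground truth.

    Writes ``depth_%06d.png`` (16-bit mm), ``color_%06d.png``, ``gps.csv``,
    plus ``truth/label_%06d.png`` (0 ground, 1 canopy, 2 weed),
    ``truth/truth_traits.csv`` and ``truth/meta.json`` (true frame poses and
    the scene spec).  Returns the metadata dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    e0, n0, zone = spec.base_utm()
    cam = spec.camera

    y_start = min(p.start for p in spec.plots) - 0.2
    y_end = max(p.end for p in spec.plots) + 0.2
    n_frames = int(np.floor((y_end - y_start) / spec.frame_spacing)) + 1
    row_x = spec.plots[0].row_x

    poses = []
    gps_rows = []
    for i in range(n_frames):
        cam_y = y_start + i * spec.frame_spacing
        depth, labels = _render_depth(spec, row_x, cam_y)
        if spec.depth_sigma > 0:
            depth = depth + rng.normal(0.0, spec.depth_sigma, depth.shape)
        depth_mm = np.clip(np.round(depth * 1000.0), 0, 65535).astype(np.uint16)
        Image.fromarray(depth_mm).save(out_dir / f"depth_{i:06d}.png")

        color = np.empty((*labels.shape, 3), dtype=float)
        color[labels == LABEL_GROUND] = _COLOR_GROUND
        color[labels == LABEL_CANOPY] = _COLOR_CANOPY
        color[labels == LABEL_WEED] = _COLOR_WEED
        color += rng.normal(0.0, 8.0, color.shape)
        Image.fromarray(np.clip(color, 0, 255).astype(np.uint8), "RGB").save(
            out_dir / f"color_{i:06d}.png")
        Image.fromarray(labels.astype(np.uint8)).save(
            truth_dir / f"label_{i:06d}.png")

        je, jn = (rng.normal(0.0, spec.gps_sigma, 2)
                  if spec.gps_sigma > 0 else (0.0, 0.0))
        lat, lon = utm_to_geographic(e0 + row_x + je, n0 + cam_y + jn, zone)
        t = (cam_y - y_start) / spec.speed
        gps_rows.append((i, f"{t:.3f}", f"{lat:.9f}", f"{lon:.9f}",
                         f"{spec.base_altitude:.3f}"))
        poses.append({"frame_index": i, "x": row_x, "y": cam_y, "z": 0.0})

    with open(out_dir / GPS_FILENAME, "w") as fh:
        fh.write("frame_index,timestamp,latitude,longitude,altitude\n")
        for row in gps_rows:
            fh.write(",".join(str(c) for c in row) + "\n")

    analytic_traits(spec).to_csv(truth_dir / "truth_traits.csv", index=False)
    meta = {"n_frames": n_frames, "poses": poses,
            "utm_zone": zone, "base_easting": e0, "base_northing": n0,
            "spec": dataclasses.asdict(spec)}
    (truth_dir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return meta


# ---------------------------------------------------------------------------
# Analytic ground-truth traits
# ---------------------------------------------------------------------------

def _plot_solids(spec: SceneSpec, plot: PlotSpec,
                 label: str = "canopy") -> list[Solid]:
    return [s for s in spec.solids
            if s.label == label and plot.start <= s.y <= plot.end]


def analytic_traits(spec: SceneSpec) -> pd.DataFrame:
    """Closed-form traits of each plot's generating canopy solids.

    ``max_height`` is the tallest canopy solid; ``projected_area`` the area
    of the union of the canopy footprint disks (polygonized circles);
    ``solid_volume`` the sum of individual solid volumes; ``convex_volume``
    is only stated for single-solid plots, where it equals the solid volume
    (a hull over several separated solids also spans the space between them).
    """
    rows = []
    for plot in spec.plots:
        canopy = _plot_solids(spec, plot, "canopy")
        if not canopy:
            rows.append({"plot_id": plot.plot_id, "max_height": np.nan,
                         "projected_area": np.nan, "solid_volume": np.nan,
                         "convex_volume": np.nan})
            continue
        discs = [shapely.Point(s.x, s.y).buffer(s.radius, quad_segs=256)
                 for s in canopy]
        union = shapely.unary_union(discs)
        rows.append({
            "plot_id": plot.plot_id,
            "max_height": max(s.height for s in canopy),
            "projected_area": float(union.area),
            "solid_volume": float(sum(s.volume for s in canopy)),
            "convex_volume": (canopy[0].volume if len(canopy) == 1
                              else np.nan),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth labeling of reconstructed clouds
# ---------------------------------------------------------------------------

def truth_point_labels(spec: SceneSpec, world_x: np.ndarray,
                       world_y: np.ndarray) -> np.ndarray:
    """Label world positions by footprint membership (canopy wins ties)."""
    x = np.asarray(world_x, dtype=float)
    y = np.asarray(world_y, dtype=float)
    labels = np.full(x.shape, LABEL_GROUND, dtype=np.uint8)
    for s in spec.solids:
        if s.label != "weed":
            continue
        inside = (x - s.x) ** 2 + (y - s.y) ** 2 <= s.radius**2
        labels[inside] = LABEL_WEED
    for s in spec.solids:
        if s.label != "canopy":
            continue
        inside = (x - s.x) ** 2 + (y - s.y) ** 2 <= s.radius**2
        labels[inside] = LABEL_CANOPY
    return labels


def truth_cell_mask(raster: DepthRaster, veg_cloud: PointCloud,
                    spec: SceneSpec, origin_xy: tuple[float, float],
                    ) -> np.ndarray:
    """Majority-vote canopy truth per raster cell of a vegetation cloud.

    ``origin_xy`` is the world position of the cloud's local origin (the
    first frame's acquisition position).  Each vegetation point is labeled by
    footprint membership and cells vote canopy vs weed.
    """
    wx = veg_cloud.coords[:, 0] + origin_xy[0]
    wy = veg_cloud.coords[:, 1] + origin_xy[1]
    labels = truth_point_labels(spec, wx, wy)
    nx, ny = raster.shape
    canopy_votes = np.zeros(nx * ny)
    weed_votes = np.zeros(nx * ny)
    np.add.at(canopy_votes, raster.point_cell, labels == LABEL_CANOPY)
    np.add.at(weed_votes, raster.point_cell, labels == LABEL_WEED)
    return (canopy_votes > weed_votes).reshape(nx, ny)
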