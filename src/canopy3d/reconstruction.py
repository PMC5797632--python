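"""Plot point-cloud reconstruction from nadir RGB-D frames.

Turns the frame sequence of one plot into a single stitched, colorized,
orientation-corrected point cloud:

1. fit the plot-local track from the GPS fixes (rotation of UTM deltas so the
   travel direction becomes +y, the across-row direction +x, altitude +z);
2. back-project every valid depth pixel through the pinhole model into
   frame-local meters with z measured up from the nominal ground
   (z = camera height − depth);
3. cut a per-frame region of interest: the enclosure width across-row, half
   the gap to the neighboring frames along-row, ground to camera height
   vertically;
4. detect the ground plane in each ROI by MLESAC and rotate the ROI so the
   detected ground normal matches vertical (no rotation when no reliable
   ground plane is found — e.g. full vegetation cover);
5. translate each ROI by its frame's local track position and concatenate.

All transforms are rigid: point counts and pairwise distances are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .config import MLESACParams, IntrinsicsConfig, PipelineConfig
from .frame_io import FrameRecord, GeoFix

logger = logging.getLogger("canopy3d")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics plus the mounting height of the nadir camera."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    camera_height: float = 2.4

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "CameraIntrinsics":
        ic: IntrinsicsConfig = cfg.intrinsics
        return cls(ic.fx, ic.fy, ic.cx, ic.cy, ic.width, ic.height,
                   camera_height=cfg.camera_height)


class PointCloud:
    """N colorized points: ``coords`` (N,3) float64 meters, ``colors`` (N,3) uint8."""

    __slots__ = ("coords", "colors")

    def __init__(self, coords: np.ndarray, colors: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if colors is None:
            colors = np.zeros((len(coords), 3), dtype=np.uint8)
        colors = np.asarray(colors, dtype=np.uint8).reshape(-1, 3)
        if len(colors) != len(coords):
            raise ValueError("colors and coords must have equal length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        self.coords = coords
        self.colors = colors

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, mask_or_idx) -> "PointCloud":
        return PointCloud(self.coords[mask_or_idx], self.colors[mask_or_idx])

    def translated(self, offset) -> "PointCloud":
        return PointCloud(self.coords + np.asarray(offset, dtype=float),
                          self.colors)

    def rotated(self, rot: np.ndarray) -> "PointCloud":
        return PointCloud(self.coords @ np.asarray(rot, dtype=float).T,
                          self.colors)

    @staticmethod
    def concatenate(clouds: Sequence["PointCloud"]) -> "PointCloud":
        if not clouds:
            return PointCloud(np.empty((0, 3)))
        return PointCloud(np.vstack([c.coords for c in clouds]),
                          np.vstack([c.colors for c in clouds]))


@dataclass
class LocalTrack:
    """Plot-local acquisition track: rotation angle and per-frame positions.

    ``theta_gl`` is the angle between the fitted travel line and the north
    axis, with the sign chosen so travel maps to increasing local y.  The
    first frame is the local origin.
    """

    theta_gl: float
    positions: np.ndarray  # (n_frames, 3) meters, first row == 0


@dataclass
class GroundPlane:
    """A fitted ground plane n·p = offset with unit normal oriented upward."""

    normal: np.ndarray
    offset: float
    inlier_count: int
    found: bool


@dataclass
class ROIBounds:
    x_lower: float
    x_upper: float
    y_lower: float
    y_upper: float
    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        for lo, hi in ((self.x_lower, self.x_upper),
                       (self.y_lower, self.y_upper),
                       (self.z_lower, self.z_upper)):
            if lo > hi:
                raise ValueError("ROI lower bound exceeds upper bound")


# ---------------------------------------------------------------------------
# PLY I/O
# ---------------------------------------------------------------------------

def write_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write a binary little-endian PLY with xyz float and uchar colors."""
    pc = trimesh.PointCloud(cloud.coords, colors=np.column_stack(
        [cloud.colors, np.full(len(cloud), 255, dtype=np.uint8)]))
    Path(path).write_bytes(pc.export(file_type="ply"))


def read_ply(path: str | Path) -> PointCloud:
    pc = trimesh.load(str(path), process=False)
    colors = np.asarray(pc.colors)
    if colors.size == 0:
        colors = None
    else:
        colors = colors[:, :3].astype(np.uint8)
    return PointCloud(np.asarray(pc.vertices, dtype=np.float64), colors)


# ---------------------------------------------------------------------------
# Stage 1: depth back-projection
# ---------------------------------------------------------------------------

def depth_to_points(frame: FrameRecord, intr: CameraIntrinsics,
                    below_ground_tol: float = 0.05) -> PointCloud:
    """Back-project one depth frame to frame-local colorized points.

    x is across-row (image u axis), y along-row (image v axis), z up from
    the nominal ground: z = camera height − depth.  Pixels with no depth
    return or with depth more than ``below_ground_tol`` beyond the camera
    height (below ground) are dropped.
    """
    depth_m = frame.depth.astype(np.float64) / 1000.0
    v, u = np.indices(depth_m.shape)
    valid = (frame.depth > 0) & (depth_m <= intr.camera_height + below_ground_tol)
    if not valid.any():
        logger.warning("frame %d: no valid depth pixels", frame.frame_index)
        return PointCloud(np.empty((0, 3)))
    d = depth_m[valid]
    x = (u[valid] - intr.cx) * d / intr.fx
    y = (v[valid] - intr.cy) * d / intr.fy
    z = intr.camera_height - d
    colors = frame.color[valid]
    return PointCloud(np.column_stack([x, y, z]), colors)


# ---------------------------------------------------------------------------
# Stage 2: local track from GPS
# ---------------------------------------------------------------------------

def fit_local_track(fixes: Sequence[GeoFix]) -> LocalTrack:
    """Rotate UTM deltas into the plot-local frame (travel along +y).

    The travel direction is a total-least-squares (principal-axis) fit to the
    easting/northing scatter, oriented from the first toward the last fix.
    The rotation angle is measured from the north axis; its sign is chosen so
    the fitted direction maps to +y.  Altitude deltas pass through as local z.
    """
    if len(fixes) < 2:
        raise ValueError("need at least two fixes to fit a track")
    en = np.array([[f.easting, f.northing] for f in fixes], dtype=float)
    d = en - en.mean(axis=0)
    cov = d.T @ d
    if np.allclose(cov, 0.0):
        raise ValueError("all fixes coincident: travel direction undefined")
    _, vecs = np.linalg.eigh(cov)
    direction = vecs[:, -1]  # dominant principal axis (unit)
    travel = en[-1] - en[0]
    if direction @ travel < 0:
        direction = -direction
    theta = -np.arctan2(direction[0], direction[1])  # from north, travel -> +y
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    deltas = np.array(
        [[f.easting - fixes[0].easting,
          f.northing - fixes[0].northing,
          f.altitude - fixes[0].altitude] for f in fixes])
    return LocalTrack(theta_gl=float(theta), positions=deltas @ rot.T)


# ---------------------------------------------------------------------------
# Stage 3: ROI selection
# ---------------------------------------------------------------------------

def select_roi(cloud: PointCloud, dist_prev: float, dist_next: float,
               enclosure_width: float, camera_height: float,
               ) -> tuple[PointCloud, ROIBounds]:
    """Keep the slab of frame-local points this frame is responsible for.

    Across-row: half the enclosure width each side.  Along-row: half the
    distance to the previous/next acquisition position.  Vertical: ground to
    camera height.
    """
    bounds = ROIBounds(-enclosure_width / 2, enclosure_width / 2,
                       -dist_prev / 2, dist_next / 2,
                       0.0, camera_height)
    c = cloud.coords
    keep = ((c[:, 0] >= bounds.x_lower) & (c[:, 0] <= bounds.x_upper)
            & (c[:, 1] >= bounds.y_lower) & (c[:, 1] <= bounds.y_upper)
            & (c[:, 2] >= bounds.z_lower) & (c[:, 2] <= bounds.z_upper))
    return cloud.select(keep), bounds


# ---------------------------------------------------------------------------
# Stage 4: MLESAC ground plane and orientation adjustment
# ---------------------------------------------------------------------------

def _plane_from_points(p: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Least-squares plane (unit normal, offset) through points, +z oriented."""
    centroid = p.mean(axis=0)
    _, s, vt = np.linalg.svd(p - centroid, full_matrices=False)
    if s[-1] == s[0] == 0:
        return None
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
        return None
    return normal, float(normal @ centroid)


def fit_ground_plane_mlesac(cloud: PointCloud,
                            params: MLESACParams | None = None) -> GroundPlane:
    """Robust ground-plane detection by sample consensus.

    Three-point hypotheses are scored with the truncated-quadratic
    (maximum-likelihood-style) cost min(r², T²), T = 1.96·sigma; the best
    hypothesis is refit by least squares on its inliers.  The fit is reported
    as not found when the inlier fraction is below ``min_inlier_fraction`` or
    the fitted normal tilts more than ``max_tilt_deg`` from vertical —
    downstream then assumes the ground normal is the +z axis.
    """
    if params is None:
        params = MLESACParams()
    n = len(cloud)
    no_plane = GroundPlane(np.array([0.0, 0.0, 1.0]), 0.0, 0, False)
    if n < 3:
        return no_plane
    rng = np.random.default_rng(params.seed)
    pts = cloud.coords
    thresh = 1.96 * params.sigma
    best_cost = np.inf
    best_inliers: np.ndarray | None = None
    for _ in range(params.iterations):
        idx = rng.choice(n, size=3, replace=False)
        a, b, c = pts[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        r = np.abs((pts - a) @ normal)
        cost = np.minimum(r, thresh) ** 2
        total = cost.sum()
        if total < best_cost:
            best_cost = total
            best_inliers = r < thresh
    if best_inliers is None or best_inliers.sum() < 3:
        return no_plane
    fit = _plane_from_points(pts[best_inliers])
    if fit is None:
        return no_plane
    normal, offset = fit
    # one re-estimation pass with the refit plane's residuals
    r = np.abs(pts @ normal - offset)
    inliers = r < thresh
    if inliers.sum() >= 3:
        refit = _plane_from_points(pts[inliers])
        if refit is not None:
            normal, offset = refit
            r = np.abs(pts @ normal - offset)
            inliers = r < thresh
    count = int(inliers.sum())
    tilt = np.degrees(np.arccos(np.clip(normal[2], -1.0, 1.0)))
    found = (count / n >= params.min_inlier_fraction) and (tilt <= params.max_tilt_deg)
    return GroundPlane(normal, offset, count, found)


def adjust_orientation(roi: PointCloud, plane: GroundPlane) -> PointCloud:
    """Rotate an ROI so the detected ground normal becomes vertical.

    The tilt is split into its X-Z and Y-Z projections and removed by a
    rotation about y followed by a rotation about x (applied as one composed
    rigid rotation).  When no ground plane was found the cloud passes through
    unchanged.
    """
    if not plane.found:
        return roi
    nx, ny, nz = plane.normal
    theta_xz = np.arctan2(-nx, nz)  # tilt seen in the X-Z plane
    theta_yz = np.arctan2(-ny, nz)  # tilt seen in the Y-Z plane
    cx_, sx_ = np.cos(theta_yz), np.sin(theta_yz)
    cy_, sy_ = np.cos(theta_xz), np.sin(theta_xz)
    rot_y = np.array([[cy_, 0.0, sy_], [0.0, 1.0, 0.0], [-sy_, 0.0, cy_]])
    rot_x = np.array([[1.0, 0.0, 0.0], [0.0, cx_, sx_], [0.0, -sx_, cx_]])
    return roi.rotated(rot_y @ rot_x)


# ---------------------------------------------------------------------------
# Stage 5: stitching
# ---------------------------------------------------------------------------

def stitch_rois(rois: Sequence[PointCloud], track: LocalTrack) -> PointCloud:
    """Translate each ROI by its frame's local position and concatenate."""
    if len(rois) != len(track.positions):
        raise ValueError(
            f"{len(rois)} ROIs but {len(track.positions)} track positions")
    origin = track.positions[0]
    shifted = [roi.translated(pos - origin)
               for roi, pos in zip(rois, track.positions)]
    return PointCloud.concatenate(shifted)


# ---------------------------------------------------------------------------
# Full plot reconstruction
# ---------------------------------------------------------------------------

def reconstruct_plot(frames: Sequence[FrameRecord],
                     intr: CameraIntrinsics | None = None,
                     config: PipelineConfig | None = None,
                     ply_path: str | Path | None = None) -> PointCloud:
    """Compose the five reconstruction stages for one plot's frame sequence."""
    if not frames:
        raise ValueError("reconstruct_plot needs at least one frame")
    config = config or PipelineConfig()
    intr = intr or CameraIntrinsics.from_config(config)

    if len(frames) == 1:
        track = LocalTrack(0.0, np.zeros((1, 3)))
        gaps, med = np.empty(0), 0.4  # lone frame: default 0.2 m half-extent
    else:
        track = fit_local_track([f.fix for f in frames])
        gaps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
        med = float(np.median(gaps))

    rois: list[PointCloud] = []
    n = len(frames)
    for i, frame in enumerate(frames):
        cloud = depth_to_points(frame, intr)
        # end frames have no neighbor on one side: use the median gap
        d_prev = gaps[i - 1] if i > 0 else med
        d_next = gaps[i] if i < n - 1 else med
        roi, _ = select_roi(cloud, d_prev, d_next,
                            config.enclosure_width, intr.camera_height)
        plane = fit_ground_plane_mlesac(roi, config.mlesac)
        rois.append(adjust_orientation(roi, plane))

    stitched = stitch_rois(rois, track)
    if len(stitched) == 0:
        logger.warning("reconstructed plot cloud is empty")
    if ply_path is not None:
        write_ply(stitched, ply_path)
    return stitched
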