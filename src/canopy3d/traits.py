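"""Canopy-size trait extraction from segmented plot point clouds.

Static traits per plot and date (days after planting, DAP):

* maximum / mean canopy height — extremes and average of point heights;
* cumulative height profile — the 5th…95th height percentiles in 5% steps
  (19 values), a compact multivariate descriptor of the canopy envelope;
* maximum / mean canopy width — the along-row extent is split into ten
  segments and the across-row spread measured in each;
* projected canopy area — area of the planar boundary (alpha shape, or the
  convex hull as alpha → ∞) of the points projected to the ground plane;
* convex and concave canopy volume — the 3D convex hull and a 3D alpha
  shape of the canopy points.

Dynamic traits are per-period growth rates: the trait difference between two
consecutive observation dates divided by the elapsed days, with the first
period anchored at planting (trait 0 at DAP 0).

Undefined traits (empty cloud, degenerate geometry) are NaN, never zero, so
downstream regressions drop them instead of absorbing fake zeros.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .reconstruction import PointCloud

logger = logging.getLogger("canopy3d")

PROFILE_PERCENTILES = np.arange(5, 100, 5)  # 5, 10, ..., 95


# ---------------------------------------------------------------------------
# One-dimensional traits
# ---------------------------------------------------------------------------

def canopy_heights(cloud: PointCloud) -> tuple[float, float]:
    """(max, mean) of point heights; NaN for an empty cloud."""
    if len(cloud) == 0:
        return float("nan"), float("nan")
    z = cloud.coords[:, 2]
    return float(z.max()), float(z.mean())


def cumulative_height_profile(cloud: PointCloud) -> np.ndarray:
    """Heights at the 5th–95th percentiles (5% steps, 19 values)."""
    if len(cloud) == 0:
        return np.full(len(PROFILE_PERCENTILES), np.nan)
    return np.percentile(cloud.coords[:, 2], PROFILE_PERCENTILES)


def canopy_widths(cloud: PointCloud, n_segments: int = 10,
                  include_empty: bool = False) -> tuple[float, float]:
    """(max, mean) across-row spread over along-row segments.

    The y extent is split into ``n_segments`` equal bins; each non-empty
    bin's width is max(x) − min(x) of its points.  Empty bins are excluded
    from the statistics unless ``include_empty`` is set (then they count as
    zero width in the mean) — sparse stands would otherwise drag the mean to
    zero.
    """
    if len(cloud) == 0:
        return float("nan"), float("nan")
    c = cloud.coords
    y0, y1 = c[:, 1].min(), c[:, 1].max()
    if y1 == y0:
        w = float(c[:, 0].max() - c[:, 0].min())
        return w, w
    edges = np.linspace(y0, y1, n_segments + 1)
    seg = np.minimum(np.searchsorted(edges, c[:, 1], side="right") - 1,
                     n_segments - 1)
    widths = []
    for s in range(n_segments):
        xs = c[seg == s, 0]
        if xs.size:
            widths.append(float(xs.max() - xs.min()))
        elif include_empty:
            widths.append(0.0)
    return float(np.max(widths)), float(np.mean(widths))


# ---------------------------------------------------------------------------
# Alpha shapes (2D boundary area, 3D concave volume)
# ---------------------------------------------------------------------------

def _triangle_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each 2D triangle (R = abc / 4A); degenerate -> inf."""
    a = np.linalg.norm(pts[simplices[:, 0]] - pts[simplices[:, 1]], axis=1)
    b = np.linalg.norm(pts[simplices[:, 1]] - pts[simplices[:, 2]], axis=1)
    c = np.linalg.norm(pts[simplices[:, 2]] - pts[simplices[:, 0]], axis=1)
    s = (a + b + c) / 2.0
    area2 = np.maximum(s * (s - a) * (s - b) * (s - c), 0.0)
    area = np.sqrt(area2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4.0 * area)
    r[~np.isfinite(r)] = np.inf
    return r


def _triangle_areas(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v1 = pts[simplices[:, 1]] - pts[simplices[:, 0]]
    v2 = pts[simplices[:, 2]] - pts[simplices[:, 0]]
    return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def _tet_volumes(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v = pts[simplices[:, 1:]] - pts[simplices[:, [0]]]
    return np.abs(np.linalg.det(v)) / 6.0


def _tet_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron via its circumcenter; degenerate -> inf."""
    p0 = pts[simplices[:, 0]]
    d = pts[simplices[:, 1:]] - p0[:, None, :]          # (m, 3, 3)
    rhs = 0.5 * np.einsum("mij,mij->mi", d, d)          # (m, 3)
    det = np.linalg.det(d)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-14
    if ok.any():
        centers = np.linalg.solve(d[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def projected_canopy_area(cloud: PointCloud,
                          alpha: float = np.inf) -> float:
    """Area of the planar boundary of the canopy's ground projection.

    The points are projected to the X-Y plane and triangulated; triangles
    with circumradius at most ``alpha`` are kept and their areas summed
    (Delaunay triangles partition the convex hull, so the sum is the area of
    the alpha-shape region; alpha = inf gives the convex-hull area).  Returns
    NaN for fewer than 3 points and 0 for a degenerate (collinear) cloud.
    """
    if len(cloud) < 3:
        return float("nan")
    xy = cloud.coords[:, :2]
    try:
        tri = Delaunay(xy)
    except QhullError:
        logger.warning("degenerate planar projection: area set to 0")
        return 0.0
    keep = _triangle_circumradii(xy, tri.simplices) <= alpha
    return float(_triangle_areas(xy, tri.simplices[keep]).sum())


def canopy_volumes(cloud: PointCloud,
                   alpha: float = 0.10) -> tuple[float, float]:
    """(convex, concave) canopy volume in cubic meters.

    Convex is the 3D convex-hull volume; concave is the volume of the 3D
    alpha shape — Delaunay tetrahedra with circumradius at most ``alpha``.
    The concave volume never exceeds the convex one.  Returns NaN pairs for
    fewer than 4 points and zeros for a coplanar cloud.
    """
    if len(cloud) < 4:
        return float("nan"), float("nan")
    pts = cloud.coords
    try:
        hull = ConvexHull(pts)
        if np.isinf(alpha):
            return float(hull.volume), float(hull.volume)
        tri = Delaunay(pts)
    except QhullError:
        logger.warning("degenerate (coplanar) cloud: volumes set to 0")
        return 0.0, 0.0
    keep = _tet_circumradii(pts, tri.simplices) <= alpha
    concave = float(_tet_volumes(pts, tri.simplices[keep]).sum())
    return float(hull.volume), min(concave, float(hull.volume))


# ---------------------------------------------------------------------------
# Static trait table
# ---------------------------------------------------------------------------

def compute_static_traits(cloud: PointCloud, plot_id: str = "", dap: int | None = None,
                          alpha: float = 0.10, n_segments: int = 10,
                          include_empty: bool = False,
                          convex_boundary: bool = False) -> dict:
    """All static traits of one plot cloud as a flat record (NaN = undefined)."""
    max_h, mean_h = canopy_heights(cloud)
    profile = cumulative_height_profile(cloud)
    max_w, mean_w = canopy_widths(cloud, n_segments, include_empty)
    area = projected_canopy_area(
        cloud, alpha=np.inf if convex_boundary else alpha)
    convex_v, concave_v = canopy_volumes(cloud, alpha)
    rec = {
        "plot_id": plot_id,
        "dap": dap,
        "max_height": max_h,
        "mean_height": mean_h,
        "max_width": max_w,
        "mean_width": mean_w,
        "projected_area": area,
        "convex_volume": convex_v,
        "concave_volume": concave_v,
    }
    for p, v in zip(PROFILE_PERCENTILES, profile):
        rec[f"height_p{p:02d}"] = float(v)
    return rec


def traits_table(records: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(records))


# ---------------------------------------------------------------------------
# Growth rates
# ---------------------------------------------------------------------------

def growth_rates(table: pd.DataFrame,
                 trait_columns: Sequence[str] | None = None,
                 planting_origin: bool = True) -> pd.DataFrame:
    """Per-plot, per-period growth rates between consecutive observations.

    ``table`` is a static-trait table with ``plot_id`` and ``dap`` columns.
    For each plot and trait column, the rate over a period is
    (T(d_last) − T(d_first)) / (d_last − d_first) in trait units per day.
    With ``planting_origin`` the first period P1 runs from planting (trait 0
    at DAP 0) to the first observation.  Duplicate DAPs for a plot are an
    error; a NaN trait at either endpoint yields a NaN rate.
    """
    if trait_columns is None:
        trait_columns = [c for c in table.columns
                         if c not in ("plot_id", "dap", "genotype")]
    rows = []
    for plot_id, sub in table.groupby("plot_id", sort=False):
        sub = sub.sort_values("dap")
        daps = sub["dap"].to_numpy()
        if len(np.unique(daps)) != len(daps):
            raise ValueError(f"plot {plot_id}: duplicate DAP observations")
        for trait in trait_columns:
            vals = sub[trait].to_numpy(float)
            if planting_origin:
                d = np.concatenate([[0.0], daps])
                v = np.concatenate([[0.0], vals])
            else:
                d, v = daps.astype(float), vals
            for k in range(1, len(d)):
                rows.append({
                    "plot_id": plot_id,
                    "trait": trait,
                    "period": f"P{k}",
                    "dap_first": d[k - 1],
                    "dap_last": d[k],
                    "rate": (v[k] - v[k - 1]) / (d[k] - d[k - 1]),
                })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.DataFrame(rows)
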