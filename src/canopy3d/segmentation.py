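"""Canopy segmentation: isolate the crop canopy from ground, frame and weeds.

Two-stage segmentation of a reconstructed plot cloud:

* **Vegetation filter** — excess green index ExG = 2g − r − b on
  sum-normalized (chromatic) RGB; points above a threshold (default 0.15)
  are vegetation.  ExG is invariant to brightness scaling, so shadows and
  exposure differences do not move points across the cut.
* **Canopy vs weed** — the vegetation cloud is rasterized to a max-height
  grid.  Short in-row weeds fall below a height-percentile binarization;
  small connected components below an area threshold are discarded; tall
  between-plot weeds survive both but sit away from the largest component
  (the main canopy) and are rejected by a centroid-distance rule.  Pixels of
  the accepted components are back-projected to the vegetation points of
  their grid cells.

The module also scores a predicted canopy mask against ground truth
(accuracy / false-positive rate / false-negative rate, with the clean /
weed-under-removal / canopy-over-removal categories).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .config import PipelineConfig
from .reconstruction import PointCloud

logger = logging.getLogger("canopy3d")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DepthRaster:
    """Max-height rasterization of a point cloud.

    ``values[i, j]`` is the maximum z (meters) among the points of cell
    (i, j), NaN where the cell is empty; axis 0 bins x, axis 1 bins y.
    ``point_cell`` maps every input point to its flat cell index, so raster
    pixels can be back-projected to the exact point sets they summarize.
    """

    values: np.ndarray        # (nx, ny) float, NaN = empty
    grid_size: float          # m
    x_lower: float
    y_lower: float
    point_cell: np.ndarray    # (n_points,) flat cell index per source point

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def points_in_cells(self, flat_cells: np.ndarray) -> np.ndarray:
        """Boolean mask over source points belonging to the given flat cells."""
        return np.isin(self.point_cell, flat_cells)


@dataclass
class ComponentTable:
    """Connected components of the binarized raster with filter/class flags."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["label", "area", "centroid_i", "centroid_j",
                 "min_i", "min_j", "max_i", "max_j",
                 "included", "cls", "is_main"]))
    labels_image: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SegmentationScore:
    accuracy: float   # percent
    fpr: float        # percent, weed pixels kept as canopy
    fnr: float        # percent, canopy pixels removed as weed
    category: str     # clean | weed_under_removal | canopy_over_removal | other


# ---------------------------------------------------------------------------
# Vegetation filter
# ---------------------------------------------------------------------------

def excess_green(colors: np.ndarray) -> np.ndarray:
    """ExG = 2g − r − b on chromatic coordinates; all-zero color gives 0."""
    rgb = np.asarray(colors, dtype=np.float64)
    total = rgb.sum(axis=-1)
    safe = np.where(total > 0, total, 1.0)
    r, g, b = (rgb[..., k] / safe for k in range(3))
    return np.where(total > 0, 2.0 * g - r - b, 0.0)


def excess_green_filter(cloud: PointCloud, threshold: float = 0.15) -> PointCloud:
    """Keep points whose excess-green index exceeds the threshold."""
    return cloud.select(excess_green(cloud.colors) > threshold)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_max_height(cloud: PointCloud, grid_size: float = 0.05) -> DepthRaster:
    """Bin points on a grid anchored at the cloud minimum; cell value = max z.

    Cells are half-open intervals [lower + k·S, lower + (k+1)·S) with the
    global maximum closed into the last cell, so every point maps to exactly
    one cell.
    """
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    if grid_size <= 0:
        raise ValueError("grid size must be positive")
    c = cloud.coords
    x_lower, y_lower = c[:, 0].min(), c[:, 1].min()
    nx = max(1, int(np.ceil((c[:, 0].max() - x_lower) / grid_size)))
    ny = max(1, int(np.ceil((c[:, 1].max() - y_lower) / grid_size)))
    i = np.minimum(((c[:, 0] - x_lower) / grid_size).astype(np.int64), nx - 1)
    j = np.minimum(((c[:, 1] - y_lower) / grid_size).astype(np.int64), ny - 1)
    flat = i * ny + j
    values = np.full(nx * ny, -np.inf)
    np.maximum.at(values, flat, c[:, 2])
    values[np.isneginf(values)] = np.nan
    return DepthRaster(values.reshape(nx, ny), grid_size,
                       float(x_lower), float(y_lower), flat)


def binarize_by_height_percentile(raster: DepthRaster,
                                  pct: float = 30.0) -> np.ndarray:
    """Threshold the raster at the given percentile of its non-empty cells.

    Returns a boolean mask: True where the cell value is at or above the
    percentile (linear interpolation); empty cells are False.
    """
    filled = raster.values[~np.isnan(raster.values)]
    if filled.size == 0:
        raise ValueError("raster has no non-empty cells")
    threshold = np.percentile(filled, pct)
    mask = np.zeros(raster.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[~np.isnan(raster.values)] = \
            raster.values[~np.isnan(raster.values)] >= threshold
    return mask


# ---------------------------------------------------------------------------
# Connected components: area filter and position-based classification
# ---------------------------------------------------------------------------

def label_and_filter_components(mask: np.ndarray,
                                area_threshold: int = 15) -> ComponentTable:
    """8-connected labeling; components with area >= threshold are included."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    rows = []
    for rp in measure.regionprops(labels):
        rows.append({
            "label": rp.label,
            "area": int(rp.area),
            "centroid_i": rp.centroid[0],
            "centroid_j": rp.centroid[1],
            "min_i": rp.bbox[0], "min_j": rp.bbox[1],
            "max_i": rp.bbox[2], "max_j": rp.bbox[3],
            "included": int(rp.area) >= area_threshold,
            "cls": False,
            "is_main": False,
        })
    if not rows:
        return ComponentTable(labels_image=labels)
    return ComponentTable(pd.DataFrame(rows), labels)


def classify_components(table: ComponentTable, row_axis: int = 1) -> ComponentTable:
    """Classify included components as canopy or weed by position.

    The included component with the largest area (ties: lowest label) is the
    main canopy.  Any other included component is canopy iff the Euclidean
    distance between its centroid and the main canopy's centroid is at most
    the main canopy's bounding-box extent along the row axis (in cells);
    farther components are between-plot weeds.
    """
    df = table.df
    if df.empty or not df["included"].any():
        return table
    inc = df[df["included"]]
    main_idx = inc.sort_values(["area", "label"],
                               ascending=[False, True]).index[0]
    if row_axis == 1:
        w_b = df.loc[main_idx, "max_j"] - df.loc[main_idx, "min_j"]
    else:
        w_b = df.loc[main_idx, "max_i"] - df.loc[main_idx, "min_i"]
    cm = df.loc[main_idx, ["centroid_i", "centroid_j"]].to_numpy(float)
    cent = df[["centroid_i", "centroid_j"]].to_numpy(float)
    dist = np.linalg.norm(cent - cm, axis=1)
    df = df.copy()
    df["cls"] = df["included"] & (dist <= w_b)
    df.loc[main_idx, "cls"] = True
    df["is_main"] = False
    df.loc[main_idx, "is_main"] = True
    return ComponentTable(df, table.labels_image)


def backproject_canopy(cloud: PointCloud, raster: DepthRaster,
                       table: ComponentTable) -> PointCloud:
    """Return the points of every grid cell covered by a canopy component."""
    df = table.df
    if df.empty or not df["cls"].any() or table.labels_image is None:
        logger.warning("no canopy components: returning an empty cloud")
        return PointCloud(np.empty((0, 3)))
    keep_labels = df.loc[df["cls"], "label"].to_numpy()
    cell_mask = np.isin(table.labels_image, keep_labels)
    flat_cells = np.flatnonzero(cell_mask.ravel())
    return cloud.select(raster.points_in_cells(flat_cells))


# ---------------------------------------------------------------------------
# Full segmentation and scoring
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """All intermediates of one plot's canopy segmentation."""

    vegetation: PointCloud          # after the excess-green filter
    raster: DepthRaster | None      # max-height grid of the vegetation cloud
    mask: np.ndarray | None         # height-percentile binarization
    components: ComponentTable | None
    canopy: PointCloud              # back-projected canopy points
    canopy_cells: np.ndarray | None  # grid cells classified as canopy

    def predicted_mask(self) -> np.ndarray:
        if self.canopy_cells is None:
            raise ValueError("segmentation produced no raster")
        return self.canopy_cells


def segment_plot(cloud: PointCloud, config: PipelineConfig | None = None,
                 ) -> SegmentationResult:
    """Run the full canopy segmentation, keeping stage intermediates."""
    config = config or PipelineConfig()
    veg = excess_green_filter(cloud, config.exg_threshold)
    empty = PointCloud(np.empty((0, 3)))
    if len(veg) == 0:
        logger.warning("no vegetation points after excess-green filtering")
        return SegmentationResult(veg, None, None, None, empty, None)
    raster = rasterize_max_height(veg, config.grid_size)
    mask = binarize_by_height_percentile(raster, config.binarize_percentile)
    table = label_and_filter_components(mask, config.cc_area_threshold)
    table = classify_components(table, row_axis=config.main_cc_axis)
    canopy = backproject_canopy(veg, raster, table)
    cells = np.zeros(raster.shape, dtype=bool)
    if not table.df.empty and table.df["cls"].any():
        keep = table.df.loc[table.df["cls"], "label"].to_numpy()
        cells = np.isin(table.labels_image, keep)
    return SegmentationResult(veg, raster, mask, table, canopy, cells)


def segment_canopy(cloud: PointCloud, config: PipelineConfig | None = None,
                   ) -> PointCloud:
    """Compose vegetation filtering and canopy/weed separation for one plot."""
    return segment_plot(cloud, config).canopy


def score_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegmentationScore:
    """Confusion-matrix scoring of a canopy mask against ground truth.

    Both masks are boolean arrays over the same vegetation pixels (True =
    canopy).  Accuracy = (TP+TN)/total, FPR = FP/(FP+TN) (weed kept as
    canopy), FNR = FN/(FN+TP) (canopy removed), all in percent; empty
    denominators count as 0.  Categories, in precedence order: clean
    (accuracy >= 95%), weed_under_removal (FPR >= 10%), canopy_over_removal
    (FNR >= 10%), else other.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks differ in shape")
    if truth.size == 0:
        raise ValueError("empty truth mask")
    tp = float(np.sum(pred & truth))
    tn = float(np.sum(~pred & ~truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    accuracy = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    fpr = 100.0 * fp / (fp + tn) if (fp + tn) > 0 else 0.0
    fnr = 100.0 * fn / (fn + tp) if (fn + tp) > 0 else 0.0
    if accuracy >= 95.0:
        category = "clean"
    elif fpr >= 10.0:
        category = "weed_under_removal"
    elif fnr >= 10.0:
        category = "canopy_over_removal"
    else:
        category = "other"
    return SegmentationScore(accuracy, fpr, fnr, category)
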