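"""Vegetation filtering, rasterization, component rules, scoring."""

from __future__ import annotations

import numpy as np
import pytest

import canopy3d as c3
from canopy3d.segmentation import segment_plot
from canopy3d.synthetic import (
    LABEL_WEED,
    scene_config,
    truth_cell_mask,
    truth_point_labels,
)
from conftest import local_origin, random_cloud, reconstruct_groups


# ---------------------------------------------------------------------------
# Excess-green filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rgb, exg", [
    ((0, 255, 0), 2.0),        # pure green: chromatic extreme
    ((120, 120, 120), 0.0),    # gray: symmetric channels
    ((100, 150, 50), 0.5),     # 2*(150/300) - 100/300 - 50/300
    ((0, 0, 0), 0.0),          # all-zero color defined as 0
])
def test_excess_green_values(rgb, exg):
    assert c3.excess_green(np.array([rgb])) == pytest.approx(exg)


def test_excess_green_filter_keeps_vegetation():
    cloud = c3.PointCloud(np.zeros((3, 3)),
                          [[0, 255, 0], [120, 120, 120], [100, 150, 50]])
    kept = c3.excess_green_filter(cloud, threshold=0.15)
    assert len(kept) == 2


def test_excess_green_brightness_invariance():
    rng = np.random.default_rng(21)
    colors = rng.integers(10, 256, (500, 3))
    dimmed = (colors * 0.5).astype(np.uint8)
    # chromatic normalization: scaling all channels leaves ExG unchanged
    # (tolerance covers the uint8 rounding of the halved channels)
    np.testing.assert_allclose(c3.excess_green(colors.astype(np.uint8)),
                               c3.excess_green(dimmed), atol=0.03)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def test_rasterize_single_point():
    raster = c3.rasterize_max_height(c3.PointCloud([[0.01, 0.01, 0.5]]), 0.05)
    assert raster.shape == (1, 1)
    assert raster.values[0, 0] == pytest.approx(0.5)


def test_rasterize_same_cell_takes_max():
    cloud = c3.PointCloud([[0.01, 0.01, 0.5], [0.02, 0.03, 0.8]])
    raster = c3.rasterize_max_height(cloud, 0.05)
    assert raster.shape == (1, 1)
    assert raster.values[0, 0] == pytest.approx(0.8)


def test_rasterize_matches_brute_force():
    rng = np.random.default_rng(22)
    cloud = random_cloud(rng, 10000, box=((0, 2.0), (0, 3.0), (0, 1.0)))
    s = 0.05
    raster = c3.rasterize_max_height(cloud, s)
    c = cloud.coords
    x0, y0 = c[:, 0].min(), c[:, 1].min()
    nx, ny = raster.shape
    expected = np.full((nx, ny), np.nan)
    for k in range(len(c)):  # O(N) brute force, independent of the module
        i = min(int((c[k, 0] - x0) / s), nx - 1)
        j = min(int((c[k, 1] - y0) / s), ny - 1)
        if np.isnan(expected[i, j]) or c[k, 2] > expected[i, j]:
            expected[i, j] = c[k, 2]
    np.testing.assert_allclose(raster.values, expected, equal_nan=True)
    # every point maps to exactly one cell
    assert raster.point_cell.shape == (len(c),)
    assert raster.point_cell.min() >= 0
    assert raster.point_cell.max() < nx * ny


def test_rasterize_rejects_empty_cloud():
    with pytest.raises(ValueError):
        c3.rasterize_max_height(c3.PointCloud(np.empty((0, 3))), 0.05)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def test_binarize_all_equal_sets_every_filled_cell():
    cloud = c3.PointCloud([[0.0, 0.0, 0.5], [0.2, 0.2, 0.5]])
    raster = c3.rasterize_max_height(cloud, 0.05)
    mask = c3.binarize_by_height_percentile(raster, 30)
    filled = ~np.isnan(raster.values)
    assert mask[filled].all()
    assert not mask[~filled].any()


def test_binarize_percentile_linear_interpolation():
    coords = [[0.06 * i, 0.0, float(v)] for i, v in enumerate(range(1, 11))]
    raster = c3.rasterize_max_height(c3.PointCloud(coords), 0.05)
    mask = c3.binarize_by_height_percentile(raster, 30)
    # 30th percentile of 1..10 = 3.7, so cells 4..10 survive
    assert mask.sum() == 7


def test_binarize_single_cell():
    raster = c3.rasterize_max_height(c3.PointCloud([[0, 0, 1.0]]), 0.05)
    assert c3.binarize_by_height_percentile(raster, 30).sum() == 1


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

def _mask_with_blobs(shape, blobs):
    mask = np.zeros(shape, dtype=bool)
    for (i0, j0, h, w) in blobs:
        mask[i0:i0 + h, j0:j0 + w] = True
    return mask


def test_component_area_filter():
    mask = _mask_with_blobs((30, 30), [(2, 2, 4, 5), (20, 20, 1, 5)])
    table = c3.label_and_filter_components(mask, area_threshold=15)
    by_area = table.df.sort_values("area", ascending=False)
    assert list(by_area["area"]) == [20, 5]
    assert list(by_area["included"]) == [True, False]


def test_component_exactly_at_threshold_included():
    mask = _mask_with_blobs((20, 20), [(2, 2, 3, 5)])  # area 15
    table = c3.label_and_filter_components(mask, area_threshold=15)
    assert table.df["included"].all()


def test_empty_mask_gives_empty_table():
    table = c3.label_and_filter_components(np.zeros((10, 10), dtype=bool))
    assert len(table) == 0


def test_classification_by_distance_to_main():
    # main blob spans 11 columns (row axis); neighbors at 8 and 25 cells
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:15, 10:21] = True             # main: area 55, centroid j=15
    mask[11:15, 26:31] = True             # centroid j=28, dist ~ 13 > 10? no:
    mask[40:44, 40:45] = True             # far blob
    table = c3.classify_components(
        c3.label_and_filter_components(mask, area_threshold=15), row_axis=1)
    df = table.df.set_index("label")
    main_label = df.index[df["is_main"]][0]
    assert df.loc[main_label, "area"] == 55
    w_b = df.loc[main_label, "max_j"] - df.loc[main_label, "min_j"]
    cm = df.loc[main_label, ["centroid_i", "centroid_j"]].to_numpy(float)
    for label, row in df.iterrows():
        d = np.hypot(row["centroid_i"] - cm[0], row["centroid_j"] - cm[1])
        if row["included"]:
            assert row["cls"] == (label == main_label or d <= w_b)


def test_classification_tie_breaks_to_lowest_label():
    mask = _mask_with_blobs((40, 40), [(2, 2, 4, 4), (20, 20, 4, 4)])
    table = c3.classify_components(
        c3.label_and_filter_components(mask, area_threshold=15))
    df = table.df
    assert df.loc[df["is_main"], "label"].item() == df["label"].min()


def test_single_component_is_main_canopy():
    mask = _mask_with_blobs((20, 20), [(5, 5, 5, 5)])
    table = c3.classify_components(
        c3.label_and_filter_components(mask, area_threshold=15))
    assert table.df["cls"].all() and table.df["is_main"].all()


def test_component_flags_match_hand_computation_on_random_masks():
    """Inclusion and class flags equal a brute-force recomputation."""
    rng = np.random.default_rng(23)
    from scipy import ndimage

    for _ in range(25):
        mask = rng.random((40, 50)) < 0.12
        table = c3.classify_components(
            c3.label_and_filter_components(mask, area_threshold=15),
            row_axis=1)
        # independent oracle: scipy labeling + first-principles flags
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n == 0:
            assert len(table) == 0
            continue
        areas = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
        included = areas >= 15
        df = table.df.sort_values("label")
        assert list(df["included"]) == list(included)
        if not included.any():
            assert not df["cls"].any()
            continue
        main = int(np.flatnonzero(
            areas == areas[included].max())[0])  # lowest label wins ties
        js = np.flatnonzero((labels == main + 1).any(axis=0))
        w_b = js.max() - js.min() + 1  # bounding-box width in cells
        cm = np.asarray(centroids[main])
        for k in range(n):
            d = np.hypot(*(np.asarray(centroids[k]) - cm))
            expect = bool(included[k]) and (k == main or d <= w_b)
            assert bool(df.iloc[k]["cls"]) == expect


# ---------------------------------------------------------------------------
# Back-projection
# ---------------------------------------------------------------------------

def test_backprojection_round_trip_conserves_points():
    rng = np.random.default_rng(24)
    cloud = random_cloud(rng, 2000, box=((0, 1), (0, 1), (0.5, 1.0)))
    raster = c3.rasterize_max_height(cloud, 0.05)
    mask = np.ones(raster.shape, dtype=bool)
    table = c3.classify_components(
        c3.label_and_filter_components(mask, area_threshold=1))
    out = c3.backproject_canopy(cloud, raster, table)
    assert len(out) == len(cloud)


def test_backprojection_excludes_rejected_component():
    # two separated clusters; drop the smaller one and check set difference
    a = np.column_stack([np.random.default_rng(25).uniform(0, 0.3, (400, 2)),
                         np.full(400, 0.8)])
    b = np.column_stack([np.random.default_rng(26).uniform(2.0, 2.1, (30, 2)),
                         np.full(30, 0.9)])
    cloud = c3.PointCloud(np.vstack([a, b]))
    raster = c3.rasterize_max_height(cloud, 0.05)
    mask = c3.binarize_by_height_percentile(raster, 0)
    table = c3.classify_components(
        c3.label_and_filter_components(mask, area_threshold=15))
    out = c3.backproject_canopy(cloud, raster, table)
    # the small distant cluster is not the main canopy and sits farther than
    # the main bounding-box extent: its points must be absent
    assert len(out) == 400
    assert out.coords[:, 0].max() < 1.0


def test_backprojected_cloud_is_subset_of_input():
    rng = np.random.default_rng(27)
    cloud = random_cloud(rng, 3000, box=((0, 2), (0, 2), (0, 1)))
    seg = c3.segment_canopy(cloud)
    assert len(seg) <= len(cloud)


# ---------------------------------------------------------------------------
# Full segmentation on simulated plots
# ---------------------------------------------------------------------------

def test_segmentation_removes_in_row_weeds(field_session):
    """Short in-row weeds are absent from the segmented canopy cloud."""
    spec, session_dir, _ = field_session
    groups, clouds, cfg = reconstruct_groups(spec, session_dir)
    e0, n0, _ = spec.base_utm()
    for pid, cloud in clouds.items():
        res = segment_plot(cloud, cfg)
        ox, oy = local_origin(spec, groups[pid])
        labels = truth_point_labels(
            spec, res.canopy.coords[:, 0] + ox, res.canopy.coords[:, 1] + oy)
        weed_fraction = np.mean(labels == LABEL_WEED)
        assert weed_fraction < 0.05
        # anti-extensive pipeline: canopy ⊆ vegetation ⊆ input
        assert len(res.canopy) <= len(res.vegetation) <= len(cloud)


def test_position_rule_removes_tall_between_plot_weed(tmp_path):
    """A tall alley weed beyond the canopy extent is rejected by position."""
    plants = [c3.Solid("ellipsoid", 0.0, 0.15 + 0.15 * k, 0.7, 0.3)
              for k in range(6)]                       # short stand: 1.2 m
    weed = c3.Solid("ellipsoid", 0.0, 3.25, 1.0, 0.3, label="weed")
    spec = c3.SceneSpec(
        plots=[c3.synthetic.PlotSpec("plot01", 0, 0.0, 3.05, 0.0)],
        solids=plants + [weed], depth_sigma=0.0, gps_sigma=0.0, seed=2)
    c3.render_frames(spec, tmp_path)
    groups, clouds, cfg = reconstruct_groups(spec, tmp_path)
    res = segment_plot(clouds["plot01"], cfg)
    ox, oy = local_origin(spec, groups["plot01"])
    labels = truth_point_labels(
        spec, res.canopy.coords[:, 0] + ox, res.canopy.coords[:, 1] + oy)
    assert np.mean(labels == LABEL_WEED) < 0.01
    # the weed was visible in the vegetation cloud before segmentation
    veg_labels = truth_point_labels(
        spec, res.vegetation.coords[:, 0] + ox,
        res.vegetation.coords[:, 1] + oy)
    assert (veg_labels == LABEL_WEED).sum() > 100


def test_weed_free_plot_segmentation_keeps_tall_vegetation(
        clean_noisefree_session):
    spec, session_dir, _ = clean_noisefree_session
    _, clouds, cfg = reconstruct_groups(spec, session_dir)
    res = segment_plot(clouds["plot01"], cfg)
    # with no weeds, segmentation reduces to the height binarization:
    # everything above the height threshold survives
    thr = np.nanpercentile(res.raster.values, cfg.binarize_percentile)
    tall_cells = np.nan_to_num(res.raster.values, nan=-np.inf) >= thr + 0.05
    assert res.canopy_cells[tall_cells].mean() > 0.99


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def test_perfect_prediction_is_clean():
    truth = np.array([[1, 1, 0], [0, 1, 0]], dtype=bool)
    score = c3.score_segmentation(truth, truth)
    assert score.accuracy == 100.0
    assert score.fpr == 0.0 and score.fnr == 0.0
    assert score.category == "clean"


def test_confusion_arithmetic():
    truth = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
    pred = truth.copy()
    pred[90:100] = False  # 10 FN
    pred[100:120] = True  # 20 FP
    score = c3.score_segmentation(pred, truth)
    assert score.accuracy == pytest.approx(85.0)
    assert score.fpr == pytest.approx(20.0)
    assert score.fnr == pytest.approx(10.0)
    assert score.category == "weed_under_removal"


def test_all_canopy_removed_is_over_removal():
    truth = np.ones(50, dtype=bool)
    truth[:10] = False
    score = c3.score_segmentation(np.zeros(50, dtype=bool), truth)
    assert score.fnr == 100.0
    assert score.category == "canopy_over_removal"


def test_empty_truth_rejected():
    with pytest.raises(ValueError):
        c3.score_segmentation(np.empty(0, bool), np.empty(0, bool))


def test_category_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(28)
    for _ in range(200):
        truth = rng.random(300) < rng.uniform(0.2, 0.8)
        pred = truth ^ (rng.random(300) < rng.uniform(0, 0.3))
        if not truth.any() and not pred.any():
            continue
        s = c3.score_segmentation(pred, truth)
        tp = np.sum(pred & truth)
        tn = np.sum(~pred & ~truth)
        fp = np.sum(pred & ~truth)
        fn = np.sum(~pred & truth)
        acc = 100 * (tp + tn) / 300
        fpr = 100 * fp / (fp + tn) if fp + tn else 0.0
        fnr = 100 * fn / (fn + tp) if fn + tp else 0.0
        expect = ("clean" if acc >= 95 else
                  "weed_under_removal" if fpr >= 10 else
                  "canopy_over_removal" if fnr >= 10 else "other")
        assert s.accuracy == pytest.approx(acc)
        assert s.fpr == pytest.approx(fpr)
        assert s.fnr == pytest.approx(fnr)
        assert s.category == expect
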