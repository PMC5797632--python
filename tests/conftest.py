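"""Shared fixtures: rendered virtual-field sessions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import canopy3d as c3
from canopy3d.synthetic import scene_config


@pytest.fixture(scope="session")
def field_session(tmp_path_factory):
    """Two weedy plots under the default (noisy) scanning conditions."""
    spec = c3.default_field_scene(seed=0)
    out = tmp_path_factory.mktemp("field_session")
    meta = c3.render_frames(spec, out)
    return spec, out, meta


@pytest.fixture(scope="session")
def weedy_noisefree_session(tmp_path_factory):
    """Same weedy field without sensor noise (exact geometry)."""
    spec = c3.default_field_scene(seed=0, noise=False)
    out = tmp_path_factory.mktemp("weedy_nf_session")
    meta = c3.render_frames(spec, out)
    return spec, out, meta


@pytest.fixture(scope="session")
def clean_noisefree_session(tmp_path_factory):
    """One weed-free plot, noise-free: ground truth for trait recovery."""
    spec = c3.default_field_scene(seed=3, n_plots=1, inrow_weeds_per_plot=0,
                                  alley_weeds=False, noise=False)
    out = tmp_path_factory.mktemp("clean_nf_session")
    meta = c3.render_frames(spec, out)
    return spec, out, meta


@pytest.fixture(scope="session")
def flat_session(tmp_path_factory):
    """One empty plot (bare ground), noise-free: pure plane geometry."""
    spec = c3.default_field_scene(seed=5, n_plots=1, plants_per_plot=0,
                                  inrow_weeds_per_plot=0, alley_weeds=False,
                                  noise=False)
    out = tmp_path_factory.mktemp("flat_session")
    meta = c3.render_frames(spec, out)
    return spec, out, meta


def reconstruct_groups(spec, session_dir):
    """Load a rendered session and reconstruct every plot."""
    frames = c3.load_session(session_dir)
    groups = c3.group_frames_by_plot(frames, c3.scene_layout(spec))
    cfg = scene_config(spec)
    intr = c3.CameraIntrinsics.from_config(cfg)
    clouds = {pid: c3.reconstruct_plot(frs, intr, cfg)
              for pid, frs in groups.items() if frs}
    return groups, clouds, cfg


def local_origin(spec, plot_frames):
    """World (x, y) of a plot's local origin (first frame position)."""
    e0, n0, _ = spec.base_utm()
    f = plot_frames[0].fix
    return f.easting - e0, f.northing - n0


def random_cloud(rng: np.random.Generator, n: int = 500,
                 box=((-1, 1), (-1, 1), (0, 2))) -> c3.PointCloud:
    coords = np.column_stack([rng.uniform(lo, hi, n) for lo, hi in box])
    colors = rng.integers(0, 256, (n, 3), dtype=np.uint8)
    return c3.PointCloud(coords, colors)
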