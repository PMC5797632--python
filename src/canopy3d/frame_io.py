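"""Frame-session input/output and GPS handling.

A *session* is one scanning pass: per-frame 16-bit depth PNGs (millimeters,
0 = no return), registered 8-bit color PNGs, and a GPS log ``gps.csv`` with
one row per frame (``frame_index,timestamp,latitude,longitude,altitude``).
This module reads sessions, converts geographic fixes to planar UTM meters
(WGS84), and groups frames into field plots from a surveyed plot layout.

The UTM conversion is a direct implementation of the transverse-Mercator
projection using Krueger's series in the third flattening to sixth order
(Karney 2011), accurate to well under a millimeter inside a zone.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .config import PipelineConfig

logger = logging.getLogger("canopy3d")

# ---------------------------------------------------------------------------
# UTM projection (WGS84)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0            # semi-major axis, m
_WGS84_F = 1.0 / 298.257223563  # flattening
_K0 = 0.9996                    # UTM central scale
_FALSE_E = 500000.0
_FALSE_N_SOUTH = 10000000.0

_N = _WGS84_F / (2.0 - _WGS84_F)  # third flattening
_E2 = _WGS84_F * (2.0 - _WGS84_F)
_ECC = math.sqrt(_E2)
# rectifying radius
_A_RECT = _WGS84_A / (1 + _N) * (1 + _N**2 / 4 + _N**4 / 64 + _N**6 / 256)

# Krueger series coefficients in the third flattening n, to order n^6.
_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630
    - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
)
_BETA = (
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
)


def utm_zone_number(lat: float, lon: float) -> int:
    """Standard 6-degree zone number (no Norway/Svalbard exceptions)."""
    return int((lon + 180.0) // 6.0) % 60 + 1


def geographic_to_utm(lat: float, lon: float) -> tuple[float, float, str]:
    """Project WGS84 geographic coordinates to UTM easting/northing meters.

    Returns ``(easting, northing, zone)`` where zone is e.g. ``"17N"``
    (zone number + hemisphere letter).  Raises ``ValueError`` outside the
    UTM latitude domain (|lat| > 84 degrees) or for invalid longitude.
    """
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ValueError(f"invalid geographic coordinate ({lat}, {lon})")
    if abs(lat) > 84.0:
        raise ValueError(f"latitude {lat} outside the UTM domain (|lat| <= 84)")
    zone = utm_zone_number(lat, lon)
    lon0 = math.radians(zone * 6 - 183)
    phi = math.radians(lat)
    dlam = math.radians(lon) - lon0

    # conformal latitude
    tau = math.tan(phi)
    sigma = math.sinh(_ECC * math.atanh(_ECC * tau / math.hypot(1.0, tau)))
    taup = tau * math.hypot(1.0, sigma) - sigma * math.hypot(1.0, tau)

    xi_p = math.atan2(taup, math.cos(dlam))
    eta_p = math.asinh(math.sin(dlam) / math.hypot(taup, math.cos(dlam)))

    xi = xi_p + sum(
        a * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        for j, a in enumerate(_ALPHA, start=1)
    )
    eta = eta_p + sum(
        a * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)
        for j, a in enumerate(_ALPHA, start=1)
    )
    easting = _FALSE_E + _K0 * _A_RECT * eta
    northing = _K0 * _A_RECT * xi
    hemi = "N"
    if lat < 0:
        northing += _FALSE_N_SOUTH
        hemi = "S"
    return easting, northing, f"{zone}{hemi}"


def utm_to_geographic(easting: float, northing: float, zone: str) -> tuple[float, float]:
    """Inverse UTM projection; ``zone`` as returned by :func:`geographic_to_utm`."""
    m = re.fullmatch(r"(\d{1,2})([NS])", zone.strip().upper())
    if not m:
        raise ValueError(f"malformed UTM zone label {zone!r}")
    zone_num, hemi = int(m.group(1)), m.group(2)
    lon0 = math.radians(zone_num * 6 - 183)
    y = northing - (_FALSE_N_SOUTH if hemi == "S" else 0.0)
    xi = y / (_K0 * _A_RECT)
    eta = (easting - _FALSE_E) / (_K0 * _A_RECT)

    xi_p = xi - sum(
        b * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
        for j, b in enumerate(_BETA, start=1)
    )
    eta_p = eta - sum(
        b * math.cos(2 * j * xi) * math.sinh(2 * j * eta)
        for j, b in enumerate(_BETA, start=1)
    )
    taup = math.sin(xi_p) / math.hypot(math.sinh(eta_p), math.cos(xi_p))
    dlam = math.atan2(math.sinh(eta_p), math.cos(xi_p))

    # invert the conformal-latitude relation by Newton iteration
    tau = taup
    for _ in range(8):
        sigma = math.sinh(_ECC * math.atanh(_ECC * tau / math.hypot(1.0, tau)))
        f = tau * math.hypot(1.0, sigma) - sigma * math.hypot(1.0, tau) - taup
        df = (math.hypot(1.0, sigma) * math.hypot(1.0, tau) - sigma * tau) \
            * (1.0 - _E2) * math.hypot(1.0, tau) / (1.0 + (1.0 - _E2) * tau**2)
        tau -= f / df
        if abs(f) < 1e-15:
            break
    lat = math.degrees(math.atan(tau))
    lon = math.degrees(lon0 + dlam)
    return lat, lon


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeoFix:
    """One GPS fix: geographic degrees plus the derived planar UTM meters."""

    latitude: float
    longitude: float
    altitude: float
    easting: float = field(default=float("nan"))
    northing: float = field(default=float("nan"))
    utm_zone: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.easting):
            self.easting, self.northing, self.utm_zone = geographic_to_utm(
                self.latitude, self.longitude
            )


@dataclass
class FrameRecord:
    """One acquisition event: depth raster (mm), color raster, geo-fix."""

    frame_index: int
    depth: np.ndarray   # (H, W) uint16 millimeters, 0 = invalid
    color: np.ndarray   # (H, W, 3) uint8 registered to the depth grid
    fix: GeoFix


@dataclass
class PlotLayout:
    """One field plot: an interval on a row line in UTM (or field-local) meters.

    ``start``/``end`` bound the plot along the row axis (northing for
    north-running rows); ``row_center`` is the across-row coordinate of the
    row line (easting for north-running rows).
    """

    plot_id: str
    row_index: int
    start: float
    end: float
    row_center: float
    enclosure_width: float = 1.52

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"plot {self.plot_id}: end must exceed start")


# ---------------------------------------------------------------------------
# Session loading
# ---------------------------------------------------------------------------

DEPTH_PATTERN = "depth_{:06d}.png"
COLOR_PATTERN = "color_{:06d}.png"
GPS_FILENAME = "gps.csv"


def read_depth_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit single-channel depth PNG (millimeters)."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: depth image must be single-channel")
    return arr.astype(np.uint16)


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    Image.fromarray(depth_mm.astype(np.uint16)).save(path)


def read_gps_csv(path: str | Path) -> dict[int, GeoFix]:
    """Read ``gps.csv`` (frame_index, timestamp, latitude, longitude, altitude)."""
    fixes: dict[int, GeoFix] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"frame_index", "latitude", "longitude", "altitude"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: GPS CSV must have columns {sorted(required)}")
        for row in reader:
            idx = int(row["frame_index"])
            fixes[idx] = GeoFix(
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                altitude=float(row["altitude"]),
            )
    return fixes


def load_session(session_dir: str | Path,
                 config: PipelineConfig | None = None) -> list[FrameRecord]:
    """Load every matched (depth, color, GPS) triple in a session directory.

    Frames are returned ordered by frame index.  A depth frame lacking its
    color image or GPS row is a hard error naming the frame; stray color
    frames without depth are reported and skipped.
    """
    session_dir = Path(session_dir)
    depth_files = sorted(session_dir.glob("depth_*.png"))
    color_files = {p.name: p for p in session_dir.glob("color_*.png")}
    if not depth_files:
        logger.warning("session %s contains no depth frames", session_dir)
        return []
    gps_path = session_dir / GPS_FILENAME
    if not gps_path.exists():
        raise FileNotFoundError(f"missing GPS log {gps_path}")
    fixes = read_gps_csv(gps_path)

    records: list[FrameRecord] = []
    for dpath in depth_files:
        idx = int(re.search(r"(\d+)", dpath.stem).group(1))
        cname = COLOR_PATTERN.format(idx)
        if cname not in color_files:
            raise FileNotFoundError(f"frame {idx}: color image {cname} missing")
        if idx not in fixes:
            raise ValueError(f"frame {idx}: no GPS row in {gps_path}")
        depth = read_depth_png(dpath)
        color = np.asarray(Image.open(color_files[cname]).convert("RGB"))
        if color.shape[:2] != depth.shape:
            raise ValueError(f"frame {idx}: color/depth shape mismatch")
        records.append(FrameRecord(idx, depth, color, fixes[idx]))

    matched = {r.frame_index for r in records}
    stray = [n for n in color_files
             if int(re.search(r"(\d+)", n).group(1)) not in matched]
    if stray:
        logger.warning("%d color frames without depth: %s", len(stray), stray[:5])
    return sorted(records, key=lambda r: r.frame_index)


# ---------------------------------------------------------------------------
# Plot grouping
# ---------------------------------------------------------------------------

def group_frames_by_plot(frames: Sequence[FrameRecord],
                         layout: Sequence[PlotLayout],
                         row_spacing: float = 1.52,
                         ) -> dict[str, list[FrameRecord]]:
    """Assign frames to plots by projecting each fix onto its nearest row line.

    A frame goes to the plot whose along-row interval contains the frame's
    projection, provided the frame lies within half the row spacing of that
    row's line; frames in alleys or off every row are discarded (a count is
    logged).  The result is a partition: each frame lands in at most one plot
    and within-plot frame order is preserved.
    """
    groups: dict[str, list[FrameRecord]] = {p.plot_id: [] for p in layout}
    unassigned = 0
    tol = row_spacing / 2.0
    rows: dict[int, float] = {}
    for p in layout:
        if p.row_index in rows and rows[p.row_index] != p.row_center:
            raise ValueError(f"row {p.row_index} has inconsistent row_center")
        rows[p.row_index] = p.row_center

    for fr in frames:
        along, across = fr.fix.northing, fr.fix.easting
        best = None
        for p in layout:
            d_across = abs(across - p.row_center)
            if d_across > tol:
                continue
            if p.start <= along <= p.end:
                if best is None or d_across < best[0]:
                    best = (d_across, p.plot_id)
        if best is None:
            unassigned += 1
        else:
            groups[best[1]].append(fr)
    if unassigned:
        logger.info("%d frames unassigned (alleys or off-row)", unassigned)
    return groups


def write_manifest(groups: dict[str, list[FrameRecord]], path: str | Path) -> None:
    """Write a frame → plot manifest CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "plot_id"])
        for plot_id, frames in groups.items():
            for fr in frames:
                w.writerow([fr.frame_index, plot_id])
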