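"""Trajectory data model, readers/writers, and elementary kinematics.

Positions are continuous physical coordinates in micrometres, times in
seconds. A :class:`Track` is one cell's time-ordered positions; a
:class:`TrackSet` is one movie's worth of tracks plus the acquisition
metadata (frame interval, duration). :class:`BeadAssayGeometry` describes
the bead-centred concentric-ring binning used by every downstream metric.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from lxml import etree

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`radial_bin` for positions beyond the last ring.
OUTSIDE = -1

TABLE_COLUMNS = ("track_id", "frame", "time_s", "x_um", "y_um")


class TrackFormatError(ValueError):
    """A trajectory file violates the expected format."""


@dataclass(frozen=True)
class TrackPoint:
    """One observation of one cell: time (s) and position (μm)."""

    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and self.t >= 0):
            raise ValueError(f"time must be finite and >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class Track:
    """A single cell's trajectory: >= 2 points with strictly increasing times."""

    track_id: str
    points: tuple[TrackPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"track {self.track_id!r} needs >= 2 points")
        times = [p.t for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.track_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in μm."""
        return np.array([(p.x, p.y) for p in self.points])

    @property
    def duration(self) -> float:
        return self.points[-1].t - self.points[0].t


@dataclass(frozen=True)
class TrackSet:
    """All tracks from one recording."""

    tracks: tuple[Track, ...]
    frame_interval: float = 1.0
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate track ids: {dupes}")
        if self.duration is None:
            end = max((t.points[-1].t for t in self.tracks), default=0.0)
            object.__setattr__(self, "duration", end)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)


@dataclass(frozen=True)
class BeadAssayGeometry:
    """Bead position/radius and the concentric-ring bin layout around it.

    The observation area is a disc of radius ``n_bins * bin_width`` centred
    on the bead; ring ``k`` covers radial distances ``[k*Δr, (k+1)*Δr)``.
    Defaults follow the three 112-μm rings (bins A-C) of the bead assay.
    """

    bead_x: float = 0.0
    bead_y: float = 0.0
    bead_radius: float = 50.0
    bin_width: float = 112.0
    n_bins: int = 3

    def __post_init__(self) -> None:
        if self.bead_radius < 0:
            raise ValueError("bead_radius must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def observation_radius(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def observation_area_mm2(self) -> float:
        """Area of the full counting disc in mm² (336-μm radius → 0.355 mm²)."""
        r_mm = self.observation_radius * 1e-3
        return math.pi * r_mm**2

    def bin_label(self, index: int) -> str:
        """0 → 'A', 1 → 'B', ... for report readability."""
        return chr(ord("A") + index)


def radial_bin(x: float, y: float, geometry: BeadAssayGeometry) -> int:
    """Concentric-ring index of a position, or :data:`OUTSIDE`.

    Bins are half-open and lower-inclusive: bin ``k`` iff
    ``k*Δr <= ρ < (k+1)*Δr`` with ρ the distance to the bead centre.
    Positions on the bead itself (ρ < bead radius) count as bin 0 — cells
    in the movies physically contact the bead.
    """
    rho = math.hypot(x - geometry.bead_x, y - geometry.bead_y)
    if rho < geometry.bead_radius:
        return 0
    k = int(rho // geometry.bin_width)
    return k if k < geometry.n_bins else OUTSIDE


def radial_distance(xy: np.ndarray, geometry: BeadAssayGeometry) -> np.ndarray:
    """Vectorised distance to the bead centre for an (n, 2) position array."""
    xy = np.asarray(xy, dtype=float)
    return np.hypot(xy[..., 0] - geometry.bead_x, xy[..., 1] - geometry.bead_y)


def radial_bin_array(xy: np.ndarray, geometry: BeadAssayGeometry) -> np.ndarray:
    """Vectorised :func:`radial_bin` over an (n, 2) position array."""
    rho = radial_distance(xy, geometry)
    k = np.floor_divide(rho, geometry.bin_width).astype(int)
    k[rho < geometry.bead_radius] = 0
    k[k >= geometry.n_bins] = OUTSIDE
    return k


def step_speeds(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Per-step speeds of a track.

    Returns ``(t_mid, speed)``: midpoint times of successive point pairs and
    the corresponding displacement-over-interval speeds in μm/s; both arrays
    have length ``len(track) - 1``.
    """
    times = track.times
    xy = track.xy
    dt = np.diff(times)
    disp = np.hypot(*np.diff(xy, axis=0).T)
    return (times[:-1] + times[1:]) / 2.0, disp / dt


def _trackset_from_frame(df: pd.DataFrame, frame_interval: float, source: str) -> TrackSet:
    dup = df.duplicated(subset=["track_id", "time_s"])
    if dup.any():
        offender = df.loc[dup.idxmax()]
        raise TrackFormatError(
            f"{source}: duplicated (track_id, time) entry "
            f"(track {offender['track_id']!r} at t={offender['time_s']})"
        )
    tracks = []
    for tid, grp in df.sort_values("time_s").groupby("track_id", sort=True):
        if len(grp) < 2:
            logger.warning("dropping track %r: fewer than 2 points", tid)
            continue
        pts = tuple(
            TrackPoint(t=float(r.time_s), x=float(r.x_um), y=float(r.y_um))
            for r in grp.itertuples()
        )
        tracks.append(Track(track_id=str(tid), points=pts))
    return TrackSet(tracks=tuple(tracks), frame_interval=frame_interval)


def read_tracks_table(path: str | Path, frame_interval: float = 1.0) -> TrackSet:
    """Read a trajectory CSV with columns track_id, frame, time_s, x_um, y_um.

    Points are sorted by time within each track; tracks with fewer than two
    points are dropped with a warning (tracking exports routinely contain
    singleton detections).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required columns {missing}")
    return _trackset_from_frame(df, frame_interval, str(path))


def write_tracks_table(trackset: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to the trajectory CSV format (round-trips exactly)."""
    rows = []
    for track in trackset:
        for p in track.points:
            rows.append(
                {
                    "track_id": track.track_id,
                    "frame": int(round(p.t / trackset.frame_interval)),
                    "time_s": p.t,
                    "x_um": p.x,
                    "y_um": p.y,
                }
            )
    # %.17g keeps doubles exactly round-trippable through the text format
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_tracking_xml(path: str | Path, frame_interval: float = 1.0) -> TrackSet:
    """Read the subset of a TrackMate-style XML export that we consume.

    Only spot coordinates (POSITION_X/POSITION_Y, μm), spot times
    (POSITION_T, or FRAME × frame_interval) and track membership (the edges
    listed under each Track element) are used; every other element and
    attribute is ignored. Spots that belong to no track are dropped, as are
    tracks with fewer than two distinct spots.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()

    spots: dict[str, TrackPoint] = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID")
        x, y = spot.get("POSITION_X"), spot.get("POSITION_Y")
        if sid is None or x is None or y is None:
            raise TrackFormatError(f"{path}: Spot lacking ID or coordinate attribute")
        t = spot.get("POSITION_T")
        if t is None:
            frame = spot.get("FRAME")
            if frame is None:
                raise TrackFormatError(f"{path}: Spot {sid} lacks POSITION_T and FRAME")
            t = float(frame) * frame_interval
        spots[sid] = TrackPoint(t=float(t), x=float(x), y=float(y))

    track_elems = list(root.iter("Track"))
    if not track_elems:
        raise TrackFormatError(f"{path}: no Track elements found")

    rows = []
    for trk in track_elems:
        tid = trk.get("TRACK_ID", trk.get("name", ""))
        members: set[str] = set()
        for edge in trk.iter("Edge"):
            for attr in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                sid = edge.get(attr)
                if sid is not None:
                    members.add(sid)
        # some exports list spots directly under the track
        for spot_ref in trk.iter("SpotRef"):
            sid = spot_ref.get("ID")
            if sid is not None:
                members.add(sid)
        for sid in members:
            if sid not in spots:
                raise TrackFormatError(f"{path}: track {tid} references unknown spot {sid}")
            p = spots[sid]
            rows.append({"track_id": tid, "time_s": p.t, "x_um": p.x, "y_um": p.y})

    df = pd.DataFrame(rows, columns=["track_id", "time_s", "x_um", "y_um"])
    return _trackset_from_frame(df, frame_interval, str(path))


def read_geometry(path: str | Path) -> tuple[BeadAssayGeometry, dict]:
    """Read a JSON/YAML assay-geometry config.

    Recognised keys: bead_x_um, bead_y_um, bead_radius_um, bin_width_um
    (default 112), n_bins (default 3), frame_interval_s (default 1). Returns
    the geometry plus the full raw mapping (for provenance echoing).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise TrackFormatError(f"{path}: geometry config must be a mapping")
    geom = BeadAssayGeometry(
        bead_x=float(raw.get("bead_x_um", 0.0)),
        bead_y=float(raw.get("bead_y_um", 0.0)),
        bead_radius=float(raw.get("bead_radius_um", 50.0)),
        bin_width=float(raw.get("bin_width_um", 112.0)),
        n_bins=int(raw.get("n_bins", 3)),
    )
    return geom, raw


def trackset_from_arrays(
    track_ids: Sequence[str],
    times: np.ndarray,
    positions: np.ndarray,
    frame_interval: float = 1.0,
) -> TrackSet:
    """Build a TrackSet from a shared time grid and an (n_tracks, n_t, 2) array."""
    tracks = []
    for i, tid in enumerate(track_ids):
        pts = tuple(
            TrackPoint(t=float(t), x=float(xy[0]), y=float(xy[1]))
            for t, xy in zip(times, positions[i])
        )
        tracks.append(Track(track_id=str(tid), points=pts))
    return TrackSet(tracks=tuple(tracks), frame_interval=frame_interval)
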