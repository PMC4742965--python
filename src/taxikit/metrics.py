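"""Per-bin chemotaxis readouts around a bead source.

The observation disc is divided into concentric rings (bins A, B, C ...)
centred on the bead. For each ring the module computes the study's four
readouts on a regular sampling grid:

* cell counts (and their Z-score normalisation with a T=0 baseline),
* the signed sine-angle orientation of movement steps,
* the summed cell-to-bead distance,
* (via :mod:`taxikit.kinetics`) mean gliding speed.

Point metrics (counts, sum distance) are snapshots at the sample times,
with positions linearly interpolated onto the grid. Step metrics (sine
angle, speed) are attributed to the ring containing the step midpoint and
to the time window containing the step's midpoint time; windows to which
only a single track contributes are reported as missing, mirroring the
single-track exclusion rule of the original analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import (
    OUTSIDE,
    BeadAssayGeometry,
    Track,
    TrackSet,
    radial_bin_array,
    radial_distance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinSeries:
    """Time series of one metric in one concentric ring.

    ``values`` uses NaN for missing entries (empty or single-track
    windows); ``n_contributing`` counts the tracks behind each entry.
    """

    bin: int
    metric: str
    times: np.ndarray
    values: np.ndarray
    n_contributing: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.n_contributing < 0):
            raise ValueError("n_contributing must be >= 0")

    def value_at(self, t: float) -> float:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not in series")
        return float(self.values[idx[0]])


def binseries_to_frame(series: Iterable[BinSeries]) -> pd.DataFrame:
    """Tidy long-format table: columns bin, label, metric, time_s, value, n."""
    rows = []
    for s in series:
        for t, v, n in zip(s.times, s.values, s.n_contributing):
            rows.append(
                {"bin": s.bin, "label": s.label, "metric": s.metric,
                 "time_s": t, "value": v, "n": int(n)}
            )
    return pd.DataFrame(rows, columns=["bin", "label", "metric", "time_s", "value", "n"])


@dataclass(frozen=True)
class NormalizationSpec:
    """How counts are Z-scored.

    The Z population pools all counts of one treatment within one ring,
    over time points and replicate series; after standardisation each
    series has its value at ``baseline_time`` subtracted so every series
    starts at exactly 0. ``population_sd=True`` uses the population
    (ddof=0) standard deviation.
    """

    baseline_time: float = 0.0
    population_sd: bool = True


class TrendResult(NamedTuple):
    slope: float
    stderr: float
    tvalue: float
    pvalue: float


# ---------------------------------------------------------------------------
# snapshot helpers

def _positions_at(trackset: TrackSet, t: float) -> tuple[np.ndarray, list[str]]:
    """Interpolated (n, 2) positions of all tracks alive at time t."""
    pts, ids = [], []
    for track in trackset:
        times = track.times
        if times[0] - 1e-9 <= t <= times[-1] + 1e-9:
            xy = track.xy
            pts.append([np.interp(t, times, xy[:, 0]), np.interp(t, times, xy[:, 1])])
            ids.append(track.track_id)
    return (np.array(pts).reshape(-1, 2), ids)


def _sample_times(trackset: TrackSet, interval_s: float) -> np.ndarray:
    n = int(math.floor(trackset.duration / interval_s + 1e-9))
    return np.arange(n + 1) * interval_s


def frame_bin_counts(
    trackset: TrackSet, geometry: BeadAssayGeometry, interval_s: float = 60.0
) -> list[BinSeries]:
    """Number of cells in each ring at every sampled time point.

    ``interval_s`` must be a multiple of the acquisition frame interval.
    Cells outside the outermost ring are not counted anywhere.
    """
    ratio = interval_s / trackset.frame_interval
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("interval_s must be a multiple of frame_interval")
    times = _sample_times(trackset, interval_s)
    counts = np.zeros((geometry.n_bins, times.size), dtype=int)
    for j, t in enumerate(times):
        xy, _ = _positions_at(trackset, t)
        if xy.size == 0:
            continue
        bins = radial_bin_array(xy, geometry)
        for k in range(geometry.n_bins):
            counts[k, j] = int(np.sum(bins == k))
    return [
        BinSeries(
            bin=k, metric="count", times=times,
            values=counts[k].astype(float), n_contributing=counts[k],
            label=geometry.bin_label(k),
        )
        for k in range(geometry.n_bins)
    ]


def sum_distance_series(
    trackset: TrackSet, geometry: BeadAssayGeometry, interval_s: float = 60.0
) -> list[BinSeries]:
    """Per-ring sum of cell-to-bead distances at every sampled time point."""
    times = _sample_times(trackset, interval_s)
    sums = np.zeros((geometry.n_bins, times.size))
    ns = np.zeros((geometry.n_bins, times.size), dtype=int)
    for j, t in enumerate(times):
        xy, _ = _positions_at(trackset, t)
        if xy.size == 0:
            continue
        rho = radial_distance(xy, geometry)
        bins = radial_bin_array(xy, geometry)
        for k in range(geometry.n_bins):
            mask = bins == k
            sums[k, j] = float(rho[mask].sum())
            ns[k, j] = int(mask.sum())
    return [
        BinSeries(bin=k, metric="sum_distance", times=times, values=sums[k],
                  n_contributing=ns[k], label=geometry.bin_label(k))
        for k in range(geometry.n_bins)
    ]


def total_sum_distance(
    trackset: TrackSet,
    geometry: BeadAssayGeometry,
    interval_s: float = 60.0,
    include_outside: bool = False,
) -> BinSeries:
    """Total cell-to-bead sum distance at every sampled time point.

    By default only cells inside the observation disc contribute (what a
    real movie shows). ``include_outside=True`` sums over every tracked
    cell regardless of position — the simulator's ground-truth variant,
    whose trend sign reflects pure drift and is not confounded by cells
    entering or leaving the field of view.
    """
    if include_outside:
        times = _sample_times(trackset, interval_s)
        values = np.zeros(times.size)
        ns = np.zeros(times.size, dtype=int)
        for j, t in enumerate(times):
            xy, _ = _positions_at(trackset, t)
            if xy.size == 0:
                continue
            values[j] = float(radial_distance(xy, geometry).sum())
            ns[j] = xy.shape[0]
        return BinSeries(bin=-1, metric="sum_distance", times=times,
                         values=values, n_contributing=ns, label="ALL_CELLS")
    per_bin = sum_distance_series(trackset, geometry, interval_s)
    values = np.sum([s.values for s in per_bin], axis=0)
    ns = np.sum([s.n_contributing for s in per_bin], axis=0)
    return BinSeries(bin=-1, metric="sum_distance", times=per_bin[0].times,
                     values=values, n_contributing=ns, label="ALL")


# ---------------------------------------------------------------------------
# normalisation

def normalize_counts(
    series: Sequence[BinSeries], spec: NormalizationSpec | None = None
) -> list[BinSeries]:
    """Standardise count series and anchor each to 0 at the baseline time.

    All series sharing a ring index form one Z population (replicates and
    time points pooled); Z = (X − μ)/σ, then each series' Z at
    ``baseline_time`` is subtracted so its first reported value is exactly
    0. A constant population (σ = 0) yields all-zero output with a warning
    rather than an error.
    """
    spec = spec or NormalizationSpec()
    by_bin: dict[int, list[BinSeries]] = {}
    for s in series:
        by_bin.setdefault(s.bin, []).append(s)

    out: list[BinSeries] = []
    for k, group in by_bin.items():
        pooled = np.concatenate([s.values for s in group])
        pooled = pooled[np.isfinite(pooled)]
        mu = float(pooled.mean())
        sigma = float(pooled.std(ddof=0 if spec.population_sd else 1))
        for s in group:
            if sigma == 0.0:
                logger.warning("constant counts in bin %s: normalized series set to 0", s.label or k)
                z = np.zeros_like(s.values)
            else:
                z = (s.values - mu) / sigma
                base_idx = np.nonzero(np.isclose(s.times, spec.baseline_time))[0]
                if base_idx.size == 0:
                    raise ValueError(
                        f"baseline_time {spec.baseline_time} not present in series times"
                    )
                z = z - z[base_idx[0]]
            out.append(
                BinSeries(bin=s.bin, metric="normalized_count", times=s.times,
                          values=z, n_contributing=s.n_contributing, label=s.label)
            )
    return out


# ---------------------------------------------------------------------------
# step metrics

def step_sine_angle(
    p_from: Sequence[float], p_to: Sequence[float], bead_center: Sequence[float]
) -> float:
    """Signed radial component of a movement step, in [−1, 1].

    Computed as (ρ_from − ρ_to) / ‖p_to − p_from‖ where ρ is the distance
    to the bead centre: +1 for a step straight at the bead, −1 straight
    away, 0 tangential. Returns NaN for a zero-length step.
    """
    p_from = np.asarray(p_from, dtype=float)
    p_to = np.asarray(p_to, dtype=float)
    bead = np.asarray(bead_center, dtype=float)
    step = float(np.hypot(*(p_to - p_from)))
    if step == 0.0:
        return math.nan
    rho_from = float(np.hypot(*(p_from - bead)))
    rho_to = float(np.hypot(*(p_to - bead)))
    return (rho_from - rho_to) / step


def _track_steps(track: Track) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(t_mid, midpoint xy, from xy, to xy) for all steps of a track."""
    times = track.times
    xy = track.xy
    t_mid = (times[:-1] + times[1:]) / 2.0
    return t_mid, (xy[:-1] + xy[1:]) / 2.0, xy[:-1], xy[1:]


def binned_step_statistic(
    trackset: TrackSet,
    geometry: BeadAssayGeometry,
    window_s: float,
    step_fn: Callable[[Track], np.ndarray],
    metric: str,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[BinSeries]:
    """Window × ring means of an arbitrary per-step quantity.

    ``step_fn(track)`` returns one value per step. Steps land in the ring
    of their midpoint position and the window ``[k·w, (k+1)·w)`` holding
    their midpoint time. Windows with fewer than two distinct contributing
    tracks are missing (NaN). ``transform`` (e.g. log1p) is applied to the
    step values before averaging.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n_windows = int(math.floor(trackset.duration / window_s + 1e-9))
    n_windows = max(n_windows, 1)
    win_times = np.arange(n_windows) * window_s

    sums = np.zeros((geometry.n_bins, n_windows))
    counts = np.zeros((geometry.n_bins, n_windows), dtype=int)
    contributors: dict[tuple[int, int], set[str]] = {}

    for track in trackset:
        t_mid, mid_xy, _, _ = _track_steps(track)
        vals = np.asarray(step_fn(track), dtype=float)
        if transform is not None:
            vals = transform(vals)
        bins = radial_bin_array(mid_xy, geometry)
        wins = np.floor_divide(t_mid, window_s).astype(int)
        ok = (bins != OUTSIDE) & (wins >= 0) & (wins < n_windows) & np.isfinite(vals)
        for b, w, v in zip(bins[ok], wins[ok], vals[ok]):
            sums[b, w] += v
            counts[b, w] += 1
            contributors.setdefault((b, w), set()).add(track.track_id)

    out = []
    for k in range(geometry.n_bins):
        values = np.full(n_windows, math.nan)
        ns = np.zeros(n_windows, dtype=int)
        for w in range(n_windows):
            n_tracks = len(contributors.get((k, w), ()))
            ns[w] = n_tracks
            if n_tracks >= 2:
                values[w] = sums[k, w] / counts[k, w]
        out.append(
            BinSeries(bin=k, metric=metric, times=win_times, values=values,
                      n_contributing=ns, label=geometry.bin_label(k))
        )
    return out


def _sine_steps(track: Track, geometry: BeadAssayGeometry) -> np.ndarray:
    _, _, p_from, p_to = _track_steps(track)
    step_len = np.hypot(*(p_to - p_from).T)
    rho_from = radial_distance(p_from, geometry)
    rho_to = radial_distance(p_to, geometry)
    with np.errstate(divide="ignore", invalid="ignore"):
        sine = (rho_from - rho_to) / step_len
    sine[step_len == 0] = math.nan
    return sine


def binned_mean_sine(
    trackset: TrackSet, geometry: BeadAssayGeometry, interval_s: float = 60.0
) -> list[BinSeries]:
    """Mean step sine angle per ring and time window (default 60-s windows)."""
    return binned_step_statistic(
        trackset, geometry, interval_s,
        step_fn=lambda trk: _sine_steps(trk, geometry),
        metric="sine_angle",
    )


def pooled_sine_summary(trackset: TrackSet, geometry: BeadAssayGeometry) -> tuple[float, float]:
    """Grand mean step sine angle and its track-clustered standard error.

    Tracks are the independent sampling units, so the SE is computed over
    per-track mean sine angles; step-level SEs would ignore the strong
    within-track correlation of a run-and-reverse walker.
    """
    track_means = []
    for track in trackset:
        sine = _sine_steps(track, geometry)
        sine = sine[np.isfinite(sine)]
        if sine.size:
            track_means.append(sine.mean())
    track_means = np.asarray(track_means)
    if track_means.size < 2:
        raise ValueError("need >= 2 tracks with finite steps")
    return float(track_means.mean()), float(track_means.std(ddof=1) / math.sqrt(track_means.size))


# ---------------------------------------------------------------------------
# trends

def trend_slope(series: BinSeries | tuple[np.ndarray, np.ndarray]) -> TrendResult:
    """Ordinary-least-squares slope of value against time.

    Accepts a :class:`BinSeries` or a ``(times, values)`` pair; missing
    values are dropped. Returns slope, classical standard error, the t
    statistic and its two-sided p-value. Descriptive only: no correction
    for serial correlation or multiplicity is attempted.
    """
    if isinstance(series, BinSeries):
        t, y = series.times, series.values
    else:
        t, y = np.asarray(series[0], dtype=float), np.asarray(series[1], dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 3:
        raise ValueError("need >= 3 non-missing points for a trend")
    res = stats.linregress(t, y)
    if res.stderr == 0.0:
        tval = math.inf if res.slope != 0 else 0.0
    else:
        tval = res.slope / res.stderr
    return TrendResult(slope=float(res.slope), stderr=float(res.stderr),
                       tvalue=float(tval), pvalue=float(res.pvalue))
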