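"""Motility kinetics: RMS net displacement, Taylor-equation fits, derived
dispersal parameters, windowed speed summaries and motile-fraction scoring.

The central model is Taylor's dispersion equation for a persistent random
walker,

    rms(t) = [ 2 v² τ ( t − τ (1 − e^(−t/τ)) ) ]^0.5 ,

with effective speed v and decorrelation timescale τ. It interpolates
between ballistic motion (rms → v·t for t ≪ τ) and diffusion
(rms² → 4Dt in two dimensions for t ≫ τ). From a fit we derive the
decorrelation length λ = vτ, the effective diffusivity D = v²τ/n for n
spatial dimensions, and the encounter kernel β = 4πRD for a target of
radius R — the water volume a cell screens per unit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .metrics import BinSeries, binned_step_statistic
from .tracks import BeadAssayGeometry, TrackSet, step_speeds

#: τ within this factor of its optimisation bound flags a non-identifiable fit.
_TAU_BOUND_FACTOR = 100.0


class TaylorFitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best candidate."""

    def __init__(self, message: str, best: "TaylorFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RmsSeries:
    """Root-mean-square net displacement against elapsed time.

    ``estimator`` records how the series was computed ("origin" or
    "all_lag"); the fit uses it to choose the right variance model.
    """

    times: np.ndarray
    rms: np.ndarray
    n_tracks_at_t: np.ndarray
    estimator: str = "origin"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rms < 0):
            raise ValueError("rms must be >= 0")


@dataclass(frozen=True)
class TaylorFit:
    """Fitted and derived motility parameters of one condition.

    v (μm/s) and τ (s) come from the nonlinear fit; λ (μm), D (μm²/s) and
    β (μm³/s) from the defining identities λ = vτ, D = v²τ/n, β = 4πRD.
    Derived fields are None until :func:`derive_motility_params` fills
    them. ``identifiable`` is False when τ ran into its bound (e.g. a
    purely ballistic series, for which τ is unconstrained from above).
    """

    v: float
    tau: float
    n_dims: int = 2
    lam: float | None = None
    D: float | None = None
    beta: float | None = None
    bead_radius: float | None = None
    residual_norm: float = math.nan
    n_tracks: int = 0
    converged: bool = True
    identifiable: bool = True


def taylor_rms(t: np.ndarray, v: float, tau: float) -> np.ndarray:
    """Closed-form Taylor RMS curve; numerically safe for t/τ large or small."""
    t = np.asarray(t, dtype=float)
    x = t / tau
    # t − τ(1−e^−x) = τ(x − 1 + e^−x); expm1 keeps precision at small x
    inner = tau * (x + np.expm1(-x))
    return np.sqrt(np.maximum(2.0 * v**2 * tau * inner, 0.0))


def rms_net_displacement(
    trackset: TrackSet,
    time_grid: np.ndarray | None = None,
    estimator: str = "origin",
) -> RmsSeries:
    """RMS net displacement of a track population over elapsed time.

    ``origin`` (default): each track's net displacement at elapsed time t
    is measured from its own first point, with positions linearly
    interpolated; tracks shorter than t are excluded and grid points with
    no contributing track are dropped. ``all_lag`` instead averages the
    squared displacement over every same-lag pair of sampled frames
    (overlapping windows), a lower-variance but serially correlated
    estimator kept for robustness comparisons.
    """
    if len(trackset) == 0:
        raise ValueError("empty trackset")
    if estimator not in ("origin", "all_lag"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if time_grid is None:
        max_dur = max(trk.duration for trk in trackset)
        n = int(math.floor(max_dur / trackset.frame_interval + 1e-9))
        time_grid = np.arange(1, n + 1) * trackset.frame_interval
    time_grid = np.asarray(time_grid, dtype=float)

    sum_sq = np.zeros(time_grid.size)
    counts = np.zeros(time_grid.size, dtype=int)
    for track in trackset:
        times = track.times
        xy = track.xy
        if estimator == "origin":
            usable = time_grid <= track.duration + 1e-9
            if not np.any(usable):
                continue
            tq = times[0] + time_grid[usable]
            x = np.interp(tq, times, xy[:, 0])
            y = np.interp(tq, times, xy[:, 1])
            net2 = (x - xy[0, 0]) ** 2 + (y - xy[0, 1]) ** 2
            sum_sq[usable] += net2
            counts[usable] += 1
        else:
            # frame-aligned overlapping windows
            for j, lag in enumerate(time_grid):
                k = int(round(lag / trackset.frame_interval))
                if k < 1 or k >= len(times):
                    continue
                d = xy[k:] - xy[:-k]
                sum_sq[j] += float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
                counts[j] += 1

    keep = counts > 0
    rms = np.sqrt(sum_sq[keep] / counts[keep])
    return RmsSeries(times=time_grid[keep], rms=rms, n_tracks_at_t=counts[keep],
                     estimator=estimator)


def fit_taylor(series: RmsSeries, n_dims: int = 2) -> TaylorFit:
    """Weighted nonlinear least-squares fit of the Taylor curve.

    Residuals are whitened by the predicted sampling error of each RMS
    point: the SD of an RMS estimate is proportional to its value and
    inversely proportional to the square root of the number of
    independent contributions — the contributing tracks, times (for the
    overlapping-window estimator) the ≈ T/lag disjoint windows per track.
    Without this weighting the many late, strongly correlated points
    dominate and push the fit onto the degenerate pure-diffusion ridge
    (v → ∞, τ → 0 at fixed v²τ).

    v and τ are constrained positive; initialisation takes v0 from the
    first grid point's secant slope and τ0 = 10 s, with a deterministic
    multi-start over τ0 ∈ {1, 5, 20, 60} s if the first fit is poor. A τ
    at its upper bound (ballistic, curvature-free data) is flagged
    non-identifiable rather than trusted.
    """
    t, y = series.times, series.rms
    if t.size < 5:
        raise ValueError("need >= 5 time points to fit")
    if np.any(y[t > 0] <= 0):
        raise ValueError("rms must be positive beyond t = 0")

    t_max = float(t[-1])
    tau_hi = _TAU_BOUND_FACTOR * t_max
    v0 = float(y[0] / t[0])

    w = np.sqrt(series.n_tracks_at_t / series.n_tracks_at_t.max()) / y
    if series.estimator == "all_lag":
        w = w * np.sqrt(np.maximum(1.0, t_max / t))

    def resid(p: np.ndarray) -> np.ndarray:
        return (taylor_rms(t, p[0], p[1]) - y) * w

    best = None
    y_w = y * w
    for tau0 in (10.0, 1.0, 5.0, 20.0, 60.0):
        sol = least_squares(
            resid, x0=[max(v0, 1e-6), tau0],
            bounds=([1e-9, 1e-9], [np.inf, tau_hi]), method="trf",
            x_scale=[1.0, 10.0],
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= (0.01 * np.linalg.norm(y_w)) ** 2:
            break

    v, tau = float(best.x[0]), float(best.x[1])
    fit = TaylorFit(
        v=v, tau=tau, n_dims=n_dims,
        residual_norm=float(np.linalg.norm(taylor_rms(t, v, tau) - y)),
        n_tracks=int(series.n_tracks_at_t.max()),
        converged=bool(best.success),
        identifiable=tau < 0.99 * tau_hi,
    )
    if not best.success:
        raise TaylorFitError("Taylor fit did not converge after multi-start", best=fit)
    return fit


def derive_motility_params(
    fit: TaylorFit, n_dims: int | None = None, bead_radius: float | None = None
) -> TaylorFit:
    """Complete a fit with λ = vτ, D = v²τ/n and (given R) β = 4πRD.

    The bead radius has no default: β depends on the actual target size,
    which must come from the assay geometry. n defaults to the fit's
    n_dims (2 for the flat-chamber assay).
    """
    if fit.v <= 0 or fit.tau <= 0:
        raise ValueError("fit must have positive v and tau")
    if bead_radius is not None and bead_radius < 0:
        raise ValueError("bead_radius must be >= 0")
    n = n_dims if n_dims is not None else fit.n_dims
    lam = fit.v * fit.tau
    D = fit.v**2 * fit.tau / n
    beta = 4.0 * math.pi * bead_radius * D if bead_radius is not None else None
    return replace(fit, n_dims=n, lam=lam, D=D, beta=beta, bead_radius=bead_radius)


def empirical_diffusivity(
    series: RmsSeries,
    t_min: float | None = None,
    t_max: float | None = None,
) -> float:
    """Model-free D from the linear growth of the mean-square displacement.

    Regresses rms²(t) on t over ``[t_min, t_max]`` and returns slope/4
    (two dimensions) — an independent check on the Taylor-fit D. The
    default window is [0.1·T, 0.5·T]: well past any realistic
    decorrelation time yet early enough that many disjoint windows per
    track contribute, keeping the estimate's variance down.
    """
    T = float(series.times[-1])
    lo = 0.1 * T if t_min is None else t_min
    hi = 0.5 * T if t_max is None else t_max
    cut = (series.times >= lo) & (series.times <= hi)
    if np.count_nonzero(cut) < 3:
        raise ValueError("regression window contains fewer than 3 points")
    slope = float(np.polyfit(series.times[cut], series.rms[cut] ** 2, 1)[0])
    return slope / 4.0


def compare_motility(fit_a: TaylorFit, fit_b: TaylorFit) -> pd.DataFrame:
    """Percent change of each motility parameter from condition a to b.

    Rows v, tau, lambda, D, beta with columns a, b and
    percent_change = 100·(b−a)/a; an entry whose reference value is zero
    or missing is reported as NaN.
    """
    rows = []
    for name, attr in (("v", "v"), ("tau", "tau"), ("lambda", "lam"),
                       ("D", "D"), ("beta", "beta")):
        a, b = getattr(fit_a, attr), getattr(fit_b, attr)
        if a is None or b is None or a == 0:
            pct = math.nan
        else:
            pct = 100.0 * (b - a) / a
        rows.append({"parameter": name, "a": a, "b": b, "percent_change": pct})
    return pd.DataFrame(rows, columns=["parameter", "a", "b", "percent_change"])


def binned_mean_speed(
    trackset: TrackSet, geometry: BeadAssayGeometry, window_s: float = 30.0
) -> tuple[list[BinSeries], list[BinSeries]]:
    """Ring × window mean gliding speed, raw and log(1+speed) transformed.

    Steps land in the ring of their midpoint and the 30-s window holding
    their midpoint time; windows with a single contributing track are
    missing. Returns ``(raw, log1p)`` series lists.
    """
    def speeds(track):
        return step_speeds(track)[1]

    raw = binned_step_statistic(trackset, geometry, window_s, speeds, metric="speed")
    logged = binned_step_statistic(
        trackset, geometry, window_s, speeds, metric="log1p_speed", transform=np.log1p
    )
    return raw, logged


def motile_fraction(
    frame_a: np.ndarray, frame_b: np.ndarray, tolerance_um: float = 1.0
) -> float:
    """Fraction of cells that moved between two matched snapshots.

    ``frame_a`` and ``frame_b`` are (n, 2) position arrays of the *same*
    cells at two times (the 15-s photograph-overlay assay); a cell whose
    displacement is ≤ tolerance is immotile. The default 1-μm tolerance
    absorbs localisation noise that a strict exact-position rule would
    misread as motility.
    """
    a = np.asarray(frame_a, dtype=float).reshape(-1, 2)
    b = np.asarray(frame_b, dtype=float).reshape(-1, 2)
    if a.shape != b.shape:
        raise ValueError(f"matched frames required: {a.shape} vs {b.shape}")
    if tolerance_um < 0:
        raise ValueError("tolerance must be >= 0")
    if a.shape[0] == 0:
        raise ValueError("no cells supplied")
    disp = np.hypot(*(b - a).T)
    return float(np.mean(disp > tolerance_um))
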