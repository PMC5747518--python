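"""Per-track and per-group motility statistics.

Conventions (documented because the source material leaves them open):

* instantaneous velocity uses consecutive frames, no smoothing;
* mean track velocity is the mean of instantaneous velocities;
* thresholds (<2, <7 µm/min) are strict inequalities;
* MSD averages over all ordered frame pairs (overlapping windows);
* the motility coefficient is ``slope / (2 * dim)`` from a zero-intercept
  linear fit of MSD versus lag over the first quarter of available lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import ARREST_THRESHOLD_UM_MIN, SLOW_CELL_THRESHOLD_UM_MIN, Track, TrackSet

__all__ = [
    "MotilitySummary",
    "instantaneous_velocities",
    "arrest_coefficient",
    "pause_segments",
    "coefficient_of_variation",
    "turn_angles",
    "directionality_ratio_curve",
    "msd_curve",
    "velocity_histogram",
    "summarize_track",
    "summarize_trackset",
]


@dataclass
class MotilitySummary:
    """All per-track motility scalars reported by the pipeline."""

    cell_id: str
    mean_velocity_um_min: float
    max_inst_velocity_um_min: float
    min_inst_velocity_um_min: float
    arrest_coefficient: float
    cov_percent: float
    pause_durations_s: list[float] = field(default_factory=list)
    n_frames: int = 0

    def __post_init__(self) -> None:
        if not (
            self.min_inst_velocity_um_min
            <= self.mean_velocity_um_min
            <= self.max_inst_velocity_um_min
        ):
            raise ValueError("velocity summary violates min <= mean <= max")
        if not 0.0 <= self.arrest_coefficient <= 1.0:
            raise ValueError("arrest coefficient outside [0, 1]")


def instantaneous_velocities(track: Track) -> np.ndarray:
    """Frame-to-frame speeds in µm/min, length ``n_frames - 1``.

    Uses all available spatial dimensions (3D velocity for 3D tracks).
    """
    disp = np.diff(track.pos_um, axis=0)
    dts = np.diff(track.t_s)
    if np.any(dts == 0):
        raise ValueError(f"duplicate timestamps in track {track.cell_id!r}")
    return np.linalg.norm(disp, axis=1) / dts * 60.0


def arrest_coefficient(
    track: Track, threshold_um_min: float = ARREST_THRESHOLD_UM_MIN
) -> float:
    """Fraction of steps with instantaneous velocity strictly below threshold."""
    if threshold_um_min <= 0:
        raise ValueError("threshold must be positive")
    v = instantaneous_velocities(track)
    return float(np.count_nonzero(v < threshold_um_min)) / len(v)


def pause_segments(
    track: Track, threshold_um_min: float = ARREST_THRESHOLD_UM_MIN
) -> list[float]:
    """Durations (s) of maximal runs of consecutive sub-threshold steps."""
    if threshold_um_min <= 0:
        raise ValueError("threshold must be positive")
    v = instantaneous_velocities(track)
    dt = track.dt_s
    below = v < threshold_um_min
    durations: list[float] = []
    run = 0
    for b in below:
        if b:
            run += 1
        elif run:
            durations.append(run * dt)
            run = 0
    if run:
        durations.append(run * dt)
    return durations


def coefficient_of_variation(track: Track) -> float:
    """100 * SD / mean of instantaneous velocity (sample SD, n-1)."""
    v = instantaneous_velocities(track)
    m = v.mean()
    if m <= 0:
        raise ValueError(
            f"track {track.cell_id!r}: zero mean velocity, CoV undefined"
        )
    if len(v) < 2:
        raise ValueError("CoV needs >= 2 instantaneous velocities")
    return float(100.0 * v.std(ddof=1) / m)


def turn_angles(track: Track, min_step_um: float = 0.5) -> list[float]:
    """Angles (degrees, in [0, 180]) between successive displacement vectors.

    Steps shorter than ``min_step_um`` are skipped; the angle is then taken
    between the displacements flanking the gap.
    """
    if track.n_frames < 3:
        raise ValueError("turn angles need >= 3 frames")
    disp = np.diff(track.pos_um, axis=0)
    lengths = np.linalg.norm(disp, axis=1)
    keep = disp[lengths >= min_step_um]
    kept_len = lengths[lengths >= min_step_um]
    angles: list[float] = []
    for i in range(len(keep) - 1):
        cosang = np.dot(keep[i], keep[i + 1]) / (kept_len[i] * kept_len[i + 1])
        angles.append(float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))
    return angles


def _directionality_per_track(track: Track) -> np.ndarray:
    """ratio(t_i) = |pos(t_i) - pos(0)| / path length to t_i; index 0 skipped."""
    disp = track.pos_um - track.pos_um[0]
    net = np.linalg.norm(disp, axis=1)
    steps = np.linalg.norm(np.diff(track.pos_um, axis=0), axis=1)
    path = np.concatenate([[0.0], np.cumsum(steps)])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(path > 0, net / np.maximum(path, 1e-300), np.nan)
    return ratio[1:]  # elapsed times t_1..t_{n-1}


def directionality_ratio_curve(
    tracks: TrackSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, dict]:
    """Mean directionality ratio versus elapsed time, with fitted decay tau.

    Returns ``(elapsed_s, mean_ratio, sem_ratio, tau_s, fit_info)``.  The
    decay model is ``r(t) = r_inf + (1 - r_inf) * exp(-t / tau)`` fitted to
    the track-averaged curve with ``r_inf`` free in [0, 1].
    """
    if len(tracks) == 0:
        raise ValueError("empty TrackSet")
    dt = tracks.dt_s
    max_steps = max(t.n_frames - 1 for t in tracks)
    acc = np.full((len(tracks), max_steps), np.nan)
    for k, tr in enumerate(tracks):
        r = _directionality_per_track(tr)
        acc[k, : len(r)] = r
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(acc, axis=0)
        n_alive = np.sum(~np.isnan(acc), axis=0)
        sem = np.nanstd(acc, axis=0, ddof=1) / np.sqrt(np.maximum(n_alive, 1))
    elapsed = (np.arange(max_steps) + 1) * dt

    def model(t, r_inf, tau):
        return r_inf + (1.0 - r_inf) * np.exp(-t / tau)

    ok = np.isfinite(mean)
    try:
        popt, pcov = curve_fit(
            model,
            elapsed[ok],
            mean[ok],
            p0=[0.1, max(elapsed[ok].mean(), dt)],
            bounds=([0.0, dt / 10.0], [1.0, 1e7]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"directionality decay fit failed: {exc}; "
            f"curve range [{np.nanmin(mean):.3f}, {np.nanmax(mean):.3f}] "
            f"over {ok.sum()} time points"
        ) from exc
    tau = float(popt[1])
    info = {
        "r_inf": float(popt[0]),
        "tau_s": tau,
        "tau_se": float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan,
        "n_tracks": len(tracks),
    }
    return elapsed, mean, sem, tau, info


def _msd_single(pos: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping-window MSD for one track: mean over all ordered pairs."""
    n = pos.shape[0]
    msd = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for lag in range(1, max_lag + 1):
        if lag >= n:
            break
        d = pos[lag:] - pos[:-lag]
        msd[lag - 1] = np.mean(np.sum(d * d, axis=1))
        counts[lag - 1] = n - lag
    return msd, counts


def msd_curve(
    tracks: TrackSet, fit_fraction: float = 0.25
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Ensemble MSD versus lag plus the fitted motility coefficient.

    Returns ``(lag_min, msd_um2, motility_coefficient_um2_min, info)``.
    MSD at each lag averages over every ordered frame pair at that lag in
    every track.  The motility coefficient M solves ``MSD = 2 * dim * M * t``
    by zero-intercept least squares over the first ``fit_fraction`` of lags.
    """
    if len(tracks) == 0:
        raise ValueError("empty TrackSet")
    dts = np.array([t.dt_s for t in tracks])
    if np.max(np.abs(dts - dts.mean())) > 0.01 * dts.mean():
        raise ValueError("mixed frame intervals across tracks")
    dt = float(dts.mean())
    max_lag = max(t.n_frames - 1 for t in tracks)
    total = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in tracks:
        m, c = _msd_single(tr.pos_um, max_lag)
        total += m * c
        counts += c
    valid = counts > 0
    msd = np.full(max_lag, np.nan)
    msd[valid] = total[valid] / counts[valid]
    lag_min = (np.arange(max_lag) + 1) * dt / 60.0

    n_fit = max(int(np.ceil(max_lag * fit_fraction)), 1)
    fit_mask = valid.copy()
    fit_mask[n_fit:] = False
    x = lag_min[fit_mask]
    y = msd[fit_mask]
    slope = float(np.sum(x * y) / np.sum(x * x))
    dim = tracks.dim
    M = slope / (2.0 * dim)
    info = {
        "slope_um2_min": slope,
        "dim": dim,
        "n_fit_lags": int(fit_mask.sum()),
        "fit_fraction": fit_fraction,
        "estimator": "zero-intercept LSQ, MSD = 2*dim*M*lag",
    }
    return lag_min, msd, M, info


def velocity_histogram(
    tracks: TrackSet,
    bin_um_min: float = 1.0,
    slow_threshold_um_min: float = SLOW_CELL_THRESHOLD_UM_MIN,
) -> dict:
    """Histogram of per-track mean velocities, as fractions summing to 1.

    ``fraction_below`` counts per-track means strictly below the slow-cell
    threshold (default 7 µm/min).
    """
    if len(tracks) == 0:
        raise ValueError("empty TrackSet")
    means = np.array([instantaneous_velocities(t).mean() for t in tracks])
    hi = np.ceil(means.max() / bin_um_min) * bin_um_min + bin_um_min
    edges = np.arange(0.0, hi + bin_um_min / 2, bin_um_min)
    counts, edges = np.histogram(means, bins=edges)
    fractions = counts / counts.sum()
    return {
        "bin_edges_um_min": edges,
        "fractions": fractions,
        "mean_velocities_um_min": means,
        "fraction_below": float(np.mean(means < slow_threshold_um_min)),
        "slow_threshold_um_min": slow_threshold_um_min,
    }


def summarize_track(
    track: Track, threshold_um_min: float = ARREST_THRESHOLD_UM_MIN
) -> MotilitySummary:
    v = instantaneous_velocities(track)
    return MotilitySummary(
        cell_id=track.cell_id,
        mean_velocity_um_min=float(v.mean()),
        max_inst_velocity_um_min=float(v.max()),
        min_inst_velocity_um_min=float(v.min()),
        arrest_coefficient=arrest_coefficient(track, threshold_um_min),
        cov_percent=coefficient_of_variation(track) if len(v) >= 2 and v.mean() > 0 else float("nan"),
        pause_durations_s=pause_segments(track, threshold_um_min),
        n_frames=track.n_frames,
    )


def summarize_trackset(
    tracks: TrackSet, threshold_um_min: float = ARREST_THRESHOLD_UM_MIN
) -> list[MotilitySummary]:
    return [summarize_track(t, threshold_um_min) for t in tracks]
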