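"""Temporal coupling between calcium signals and motility.

Two analyses: (1) pooled scatter / Spearman rank correlation of
instantaneous velocity against the normalized ratio, and (2) the
ratio-rise-triggered velocity average establishing that the calcium rise
precedes the velocity minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ELEVATED_RATIO_THRESHOLD, RatioTrace, Track
from .motility import instantaneous_velocities
from .ratio import pair_velocity_ratio

__all__ = [
    "AlignedAverage",
    "detect_ratio_rises",
    "event_triggered_average",
    "velocity_ratio_scatter",
]


@dataclass
class AlignedAverage:
    """Ca-rise-triggered average of velocity (and ratio) traces."""

    rel_time_s: np.ndarray
    mean_velocity: np.ndarray
    sem_velocity: np.ndarray
    mean_norm_ratio: np.ndarray
    n_events: int
    t_min_s: float
    baseline_window_s: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("aligned average needs >= 1 event")
        if not self.baseline_window_s[1] <= 0:
            raise ValueError("baseline window must precede time 0")
        dts = np.diff(self.rel_time_s)
        if len(dts) and np.max(np.abs(dts - dts[0])) > 1e-6 * abs(dts[0]):
            raise ValueError("relative-time grid must be uniform")


def detect_ratio_rises(
    trace: RatioTrace,
    rise_threshold: float = ELEVATED_RATIO_THRESHOLD,
    min_separation_s: float = 30.0,
) -> np.ndarray:
    """Onset times (s) of upward threshold crossings of the normalized ratio.

    A crossing requires the previous sample at or below threshold and the
    current one above it; crossings within ``min_separation_s`` of the last
    accepted onset are suppressed.
    """
    if trace.norm_ratio is None:
        raise ValueError("trace not normalized")
    r = trace.norm_ratio
    t = trace.t_s
    above = r > rise_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    onsets: list[float] = []
    for idx in crossings:
        if onsets and t[idx] - onsets[-1] < min_separation_s:
            continue
        onsets.append(float(t[idx]))
    return np.array(onsets)


def event_triggered_average(
    cells: list[tuple[Track, RatioTrace, np.ndarray]],
    window_s: tuple[float, float] = (-40.0, 40.0),
    baseline_s: tuple[float, float] = (-30.0, -10.0),
    min_search_s: tuple[float, float] = (0.0, 20.0),
) -> AlignedAverage:
    """Average velocity traces aligned on calcium-rise onsets.

    ``cells`` holds ``(track, normalized trace, onset_times_s)`` triples.
    Velocity segments are resampled onto a common grid by nearest frame
    (step velocities indexed at the earlier frame).  The reported minimum
    is the grid point of minimum mean velocity within ``min_search_s``; the
    p value is a two-tailed paired t-test of per-event velocity at that
    point against each event's own baseline mean.
    """
    if not cells:
        raise ValueError("no cells supplied")
    if not (baseline_s[0] < baseline_s[1] <= 0):
        raise ValueError("baseline window must precede the onset")
    dt = cells[0][0].dt_s
    grid = np.arange(
        np.floor(window_s[0] / dt), np.floor(window_s[1] / dt) + 1
    ) * dt

    v_rows: list[np.ndarray] = []
    r_rows: list[np.ndarray] = []
    for track, trace, onsets in cells:
        v = instantaneous_velocities(track)
        step_t = track.t_s[:-1]
        r = trace.norm_ratio
        for onset in np.atleast_1d(onsets):
            sample_t = onset + grid
            vi = np.rint((sample_t - step_t[0]) / dt).astype(int)
            v_row = np.full(len(grid), np.nan)
            ok = (vi >= 0) & (vi < len(v))
            v_row[ok] = v[vi[ok]]
            r_row = np.full(len(grid), np.nan)
            ri = np.rint((sample_t - track.t_s[0]) / dt).astype(int)
            okr = (ri >= 0) & (ri < len(r))
            r_row[okr] = r[ri[okr]]
            base_mask = (grid >= baseline_s[0]) & (grid <= baseline_s[1])
            post_mask = (grid > 0) & (grid <= window_s[1])
            if np.any(np.isfinite(v_row[base_mask])) and np.any(
                np.isfinite(v_row[post_mask])
            ):
                v_rows.append(v_row)
                r_rows.append(r_row)
    if not v_rows:
        raise ValueError("no qualifying events (need baseline and post-onset data)")
    V = np.vstack(v_rows)
    R = np.vstack(r_rows)
    n_per_point = np.sum(np.isfinite(V), axis=0)
    mean_v = np.nanmean(V, axis=0)
    sem_v = np.nanstd(V, axis=0, ddof=1) / np.sqrt(np.maximum(n_per_point, 1))
    mean_r = np.nanmean(R, axis=0)

    search = (grid >= min_search_s[0]) & (grid <= min_search_s[1])
    search_idx = np.flatnonzero(search)
    t_min_i = search_idx[int(np.nanargmin(mean_v[search]))]
    t_min = float(grid[t_min_i])

    base_mask = (grid >= baseline_s[0]) & (grid <= baseline_s[1])
    with np.errstate(invalid="ignore"):
        per_event_base = np.nanmean(V[:, base_mask], axis=1)
    per_event_min = V[:, t_min_i]
    paired_ok = np.isfinite(per_event_base) & np.isfinite(per_event_min)
    if paired_ok.sum() >= 2:
        t_stat, p = stats.ttest_rel(
            per_event_min[paired_ok], per_event_base[paired_ok]
        )
        p = float(p)
    else:
        p = float("nan")
    return AlignedAverage(
        rel_time_s=grid,
        mean_velocity=mean_v,
        sem_velocity=sem_v,
        mean_norm_ratio=mean_r,
        n_events=len(v_rows),
        t_min_s=t_min,
        baseline_window_s=baseline_s,
        p_value=p,
    )


def velocity_ratio_scatter(
    pairs: list[tuple[Track, RatioTrace]]
) -> dict:
    """Pool (velocity, normalized ratio) pairs and compute Spearman rho.

    Each displacement step contributes its velocity paired with the ratio
    at the step's earlier frame.
    """
    vs: list[np.ndarray] = []
    rs: list[np.ndarray] = []
    for track, trace in pairs:
        v, r = pair_velocity_ratio(track, trace)
        vs.append(v)
        rs.append(r)
    v = np.concatenate(vs)
    r = np.concatenate(rs)
    if len(v) < 10:
        raise ValueError("need >= 10 paired points")
    if np.ptp(v) <= 1e-9 * max(np.max(np.abs(v)), 1e-300) or np.ptp(r) <= 1e-9 * max(
        np.max(np.abs(r)), 1e-300
    ):
        raise ValueError("constant series: Spearman correlation undefined")
    rho, p = stats.spearmanr(v, r)
    return {
        "velocity_um_min": v,
        "norm_ratio": r,
        "rho": float(rho),
        "p_value": float(p),
        "n_pairs": len(v),
    }
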