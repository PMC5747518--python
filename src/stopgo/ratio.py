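"""Ratiometric calcium trace processing.

The ratio R is total green indicator intensity over total red anchor
intensity; R0 is the mean of a trace's first five ratios.  Red-channel
photobleaching is corrected per cell by dividing out the normalized linear
trend fitted to that cell's red trace (multiplicative model), so a flat
trace passes through unchanged and correction is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    ELEVATED_RATIO_THRESHOLD,
    FAST_VELOCITY_THRESHOLD_UM_MIN,
    RatioTrace,
    Track,
)
from .motility import instantaneous_velocities

__all__ = [
    "bleach_correct",
    "normalize_ratio",
    "classify_elevated",
    "quadrant_fractions",
    "velocity_by_ca_state",
    "process_trace",
    "trace_from_track",
    "BleachWarning",
]

N_BASELINE_POINTS = 5


class BleachWarning(UserWarning):
    """Raised when the fitted red decline is outside the expected regime."""


def bleach_correct(R_raw: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Divide out the linear photobleaching trend of a red trace.

    A line ``a + b*t`` is least-squares fitted to ``R_raw``; the corrected
    trace is ``R_raw / (1 + (b/a)*t)``.  A flat trace is returned unchanged
    and the corrected trace has zero linear trend.
    """
    R_raw = np.asarray(R_raw, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if len(R_raw) < N_BASELINE_POINTS:
        raise ValueError("bleach correction needs >= 5 frames")
    if np.any(R_raw < 0):
        raise ValueError("negative red intensities")
    b, a = np.polyfit(t_s, R_raw, 1)
    if a <= 0:
        raise ValueError(f"fitted red intercept non-positive ({a:.3g})")
    span = t_s[-1] - t_s[0]
    decline = -b * span / a
    if decline > 0.60:
        warnings.warn(
            f"fitted red decline {decline:.0%} exceeds 60% over the trace",
            BleachWarning,
            stacklevel=2,
        )
    trend = 1.0 + (b / a) * t_s
    if np.any(trend <= 0):
        raise ValueError("fitted bleaching trend crosses zero within the trace")
    return R_raw / trend


def normalize_ratio(trace: RatioTrace) -> RatioTrace:
    """Fill ``R_corr``, ``ratio`` and ``norm_ratio`` on a trace.

    R0 is the mean of the first five (bleach-corrected) ratios.
    """
    if len(trace.t_s) < N_BASELINE_POINTS:
        raise ValueError("normalization needs >= 5 frames")
    R_corr = trace.R_corr if trace.R_corr is not None else bleach_correct(
        trace.R_raw, trace.t_s
    )
    if np.any(R_corr <= 0):
        raise ValueError("corrected red trace has non-positive values")
    ratio = trace.G / R_corr
    r0 = float(ratio[:N_BASELINE_POINTS].mean())
    if r0 == 0:
        raise ValueError(f"R0 = 0 in trace {trace.cell_id!r}")
    return RatioTrace(
        cell_id=trace.cell_id,
        t_s=trace.t_s,
        G=trace.G,
        R_raw=trace.R_raw,
        R_corr=R_corr,
        ratio=ratio,
        norm_ratio=ratio / r0,
    )


def process_trace(trace: RatioTrace) -> RatioTrace:
    """Bleach-correct and normalize in one call."""
    return normalize_ratio(trace)


def trace_from_track(track: Track) -> RatioTrace:
    if not track.has_fluorescence:
        raise ValueError(f"track {track.cell_id!r} lacks green/red series")
    return RatioTrace(
        cell_id=track.cell_id, t_s=track.t_s, G=track.green, R_raw=track.red
    )


def classify_elevated(
    norm_ratio: np.ndarray, ratio_threshold: float = ELEVATED_RATIO_THRESHOLD
) -> np.ndarray:
    """Boolean series: elevated iff norm_ratio strictly above threshold."""
    return np.asarray(norm_ratio, dtype=float) > ratio_threshold


def quadrant_fractions(
    velocity_um_min: np.ndarray,
    norm_ratio: np.ndarray,
    v_threshold: float = FAST_VELOCITY_THRESHOLD_UM_MIN,
    r_threshold: float = ELEVATED_RATIO_THRESHOLD,
) -> dict[str, float]:
    """Fraction of paired time points in each velocity/ratio quadrant.

    Keys: ``elevated_fast``, ``elevated_slow``, ``basal_fast``,
    ``basal_slow``; strict inequalities at both thresholds; fractions sum
    to 1 exactly.
    """
    v = np.asarray(velocity_um_min, dtype=float)
    r = np.asarray(norm_ratio, dtype=float)
    if v.shape != r.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {r.shape}")
    if len(v) == 0:
        raise ValueError("no paired points")
    elevated = r > r_threshold
    fast = v > v_threshold
    n = len(v)
    return {
        "elevated_fast": float(np.count_nonzero(elevated & fast)) / n,
        "elevated_slow": float(np.count_nonzero(elevated & ~fast)) / n,
        "basal_fast": float(np.count_nonzero(~elevated & fast)) / n,
        "basal_slow": float(np.count_nonzero(~elevated & ~fast)) / n,
    }


def pair_velocity_ratio(track: Track, trace: RatioTrace) -> tuple[np.ndarray, np.ndarray]:
    """Pair each step velocity with the normalized ratio at the step's
    earlier frame."""
    if trace.norm_ratio is None:
        raise ValueError("trace not normalized")
    v = instantaneous_velocities(track)
    return v, trace.norm_ratio[:-1]


def velocity_by_ca_state(
    velocity_um_min: np.ndarray, elevated: np.ndarray
) -> dict[str, float]:
    """State-conditional mean ± SEM of instantaneous velocity.

    Returns NaN mean/SEM for a state with no points; raises only if both
    states are empty.
    """
    v = np.asarray(velocity_um_min, dtype=float)
    mask = np.asarray(elevated, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError("velocity/mask length mismatch")
    if len(v) == 0:
        raise ValueError("no points in either state")

    def _mean_sem(x: np.ndarray) -> tuple[float, float]:
        if len(x) == 0:
            return float("nan"), float("nan")
        sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
        return float(x.mean()), sem

    m_e, s_e = _mean_sem(v[mask])
    m_b, s_b = _mean_sem(v[~mask])
    return {
        "elevated_mean": m_e,
        "elevated_sem": s_e,
        "elevated_n": int(mask.sum()),
        "basal_mean": m_b,
        "basal_sem": s_b,
        "basal_n": int((~mask).sum()),
    }
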