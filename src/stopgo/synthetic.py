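"""Synthetic stop-and-go tracks, coupled calcium traces, and rendered stacks.

The simulator produces ground truth alongside every artifact so that each
downstream estimator (motility statistics, ratio processing, transient
detection, event-triggered averaging) can be validated against known inputs.

Model summary
-------------
Motility is a two-state (go | pause) persistent random walk.  In GO the
heading diffuses with angular variance ``2*dt/persistence_s`` per step and
speed is a per-cell constant drawn around ``mean_speed_um_min``; in PAUSE
the speed is uniform jitter in [0, 1] µm/min.  Pauses start as a Poisson
process and end after an (discretised) exponential dwell.  Calcium traces
superimpose pause-coupled flat-topped transients and brief uncoupled
sparkles on a constant baseline ratio; the red channel declines linearly
(photobleaching).  Image stacks rasterise Gaussian cell footprints and
event blobs with optional stationary autofluorescent bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .datatypes import ImageStack, Track, TrackSet

__all__ = [
    "SimConfig",
    "GroundTruthEvent",
    "GroundTruth",
    "simulate_tracks",
    "simulate_calcium",
    "render_image_stack",
]

#: amplitude of a whole-cell sparkle signal relative to transient_amplitude
#: (sparkles occupy a small subcellular region, so their contribution to the
#: cell-total green trace is scaled down)
SPARKLE_TRACE_SCALE = 0.4

#: go-state speeds are clipped at this floor so that no go frame falls under
#: the 2 µm/min arrest threshold (keeps the pause/arrest mapping exact)
MIN_GO_SPEED_UM_MIN = 2.5


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Defaults emulate lymph-node T-cell recordings: ~11 µm/min mean speed,
    pauses of tens of seconds coupled to global calcium transients that
    lead the velocity minimum by ~5 s, ~2 µm²/~2 s uncoupled sparkles, and
    20–30% red-channel photobleaching over the recording.
    """

    n_cells: int = 50
    duration_s: float = 600.0
    dt_s: float = 5.0
    dim: int = 3
    mean_speed_um_min: float = 11.0
    speed_cv: float = 0.2
    persistence_s: float = 100.0
    pause_rate_per_min: float = 0.5
    pause_mean_s: float = 30.0
    ca_coupled_fraction: float = 0.9
    ca_lead_s: float = 5.0
    sparkle_rate_per_cell_min: float = 2.0
    sparkle_area_um2: float = 2.0
    sparkle_duration_s: float = 2.0
    transient_amplitude: float = 0.5
    bleach_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt_s > 0 and math.isfinite(self.dt_s)):
            raise ValueError("dt_s must be positive and finite")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if not 0 <= self.ca_coupled_fraction <= 1:
            raise ValueError("ca_coupled_fraction must lie in [0, 1]")
        if not 0 <= self.bleach_fraction < 1:
            raise ValueError("bleach_fraction must lie in [0, 1)")
        if self.pause_mean_s < self.dt_s:
            raise ValueError("pause_mean_s must be >= dt_s")
        for name in (
            "duration_s",
            "mean_speed_um_min",
            "persistence_s",
            "pause_rate_per_min",
            "pause_mean_s",
            "sparkle_rate_per_cell_min",
            "sparkle_area_um2",
            "sparkle_duration_s",
            "speed_cv",
            "transient_amplitude",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.dt_s)) + 1


@dataclass
class GroundTruthEvent:
    """True parameters of one simulated calcium event."""

    cell_id: str
    onset_s: float
    peak_s: float
    duration_s: float
    area_um2: float
    klass: str  # "sparkle" | "cell_wide"
    centroid_um: Optional[tuple[float, float]] = None
    amplitude: float = 0.0
    #: index of the coupled pause in the cell's pause list (coupled only)
    pause_index: Optional[int] = None


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst would have to infer."""

    #: cell_id -> list of (start_s, end_s) pause intervals
    pauses: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    #: cell_id -> per-step state string array ("go" | "pause"), length n-1
    states: dict[str, np.ndarray] = field(default_factory=dict)
    #: cell_id -> per-step speed in µm/min, length n-1
    step_speeds: dict[str, np.ndarray] = field(default_factory=dict)
    events: list[GroundTruthEvent] = field(default_factory=list)

    def validate(self) -> None:
        for cid, intervals in self.pauses.items():
            ordered = sorted(intervals)
            for (s0, e0), (s1, _) in zip(ordered, ordered[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping pause intervals in cell {cid!r}")
        coupled = [e for e in self.events if e.pause_index is not None]
        seen: set[tuple[str, int]] = set()
        for ev in coupled:
            key = (ev.cell_id, ev.pause_index)
            if key in seen:
                raise ValueError("two coupled events map to one pause")
            seen.add(key)


def _cell_rng(seed: int, cell_index: int, stream: int = 0) -> np.random.Generator:
    """Independent per-cell substream; stable under cell reordering."""
    return np.random.default_rng([seed, stream, cell_index])


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=dim)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=dim)
        n = np.linalg.norm(v)
    return v / n


def _rotate_heading(
    u: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate unit heading by a Gaussian angle (in-plane for 2D, about a
    random perpendicular axis for 3D); per-step <cos dθ> ≈ exp(-sigma²/2)."""
    theta = rng.normal(0.0, sigma)
    if u.shape[0] == 2:
        c, s = math.cos(theta), math.sin(theta)
        return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
    # 3D: random unit axis perpendicular to u (Rodrigues rotation)
    r = rng.normal(size=3)
    axis = np.cross(u, r)
    n = np.linalg.norm(axis)
    if n < 1e-12:  # pragma: no cover
        return u
    axis /= n
    c, s = math.cos(theta), math.sin(theta)
    return u * c + np.cross(axis, u) * s


def simulate_tracks(config: SimConfig) -> tuple[TrackSet, GroundTruth]:
    """Simulate a two-state persistent random walk per cell.

    Returns the tracks plus ground truth (per-step state sequences, pause
    intervals, per-step speeds).  Deterministic given ``config.seed``.
    """
    n_frames = config.n_frames
    n_steps = n_frames - 1
    dt = config.dt_s
    sigma_theta = math.sqrt(2.0 * dt / config.persistence_s) if config.persistence_s > 0 else math.pi * 4
    p_enter = 1.0 - math.exp(-config.pause_rate_per_min / 60.0 * dt)
    p_exit = 1.0 - math.exp(-dt / config.pause_mean_s)

    truth = GroundTruth()
    tracks: list[Track] = []
    t_s = np.arange(n_frames) * dt

    for ci in range(config.n_cells):
        rng = _cell_rng(config.seed, ci, stream=0)
        cid = f"cell{ci:04d}"
        speed = config.mean_speed_um_min * (1.0 + config.speed_cv * rng.normal())
        speed = max(speed, MIN_GO_SPEED_UM_MIN)

        heading = _unit_vector(rng, config.dim)
        pos = np.zeros((n_frames, config.dim))
        pos[0] = rng.uniform(0.0, 250.0, size=config.dim)
        states = np.empty(n_steps, dtype=object)
        step_speeds = np.empty(n_steps)

        in_pause = False
        for i in range(n_steps):
            if in_pause:
                if rng.random() < p_exit:
                    in_pause = False
                    # arrested cells round up and lose polarity; resume in a
                    # fresh random direction
                    heading = _unit_vector(rng, config.dim)
            else:
                if rng.random() < p_enter:
                    in_pause = True
            # heading keeps diffusing in both states: pausing cells lose
            # directional memory, which shortens directionality decay
            heading = _rotate_heading(heading, sigma_theta, rng)
            if in_pause:
                v = rng.uniform(0.0, 1.0)  # µm/min, always < 2
                states[i] = "pause"
            else:
                v = speed
                states[i] = "go"
            step_speeds[i] = v
            pos[i + 1] = pos[i] + heading * (v / 60.0) * dt

        # pause intervals in seconds (maximal runs of pause steps)
        intervals: list[tuple[float, float]] = []
        i = 0
        while i < n_steps:
            if states[i] == "pause":
                j = i
                while j < n_steps and states[j] == "pause":
                    j += 1
                intervals.append((i * dt, j * dt))
                i = j
            else:
                i += 1

        tracks.append(Track(cell_id=cid, t_s=t_s.copy(), pos_um=pos))
        truth.pauses[cid] = intervals
        truth.states[cid] = states
        truth.step_speeds[cid] = step_speeds

    truth.validate()
    return TrackSet(tracks=tracks, group="sim"), truth


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _flat_top_waveform(
    t: np.ndarray, start_s: float, end_s: float, edge_s: float
) -> np.ndarray:
    """Plateau of 1 between start and end with smoothstep edges."""
    rise = _smoothstep((t - (start_s - edge_s)) / edge_s)
    fall = _smoothstep(((end_s + edge_s) - t) / edge_s)
    return np.minimum(rise, fall)


def simulate_calcium(
    tracks: TrackSet, truth: GroundTruth, config: SimConfig, noise_sd: float = 0.0
) -> tuple[TrackSet, GroundTruth]:
    """Attach green/red fluorescence series to tracks; record true events.

    Red: ``R0 * (1 - bleach_fraction * t / duration) * (1 + noise)``.
    Green: a constant baseline times ``1 + sum(transient waveforms)`` (the
    green fluorophore does not bleach), so the raw ratio drifts upward with
    red bleaching while the true bleach-corrected normalized ratio peaks at
    ``1 + transient_amplitude``.

    Coupled transients are flat-topped and span their pause; each peak is
    placed ``ca_lead_s`` before the pause's minimum-velocity step time.
    Sparkles are temporal Gaussians with FWHM ``sparkle_duration_s`` and a
    reduced whole-cell amplitude (``SPARKLE_TRACE_SCALE``).
    """
    new_tracks: list[Track] = []
    for ci, track in enumerate(tracks):
        cid = track.cell_id
        if cid not in truth.states:
            raise ValueError(f"track {cid!r} missing from ground truth")
        rng = _cell_rng(config.seed, ci, stream=1)
        t = track.t_s
        duration = t[-1] - t[0] if t[-1] > t[0] else 1.0

        shape = 1.0 - config.bleach_fraction * (t - t[0]) / duration
        r0 = 1000.0 * (1.0 + 0.1 * rng.normal())
        r0 = max(r0, 100.0)
        R = r0 * shape
        if noise_sd > 0:
            R = R * (1.0 + noise_sd * rng.normal(size=len(t)))
        R = np.maximum(R, 0.0)

        wave = np.zeros(len(t))
        speeds = truth.step_speeds[cid]
        step_t = t[:-1]  # step i spans [t_i, t_{i+1}); index by earlier frame
        for pi, (p_start, p_end) in enumerate(truth.pauses.get(cid, [])):
            if rng.random() >= config.ca_coupled_fraction:
                continue
            in_pause = (step_t >= p_start - 1e-9) & (step_t < p_end - 1e-9)
            if not np.any(in_pause):
                continue
            idx = np.flatnonzero(in_pause)
            vmin_t = float(step_t[idx[np.argmin(speeds[idx])]])
            peak_s = vmin_t - config.ca_lead_s
            end_s = p_end
            edge = max(2.0, config.dt_s / 2.0)
            w = _flat_top_waveform(t, min(peak_s, end_s), end_s, edge)
            wave = np.maximum(wave, config.transient_amplitude * w)
            truth.events.append(
                GroundTruthEvent(
                    cell_id=cid,
                    onset_s=min(peak_s, end_s) - edge,
                    peak_s=peak_s,
                    duration_s=end_s - min(peak_s, end_s) + 2 * edge,
                    area_um2=50.0,
                    klass="cell_wide",
                    centroid_um=tuple(
                        np.interp(
                            np.clip(peak_s, t[0], t[-1]), t, track.pos_um[:, k]
                        )
                        for k in range(2)
                    ),
                    amplitude=config.transient_amplitude,
                    pause_index=pi,
                )
            )
        # uncoupled sparkles: homogeneous Poisson in time
        n_sparkles = rng.poisson(
            config.sparkle_rate_per_cell_min * duration / 60.0
        )
        amp = SPARKLE_TRACE_SCALE * config.transient_amplitude
        sig = config.sparkle_duration_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        for _ in range(n_sparkles):
            peak_s = rng.uniform(t[0], t[-1])
            if amp > 0:
                wave = np.maximum(
                    wave, amp * np.exp(-0.5 * ((t - peak_s) / sig) ** 2)
                )
            truth.events.append(
                GroundTruthEvent(
                    cell_id=cid,
                    onset_s=peak_s - config.sparkle_duration_s / 2.0,
                    peak_s=peak_s,
                    duration_s=config.sparkle_duration_s,
                    area_um2=config.sparkle_area_um2,
                    klass="sparkle",
                    centroid_um=tuple(
                        np.interp(peak_s, t, track.pos_um[:, k]) for k in range(2)
                    ),
                    amplitude=amp,
                )
            )

        # only the red fluorophore bleaches; the raw ratio therefore drifts
        # upward and bleach correction restores a flat baseline
        g0 = 0.5 * r0
        G = g0 * (1.0 + wave)
        if noise_sd > 0:
            G = G * (1.0 + noise_sd * rng.normal(size=len(t)))
        G = np.maximum(G, 0.0)

        new_tracks.append(
            Track(
                cell_id=cid,
                t_s=t.copy(),
                pos_um=track.pos_um.copy(),
                green=G,
                red=R,
            )
        )
    truth.validate()
    return TrackSet(tracks=new_tracks, group=tracks.group), truth


def _add_gaussian_blob(
    frame: np.ndarray, cx_px: float, cy_px: float, sigma_px: float, amp: float
) -> None:
    """Accumulate an isotropic Gaussian into one 2D frame (in place)."""
    h, w = frame.shape
    r = max(int(math.ceil(4 * sigma_px)), 2)
    x0, x1 = int(math.floor(cx_px)) - r, int(math.floor(cx_px)) + r + 1
    y0, y1 = int(math.floor(cy_px)) - r, int(math.floor(cy_px)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    ys = np.arange(y0c, y1c)[:, None]
    xs = np.arange(x0c, x1c)[None, :]
    frame[y0c:y1c, x0c:x1c] += amp * np.exp(
        -0.5 * (((xs - cx_px) ** 2 + (ys - cy_px) ** 2) / sigma_px**2)
    )


def sparkle_sigma_um(area_um2: float) -> float:
    """Spatial Gaussian sigma whose half-max support covers ``area_um2``."""
    return math.sqrt(area_um2 / (2.0 * math.pi * math.log(2.0)))


def render_image_stack(
    tracks: Optional[TrackSet],
    events: list[GroundTruthEvent],
    pixel_um: float = 0.65,
    dt_s: float = 0.5,
    size_px: tuple[int, int] = (300, 300),
    n_frames: int = 600,
    n_autofluorescent: int = 0,
    seed: int = 0,
    cell_sigma_um: float = 3.0,
    cell_amp: float = 300.0,
    green_baseline_frac: float = 0.15,
    event_amp: float = 600.0,
    autofluor_amp: float = 2000.0,
    background: float = 100.0,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Rasterise tracks and calcium events into a two-channel XY-T stack.

    Red: Gaussian cell footprints following track positions. Green: a dim
    per-cell baseline plus Gaussian event blobs whose half-max support
    matches each event's true area and whose temporal support is a
    rectangular window of the event's true duration (unambiguous ground
    truth).  Stationary bright blobs appear in both channels at
    ``n_autofluorescent`` fixed sites.  Pixels are 16-bit integers with
    shot-noise-like perturbation (Gaussian, variance = mean, above 20
    counts; Poisson below).
    """
    h, w = size_px
    sigma_cell_px = cell_sigma_um / pixel_um
    if 4 * sigma_cell_px > min(h, w):
        raise ValueError("field smaller than one cell footprint")
    rng = np.random.default_rng([seed, 99])

    red = np.full((n_frames, h, w), background, dtype=float)
    green = np.full((n_frames, h, w), background, dtype=float)
    times = np.arange(n_frames) * dt_s

    if tracks is not None:
        for track in tracks:
            px = np.column_stack(
                [
                    np.interp(times, track.t_s, track.pos_um[:, 0]) / pixel_um,
                    np.interp(times, track.t_s, track.pos_um[:, 1]) / pixel_um,
                ]
            )
            for fi in range(n_frames):
                _add_gaussian_blob(red[fi], px[fi, 0], px[fi, 1], sigma_cell_px, cell_amp)
                _add_gaussian_blob(
                    green[fi], px[fi, 0], px[fi, 1], sigma_cell_px,
                    green_baseline_frac * cell_amp,
                )

    truth = GroundTruth()
    for ev in events:
        if ev.centroid_um is None:
            raise ValueError("rendered events need centroids")
        cx = ev.centroid_um[0] / pixel_um
        cy = ev.centroid_um[1] / pixel_um
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"event centroid {ev.centroid_um} outside field")
        sigma_px = sparkle_sigma_um(ev.area_um2) / pixel_um
        f0 = int(round(ev.onset_s / dt_s))
        n_ev_frames = max(int(round(ev.duration_s / dt_s)), 1)
        f1 = f0 + n_ev_frames
        if f0 < 0 or f1 > n_frames:
            raise ValueError("event outside recording")
        amp = event_amp * (ev.amplitude if ev.amplitude > 0 else 1.0)
        for fi in range(f0, f1):
            _add_gaussian_blob(green[fi], cx, cy, sigma_px, amp)
        truth.events.append(ev)

    for _ in range(n_autofluorescent):
        ax = rng.uniform(0.1 * w, 0.9 * w)
        ay = rng.uniform(0.1 * h, 0.9 * h)
        asig = rng.uniform(2.0, 4.0) / pixel_um
        for fi in range(n_frames):
            _add_gaussian_blob(green[fi], ax, ay, asig, autofluor_amp)
            _add_gaussian_blob(red[fi], ax, ay, asig, autofluor_amp)

    if noise:
        for chan in (green, red):
            big = chan > 20
            noise_arr = rng.normal(size=chan.shape) * np.sqrt(np.maximum(chan, 0))
            chan[big] += noise_arr[big]
            small = ~big
            if np.any(small):
                chan[small] = rng.poisson(np.maximum(chan[small], 0))

    green_i = np.clip(np.round(green), 0, 65535).astype(np.uint16)
    red_i = np.clip(np.round(red), 0, 65535).astype(np.uint16)
    stack = ImageStack(green=green_i, red=red_i, pixel_um=pixel_um, dt_s=dt_s)
    return stack, truth
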