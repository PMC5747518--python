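"""Core data containers shared across the pipeline.

Coordinates are physical micrometres, time is seconds from track start,
velocities are reported in µm/min.  Frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Track",
    "TrackSet",
    "RatioTrace",
    "ImageStack",
    "TransientEvent",
]

#: velocity threshold (µm/min) below which a step counts as arrested
ARREST_THRESHOLD_UM_MIN = 2.0
#: per-track mean-velocity threshold (µm/min) used in "slow cell" fractions
SLOW_CELL_THRESHOLD_UM_MIN = 7.0
#: normalized G/R ratio above which calcium is called elevated
ELEVATED_RATIO_THRESHOLD = 1.10
#: instantaneous velocity threshold (µm/min) splitting fast/slow quadrants
FAST_VELOCITY_THRESHOLD_UM_MIN = 10.0


@dataclass
class Track:
    """One cell's time-stamped positions, optionally with fluorescence totals.

    Parameters
    ----------
    cell_id
        Identifier unique within a :class:`TrackSet`.
    t_s
        Strictly increasing sample times in seconds, shape ``(n,)``.
    pos_um
        Positions in µm, shape ``(n, dim)`` with ``dim`` 2 or 3.
    green, red
        Optional per-frame total fluorescence intensities (arbitrary units).
    """

    cell_id: str
    t_s: np.ndarray
    pos_um: np.ndarray
    green: Optional[np.ndarray] = None
    red: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.pos_um = np.asarray(self.pos_um, dtype=float)
        if self.pos_um.ndim != 2 or self.pos_um.shape[1] not in (2, 3):
            raise ValueError(
                f"track {self.cell_id!r}: pos_um must be (n, 2|3), "
                f"got {self.pos_um.shape}"
            )
        n = len(self.t_s)
        if n < 2:
            raise ValueError(f"track {self.cell_id!r}: needs >= 2 frames, got {n}")
        if self.pos_um.shape[0] != n:
            raise ValueError(f"track {self.cell_id!r}: time/position length mismatch")
        if not np.all(np.isfinite(self.t_s)) or not np.all(np.isfinite(self.pos_um)):
            raise ValueError(f"track {self.cell_id!r}: non-finite coordinates")
        dts = np.diff(self.t_s)
        if np.any(dts <= 0):
            bad = int(np.argmax(dts <= 0)) + 1
            raise ValueError(
                f"track {self.cell_id!r}: time not strictly increasing at frame {bad}"
            )
        if np.max(np.abs(dts - dts.mean())) > 0.01 * dts.mean():
            raise ValueError(
                f"track {self.cell_id!r}: frame interval non-uniform beyond 1%"
            )
        for name in ("green", "red"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"track {self.cell_id!r}: {name} length mismatch"
                    )
                setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def dim(self) -> int:
        return self.pos_um.shape[1]

    @property
    def dt_s(self) -> float:
        """Mean frame interval in seconds."""
        return float(np.diff(self.t_s).mean())

    @property
    def has_fluorescence(self) -> bool:
        return self.green is not None and self.red is not None


@dataclass
class TrackSet:
    """A group-labeled collection of tracks sharing dimensionality and Δt."""

    tracks: list[Track]
    group: str = "default"

    def __post_init__(self) -> None:
        if self.tracks:
            dims = {t.dim for t in self.tracks}
            if len(dims) > 1:
                raise ValueError(f"mixed track dimensionality: {sorted(dims)}")
            dts = np.array([t.dt_s for t in self.tracks])
            if np.max(np.abs(dts - dts.mean())) > 0.01 * dts.mean():
                raise ValueError("mixed frame intervals across tracks")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def dim(self) -> int:
        if not self.tracks:
            raise ValueError("empty TrackSet has no dimensionality")
        return self.tracks[0].dim

    @property
    def dt_s(self) -> float:
        if not self.tracks:
            raise ValueError("empty TrackSet has no frame interval")
        return float(np.mean([t.dt_s for t in self.tracks]))


@dataclass
class RatioTrace:
    """Per-cell ratiometric calcium trace (green indicator over red anchor)."""

    cell_id: str
    t_s: np.ndarray
    G: np.ndarray
    R_raw: np.ndarray
    R_corr: Optional[np.ndarray] = None
    ratio: Optional[np.ndarray] = None
    norm_ratio: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.R_raw = np.asarray(self.R_raw, dtype=float)
        n = len(self.t_s)
        for name in ("G", "R_raw", "R_corr", "ratio", "norm_ratio"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{name} length mismatch in trace {self.cell_id!r}")
                setattr(self, name, arr)
        if np.any(self.G < 0) or np.any(self.R_raw < 0):
            raise ValueError(f"negative intensities in trace {self.cell_id!r}")


@dataclass
class ImageStack:
    """Two-channel XY-T intensity stack with physical calibration.

    ``green`` and ``red`` are integer arrays of shape ``(T, Y, X)``.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_um: float
    dt_s: float
    field: str = ""

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ValueError("green/red shape mismatch")
        if self.green.ndim != 3:
            raise ValueError("image stacks must be (T, Y, X)")
        if not self.pixel_um > 0:
            raise ValueError("pixel_um must be positive")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape


@dataclass
class TransientEvent:
    """A detected calcium transient measured from an XY-T component."""

    centroid_xy_um: tuple[float, float]
    onset_s: float
    duration_s: float
    area_um2: float
    x_diameter_um: float
    y_diameter_um: float
    t_diameter_s: float
    integrated_norm_intensity: float
    klass: str  # "sparkle" | "cell_wide"
    n_voxels: int

    def __post_init__(self) -> None:
        if self.klass not in ("sparkle", "cell_wide"):
            raise ValueError(f"unknown event class {self.klass!r}")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive")
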