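"""File formats: track CSV, two-channel TIFF stacks, YAML configs, manifests.

Track CSV schema: ``cell_id, frame, t_s, x_um, y_um[, z_um][, green, red]``.
TIFF stacks are multi-page with channel-interleaved pages (green page, red
page, per frame) and pixel size / frame interval in the image description.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import ImageStack, Track, TrackSet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_stack",
    "write_stack",
    "read_config",
    "write_config",
    "config_hash",
    "write_manifest",
]

REQUIRED_COLUMNS = ("cell_id", "frame", "t_s", "x_um", "y_um")


class TrackParseError(ValueError):
    pass


def read_tracks(path, group: str = "default") -> TrackSet:
    """Load a track CSV into a validated :class:`TrackSet`.

    Missing ``z_um`` means 2D tracks.  Tracks whose sampling is non-uniform
    beyond 1% are rejected with a row-identifying error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing required columns {missing}")
    has_z = "z_um" in df.columns
    has_fluor = "green" in df.columns and "red" in df.columns
    tracks = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        t = sub["t_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            row = int(sub.index[bad[0] + 1]) + 2  # 1-based incl. header
            raise TrackParseError(
                f"{path}: time not increasing for cell {cid!r} at file row {row}"
            )
        cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
        pos = sub[cols].to_numpy(dtype=float)
        tracks.append(
            Track(
                cell_id=str(cid),
                t_s=t,
                pos_um=pos,
                green=sub["green"].to_numpy(dtype=float) if has_fluor else None,
                red=sub["red"].to_numpy(dtype=float) if has_fluor else None,
            )
        )
    return TrackSet(tracks=tracks, group=group)


def write_tracks(tracks: TrackSet, path) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            row = {
                "cell_id": tr.cell_id,
                "frame": i,
                "t_s": tr.t_s[i],
                "x_um": tr.pos_um[i, 0],
                "y_um": tr.pos_um[i, 1],
            }
            if tr.dim == 3:
                row["z_um"] = tr.pos_um[i, 2]
            if tr.has_fluorescence:
                row["green"] = tr.green[i]
                row["red"] = tr.red[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_stack(stack: ImageStack, path) -> None:
    """Write channel-interleaved pages (G0, R0, G1, R1, ...) with metadata."""
    t, h, w = stack.shape
    pages = np.empty((2 * t, h, w), dtype=stack.green.dtype)
    pages[0::2] = stack.green
    pages[1::2] = stack.red
    meta = {
        "pixel_um": stack.pixel_um,
        "dt_s": stack.dt_s,
        "channels": "green,red",
        "field": stack.field,
    }
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_stack(path, pixel_um: float | None = None, dt_s: float | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    pixel_um = pixel_um if pixel_um is not None else meta.get("pixel_um")
    dt_s = dt_s if dt_s is not None else meta.get("dt_s")
    if pixel_um is None or dt_s is None:
        raise ValueError(f"{path}: pixel_um/dt_s not in metadata; pass overrides")
    if pages.shape[0] % 2:
        raise ValueError(f"{path}: odd page count, expected channel-interleaved pairs")
    return ImageStack(
        green=pages[0::2],
        red=pages[1::2],
        pixel_um=float(pixel_um),
        dt_s=float(dt_s),
        field=str(meta.get("field", "")),
    )


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int, outputs: list[str]) -> Path:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "outputs": outputs,
    }
    out = Path(out_dir) / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
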