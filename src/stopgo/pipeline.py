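"""End-to-end pipeline driver: simulate -> motility -> calcium -> detect ->
couple -> compare, with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, detect, io, motility, ratio, stats, synthetic
from .datatypes import TrackSet

log = logging.getLogger("stopgo")

ALL_STAGES = ("simulate", "motility", "calcium", "detect", "couple", "compare")


def run_pipeline(cfg: dict, out_dir, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the configured stages, writing tables and a manifest.

    Returns a dict of in-memory results keyed by stage.  Deterministic
    given the seeds in ``cfg``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outputs: list[str] = []
    results: dict = {}
    seed = int(cfg.get("seed", 0))

    tracks: TrackSet | None = None
    truth = None
    if "simulate" in stages:
        sim_cfg = synthetic.SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
        tracks, truth = synthetic.simulate_tracks(sim_cfg)
        tracks, truth = synthetic.simulate_calcium(tracks, truth, sim_cfg)
        path = out_dir / "tracks.csv"
        io.write_tracks(tracks, path)
        outputs.append(str(path))
        results["simulate"] = {"tracks": tracks, "truth": truth, "config": sim_cfg}
        log.info("simulate: %d tracks, %d true events", len(tracks), len(truth.events))
    elif "tracks_csv" in cfg:
        tracks = io.read_tracks(cfg["tracks_csv"])

    if "motility" in stages:
        if tracks is None:
            raise RuntimeError("motility stage needs tracks (simulate or tracks_csv)")
        summaries = motility.summarize_trackset(tracks)
        df = pd.DataFrame(
            [
                {
                    "cell_id": s.cell_id,
                    "mean_velocity_um_min": s.mean_velocity_um_min,
                    "max_inst_velocity_um_min": s.max_inst_velocity_um_min,
                    "min_inst_velocity_um_min": s.min_inst_velocity_um_min,
                    "arrest_coefficient": s.arrest_coefficient,
                    "cov_percent": s.cov_percent,
                    "n_pauses": len(s.pause_durations_s),
                    "n_frames": s.n_frames,
                }
                for s in summaries
            ]
        )
        path = out_dir / "motility_summary.csv"
        df.to_csv(path, index=False)
        outputs.append(str(path))
        lag, msd, M, _ = motility.msd_curve(tracks)
        elapsed, mean_r, sem_r, tau, _ = motility.directionality_ratio_curve(tracks)
        pd.DataFrame(
            {"lag_min": lag, "msd_um2": msd}
        ).to_csv(out_dir / "msd_curve.csv", index=False)
        pd.DataFrame(
            {"elapsed_s": elapsed, "mean_ratio": mean_r, "sem": sem_r}
        ).to_csv(out_dir / "directionality_curve.csv", index=False)
        outputs += [str(out_dir / "msd_curve.csv"), str(out_dir / "directionality_curve.csv")]
        results["motility"] = {
            "summaries": summaries,
            "motility_coefficient_um2_min": M,
            "directionality_tau_s": tau,
        }
        log.info("motility: M=%.2f µm²/min, tau=%.0f s", M, tau)

    traces = None
    if "calcium" in stages:
        if tracks is None or not tracks.tracks[0].has_fluorescence:
            raise RuntimeError("calcium stage needs tracks with green/red columns")
        traces = [ratio.process_trace(ratio.trace_from_track(t)) for t in tracks]
        rows = []
        for tr, trc in zip(tracks, traces):
            for i in range(tr.n_frames):
                rows.append(
                    {
                        "cell_id": tr.cell_id,
                        "t_s": tr.t_s[i],
                        "G": trc.G[i],
                        "R_raw": trc.R_raw[i],
                        "R_corr": trc.R_corr[i],
                        "ratio": trc.ratio[i],
                        "norm_ratio": trc.norm_ratio[i],
                    }
                )
        path = out_dir / "ratio_traces.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs.append(str(path))
        v_all = np.concatenate(
            [motility.instantaneous_velocities(t) for t in tracks]
        )
        r_all = np.concatenate([trc.norm_ratio[:-1] for trc in traces])
        quads = ratio.quadrant_fractions(v_all, r_all)
        state = ratio.velocity_by_ca_state(v_all, ratio.classify_elevated(r_all))
        with open(out_dir / "calcium_summary.json", "w") as fh:
            json.dump({"quadrants": quads, "velocity_by_state": state}, fh, indent=2)
        outputs.append(str(out_dir / "calcium_summary.json"))
        results["calcium"] = {"traces": traces, "quadrants": quads, "state": state}

    if "detect" in stages:
        stack = None
        if "stack_tiff" in cfg:
            stack = io.read_stack(cfg["stack_tiff"])
        elif truth is not None:
            render = dict(cfg.get("render", {}))
            size_px = tuple(render.pop("size_px", (128, 128)))
            n_frames = int(render.pop("n_frames", 120))
            pixel_um = float(render.pop("pixel_um", 0.65))
            dt_img = float(render.pop("dt_s", 0.5))
            # re-place simulated sparkle events on an in-field grid so the
            # rendered demo stack is self-contained
            demo: list[synthetic.GroundTruthEvent] = []
            rng = np.random.default_rng([seed, 7])
            side = int(np.ceil(np.sqrt(min(len(truth.events), 25)))) or 1
            pitch_x = size_px[1] * pixel_um / side
            pitch_y = size_px[0] * pixel_um / side
            for k, ev in enumerate(e for e in truth.events if e.klass == "sparkle"):
                if k >= side * side:
                    break
                gx, gy = k % side, k // side
                onset = rng.uniform(1.0, max(n_frames * dt_img - ev.duration_s - 1.0, 1.5))
                demo.append(
                    synthetic.GroundTruthEvent(
                        cell_id=ev.cell_id,
                        onset_s=onset,
                        peak_s=onset,
                        duration_s=min(ev.duration_s, n_frames * dt_img / 4),
                        area_um2=ev.area_um2,
                        klass=ev.klass,
                        centroid_um=((gx + 0.5) * pitch_x, (gy + 0.5) * pitch_y),
                        amplitude=1.0,
                    )
                )
            stack, _ = synthetic.render_image_stack(
                tracks=None,
                events=demo,
                pixel_um=pixel_um,
                dt_s=dt_img,
                size_px=size_px,
                n_frames=n_frames,
                seed=seed,
                event_amp=100.0,
                **render,
            )
        if stack is not None:
            masked, mask = detect.mask_autofluorescence(stack)
            events = detect.detect_transients(masked)
            df = pd.DataFrame(
                [
                    {
                        "x_um": e.centroid_xy_um[0],
                        "y_um": e.centroid_xy_um[1],
                        "onset_s": e.onset_s,
                        "duration_s": e.duration_s,
                        "area_um2": e.area_um2,
                        "norm_intensity": e.integrated_norm_intensity,
                        "class": e.klass,
                        "n_voxels": e.n_voxels,
                    }
                    for e in events
                ]
            )
            path = out_dir / "events.csv"
            df.to_csv(path, index=False)
            outputs.append(str(path))
            results["detect"] = {"events": events, "mask": mask}
            log.info("detect: %d events", len(events))

    if "couple" in stages:
        if traces is None or tracks is None:
            raise RuntimeError("couple stage needs calcium traces")
        cells = []
        for tr, trc in zip(tracks, traces):
            onsets = coupling.detect_ratio_rises(trc)
            if len(onsets):
                cells.append((tr, trc, onsets))
        if cells:
            avg = coupling.event_triggered_average(cells)
            pd.DataFrame(
                {
                    "rel_time_s": avg.rel_time_s,
                    "mean_velocity": avg.mean_velocity,
                    "sem_velocity": avg.sem_velocity,
                    "mean_norm_ratio": avg.mean_norm_ratio,
                }
            ).to_csv(out_dir / "aligned_average.csv", index=False)
            outputs.append(str(out_dir / "aligned_average.csv"))
            scatter = coupling.velocity_ratio_scatter(
                [(tr, trc) for tr, trc, _ in cells]
            )
            pd.DataFrame(
                {
                    "velocity_um_min": scatter["velocity_um_min"],
                    "norm_ratio": scatter["norm_ratio"],
                }
            ).to_csv(out_dir / "scatter.csv", index=False)
            outputs.append(str(out_dir / "scatter.csv"))
            results["couple"] = {"aligned": avg, "scatter": scatter}
            log.info(
                "couple: t_min=%+.0f s, p=%.2g, rho=%.3f",
                avg.t_min_s, avg.p_value, scatter["rho"],
            )

    if "compare" in stages and "compare" in cfg:
        spec = cfg["compare"]
        df = pd.read_csv(spec["csv"])
        comparisons = stats.summarize_groups(
            df[spec["metric"]].to_numpy(), df[spec["label"]].to_numpy()
        )
        pd.DataFrame([c.__dict__ for c in comparisons]).to_csv(
            out_dir / "comparisons.csv", index=False
        )
        outputs.append(str(out_dir / "comparisons.csv"))
        results["compare"] = comparisons

    io.write_manifest(out_dir, cfg, seed, outputs)
    return results
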