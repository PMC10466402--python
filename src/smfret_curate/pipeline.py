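"""End-to-end orchestration: simulate/load -> crossings -> FRET -> thresholds
-> classification -> state analysis, with a machine-readable run manifest.

Every stage output is a plain CSV/JSON file that is a valid input for the
next stage.  All randomness flows from the single config seed via derived
per-stage seeds, so a re-run with the same config and inputs is
byte-identical.  On a stage failure a partial manifest naming the failed
stage is still written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, load_config
from .crossover import (
    DetectionIndex,
    density_profile,
    profiles_to_frame,
    summarize_crossovers,
)
from .fret import adjusted_mean_intensity, fret_trace
from .io import filter_min_length, read_detections, read_trajectories
from .model import ACCEPTOR, DONOR, CorrectionFactors
from .simulate import SceneParams, plant_bleach_templates, simulate_scene
from .states import fit_states, pool_fret_with_cells, state_proportions
from .thresholds import (
    classify_region,
    compute_bleach_events,
    infer_thresholds,
    select_templates,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Record of one pipeline run: config, counts, and output digests."""

    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "counts": self.counts,
            "outputs": self.outputs,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config, out_dir) -> RunManifest:
    """Run the full curation chain; returns the manifest (also written).

    ``config`` is a :class:`PipelineConfig` or a path to a YAML/JSON file.
    Inputs come either from ``trajectories_path``/``detections_path`` or
    from the ``simulate`` config section (scene parameters, optionally
    ``n_templates``/``n_correlated`` to plant bleach events).
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    corr = CorrectionFactors(alpha=config.alpha, delta=config.delta, gamma=config.gamma)

    def record(stage: str) -> None:
        manifest.completed_stages.append(stage)

    def fail(stage: str, exc: Exception):
        manifest.failed_stage = stage
        _write_json(manifest.to_dict(), out / "manifest.json")
        raise PipelineError(stage, exc) from exc

    # -- stage: inputs ------------------------------------------------------
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            n_templates = sim.pop("n_templates", 0)
            n_correlated = sim.pop("n_correlated", 0)
            sim.setdefault("seed", config.seed)
            params = SceneParams(**sim)
            if n_templates:
                scene = plant_bleach_templates(
                    params, n_templates, n_correlated,
                    w_pre=config.auroc.window_pre, w_post=config.auroc.window_post,
                )
            else:
                scene = simulate_scene(params)
            scene.write(out / "scene")
            trajectories = scene.trajectories
            acc_index = DetectionIndex(scene.acceptor_detections)
            don_index = DetectionIndex(scene.donor_detections)
        elif config.trajectories_path and config.detections_path:
            trajectories = read_trajectories(config.trajectories_path)
            acc_index = DetectionIndex(read_detections(config.detections_path, ACCEPTOR))
            don_index = DetectionIndex(read_detections(config.detections_path, DONOR))
        else:
            raise ValueError(
                "config must provide either a 'simulate' section or both "
                "trajectories_path and detections_path"
            )
        manifest.counts["trajectories_in"] = len(trajectories)
        if not trajectories:
            raise ValueError("no input trajectories")
        record("inputs")
    except PipelineError:
        raise
    except Exception as exc:
        fail("inputs", exc)

    # -- stage: minimum-length filter --------------------------------------
    try:
        trajectories = filter_min_length(trajectories, config.min_track_frames)
        manifest.counts["trajectories_min_length"] = len(trajectories)
        if not trajectories:
            raise ValueError("no trajectory satisfies the minimum-length filter")
        record("min_length")
    except Exception as exc:
        fail("min_length", exc)

    # -- stage: crossing-over detection ------------------------------------
    try:
        profiles = {
            t.id: density_profile(t, acc_index, don_index, config.d_min_px)
            for t in trajectories
        }
        profiles_to_frame(list(profiles.values())).to_csv(out / "profiles.csv", index=False)
        summary = summarize_crossovers(list(profiles.values()), config.end_window)
        _write_json(summary.to_dict(), out / "crossover_summary.json")
        manifest.counts["frames_total"] = summary.n_frames_total
        n_kept = sum(p.n_kept for p in profiles.values())
        manifest.counts["frames_kept"] = n_kept
        manifest.counts["frames_dropped"] = summary.n_frames_total - n_kept
        record("detect_crossings")
    except Exception as exc:
        fail("detect_crossings", exc)

    # -- stage: intensity summaries ----------------------------------------
    try:
        summaries = {}
        for t in trajectories:
            s = adjusted_mean_intensity(t, profiles[t.id])
            if s is not None:
                summaries[t.id] = s
        pd.DataFrame(
            [
                (s.traj_id, s.cell_id, s.condition, s.mean_donor, s.mean_acceptor, s.n_kept)
                for s in summaries.values()
            ],
            columns=["traj_id", "cell_id", "condition", "mean_don", "mean_acc", "n_kept"],
        ).to_csv(out / "summaries.csv", index=False)
        manifest.counts["trajectories_summarized"] = len(summaries)
        record("intensity_summaries")
    except Exception as exc:
        fail("intensity_summaries", exc)

    # -- stage: templates and thresholds -----------------------------------
    try:
        events = compute_bleach_events(
            trajectories,
            noise_floor=config.auroc.noise_floor,
            w_pre=config.auroc.window_pre,
            w_post=config.auroc.window_post,
        )
        templates = select_templates(
            trajectories, profiles, events,
            auroc_acceptor_max=config.auroc.acceptor_max,
            auroc_donor_min=config.auroc.donor_min,
        )
        th = infer_thresholds(
            templates, trajectories, events,
            w_post=config.auroc.window_post, profiles=profiles,
        )
        _write_json(
            {
                tid: {
                    "t_bleach": events[tid].t_bleach,
                    "auroc_acceptor": events[tid].auroc_acceptor,
                    "auroc_donor": events[tid].auroc_donor,
                }
                for tid in sorted(templates)
            },
            out / "templates.json",
        )
        _write_json(th.to_dict(), out / "thresholds.json")
        manifest.counts["bleach_events"] = len(events)
        manifest.counts["templates"] = len(templates)
        record("thresholds")
    except Exception as exc:
        fail("thresholds", exc)

    # -- stage: region classification --------------------------------------
    try:
        labels = {
            tid: classify_region(s, th, config.fret_low_high_bounds)
            for tid, s in summaries.items()
        }
        pd.DataFrame(
            sorted(labels.items()), columns=["traj_id", "region"]
        ).to_csv(out / "regions.csv", index=False)
        region_counts = {}
        for lab in labels.values():
            region_counts[lab] = region_counts.get(lab, 0) + 1
        manifest.counts["regions"] = region_counts
        record("classify")
    except Exception as exc:
        fail("classify", exc)

    # -- stage: FRET traces -------------------------------------------------
    try:
        traces = [fret_trace(t, profiles[t.id], corr) for t in trajectories]
        rows = []
        for tr in traces:
            for f, e in zip(tr.frames, tr.efficiency):
                rows.append((tr.traj_id, int(f), e))
        pd.DataFrame(rows, columns=["traj_id", "frame", "E"]).to_csv(
            out / "fret.csv", index=False, float_format="%.17g"
        )
        record("fret")
    except Exception as exc:
        fail("fret", exc)

    # -- stage: state analysis ----------------------------------------------
    try:
        accepted = {"high", "medium", "low"}
        values, cells = pool_fret_with_cells(traces, labels, accepted)
        manifest.counts["pooled_values"] = int(len(values))
        model = fit_states(values, k=config.states_k, seed=config.seed)
        props, per_cell = state_proportions(model, values, cells)
        _write_json(
            {
                "model": model.to_dict(),
                "proportions": props.tolist(),
                "per_cell": [
                    {
                        "cell_id": c.cell_id,
                        "fractions": c.fractions.tolist(),
                        "n_frames": c.n_frames,
                    }
                    for c in per_cell
                ],
            },
            out / "states.json",
        )
        record("states")
    except Exception as exc:
        fail("states", exc)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.outputs[str(f.relative_to(out))] = _sha256(f)
    _write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
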