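"""Pipeline configuration (YAML or JSON)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AurocConfig:
    window_pre: int = 10
    window_post: int = 10
    donor_min: float = 0.8
    acceptor_max: float = 0.2
    noise_floor: float | None = None  # None -> robust per-trace estimate


@dataclass
class PipelineConfig:
    """All tunable parameters of the curation pipeline.

    ``d_min_px`` is the crossing-over search radius; detections strictly
    closer than this to the trajectory position count toward the per-frame
    density.  ``alpha``/``delta``/``gamma`` default to the identity
    correction (uncorrected ratio) because they are instrument-specific.
    """

    d_min_px: float = 6.0
    roi_half_width_px: int = 2
    min_track_frames: int = 20
    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    auroc: AurocConfig = field(default_factory=AurocConfig)
    fret_low_high_bounds: tuple[float, float] = (0.3, 0.7)
    states_k: int = 3
    end_window: int = 5
    seed: int = 0
    # input sources: either file paths or a synthetic-scene section
    trajectories_path: str | None = None
    detections_path: str | None = None
    simulate: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fret_low_high_bounds"] = list(self.fret_low_high_bounds)
        return d


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return config_from_dict(raw or {})


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    auroc = AurocConfig(**raw.pop("auroc", {}))
    if "fret" in raw:  # accept the nested spelling fret.low_high_bounds
        fret = raw.pop("fret")
        raw.setdefault("fret_low_high_bounds", fret.get("low_high_bounds", (0.3, 0.7)))
    if "states" in raw:
        states = raw.pop("states")
        raw.setdefault("states_k", states.get("k", 3))
    cfg = PipelineConfig(auroc=auroc, **raw)
    cfg.fret_low_high_bounds = tuple(cfg.fret_low_high_bounds)
    return cfg
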