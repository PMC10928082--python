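"""Pipeline configuration: documented defaults, YAML round-trip, hashing.

The defaults encode the documented acquisition and analysis constants:
0.221 um/px calibration for 40x whole-slide scans, 25 um computational
windows, per-trait selection at alpha = 0.05, and the 1-10 composite score
range.  Every output of the pipeline embeds the configuration hash so runs
are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.221  # 40x whole-slide scan calibration
    # Stain model; None -> package defaults (synthetic SR color, 99th-pct I0).
    sr_vector: tuple[float, float, float] | None = None
    residual_vector: tuple[float, float, float] | None = None
    background_intensity: tuple[float, float, float] | None = None
    background_percentile: float = 99.0
    # Tissue detection and adequacy.
    color_distance_threshold: float = 20.0
    min_seed_area_um2: float = 500.0
    # Collagen segmentation.
    od_floor: float = 0.15
    min_object_px_base: int = 5  # at 1 um/px, scaled by (1/pixel_size)^2
    # Fine/assembled classification.
    class_node_min: int = 2
    class_length_min_um: float = 30.0
    class_width_min_um: float = 3.0
    # Architecture windows and GLCM.
    window_side_um: float = 25.0
    window_overlap_min: float = 0.5
    glcm_levels: int = 16
    glcm_od_range: tuple[float, float] = (0.0, 2.0)
    tau_uniform: float = 5.0
    tau_contrasted: float = 50.0
    # Selection and scoring.
    alpha: float = 0.05
    bh_correction: bool = False
    reference_group: str = "LEAN"
    disease_group: str = "MASH"
    score_lo: float = 1.0
    score_hi: float = 10.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("sr_vector", "residual_vector", "background_intensity", "glcm_od_range"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            json.loads(json.dumps(config.to_dict(), default=list)), fh, sort_keys=True
        )
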