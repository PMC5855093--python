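"""Run-level configuration.

All numeric constants of the quantification protocol live here so that every
output table can be stamped with the exact parameter set that produced it.
Defaults follow the published protocol: granule motion threshold 2 um over a
60 s window, filopodium length threshold 2 um sampled every 5 s over a 300 s
recording, encounter frames every 30 s with a 45 min observation window, the
missorting-index reference line 70 um from the chiasm, and the anterograde
flux segment spanning the last 50 um of shaft before the growth cone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with protocol defaults."""

    # granule transport
    motion_threshold_um: float = 2.0
    motion_window_s: float = 60.0
    domain_bin_s: float = 30.0
    flux_segment_um: float = 50.0
    flux_duration_s: float = 600.0
    # filopodia
    filopodium_length_um: float = 2.0
    filopodia_sampling_s: float = 5.0
    recording_s: float = 300.0
    # encounters
    encounter_frame_s: float = 30.0
    stall_window_min: float = 45.0
    merge_tol_um: float = 1.0
    min_follow_um: float = 10.0
    cross_dist_um: float = 5.0
    cross_max_turn_deg: float = 30.0
    track_min_turn_deg: float = 20.0
    retract_tol_um: float = 5.0
    stall_tol_um: float = 5.0
    # tract sorting
    reference_offset_um: float = 70.0
    # colocalization
    association_radius_um: float = 0.5
    enrichment_factor: float = 1.5
    tip_roi_um: float = 1.0
    # bookkeeping
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name != "seed" and v <= 0:
                raise ValueError(f"RunConfig.{f.name} must be > 0, got {v}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the full parameter set, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load YAML/JSON config; keyword overrides take precedence."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)
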