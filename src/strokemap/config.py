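"""Run configuration: one serializable object carrying every stage's parameters.

Defaults follow the study design this package models: 5 subjects x 21
collections at 15-min intervals, a 500-count intensity filter, LOESS span
0.75, 16 clusters, a 0.5 membership-selection threshold with 4 dominant
clusters, +/-0.180 Da binning with 3.84% detection-frequency retention,
|log2FC| > 1 differential filtering, and Fisher alpha 0.01.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0

    # schedule
    subjects: int = 5
    baseline_collections: int = 4
    interval_min: int = 15
    phase_durations: dict = field(
        default_factory=lambda: {"I": 60, "II": 60, "III": 120, "IV": 60}
    )

    # synthetic generator
    n_features: int = 10529
    archetype_fraction: float = 0.6
    noise_cv: float = 0.2
    tic_spread: float = 0.1
    drift_amplitude: float = 0.1
    missing_rate: float = 0.05
    subject_cv: float = 0.25
    planted_events: list = field(default_factory=list)

    # preprocessing
    intensity_threshold: float = 500.0
    loess_span: float = 0.75

    # fuzzy c-means
    c: int = 16
    m: float = 1.25
    select_grid: bool = False
    c_grid: list = field(default_factory=lambda: [8, 12, 16, 20])
    m_grid: list = field(default_factory=lambda: [1.1, 1.3, 1.5, 2.0])
    n_init: int = 10
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 200

    # labeling
    membership_threshold: float = 0.5
    dominant_k: int = 4
    dominant_override: list = field(default_factory=list)

    # phase statistics
    baseline_phase: str = "I"

    # spatial
    spatial: bool = False
    grid_width: int = 40
    grid_height: int = 40
    n_peaks: int = 285
    n_up: int = 21
    n_down: int = 29
    effect_log2fc: float = 2.0
    spatial_noise_cv: float = 0.05
    bin_tolerance: float = 0.180
    min_detection_freq: float = 0.0384
    segmentation_k: int = 3
    fc_threshold: float = 1.0

    # enrichment
    alpha: float = 0.01
    pathway_map: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
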