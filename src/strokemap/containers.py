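"""Central exchange objects shared by the pipeline stages."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """Features x samples intensity table with sample and feature metadata.

    ``intensities`` is indexed by feature id with one column per sample id;
    missing measurements are NaN.  ``sample_meta`` is indexed by sample id and
    carries ``subject``, ``collection_index``, ``injection_order`` and
    ``phase``.  ``feature_meta`` is indexed by feature id and carries ``mz``
    plus optional ``pathway``, and generator-only ground-truth columns
    (``archetype``, ``planted_fc``, ``planted_phase``).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    transform_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intensities.empty:
            raise ValueError("feature table is empty")
        if not self.intensities.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta must cover every intensity column, in order")
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ValueError("feature_meta must cover every intensity row, in order")
        if not self.intensities.index.is_unique:
            raise ValueError("feature ids must be unique")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError("intensities must be non-negative where present")

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            transform_log=copy.deepcopy(self.transform_log),
        )

    def log_step(self, step: str, **params) -> None:
        self.transform_log.append({"step": step, **params})


@dataclass
class PixelGrid:
    """Spatial grid of per-pixel mass spectra.

    ``peaks`` is a long table with columns ``x, y, mz, intensity`` (one row
    per detected peak; m/z strictly increasing within a pixel).  ``roi_masks``
    maps names (e.g. ``lesion``, ``contralateral``) to boolean (height, width)
    arrays.  ``planted`` is generator-only ground truth: per-peak true log2
    fold change between the lesion and contralateral regions.
    """

    width: int
    height: int
    peaks: pd.DataFrame
    roi_masks: dict = field(default_factory=dict)
    planted: pd.DataFrame | None = None
    pixel_size_um: float = 200.0

    def __post_init__(self) -> None:
        required = {"x", "y", "mz", "intensity"}
        if not required.issubset(self.peaks.columns):
            raise ValueError(f"peaks table needs columns {sorted(required)}")
        if (self.peaks["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        for name, mask in self.roi_masks.items():
            if mask.shape != (self.height, self.width):
                raise ValueError(f"roi mask {name!r} does not match the grid shape")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height
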