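"""Readers and writers for the pipeline's tabular interchange formats.

Feature tables travel as a CSV trio (wide intensities + sample_meta +
feature_meta sidecars) with the transform log as JSON; pixel grids as a long
CSV (x, y, mz, intensity) plus a mask CSV (mask, x, y).  A provenance JSON
records parameters, seeds and content hashes of every written file.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, PixelGrid


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_feature_table(table: FeatureTable, outdir, prefix: str = "features") -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [
        outdir / f"{prefix}_intensities.csv",
        outdir / f"{prefix}_sample_meta.csv",
        outdir / f"{prefix}_feature_meta.csv",
        outdir / f"{prefix}_transform_log.json",
    ]
    table.intensities.to_csv(paths[0])
    table.sample_meta.to_csv(paths[1])
    table.feature_meta.to_csv(paths[2])
    paths[3].write_text(json.dumps(table.transform_log, indent=2, default=str))
    return paths


def read_feature_table(outdir, prefix: str = "features") -> FeatureTable:
    outdir = Path(outdir)
    intens = pd.read_csv(outdir / f"{prefix}_intensities.csv", index_col=0)
    sample_meta = pd.read_csv(outdir / f"{prefix}_sample_meta.csv", index_col=0)
    feature_meta = pd.read_csv(
        outdir / f"{prefix}_feature_meta.csv", index_col=0, keep_default_na=False,
        na_values=[""],
    )
    if "archetype" in feature_meta:
        feature_meta["archetype"] = feature_meta["archetype"].fillna("")
    if "planted_phase" in feature_meta:
        feature_meta["planted_phase"] = feature_meta["planted_phase"].fillna("")
    log_path = outdir / f"{prefix}_transform_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else []
    return FeatureTable(intensities=intens, sample_meta=sample_meta,
                        feature_meta=feature_meta, transform_log=log)


def write_pixel_grid(grid: PixelGrid, outdir, prefix: str = "grid") -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks_path = outdir / f"{prefix}_peaks.csv"
    masks_path = outdir / f"{prefix}_masks.csv"
    grid.peaks.to_csv(peaks_path, index=False)
    rows = []
    for name, mask in grid.roi_masks.items():
        ys, xs = np.nonzero(mask)
        rows.append(pd.DataFrame({"mask": name, "x": xs, "y": ys}))
    pd.concat(rows, ignore_index=True).to_csv(masks_path, index=False)
    paths = [peaks_path, masks_path]
    if grid.planted is not None:
        truth_path = outdir / f"{prefix}_planted.csv"
        grid.planted.to_csv(truth_path, index=False)
        paths.append(truth_path)
    return paths


def read_pixel_grid(outdir, prefix: str = "grid",
                    width: int | None = None, height: int | None = None) -> PixelGrid:
    outdir = Path(outdir)
    peaks = pd.read_csv(outdir / f"{prefix}_peaks.csv")
    masks_df = pd.read_csv(outdir / f"{prefix}_masks.csv")
    if width is None:
        width = int(peaks["x"].max()) + 1
    if height is None:
        height = int(peaks["y"].max()) + 1
    masks = {}
    for name, g in masks_df.groupby("mask"):
        m = np.zeros((height, width), dtype=bool)
        m[g["y"].to_numpy(), g["x"].to_numpy()] = True
        masks[name] = m
    truth_path = outdir / f"{prefix}_planted.csv"
    planted = pd.read_csv(truth_path) if truth_path.exists() else None
    return PixelGrid(width=width, height=height, peaks=peaks,
                     roi_masks=masks, planted=planted)


def read_imzml(path) -> pd.DataFrame:
    """Read an imzML file into the long (x, y, mz, intensity) peak format."""
    from pyimzml.ImzMLParser import ImzMLParser  # optional dependency

    parser = ImzMLParser(str(path))
    rows = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, intens = parser.getspectrum(i)
        rows.append(pd.DataFrame(
            {"x": x - 1, "y": y - 1, "mz": mzs, "intensity": intens}
        ))
    return pd.concat(rows, ignore_index=True)


def write_provenance(outdir, config_dict: dict, outputs, timings: dict | None = None):
    """Manifest of a run: config, environment, and per-file content hashes."""
    outdir = Path(outdir)
    manifest = {
        "config": config_dict,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timings_s": timings or {},
        "outputs": {
            str(Path(p).name): sha256_of(p) for p in outputs if Path(p).exists()
        },
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
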