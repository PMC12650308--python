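"""End-to-end orchestration: simulate -> preprocess -> cluster -> label ->
statistics -> enrichment, and/or the spatial branch, with every intermediate
written to disk and hashed into a provenance manifest."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import fcm, io, labeling, phasestats, preprocess, spatial, synth
from .config import RunConfig
from .schedule import build_schedule

log = logging.getLogger("strokemap")


def run_pipeline(config: RunConfig, outdir, temporal: bool = True) -> dict:
    """Execute the configured stages, returning the in-memory artifacts.

    Writes intensities, memberships, labels, statistics, spatial tables and
    a provenance manifest under ``outdir``.  Deterministic under a fixed
    ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    outputs: list = []
    timings: dict = {}
    stage = "configure"
    try:
        if temporal:
            stage = "simulate"
            t0 = time.perf_counter()
            schedule = build_schedule(
                subjects=config.subjects,
                baseline_collections=config.baseline_collections,
                interval_min=config.interval_min,
                phase_durations=config.phase_durations,
            )
            table = synth.generate_feature_table(
                n_features=config.n_features,
                archetype_fraction=config.archetype_fraction,
                schedule=schedule,
                noise_cv=config.noise_cv,
                tic_spread=config.tic_spread,
                drift_amplitude=config.drift_amplitude,
                missing_rate=config.missing_rate,
                planted_events=[tuple(e) for e in config.planted_events],
                subject_cv=config.subject_cv,
                seed=config.seed,
            )
            outputs += io.write_feature_table(table, outdir, "raw")
            artifacts["schedule"] = schedule
            artifacts["raw"] = table
            timings[stage] = time.perf_counter() - t0

            stage = "preprocess"
            t0 = time.perf_counter()
            filled, matrix = preprocess.run_chain(
                table, config.intensity_threshold, config.loess_span
            )
            outputs += io.write_feature_table(filled, outdir, "processed")
            shape = preprocess.pool_and_standardize(filled)
            artifacts["processed"] = filled
            artifacts["standardized"] = matrix
            artifacts["shape_matrix"] = shape
            timings[stage] = time.perf_counter() - t0

            stage = "cluster"
            t0 = time.perf_counter()
            X = shape.values.to_numpy()
            c, m = config.c, config.m
            if config.select_grid:
                c, m, xb_table = fcm.select_parameters(
                    X, config.c_grid, config.m_grid, seed=config.seed,
                    n_init=config.n_init, tol=config.fcm_tol,
                    max_iter=config.fcm_max_iter,
                )
                xb_path = outdir / "xb_grid.csv"
                xb_table.to_csv(xb_path, index=False)
                outputs.append(xb_path)
                artifacts["xb_table"] = xb_table
            model, U = fcm.fit_fcm(
                X, c=c, m=m, seed=config.seed, tol=config.fcm_tol,
                max_iter=config.fcm_max_iter, n_init=config.n_init,
            )
            artifacts["model"] = model
            artifacts["memberships"] = U
            model_path = outdir / "cluster_model.json"
            import json
            model_path.write_text(json.dumps(model.to_dict(), indent=2))
            outputs.append(model_path)
            timings[stage] = time.perf_counter() - t0

            stage = "label"
            t0 = time.perf_counter()
            annotations = labeling.annotate_clusters(model.centroids, schedule)
            codes = [a.code for a in annotations]
            dominant = (set(config.dominant_override) if config.dominant_override
                        else labeling.identify_dominant(U, config.dominant_k, codes))
            labels = labeling.assign_labels(
                U, annotations, dominant, config.membership_threshold,
                feature_ids=shape.values.index,
            )
            memb_path = outdir / "memberships.csv"
            pd.DataFrame(U, index=shape.values.index, columns=codes).to_csv(memb_path)
            labels_path = outdir / "labels.csv"
            labeling.labels_to_frame(labels).to_csv(labels_path)
            groups, Z = labeling.hca_on_memberships(U, n_groups=min(model.c, U.shape[0]))
            newick_path = outdir / "membership_dendrogram.newick"
            if U.shape[0] <= 2000:  # keep the text artifact reviewable
                newick_path.write_text(
                    labeling.linkage_to_newick(Z, shape.values.index)
                )
                outputs.append(newick_path)
            outputs += [memb_path, labels_path]
            artifacts["annotations"] = annotations
            artifacts["dominant"] = dominant
            artifacts["labels"] = labels
            artifacts["hca_groups"] = groups
            timings[stage] = time.perf_counter() - t0

            stage = "stats"
            t0 = time.perf_counter()
            stats = phasestats.trajectory_stats(
                filled, schedule, baseline_phase=config.baseline_phase
            )
            stats_path = outdir / "trajectory_stats.csv"
            stats.to_csv(stats_path)
            outputs.append(stats_path)
            artifacts["stats"] = stats
            timings[stage] = time.perf_counter() - t0

            if config.pathway_map:
                stage = "enrich"
                t0 = time.perf_counter()
                pathways = enrich_mod.read_pathway_map(config.pathway_map)
                annotated = set().union(*pathways.values())
                background = [f for f in matrix.values.index if f in annotated]
                selected = [lab.feature_id for lab in labels
                            if lab.selected and lab.feature_id in annotated]
                ora = enrich_mod.fisher_ora(selected, background, pathways,
                                            alpha=config.alpha)
                ora_path = outdir / "enrichment.csv"
                ora.to_csv(ora_path, index=False)
                outputs.append(ora_path)
                artifacts["enrichment"] = ora
                timings[stage] = time.perf_counter() - t0

        if config.spatial:
            stage = "spatial"
            t0 = time.perf_counter()
            grid = synth.generate_pixel_grid(
                width=config.grid_width, height=config.grid_height,
                n_peaks=config.n_peaks, n_up=config.n_up, n_down=config.n_down,
                effect_log2fc=config.effect_log2fc,
                noise_cv=config.spatial_noise_cv, seed=config.seed,
            )
            outputs += io.write_pixel_grid(grid, outdir)
            bins = spatial.bin_peaks(grid, config.bin_tolerance,
                                     config.min_detection_freq)
            seg = spatial.cluster_pixels(bins, k=config.segmentation_k)
            diff = spatial.roi_differential(
                bins, grid.roi_masks["lesion"], grid.roi_masks["contralateral"],
                fc_threshold=config.fc_threshold,
            )
            bins_path = outdir / "spatial_bins.csv"
            bins.intensities.to_csv(bins_path)
            labels_path = outdir / "spatial_labels.csv"
            pd.DataFrame({
                "x": seg.pixel_index.get_level_values("x"),
                "y": seg.pixel_index.get_level_values("y"),
                "cluster": seg.labels,
            }).to_csv(labels_path, index=False)
            diff_path = outdir / "spatial_differential.csv"
            diff.to_csv(diff_path, index=False)
            outputs += [bins_path, labels_path, diff_path]
            artifacts["grid"] = grid
            artifacts["bins"] = bins
            artifacts["segmentation"] = seg
            artifacts["differential"] = diff
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifacts["provenance"] = io.write_provenance(
        outdir, config.to_dict(), outputs, timings
    )
    log.info("pipeline complete: %d output files in %s", len(outputs), outdir)
    return artifacts
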