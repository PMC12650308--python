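"""Planted-truth benchmark constructions used by the validation suite.

Each benchmark isolates the noise source it is probing: the clustering
benchmark carries measurement noise only (no TIC variation, drift or
dropout), and the fold-change benchmarks likewise, so recovery measures the
method against the named perturbation rather than a compound of nuisances.
The full nuisance stack is exercised by the pipeline tests instead.
"""

from __future__ import annotations

import numpy as np

from . import fcm, phasestats, preprocess, spatial
from .schedule import build_schedule
from .synth import generate_feature_table, generate_pixel_grid


def archetype_shape_matrix(seed: int, n_per_archetype: int = 50,
                           noise_cv: float = 0.05):
    """Standardized pooled trajectories for 16 planted archetype groups.

    Returns (X, codes): 16 * n_per_archetype shape vectors over the default
    21-collection grid, and the planted archetype code of every row.
    """
    schedule = build_schedule()
    table = generate_feature_table(
        n_features=16 * n_per_archetype, archetype_fraction=1.0,
        schedule=schedule, noise_cv=noise_cv, tic_spread=0.0,
        drift_amplitude=0.0, missing_rate=0.0, seed=seed,
    )
    filled, _ = preprocess.run_chain(table, intensity_threshold=0.0)
    shape = preprocess.pool_and_standardize(filled)
    codes = table.feature_meta.loc[shape.values.index, "archetype"].to_numpy()
    return shape.values.to_numpy(), codes


def cluster_count_benchmark(seed: int, n_per_archetype: int = 50,
                            c_grid=(8, 12, 16, 20), m_grid=(1.1, 1.5, 2.0),
                            n_init: int = 3):
    """Select (c, m) by Xie-Beni on planted archetypes and fit at c*.

    Returns (fitted cluster count, n rows, selection table).
    """
    X, _ = archetype_shape_matrix(seed, n_per_archetype)
    c_star, m_star, table = fcm.select_parameters(
        X, c_grid=c_grid, m_grid=m_grid, seed=seed, n_init=n_init
    )
    model, _ = fcm.fit_fcm(X, c=c_star, m=m_star, seed=seed, n_init=n_init)
    return model.c, len(X), table


def peak_binning_benchmark(seed: int, width: int = 40, height: int = 40,
                           n_peaks: int = 285):
    """Bin a grid with well-separated peaks present in every pixel.

    Returns (retained bin count, pixel count).
    """
    grid = generate_pixel_grid(width=width, height=height, n_peaks=n_peaks,
                               n_up=0, n_down=0, seed=seed)
    bins = spatial.bin_peaks(grid, tolerance=0.180, min_freq=0.0384)
    return bins.n_bins, grid.n_pixels


def roi_differential_benchmark(seed: int, n_peaks: int = 285,
                               n_up: int = 21, n_down: int = 29,
                               noise_cv: float = 0.02):
    """Differential filter on a two-region grid with planted effects.

    Returns (passing, up, down, bins).
    """
    grid = generate_pixel_grid(width=40, height=40, n_peaks=n_peaks,
                               n_up=n_up, n_down=n_down, effect_log2fc=2.0,
                               noise_cv=noise_cv, seed=seed)
    bins = spatial.bin_peaks(grid, tolerance=0.180, min_freq=0.0384)
    diff = spatial.roi_differential(bins, grid.roi_masks["lesion"],
                                    grid.roi_masks["contralateral"],
                                    fc_threshold=1.0)
    up = int((diff["pass"] & (diff["direction"] == "up")).sum())
    down = int((diff["pass"] & (diff["direction"] == "down")).sum())
    return int(diff["pass"].sum()), up, down, bins.n_bins


def fold_change_benchmark(seed: int, key_phase: str, fold_change: float,
                          noise_cv: float = 0.1, n_features: int = 50):
    """Pooled key-time fold change of one planted event among null features.

    Returns (recovered fold change, n samples).
    """
    schedule = build_schedule()
    target = f"F{n_features - 1:06d}"
    table = generate_feature_table(
        n_features=n_features, archetype_fraction=0.0, schedule=schedule,
        noise_cv=noise_cv, tic_spread=0.0, drift_amplitude=0.0,
        missing_rate=0.0,
        planted_events=[(target, key_phase, fold_change)], seed=seed,
    )
    pooled = phasestats.pool_subjects(table)
    fc = phasestats.key_time_fold_change(pooled.loc[target].to_numpy(),
                                         schedule, key_phase)
    return float(fc), table.n_samples
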