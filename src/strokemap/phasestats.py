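"""Trajectory statistics against the phase schedule.

Two summary statistics characterize each feature's time course:

* SD Energy — the standard deviation of the (TIC-normalized) trajectory
  across all collections, a global temporal-fluctuation magnitude;
* key-time fold change — the ratio of the trajectory's mean over its
  signature phase to its mean over the pre-occlusion baseline (phase I).

Trajectories are pooled across subjects by per-collection means before the
statistics are taken; per-subject variants are available for dispersion
reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .schedule import PHASES, PhaseSchedule


def pool_subjects(table: FeatureTable) -> pd.DataFrame:
    """Per-collection mean across subjects: features x collections."""
    coll = table.sample_meta["collection_index"]
    pooled = table.intensities.T.groupby(coll.to_numpy()).mean().T
    pooled.columns.name = "collection_index"
    return pooled


def phase_means(traj: np.ndarray, schedule: PhaseSchedule) -> dict:
    """Arithmetic mean of the trajectory within each phase block."""
    traj = np.asarray(traj, dtype=float)
    if len(traj) != schedule.n_collections:
        raise ValueError(
            f"trajectory length {len(traj)} does not match "
            f"{schedule.n_collections} collections"
        )
    present = [p for p in PHASES if len(schedule.phase_indices(p))]
    return {p: float(traj[schedule.phase_indices(p)].mean()) for p in present}


def key_time_fold_change(
    traj: np.ndarray,
    schedule: PhaseSchedule,
    key_phase: str | None = None,
    baseline_phase: str = "I",
) -> float:
    """mean(key phase) / mean(baseline phase).

    ``key_phase`` accepts fine tokens, "III", or unions like "IIIA+IIIB";
    when omitted it defaults to the phase containing the trajectory maximum.
    """
    traj = np.asarray(traj, dtype=float)
    if len(traj) != schedule.n_collections:
        raise ValueError("trajectory length does not match the schedule")
    base_idx = schedule.phase_indices(baseline_phase)
    base = traj[base_idx].mean()
    if not base > 0:
        raise ValueError(
            f"baseline phase {baseline_phase} mean is {base!r}; fold change "
            "needs a positive baseline (gap-fill or offset the trajectory)"
        )
    if key_phase is None:
        key_phase = schedule.phase_of(int(np.argmax(traj)))
    key_idx = schedule.phase_indices(key_phase)
    return float(traj[key_idx].mean() / base)


def sd_energy(traj: np.ndarray) -> float:
    """Standard deviation of the trajectory across all collections."""
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise ValueError("trajectory is empty")
    return float(traj.std(ddof=0))


def trajectory_stats(
    table: FeatureTable,
    schedule: PhaseSchedule,
    key_phase: str | None = None,
    baseline_phase: str = "I",
) -> pd.DataFrame:
    """Pooled per-feature statistics: phase means, SD Energy, key-time FC."""
    pooled = pool_subjects(table)
    rows = []
    for fid, traj in pooled.iterrows():
        t = traj.to_numpy(dtype=float)
        means = phase_means(t, schedule)
        kp = key_phase or schedule.phase_of(int(np.argmax(t)))
        rows.append({
            "feature_id": fid,
            **{f"mean_{p}": v for p, v in means.items()},
            "sd_energy": sd_energy(t),
            "key_phase": kp,
            "key_time_fc": key_time_fold_change(t, schedule, kp, baseline_phase),
        })
    return pd.DataFrame(rows).set_index("feature_id")


def pathway_trajectory_table(
    features: list,
    stats: pd.DataFrame,
    labels: list,
) -> pd.DataFrame:
    """Join masked primary labels with SD Energy and key-time fold change.

    One row per requested feature; raises if any feature is missing from the
    statistics or the labels.
    """
    by_id = {lab.feature_id: lab for lab in labels}
    orphans = [f for f in features if f not in by_id or f not in stats.index]
    if orphans:
        raise ValueError(f"features missing from stats or labels: {orphans}")
    rows = [
        {
            "feature_id": f,
            "masked_primary": by_id[f].masked_primary,
            "annotation": by_id[f].annotation,
            "sd_energy": float(stats.loc[f, "sd_energy"]),
            "key_time_fc": float(stats.loc[f, "key_time_fc"]),
        }
        for f in features
    ]
    out = pd.DataFrame(rows, columns=["feature_id", "masked_primary", "annotation",
                                      "sd_energy", "key_time_fc"])
    return out.set_index("feature_id") if len(out) else out
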