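import numpy as np
import pandas as pd
import pytest

from strokemap.containers import FeatureTable
from strokemap.schedule import build_schedule
from strokemap.synth import generate_feature_table, generate_pixel_grid


@pytest.fixture(scope="session")
def schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def clean_archetype_table(schedule):
    """Zero-noise table: 160 features, 10 per archetype, no nuisances."""
    return generate_feature_table(
        n_features=160, archetype_fraction=1.0, schedule=schedule,
        noise_cv=0.0, tic_spread=0.0, drift_amplitude=0.0, missing_rate=0.0,
        subject_cv=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def noisy_table(schedule):
    """Realistic small table with all nuisance processes and planted events."""
    return generate_feature_table(
        n_features=120, archetype_fraction=0.5, schedule=schedule,
        noise_cv=0.1, tic_spread=0.1, drift_amplitude=0.1, missing_rate=0.05,
        planted_events=[("F000100", "IV", 10.0), ("F000101", "IIIA+IIIB", 6.0)],
        seed=23,
    )


@pytest.fixture(scope="session")
def small_grid():
    return generate_pixel_grid(
        width=12, height=12, n_peaks=30, n_up=5, n_down=7,
        effect_log2fc=2.0, noise_cv=0.02, seed=3,
    )


def make_table(values, schedule=None, missing=None):
    """Hand-built FeatureTable over the default schedule's sample grid."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if missing is not None:
        values = values.copy()
        values[missing] = np.nan
    fids = pd.Index([f"F{i:06d}" for i in range(n_feat)], name="feature_id")
    sids = pd.Index([f"S{j:03d}" for j in range(n_samp)], name="sample_id")
    rng = np.random.default_rng(0)
    if schedule is not None and n_samp == schedule.n_samples:
        n_coll = schedule.n_collections
        meta = pd.DataFrame({
            "subject": np.repeat(np.arange(schedule.subject_count), n_coll),
            "collection_index": np.tile(np.arange(n_coll), schedule.subject_count),
            "phase": np.tile(schedule.phase, schedule.subject_count),
            "injection_order": rng.permutation(n_samp),
        }, index=sids)
    else:
        meta = pd.DataFrame({
            "subject": 0,
            "collection_index": np.arange(n_samp),
            "phase": "I",
            "injection_order": rng.permutation(n_samp),
        }, index=sids)
    fmeta = pd.DataFrame({"mz": 100.0 + np.arange(n_feat)}, index=fids)
    return FeatureTable(intensities=pd.DataFrame(values, index=fids, columns=sids),
                        sample_meta=meta, feature_meta=fmeta)
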