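"""Synthetic data with the statistical structure of the occlusion/reperfusion study.

Two generators live here:

* :func:`generate_feature_table` — longitudinal microdialysis-style feature
  tables: 5 subjects x 21 collections at 15-min intervals, features drawn
  from 16 kinetic archetypes (A..P) plus null (flat) features, with
  multiplicative log-normal measurement noise, per-sample total-ion-current
  variation, a smooth injection-order drift and limit-of-detection dropout.
* :func:`generate_pixel_grid` — imaging-style pixel grids with a planted
  lesion region whose mirrored contralateral region serves as control.

The archetype templates are deterministic, positive, piecewise
linear/Gaussian-bump realizations of 16 qualitative kinetic signatures
(ramps, sharp and broad peaks, boundary peaks, global monotone trends, and a
fluctuating profile).  They carry declared annotations (peak location, trend,
phase scope) against which the labeling stage's automatic annotator is
checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable, PixelGrid
from .schedule import PhaseSchedule

ARCHETYPE_CODES = tuple("ABCDEFGHIJKLMNOP")


@dataclass(frozen=True)
class ArchetypeSpec:
    """One kinetic archetype: template builder plus declared annotation."""

    code: str
    description: str
    peak_location: str | None  # coarse phase, 'X/Y' boundary, 'X+Y' pair, or None
    trend: str  # increase | decrease | peak | biphasic | fluctuating
    scope: str  # phase token or 'all'
    shape_fn: Callable[[PhaseSchedule], np.ndarray]


def _bump(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))


def _phase_center(schedule: PhaseSchedule, phase: str) -> float:
    idx = schedule.phase_indices(phase)
    return float(idx.mean())


def _boundary(schedule: PhaseSchedule, token: str) -> float:
    # midpoint between the last collection of X and the first of Y
    return schedule.transitions()[token] - 0.5


def _build_specs() -> dict:
    def t_axis(s: PhaseSchedule) -> np.ndarray:
        return np.arange(s.n_collections, dtype=float)

    def a(s):  # gradual decline across phase I, then flat
        t = t_axis(s)
        i_end = s.phase_indices("I")[-1]
        v = np.ones_like(t)
        ramp = np.clip((i_end - t) / max(i_end, 1), 0.0, 1.0)
        return v + 1.0 * ramp

    def b(s):  # rapid decline within the first collections of phase I
        t = t_axis(s)
        return 1.0 + 1.5 * np.exp(-t / 0.45)

    def c(s):  # sharp peak inside phase I
        t = t_axis(s)
        return 1.0 + 2.0 * np.exp(-((t - _phase_center(s, "I")) ** 2) / (2 * 0.7**2))

    def d(s):  # peaks in both I and II
        t = t_axis(s)
        return (1.0 + _bump(t, _phase_center(s, "I"), 0.8, 1.6)
                + _bump(t, _phase_center(s, "II"), 0.8, 1.6))

    def e(s):  # peak at the II -> III boundary
        t = t_axis(s)
        return 1.0 + _bump(t, _boundary(s, "II/IIIA"), 1.1, 2.0)

    def f(s):  # peaks in II and III (narrow pair)
        t = t_axis(s)
        iii = s.phase_indices("III")
        return (1.0 + _bump(t, _phase_center(s, "II"), 0.8, 1.6)
                + _bump(t, float(np.quantile(iii, 0.35)), 0.8, 1.6))

    def g(s):  # peaks in II and III (broader, later pair)
        t = t_axis(s)
        iii = s.phase_indices("III")
        return (1.0 + _bump(t, _phase_center(s, "II") + 0.5, 1.3, 1.4)
                + _bump(t, float(np.quantile(iii, 0.8)), 1.3, 1.4))

    def h(s):  # broad peak spanning phase III
        t = t_axis(s)
        iii = s.phase_indices("III")
        return 1.0 + _bump(t, float(iii.mean()), len(iii) / 3.5, 2.0)

    def i(s):  # peak at the III -> IV boundary
        t = t_axis(s)
        return 1.0 + _bump(t, _boundary(s, "IIIB/IV"), 0.8, 2.2)

    def j(s):  # peak at the end of III, incomplete recovery afterwards
        t = t_axis(s)
        peak_at = float(s.phase_indices("III")[-1])
        v = 1.0 + _bump(t, peak_at, 0.9, 2.2)
        return np.where(t > peak_at, np.maximum(v, 1.9), v)

    def k(s):  # broad peak at the III -> IV boundary
        t = t_axis(s)
        return 1.0 + _bump(t, _boundary(s, "IIIB/IV"), 3.0, 1.6)

    def l(s):  # rapid increase across phase IV
        t = t_axis(s)
        iv = s.phase_indices("IV")
        v = np.ones_like(t)
        v[iv] = 1.0 + 0.9 * (np.arange(len(iv)) + 1)
        return v

    def m(s):  # flat, then gradual decline across phase IV
        t = t_axis(s)
        iv = s.phase_indices("IV")
        v = np.full_like(t, 2.0)
        v[iv] = 2.0 - 0.25 * (np.arange(len(iv)) + 1)
        return v

    def n(s):  # continuous fluctuation throughout
        t = t_axis(s)
        period = s.n_collections / 3.0
        return 1.6 + 0.8 * np.sin(2 * np.pi * t / period)

    def o(s):  # gradual decline throughout all phases
        t = t_axis(s)
        return 2.5 - 2.0 * t / (s.n_collections - 1)

    def p(s):  # gradual increase throughout all phases
        t = t_axis(s)
        return 0.5 + 2.0 * t / (s.n_collections - 1)

    raw = [
        ("A", "gradual decline during phase I", None, "decrease", "I", a),
        ("B", "rapid decline during phase I", None, "decrease", "I", b),
        ("C", "sharp peak within phase I", "I", "peak", "I", c),
        ("D", "peaks during phases I and II", "I+II", "biphasic", "I+II", d),
        ("E", "peak at the II/III boundary", "II/III", "peak", "II+III", e),
        ("F", "peaks during phases II and III", "II+III", "biphasic", "II+III", f),
        ("G", "broad peaks during phases II and III", "II+III", "biphasic", "II+III", g),
        ("H", "broad peak during phase III", "III", "peak", "III", h),
        ("I", "peak at the III/IV boundary", "III/IV", "peak", "III+IV", i),
        ("J", "peak at the end of phase III without full recovery", "III/IV", "peak", "III+IV", j),
        ("K", "broad peak at the III/IV boundary", "III/IV", "peak", "III+IV", k),
        ("L", "rapid increase during phase IV", None, "increase", "IV", l),
        ("M", "gradual decline during phase IV", None, "decrease", "IV", m),
        ("N", "continuous fluctuation throughout all phases", None, "fluctuating", "all", n),
        ("O", "gradual decline throughout all phases", None, "decrease", "all", o),
        ("P", "gradual increase throughout all phases", None, "increase", "all", p),
    ]
    return {
        code: ArchetypeSpec(code, desc, peak, trend, scope, fn)
        for code, desc, peak, trend, scope, fn in raw
    }


ARCHETYPES: dict = _build_specs()


def archetype_template(code: str, schedule: PhaseSchedule) -> np.ndarray:
    """Zero-noise positive template of archetype ``code`` over the collections."""
    if code not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype code {code!r}; valid codes: {', '.join(ARCHETYPE_CODES)}"
        )
    v = ARCHETYPES[code].shape_fn(schedule)
    if np.any(v <= 0):
        raise AssertionError(f"template {code} is not strictly positive")
    return v


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_feature_table(
    n_features: int = 10529,
    archetype_fraction: float = 0.6,
    schedule: PhaseSchedule | None = None,
    noise_cv: float = 0.2,
    tic_spread: float = 0.1,
    drift_amplitude: float = 0.1,
    missing_rate: float = 0.05,
    planted_events: Sequence[tuple] | None = None,
    subject_cv: float = 0.25,
    seed: int = 0,
) -> FeatureTable:
    """Simulate a longitudinal microdialysis feature table.

    Each archetype feature's noiseless trajectory is ``base x template x
    subject scale``; measurements multiply in log-normal noise (CV =
    ``noise_cv``), a per-sample total-signal factor (CV = ``tic_spread``) and
    a linear injection-order drift of relative amplitude
    ``drift_amplitude``.  ``planted_events`` is a list of ``(feature_id,
    key_phase, fold_change)`` tuples; a planted feature's template is flat at
    the phase-I baseline and raised to ``fold_change`` over ``key_phase``, so
    at zero noise the pooled key-phase/baseline ratio equals the request
    exactly.  Missing values are injected among each feature's
    below-median cells (limit-of-detection dropout).

    Archetype codes are assigned cyclically to the first
    ``round(archetype_fraction * n_features)`` features, so equal per-code
    counts are obtained when the count divides evenly.
    """
    from .schedule import build_schedule

    for name, v in [("archetype_fraction", archetype_fraction),
                    ("noise_cv", noise_cv), ("tic_spread", tic_spread),
                    ("drift_amplitude", drift_amplitude), ("missing_rate", missing_rate)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if schedule is None:
        schedule = build_schedule()
    rng = np.random.default_rng(seed)

    n_coll = schedule.n_collections
    n_sub = schedule.subject_count
    n_samples = n_sub * n_coll

    feature_ids = [f"F{i:06d}" for i in range(n_features)]
    subjects = [f"R{j + 1}" for j in range(n_sub)]
    sample_ids = [f"{s}_T{t:02d}" for s in subjects for t in range(n_coll)]

    sample_meta = pd.DataFrame(
        {
            "subject": np.repeat(subjects, n_coll),
            "collection_index": np.tile(np.arange(n_coll), n_sub),
            "time_min": np.tile(schedule.time_min, n_sub),
            "phase": np.tile(schedule.phase, n_sub),
            "injection_order": rng.permutation(n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    n_arch = int(round(archetype_fraction * n_features))
    codes = np.array([""] * n_features, dtype=object)
    codes[:n_arch] = [ARCHETYPE_CODES[i % len(ARCHETYPE_CODES)] for i in range(n_arch)]

    templates = np.ones((n_features, n_coll))
    cached = {c: archetype_template(c, schedule) for c in ARCHETYPE_CODES}
    for i in range(n_arch):
        templates[i] = cached[codes[i]]

    planted_fc = np.full(n_features, np.nan)
    planted_phase = np.array([""] * n_features, dtype=object)
    id_pos = {fid: i for i, fid in enumerate(feature_ids)}
    for fid, key_phase, fc in planted_events or []:
        if fid not in id_pos:
            raise ValueError(f"planted event references unknown feature {fid!r}")
        idx = schedule.phase_indices(key_phase)  # raises on unknown phase
        i = id_pos[fid]
        tmpl = np.ones(n_coll)
        tmpl[idx] = float(fc)
        templates[i] = tmpl
        codes[i] = "planted"
        planted_fc[i] = float(fc)
        planted_phase[i] = str(key_phase)

    base = rng.lognormal(mean=np.log(5e3), sigma=1.0, size=n_features)
    subj_scale = _lognormal_factor(rng, subject_cv, (n_features, n_sub))

    clean = (base[:, None, None] * subj_scale[:, :, None]
             * templates[:, None, :]).reshape(n_features, n_samples)

    noise = _lognormal_factor(rng, noise_cv, (n_features, n_samples))
    tic = _lognormal_factor(rng, tic_spread, n_samples)
    order = sample_meta["injection_order"].to_numpy()
    drift = (1.0 + drift_amplitude * (2.0 * order / max(n_samples - 1, 1) - 1.0)
             if drift_amplitude > 0 else np.ones(n_samples))

    values = clean * noise * tic[None, :] * drift[None, :]

    if missing_rate > 0:
        k = int(round(missing_rate * n_samples))
        med = np.median(values, axis=1, keepdims=True)
        for i in range(n_features):
            low = np.flatnonzero(values[i] < med[i])
            if len(low) == 0:
                continue
            drop = rng.choice(low, size=min(k, len(low)), replace=False)
            values[i, drop] = np.nan

    feature_meta = pd.DataFrame(
        {
            "mz": np.sort(rng.uniform(50.0, 1300.0, size=n_features)),
            "archetype": codes,
            "planted_fc": planted_fc,
            "planted_phase": planted_phase,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    table = FeatureTable(
        intensities=pd.DataFrame(values, index=feature_meta.index, columns=sample_meta.index),
        sample_meta=sample_meta,
        feature_meta=feature_meta,
    )
    table.log_step(
        "simulate", n_features=n_features, archetype_fraction=archetype_fraction,
        noise_cv=noise_cv, tic_spread=tic_spread, drift_amplitude=drift_amplitude,
        missing_rate=missing_rate, subject_cv=subject_cv, seed=seed,
    )
    return table


def rectangle_mask(width: int, height: int, x0: int, x1: int, y0: int, y1: int) -> np.ndarray:
    """Boolean (height, width) mask for the half-open rectangle [x0,x1) x [y0,y1)."""
    if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
        raise ValueError("mask rectangle falls outside the grid")
    mask = np.zeros((height, width), dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


def generate_pixel_grid(
    width: int = 40,
    height: int = 40,
    n_peaks: int = 285,
    lesion_mask_spec: tuple | None = None,
    n_up: int = 21,
    n_down: int = 29,
    effect_log2fc: float = 2.0,
    noise_cv: float = 0.05,
    mz_start: float = 100.0,
    mz_spacing: float = 0.5,
    mz_jitter: float = 0.02,
    seed: int = 0,
) -> PixelGrid:
    """Simulate an imaging-style pixel grid with a planted lesion region.

    Every pixel carries all ``n_peaks`` peaks at consensus m/z centers spaced
    ``mz_spacing`` Da apart (with per-pixel jitter of SD ``mz_jitter``).
    Inside the lesion mask, ``n_up`` randomly chosen peaks are shifted up and
    ``n_down`` down by ``effect_log2fc`` log2 units; the contralateral mask
    is the lesion's mirror across the vertical midline and stays at baseline.
    """
    if n_up + n_down > n_peaks:
        raise ValueError("n_up + n_down must not exceed n_peaks")
    rng = np.random.default_rng(seed)

    if lesion_mask_spec is None:
        lesion_mask_spec = (width // 10, width // 10 + max(width // 4, 1),
                            height // 4, height - height // 4)
    x0, x1, y0, y1 = lesion_mask_spec
    lesion = rectangle_mask(width, height, x0, x1, y0, y1)
    contra = np.fliplr(lesion)
    if (lesion & contra).any():
        raise ValueError("lesion mask overlaps its mirrored contralateral region")

    centers = mz_start + mz_spacing * np.arange(n_peaks)
    base = rng.lognormal(mean=np.log(1e3), sigma=0.8, size=n_peaks)

    affected = rng.choice(n_peaks, size=n_up + n_down, replace=False)
    log2fc = np.zeros(n_peaks)
    log2fc[affected[:n_up]] = effect_log2fc
    log2fc[affected[n_up:]] = -effect_log2fc

    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    xs, ys = xs.ravel(), ys.ravel()
    in_lesion = lesion[ys, xs]

    n_pix = width * height
    inten = base[None, :] * np.where(in_lesion[:, None], 2.0 ** log2fc[None, :], 1.0)
    inten = inten * _lognormal_factor(rng, noise_cv, (n_pix, n_peaks))
    mz = np.broadcast_to(centers, (n_pix, n_peaks)).copy()
    if mz_jitter > 0:
        mz += rng.normal(0.0, mz_jitter, (n_pix, n_peaks))

    peaks = pd.DataFrame(
        {
            "x": np.repeat(xs, n_peaks),
            "y": np.repeat(ys, n_peaks),
            "mz": mz.ravel(),
            "intensity": inten.ravel(),
        }
    ).sort_values(["y", "x", "mz"], kind="stable", ignore_index=True)

    planted = pd.DataFrame(
        {"mz_center": centers, "base_intensity": base, "log2fc": log2fc}
    )
    return PixelGrid(width=width, height=height, peaks=peaks,
                     roi_masks={"lesion": lesion, "contralateral": contra},
                     planted=planted)
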