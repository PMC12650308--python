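"""Experimental phase schedule for the occlusion/reperfusion time course.

The microdialysis design samples brain interstitial fluid at a fixed interval
(15 min by default) across five operational phases:

* ``I``    — probe implantation / baseline,
* ``II``   — filament insertion (occlusion surgery),
* ``IIIA`` — early ischemia,
* ``IIIB`` — late ischemia,
* ``IV``   — reperfusion.

Collections are taken at ``t = 0, interval, 2*interval, ...`` up to and
including the end of the last phase, so a 1 h + 1 h + 2 h + 1 h design at
15 min yields 21 collections per subject (fencepost at t = 0).  A collection
at time ``t`` belongs to the phase whose half-open window ``[start, end)``
contains it; the final collection (exactly at the end of the last phase) is
assigned to the last phase.  Under the defaults this places exactly four
baseline collections before the occlusion surgery begins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASES = ("I", "II", "IIIA", "IIIB", "IV")

#: Coarse phase for each fine phase: early and late ischemia merge into "III".
COARSE_PHASE = {"I": "I", "II": "II", "IIIA": "III", "IIIB": "III", "IV": "IV"}

DEFAULT_PHASE_DURATIONS = {"I": 60, "II": 60, "III": 120, "IV": 60}


class ScheduleConfigError(ValueError):
    """Raised when phase durations are incompatible with the interval."""


@dataclass(frozen=True)
class PhaseSchedule:
    """Per-subject collection grid with phase assignment.

    Attributes
    ----------
    time_min : np.ndarray
        Minutes from the first collection, one entry per collection,
        consecutive entries differing by ``interval_min``.
    phase : np.ndarray
        Phase token for every collection (one of :data:`PHASES`).
    subject_count : int
        Number of subjects sharing this grid.
    interval_min : int
        Collection interval in minutes.
    """

    time_min: np.ndarray
    phase: np.ndarray
    subject_count: int
    interval_min: int
    phase_starts: dict = field(default_factory=dict)

    @property
    def n_collections(self) -> int:
        return len(self.time_min)

    @property
    def n_samples(self) -> int:
        return self.subject_count * self.n_collections

    @property
    def collection_index(self) -> np.ndarray:
        return np.arange(self.n_collections)

    def phase_indices(self, phase: str) -> np.ndarray:
        """Collection indices belonging to ``phase``.

        ``phase`` may be a fine token ("IIIA"), the coarse token "III"
        (early + late ischemia), or a '+'-joined union such as "IIIA+IIIB".
        """
        parts = _expand_phase_token(phase)
        mask = np.isin(self.phase, parts)
        return np.flatnonzero(mask)

    def phase_of(self, collection: int) -> str:
        return str(self.phase[collection])

    def transitions(self) -> dict:
        """Map 'X/Y' boundary tokens to the first collection index of Y."""
        out = {}
        for i in range(1, self.n_collections):
            a, b = self.phase[i - 1], self.phase[i]
            if a != b:
                out[f"{a}/{b}"] = i
        return out


def _expand_phase_token(phase: str) -> list:
    parts = []
    for tok in str(phase).split("+"):
        tok = tok.strip()
        if tok == "III":
            parts += ["IIIA", "IIIB"]
        elif tok in PHASES:
            parts.append(tok)
        else:
            raise ValueError(
                f"unknown phase token {tok!r}; expected one of "
                f"{PHASES + ('III',)} or a '+'-joined union"
            )
    return parts


def build_schedule(
    subjects: int = 5,
    baseline_collections: int = 4,
    interval_min: int = 15,
    phase_durations: dict | None = None,
) -> PhaseSchedule:
    """Build the per-subject collection schedule.

    Parameters
    ----------
    subjects : int
        Number of subjects (default 5).
    baseline_collections : int
        Minimum number of collections that must precede phase II (the
        pre-occlusion baseline samples; default 4).
    interval_min : int
        Minutes between consecutive collections (default 15).
    phase_durations : dict
        Minutes per phase, keyed ``I, II, III, IV``; the ischemia block
        ``III`` is split evenly into IIIA and IIIB.  Default 60/60/120/60.

    Raises
    ------
    ScheduleConfigError
        If any duration is not a positive multiple of ``interval_min`` (the
        ischemia half-blocks included), or the baseline does not fit phase I.
    """
    if subjects < 1:
        raise ScheduleConfigError("subjects must be a positive integer")
    if baseline_collections < 1:
        raise ScheduleConfigError("baseline_collections must be >= 1")
    if interval_min <= 0:
        raise ScheduleConfigError("interval_min must be positive")
    durations = dict(DEFAULT_PHASE_DURATIONS if phase_durations is None else phase_durations)

    fine: list[tuple[str, int]] = []
    for name in ("I", "II", "III", "IV"):
        if name not in durations:
            continue
        dur = durations[name]
        if dur <= 0 or dur % interval_min:
            raise ScheduleConfigError(
                f"phase {name} duration {dur} min is not a positive multiple "
                f"of the {interval_min} min interval"
            )
        if name == "III":
            half = dur // 2
            if half % interval_min:
                raise ScheduleConfigError(
                    f"phase III duration {dur} min does not split into IIIA/IIIB "
                    f"halves that are multiples of the {interval_min} min interval"
                )
            fine += [("IIIA", half), ("IIIB", half)]
        else:
            fine.append((name, dur))
    if not fine:
        raise ScheduleConfigError("at least one phase duration is required")

    total = sum(d for _, d in fine)
    time_min = np.arange(0, total + interval_min, interval_min)

    starts, cum = {}, 0
    for name, dur in fine:
        starts[name] = cum
        cum += dur

    phase = np.empty(len(time_min), dtype=object)
    for name, dur in fine:
        lo = starts[name]
        phase[(time_min >= lo) & (time_min < lo + dur)] = name
    phase[time_min == total] = fine[-1][0]  # closing fencepost -> last phase

    n_before_ii = int(np.sum(time_min < starts.get("II", total)))
    if "II" in starts and n_before_ii < baseline_collections:
        raise ScheduleConfigError(
            f"only {n_before_ii} collections precede phase II; "
            f"{baseline_collections} baseline collections requested "
            f"(extend phase I or shorten the interval)"
        )

    return PhaseSchedule(
        time_min=time_min,
        phase=phase.astype(str),
        subject_count=int(subjects),
        interval_min=int(interval_min),
        phase_starts=starts,
    )
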