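"""Kinetic labels from memberships: cluster annotation, dominant-cluster
correction, threshold selection, and hierarchical grouping of soft labels.

Soft clustering concentrates membership mass in a few dominant clusters
(typically the global monotone/fluctuating shapes), which masks features
with distinctive transient dynamics — the "drowning effect".  The correction
takes, for every feature, the highest-membership cluster *outside* the
dominant set as its primary characteristic, and selects features whose
non-dominant membership exceeds a threshold (0.5 by default, strict).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from .schedule import COARSE_PHASE, PhaseSchedule

COARSE = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ClusterAnnotation:
    """Automatic kinetic annotation of one cluster centroid."""

    code: str
    cluster_index: int
    peak_location: str | None  # coarse phase, 'X/Y' boundary, 'X+Y' pair, or None
    trend: str  # increase | decrease | peak | biphasic | fluctuating
    scope: str  # coarse phase token, 'X+Y', or 'all'
    description: str


@dataclass(frozen=True)
class LabelAssignment:
    """Per-feature kinetic label after the dominant-cluster correction."""

    feature_id: str
    primary_cluster: str
    masked_primary: str
    selected: bool
    memberships_above_threshold: tuple
    annotation: str


def _coarse_blocks(schedule: PhaseSchedule) -> dict:
    return {p: schedule.phase_indices(p) for p in COARSE if len(schedule.phase_indices(p))}


def _coarse_transitions(schedule: PhaseSchedule) -> dict:
    out = {}
    for token, idx in schedule.transitions().items():
        a, b = (COARSE_PHASE[p] for p in token.split("/"))
        if a != b:
            out[f"{a}/{b}"] = idx
    return out


def _annotate_one(
    centroid: np.ndarray,
    schedule: PhaseSchedule,
    peak_margin: float = 0.5,
    boundary_tol: float = 1.0,
    rho_thresh: float = 0.8,
    restricted_leak: float = 0.35,
) -> tuple:
    """Classify one centroid; returns (peak_location, trend, scope)."""
    v = np.asarray(centroid, dtype=float)
    if len(v) != schedule.n_collections:
        raise ValueError("centroid length does not match the schedule")
    sd = v.std()
    if sd < 1e-12:
        return None, "fluctuating", "all"
    z = (v - v.mean()) / sd
    n = len(z)
    blocks = _coarse_blocks(schedule)
    trans = _coarse_transitions(schedule)
    i_max = int(np.argmax(z))

    peaks, props = find_peaks(z, prominence=peak_margin)
    if i_max not in (0, n - 1) and len(peaks) > 0:
        if len(peaks) >= 3:
            return None, "fluctuating", "all"
        phases = [str(COARSE_PHASE[schedule.phase_of(p)]) for p in peaks]
        if len(peaks) == 2 and phases[0] != phases[1]:
            loc = f"{phases[0]}+{phases[1]}"
            return loc, "biphasic", loc
        # single (or same-phase double) peak: boundary or mid-phase
        top = int(peaks[np.argmax(props["prominences"])])
        for token, idx in trans.items():
            if abs(top - (idx - 0.5)) <= boundary_tol:
                return token, "peak", "+".join(token.split("/"))
        return phases[np.argmax(props["prominences"])] if len(peaks) > 1 else \
            str(COARSE_PHASE[schedule.phase_of(top)]), "peak", \
            str(COARSE_PHASE[schedule.phase_of(top)])

    # no interior peak: restricted trend, global monotone, else fluctuating
    ranges = {p: float(z[idx].max() - z[idx].min()) for p, idx in blocks.items()}
    best_phase = max(ranges, key=ranges.get)
    inside = blocks[best_phase]
    outside = np.setdiff1d(np.arange(n), inside)
    out_range = float(z[outside].max() - z[outside].min()) if len(outside) > 1 else 0.0
    if ranges[best_phase] > 0 and out_range <= restricted_leak * ranges[best_phase]:
        rho = spearmanr(np.arange(len(inside)), z[inside]).statistic
        if abs(rho) >= rho_thresh:
            return None, ("increase" if rho > 0 else "decrease"), best_phase
    rho = spearmanr(np.arange(n), z).statistic
    if abs(rho) >= rho_thresh:
        return None, ("increase" if rho > 0 else "decrease"), "all"
    return None, "fluctuating", "all"


def _describe(peak_location, trend, scope) -> str:
    if trend == "peak":
        where = f"at the {peak_location} boundary" if "/" in str(peak_location) \
            else f"during phase {peak_location}"
        return f"peak {where}"
    if trend == "biphasic":
        return f"peaks during phases {peak_location.replace('+', ' and ')}"
    if trend in ("increase", "decrease"):
        where = "throughout all phases" if scope == "all" else f"during phase {scope}"
        return f"gradual {trend} {where}"
    return "continuous fluctuation throughout all phases"


def _letters(c: int) -> list:
    alphabet = string.ascii_uppercase
    if c <= len(alphabet):
        return list(alphabet[:c])
    return [f"C{i:02d}" for i in range(c)]


def annotate_clusters(
    centroids: np.ndarray,
    schedule: PhaseSchedule,
    peak_margin: float = 0.5,
    boundary_tol: float = 1.0,
    rho_thresh: float = 0.8,
) -> list:
    """Annotate every centroid and assign letter codes in narrative order.

    Codes are assigned by sorting clusters by (event locality, event time):
    phase-localized events (peaks, boundary peaks, phase-restricted trends)
    come first in order of when they occur, then global trends and
    fluctuating shapes.  The ordering rule is this package's own convention
    for reproducible letter codes.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    parsed = [
        _annotate_one(v, schedule, peak_margin, boundary_tol, rho_thresh)
        for v in centroids
    ]
    keys = []
    for idx, (loc, trend, scope) in enumerate(parsed):
        z = centroids[idx]
        localized = not (scope == "all")
        if trend in ("peak", "biphasic"):
            event_t = float(np.argmax(z))
        elif localized:
            block = schedule.phase_indices(scope.replace("+", "+"))
            event_t = float(np.mean(block))
        else:
            event_t = float(schedule.n_collections + idx)
        keys.append((0 if localized else 1, event_t, idx))
    order = sorted(range(len(parsed)), key=lambda i: keys[i])
    codes = _letters(len(parsed))
    code_of = {cluster: codes[rank] for rank, cluster in enumerate(order)}
    return [
        ClusterAnnotation(
            code=code_of[i], cluster_index=i, peak_location=loc, trend=trend,
            scope=scope, description=_describe(loc, trend, scope),
        )
        for i, (loc, trend, scope) in enumerate(parsed)
    ]


def identify_dominant(U: np.ndarray, k: int = 4, codes=None) -> set:
    """The k clusters holding the largest total membership mass.

    Ties are broken by code order.  ``codes`` defaults to letters in column
    order.
    """
    U = np.asarray(U, dtype=float)
    c = U.shape[1]
    if k >= c:
        raise ValueError("k must be smaller than the number of clusters")
    if codes is None:
        codes = _letters(c)
    if k == 0:
        return set()
    mass = U.sum(axis=0)
    ranked = sorted(range(c), key=lambda j: (-mass[j], codes[j]))
    return {codes[j] for j in ranked[:k]}


def assign_labels(
    U: np.ndarray,
    annotations: list,
    dominant: set,
    threshold: float = 0.5,
    feature_ids=None,
) -> list:
    """Per-feature labels with the dominant-cluster correction applied.

    ``primary_cluster`` is the global argmax; ``masked_primary`` is the
    argmax over non-dominant clusters; a feature is ``selected`` iff any
    non-dominant membership strictly exceeds ``threshold``.  Ties resolve to
    the alphabetically first code.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    U = np.asarray(U, dtype=float)
    n, c = U.shape
    codes = [a.code for a in sorted(annotations, key=lambda a: a.cluster_index)]
    ann_of = {a.code: a for a in annotations}
    unknown = dominant - set(codes)
    if unknown:
        raise ValueError(f"dominant set references unknown codes: {sorted(unknown)}")
    if set(codes) <= set(dominant):
        raise ValueError("dominant set covers all clusters; nothing left to label")
    if feature_ids is None:
        feature_ids = [f"F{i:06d}" for i in range(n)]

    # resolve ties in alphabetical code order
    alpha = sorted(range(c), key=lambda j: codes[j])
    non_dom = [j for j in alpha if codes[j] not in dominant]
    out = []
    for i in range(n):
        row = U[i]
        primary = codes[alpha[int(np.argmax(row[alpha]))]]
        masked = codes[non_dom[int(np.argmax(row[non_dom]))]]
        above = tuple(
            (codes[j], float(row[j])) for j in non_dom if row[j] > threshold
        )
        out.append(
            LabelAssignment(
                feature_id=str(feature_ids[i]),
                primary_cluster=primary,
                masked_primary=masked,
                selected=len(above) > 0,
                memberships_above_threshold=above,
                annotation=ann_of[masked].description,
            )
        )
    return out


def labels_to_frame(labels: list) -> pd.DataFrame:
    rows = []
    for lab in labels:
        top = sorted(lab.memberships_above_threshold, key=lambda t: -t[1])[:3]
        rows.append({
            "feature_id": lab.feature_id,
            "primary": lab.primary_cluster,
            "masked_primary": lab.masked_primary,
            "selected": lab.selected,
            "above_threshold": ";".join(f"{c}:{u:.3f}" for c, u in top),
            "annotation": lab.annotation,
        })
    return pd.DataFrame(rows).set_index("feature_id")


def hca_on_memberships(U: np.ndarray, n_groups: int) -> tuple:
    """Ward/Euclidean agglomeration of features in membership space.

    Returns (labels, linkage matrix); labels are contiguous from 0 in order
    of first appearance.
    """
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must lie in [1, {n}]")
    Z = linkage(U, method="ward", metric="euclidean")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    seen: dict = {}
    labels = np.array([seen.setdefault(g, len(seen)) for g in raw])
    return labels, Z


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = to_tree(Z)
    names = list(map(str, leaf_names))

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"
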