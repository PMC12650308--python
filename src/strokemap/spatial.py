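"""Imaging-grid pipeline: spectrum smoothing, tolerance-window peak binning
with a detection-frequency filter, RMS normalization, cosine/Ward pixel
segmentation, and region-of-interest differential analysis.

Peak binning groups all per-pixel peaks into consensus +/- tolerance windows
(0.180 Da by default), greedily in order of decreasing intensity; within a
window each pixel contributes its maximum-intensity peak.  Bins detected in
fewer than ``min_freq`` of the pixels (3.84% by default) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import PixelGrid


@dataclass
class PeakBinTable:
    """Pixels x bins intensity matrix with bin metadata."""

    centers: np.ndarray  # consensus m/z per bin, ascending
    tolerance: float
    intensities: pd.DataFrame  # index (x, y) MultiIndex, one column per bin
    detection_frequency: np.ndarray  # per-bin fraction of pixels with a peak

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    @property
    def n_pixels(self) -> int:
        return len(self.intensities)


@dataclass
class SegmentationResult:
    labels: np.ndarray  # per-pixel cluster id, contiguous from 0
    k: int
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    pixel_index: pd.MultiIndex = None


def smooth_spectrum(intensity: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along the m/z axis.

    Edge positions average over the shrunken window that fits, so a constant
    spectrum is preserved exactly; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    y = np.asarray(intensity, dtype=float)
    if window == 1 or len(y) <= 1:
        return y.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(y)])
    n = len(y)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def bin_peaks(
    grid: PixelGrid,
    tolerance: float = 0.180,
    min_freq: float = 0.0384,
) -> PeakBinTable:
    """Consensus peak binning at +/- ``tolerance`` Da with frequency filtering."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not 0 <= min_freq <= 1:
        raise ValueError("min_freq must lie in [0, 1]")
    peaks = grid.peaks
    if peaks.empty:
        raise ValueError("pixel grid contains no peaks")

    mz = peaks["mz"].to_numpy(dtype=float)
    inten = peaks["intensity"].to_numpy(dtype=float)
    order_mz = np.argsort(mz, kind="stable")
    mz_sorted = mz[order_mz]
    assigned = np.full(len(mz), -1)

    centers = []
    for p in np.argsort(-inten, kind="stable"):
        if assigned[p] >= 0:
            continue
        center = mz[p]
        lo = np.searchsorted(mz_sorted, center - tolerance, side="left")
        hi = np.searchsorted(mz_sorted, center + tolerance, side="right")
        members = order_mz[lo:hi]
        members = members[assigned[members] < 0]
        assigned[members] = len(centers)
        centers.append(center)
    centers = np.asarray(centers)
    if len(centers) == 1:
        warnings.warn("tolerance merged every peak into a single bin")

    pix = pd.MultiIndex.from_frame(
        peaks[["x", "y"]].drop_duplicates().sort_values(["y", "x"]),
        names=["x", "y"],
    )
    pix_id = pd.MultiIndex.from_frame(peaks[["x", "y"]], names=["x", "y"])
    pix_code = pix.get_indexer(pix_id)

    n_pix, n_bins = len(pix), len(centers)
    mat = np.zeros((n_pix, n_bins))
    # per pixel/bin keep the maximum-intensity peak
    np.maximum.at(mat, (pix_code, assigned), inten)
    detected = np.zeros((n_pix, n_bins), dtype=bool)
    detected[pix_code, assigned] = True
    freq = detected.mean(axis=0)

    keep = freq >= min_freq
    order = np.argsort(centers[keep])
    kept = np.flatnonzero(keep)[order]
    return PeakBinTable(
        centers=centers[kept],
        tolerance=tolerance,
        intensities=pd.DataFrame(
            mat[:, kept], index=pix,
            columns=[f"mz_{c:.4f}" for c in centers[kept]],
        ),
        detection_frequency=freq[kept],
    )


def rms_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Scale every pixel row to unit root-mean-square intensity."""
    vals = intensities.to_numpy(dtype=float)
    rms = np.sqrt((vals**2).mean(axis=1))
    bad = rms <= 0
    if bad.any():
        coords = list(intensities.index[bad])
        raise ValueError(f"all-zero pixel spectra at {coords[:10]}")
    return intensities.div(rms, axis=0)


def cluster_pixels(table: PeakBinTable, k: int) -> SegmentationResult:
    """Agglomerative segmentation of pixels: cosine distance, Ward linkage.

    Ward's Lance-Williams update is applied to the cosine dissimilarities
    (the behaviour of the imaging software this reproduces), not a claim
    that cosine distances are Euclidean.
    """
    n = table.n_pixels
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    vals = table.intensities.to_numpy(dtype=float)
    Z = linkage(pdist(vals, metric="cosine"), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    seen: dict = {}
    labels = np.array([seen.setdefault(g, len(seen)) for g in raw])
    return SegmentationResult(labels=labels, k=k, linkage_matrix=Z,
                              pixel_index=table.intensities.index)


def _mask_rows(table: PeakBinTable, mask: np.ndarray) -> np.ndarray:
    xs = table.intensities.index.get_level_values("x").to_numpy()
    ys = table.intensities.index.get_level_values("y").to_numpy()
    return mask[ys, xs]


def roi_differential(
    table: PeakBinTable,
    roi_a: np.ndarray,
    roi_b: np.ndarray,
    fc_threshold: float = 1.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-bin log2 fold change between two pixel regions.

    ``log2FC = log2((mean_A + eps) / (mean_B + eps))`` with ``eps`` defaulting
    to 1% of the global median bin intensity; a bin passes iff
    ``|log2FC| > fc_threshold`` (strict).
    """
    sel_a = _mask_rows(table, np.asarray(roi_a, dtype=bool))
    sel_b = _mask_rows(table, np.asarray(roi_b, dtype=bool))
    if not sel_a.any() or not sel_b.any():
        raise ValueError("both ROI masks must cover at least one pixel")
    if (np.asarray(roi_a, dtype=bool) & np.asarray(roi_b, dtype=bool)).any():
        raise ValueError("ROI masks must be disjoint")
    vals = table.intensities.to_numpy(dtype=float)
    if pseudocount is None:
        med = float(np.median(vals))
        pseudocount = 0.01 * med if med > 0 else 1e-9
    mean_a = vals[sel_a].mean(axis=0)
    mean_b = vals[sel_b].mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    out = pd.DataFrame({
        "mz_center": table.centers,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2fc": log2fc,
        "direction": np.where(log2fc > 0, "up", "down"),
        "pass": np.abs(log2fc) > fc_threshold,
    })
    return out
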