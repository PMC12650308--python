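import numpy as np
import pandas as pd
import pytest

from strokemap import spatial
from strokemap.containers import PixelGrid
from strokemap.synth import generate_pixel_grid, rectangle_mask


class TestSmoothSpectrum:
    def test_constant_preserved(self):
        y = np.full(9, 4.2)
        assert np.allclose(spatial.smooth_spectrum(y, 3), y)

    def test_impulse_three_point(self):
        out = spatial.smooth_spectrum(np.array([0.0, 3.0, 0.0]), 3)
        assert out[1] == pytest.approx(1.0)  # full-window interior average
        assert np.allclose(out, [1.5, 1.0, 1.5])  # shrunken edge windows

    def test_window_one_identity(self):
        y = np.array([1.0, 5.0, 2.0])
        assert np.array_equal(spatial.smooth_spectrum(y, 1), y)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            spatial.smooth_spectrum(np.ones(5), 4)

    def test_length_preserved(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(size=33)
        assert len(spatial.smooth_spectrum(y, 5)) == 33


def grid_from_peaks(rows, width=4, height=1, masks=None):
    peaks = pd.DataFrame(rows, columns=["x", "y", "mz", "intensity"])
    return PixelGrid(width=width, height=height, peaks=peaks,
                     roi_masks=masks or {})


class TestBinPeaks:
    def test_planted_count_recovered(self, small_grid):
        bins = spatial.bin_peaks(small_grid, tolerance=0.180, min_freq=0.0384)
        assert bins.n_bins == 30

    def test_close_peaks_merge(self):
        g = grid_from_peaks([(0, 0, 100.00, 5.0), (0, 0, 100.10, 9.0),
                             (1, 0, 100.05, 7.0)], width=2)
        bins = spatial.bin_peaks(g, tolerance=0.180, min_freq=0.0)
        assert bins.n_bins == 1
        # maximum-intensity peak per pixel within the interval
        assert sorted(bins.intensities.iloc[:, 0]) == [7.0, 9.0]

    def test_rare_peak_dropped_by_frequency(self):
        rows = [(x, 0, 100.0, 5.0) for x in range(50)]
        rows.append((0, 0, 200.0, 50.0))  # in 1 of 50 pixels = 2%
        g = grid_from_peaks(rows, width=50)
        bins = spatial.bin_peaks(g, tolerance=0.180, min_freq=0.0384)
        assert bins.n_bins == 1
        assert bins.centers[0] == pytest.approx(100.0)

    def test_binning_idempotent_on_centers(self, small_grid):
        bins = spatial.bin_peaks(small_grid, tolerance=0.180, min_freq=0.0)
        rows = [(0, 0, c, 1.0) for c in bins.centers]
        again = spatial.bin_peaks(grid_from_peaks(rows, width=1),
                                  tolerance=0.180, min_freq=0.0)
        assert np.allclose(again.centers, bins.centers)

    def test_frequency_threshold_monotone(self, small_grid):
        counts = [
            spatial.bin_peaks(small_grid, 0.180, f).n_bins
            for f in (0.0, 0.05, 0.5, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_single_bin_warning(self):
        g = grid_from_peaks([(0, 0, 100.0, 1.0), (0, 0, 100.1, 2.0)], width=1)
        with pytest.warns(UserWarning, match="single bin"):
            spatial.bin_peaks(g, tolerance=1.0, min_freq=0.0)

    def test_invalid_tolerance(self, small_grid):
        with pytest.raises(ValueError, match="tolerance"):
            spatial.bin_peaks(small_grid, tolerance=0.0)


class TestRmsNormalize:
    def test_hand_arithmetic(self):
        df = pd.DataFrame([[3.0, 4.0]])
        out = spatial.rms_normalize(df)
        rms = np.sqrt((out.to_numpy() ** 2).mean())
        assert rms == pytest.approx(1.0)
        assert np.allclose(out.to_numpy(), [[3, 4]] / np.sqrt(12.5))

    def test_unit_rms_unchanged(self):
        df = pd.DataFrame([[1.0, 1.0]])
        assert np.allclose(spatial.rms_normalize(df), df)

    def test_random_grid_unit_rms(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        out = spatial.rms_normalize(bins.intensities)
        rms = np.sqrt((out.to_numpy() ** 2).mean(axis=1))
        assert np.allclose(rms, 1.0, atol=1e-12)

    def test_zero_pixel_named(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]],
                          index=pd.MultiIndex.from_tuples([(0, 0), (1, 0)],
                                                          names=["x", "y"]))
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            spatial.rms_normalize(df)


class TestClusterPixels:
    def test_three_planted_tissue_classes(self):
        rng = np.random.default_rng(1)
        profiles = np.array([[10, 1, 1, 1], [1, 10, 1, 1], [1, 1, 10, 1]])
        rows = []
        truth = []
        for x in range(12):
            cls = x % 3
            truth.append(cls)
            for j, mz in enumerate((100.0, 101.0, 102.0, 103.0)):
                rows.append((x, 0, mz,
                             profiles[cls, j] * rng.uniform(0.95, 1.05)))
        g = grid_from_peaks(rows, width=12)
        bins = spatial.bin_peaks(g, 0.180, 0.0)
        seg = spatial.cluster_pixels(bins, k=3)
        mapping = {}
        for lab, t in zip(seg.labels, truth):
            mapping.setdefault(lab, t)
            assert mapping[lab] == t

    def test_k_equals_pixels_gives_singletons(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        seg = spatial.cluster_pixels(bins, k=bins.n_pixels)
        assert len(set(seg.labels)) == bins.n_pixels

    def test_duplicate_pixels_co_clustered(self):
        rows = []
        for x in range(6):
            base = 5.0 if x < 3 else 50.0
            rows += [(x, 0, 100.0, base), (x, 0, 101.0, 2 * base + (x >= 3))]
        g = grid_from_peaks(rows, width=6)
        bins = spatial.bin_peaks(g, 0.180, 0.0)
        seg = spatial.cluster_pixels(bins, k=2)
        assert len(set(seg.labels[:3])) == 1
        assert len(set(seg.labels[3:])) == 1

    def test_deterministic(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        a = spatial.cluster_pixels(bins, k=3).labels
        b = spatial.cluster_pixels(bins, k=3).labels
        assert np.array_equal(a, b)

    def test_k_bounds(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        with pytest.raises(ValueError, match="k must"):
            spatial.cluster_pixels(bins, k=bins.n_pixels + 1)


class TestRoiDifferential:
    def test_identical_regions_pass_nothing(self):
        rows = [(x, 0, 100.0, 5.0) for x in range(6)]
        g = grid_from_peaks(rows, width=6)
        bins = spatial.bin_peaks(g, 0.180, 0.0)
        a = rectangle_mask(6, 1, 0, 3, 0, 1)
        b = rectangle_mask(6, 1, 3, 6, 0, 1)
        diff = spatial.roi_differential(bins, a, b)
        assert diff["pass"].sum() == 0

    def test_planted_counts_recovered(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0384)
        diff = spatial.roi_differential(bins, small_grid.roi_masks["lesion"],
                                        small_grid.roi_masks["contralateral"])
        up = int((diff["pass"] & (diff["direction"] == "up")).sum())
        down = int((diff["pass"] & (diff["direction"] == "down")).sum())
        assert (up, down) == (5, 7)

    def test_direction_antisymmetry(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        les = small_grid.roi_masks["lesion"]
        con = small_grid.roi_masks["contralateral"]
        ab = spatial.roi_differential(bins, les, con)
        ba = spatial.roi_differential(bins, con, les)
        assert np.allclose(ab["log2fc"], -ba["log2fc"])

    def test_fourfold_single_bin(self):
        rows = [(0, 0, 100.0, 8.0), (1, 0, 100.0, 2.0)]
        g = grid_from_peaks(rows, width=2)
        bins = spatial.bin_peaks(g, 0.180, 0.0)
        a = rectangle_mask(2, 1, 0, 1, 0, 1)
        b = rectangle_mask(2, 1, 1, 2, 0, 1)
        diff = spatial.roi_differential(bins, a, b, pseudocount=0.0)
        assert diff["log2fc"].iloc[0] == pytest.approx(2.0)
        assert bool(diff["pass"].iloc[0])

    def test_empty_and_overlapping_masks(self, small_grid):
        bins = spatial.bin_peaks(small_grid, 0.180, 0.0)
        empty = np.zeros((12, 12), dtype=bool)
        with pytest.raises(ValueError, match="at least one pixel"):
            spatial.roi_differential(bins, empty, small_grid.roi_masks["lesion"])
        with pytest.raises(ValueError, match="disjoint"):
            spatial.roi_differential(bins, small_grid.roi_masks["lesion"],
                                     small_grid.roi_masks["lesion"])
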