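"""Morphometry: area fraction, local thickness (vs brute-force
inscribed-disk oracle), bundle widths, summary statistics, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import fibermorph as fm
from fibermorph.morphometry import histogram_frame
from fibermorph.synthetic import ribbon_width


def brute_force_local_thickness(mask):
    """Enumerate every foreground center's inscribed disk explicitly.

    Shares only the disk convention with the efficient implementation:
    the disk at center c covers pixels strictly closer to c than the
    distance from c to the nearest background pixel.
    """
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    d = ndimage.distance_transform_edt(mask)
    d2 = np.rint(d * d).astype(np.int64)
    T = np.zeros(mask.shape)
    yy, xx = np.mgrid[:H, :W]
    for r, c in zip(*np.nonzero(mask)):
        cover = (yy - r) ** 2 + (xx - c) ** 2 <= d2[r, c] - 1
        T[cover] = np.maximum(T[cover], 2.0 * np.sqrt(d2[r, c]))
    return T


class TestAreaFraction:
    def test_analytic_cases(self):
        assert fm.area_fraction(np.ones((8, 8), bool)) == 100.0
        assert fm.area_fraction(np.zeros((8, 8), bool)) == 0.0
        mask = np.zeros((1024, 1024), bool)
        mask[:512, :512] = True
        assert fm.area_fraction(mask) == 25.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            fm.area_fraction(np.zeros((0, 0), bool))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_rotation_and_complement_invariants(self, seed):
        mask = np.random.default_rng(seed).random((17, 23)) < 0.4
        f = fm.area_fraction(mask)
        for k in (1, 2, 3):
            assert np.isclose(fm.area_fraction(np.rot90(mask, k)), f)
        assert np.isclose(f + fm.area_fraction(~mask), 100.0)


class TestLocalThickness:
    def test_disk_max_is_diameter(self):
        disk = fm.make_geometric_fixture("disk", {"radius": 20}, (128, 128))
        T = fm.local_thickness(disk)
        assert abs(T.max() - 40.0) <= 1.0

    def test_bar_interior_is_width(self):
        bar = fm.make_geometric_fixture("bar", {"width": 10, "length": 100}, (128, 128))
        T = fm.local_thickness(bar)
        assert abs(T[64, 64] - 10.0) <= 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndimage.binary_closing(rng.random((64, 64)) < 0.55, np.ones((3, 3)))
        np.testing.assert_array_equal(
            fm.local_thickness(mask), brute_force_local_thickness(mask)
        )

    def test_bounded_by_own_inscribed_disk_and_global_maximum(self):
        # every foreground pixel is covered by its own inscribed disk,
        # so thickness >= 2*EDT pointwise; and no disk exceeds the
        # largest inscribed disk anywhere, so thickness <= 2*max(EDT)
        rng = np.random.default_rng(7)
        mask = ndimage.binary_closing(rng.random((80, 80)) < 0.5, np.ones((3, 3)))
        T = fm.local_thickness(mask)
        edt = ndimage.distance_transform_edt(mask)
        assert np.all(T[mask] >= 2.0 * edt[mask] - 1e-9)
        assert T.max() <= 2.0 * edt.max() + 1e-9
        assert not T[~mask].any()

    def test_empty_mask_gives_zero_map(self):
        assert not fm.local_thickness(np.zeros((32, 32), bool)).any()


class TestMaxBundleWidth:
    def _two_bars(self):
        mask = np.zeros((100, 200), bool)
        mask[10:20, 10:110] = True   # width 10
        mask[50:80, 10:110] = True   # width 30
        ct = fm.label_components(mask, min_area=0)
        return mask, ct

    def test_per_component_maxima(self):
        mask, ct = self._two_bars()
        T = fm.local_thickness(mask)
        ct2, marker = fm.max_bundle_width(T, ct)
        widths = dict(
            zip(ct2.table["area_px"], ct2.table["max_thickness_px"])
        )
        assert abs(widths[3000] - 30.0) <= 1.0
        assert abs(widths[1000] - 10.0) <= 1.0
        assert abs(ct2.table["max_thickness_px"].max() - 30.0) <= 1.0

    def test_marker_pixels_attain_component_maximum(self):
        mask, ct = self._two_bars()
        T = fm.local_thickness(mask)
        ct2, marker = fm.max_bundle_width(T, ct)
        assert marker.any()
        for cid in ct2.table["component_id"]:
            comp = ct2.labels == cid
            mx = T[comp].max()
            assert np.all(T[marker & comp] == mx)
            assert (marker & comp).any()

    def test_shape_mismatch_rejected(self):
        _mask, ct = self._two_bars()
        with pytest.raises(ValueError):
            fm.max_bundle_width(np.zeros((10, 10)), ct)

    def test_rendered_ribbon_widths_match_generator(self):
        # a few large bundles with known stroke widths
        spec = fm.SyntheticSpec(
            shape_k=0.2, scale_sigma=800.0, n_bundles=8,
            image_size=(768, 768), fiber_aspect=4.0, seed=5,
        )
        _img, truth = fm.render_micrograph(spec)
        ct = fm.label_components(truth.fiber_mask, min_area=0)
        T = fm.local_thickness(truth.fiber_mask)
        ct2, _ = fm.max_bundle_width(T, ct)
        # match components to draws by area
        measured = ct2.table.sort_values("area_px")["max_thickness_px"].to_numpy()
        drawn = np.sort(truth.bundle_areas)
        expected = np.array([ribbon_width(a, spec.fiber_aspect) for a in drawn])
        assert measured.size == drawn.size
        assert np.all(np.abs(measured - expected) <= 2.0)


class TestSummarizeMeanCI:
    def test_constant_vector_zero_width(self):
        s = fm.summarize_mean_ci([50.0] * 5)
        assert s.mean == 50.0
        assert s.ci95 == (50.0, 50.0)

    def test_student_t_oracle(self):
        # sd({40,50,60}) = 10, t_{0.975,2} = 4.3027
        s = fm.summarize_mean_ci([40.0, 50.0, 60.0])
        half = 4.302652729911275 * 10.0 / np.sqrt(3.0)
        assert np.isclose(s.mean, 50.0)
        assert np.isclose(s.ci95[0], 50.0 - half, atol=1e-9)
        assert np.isclose(s.ci95[1], 50.0 + half, atol=1e-9)

    def test_interval_contains_mean(self):
        s = fm.summarize_mean_ci(np.random.default_rng(1).random(30) * 100)
        assert s.ci95[0] <= s.mean <= s.ci95[1]

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fm.summarize_mean_ci([5.0])


class TestAreaHistogram:
    def test_single_bin(self):
        h = fm.component_area_histogram(np.array([1.0, 1.0, 1.0]), 2.0)
        assert h.counts.tolist() == [3]
        assert h.bin_edges.tolist() == [0.0, 2.0]

    def test_right_open_bins(self):
        h = fm.component_area_histogram(np.array([1.0, 3.0, 5.0]), 2.0)
        assert h.counts.tolist() == [1, 1, 1]

    def test_empty_input_gives_zero_bins(self):
        h = fm.component_area_histogram(np.array([]), 2.0)
        assert h.counts.size == 0 and h.bin_edges.size == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.1, 1e4), min_size=1, max_size=50), st.integers(0, 10**6))
    def test_counts_sum_and_permutation_invariance(self, areas, seed):
        areas = np.asarray(areas)
        h1 = fm.component_area_histogram(areas, 7.5)
        perm = np.random.default_rng(seed).permutation(areas)
        h2 = fm.component_area_histogram(perm, 7.5)
        assert h1.counts.sum() == areas.size
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_gpd_tail_fraction_matches_theoretical_quantile(self):
        k, sigma, n = 0.7, 2.0, 10**4
        x = fm.sample_gpd(k, sigma, n, seed=77)
        h = fm.component_area_histogram(x, 1.0)
        assert h.counts.sum() == n
        q99 = sigma / k * (0.01 ** (-k) - 1.0)  # exact 99th percentile
        frac = np.mean(x > q99)
        half = 1.96 * np.sqrt(0.01 * 0.99 / n)
        assert 0.01 - half <= frac <= 0.01 + half

    def test_frame_layout(self):
        h = fm.component_area_histogram(np.array([1.0, 3.0]), 2.0)
        df = histogram_frame(h)
        assert list(df.columns) == ["bin_low", "bin_high", "count"]
        assert df["count"].sum() == 2

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            fm.component_area_histogram(np.array([1.0]), 0.0)
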