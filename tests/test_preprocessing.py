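"""Reference spectrum, peak picking, adaptive binning and the per-ion
cleaning chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatmsi.core import MSIDataset
from spatmsi.preprocessing import (
    PeakList,
    ReferenceSpectrum,
    build_adaptive_bins,
    build_reference_spectrum,
    binned_feature_table,
    drop_drug_correlated,
    filter_low_coverage,
    glog,
    normalize_glog,
    pick_peaks,
    remove_batch_effect,
    spatial_clean,
)

from conftest import grid_coords, make_feature_table


def dataset_from_spectra(spectra):
    n = len(spectra)
    coords = grid_coords(1, n)
    return MSIDataset(coords=coords, spectra=spectra, model_id=np.full(n, "M"),
                      slice_id=np.full(n, "S"), treatment=np.full(n, "t"))


class TestReferenceSpectrum:
    def test_identical_spectra_give_back_one_of_them(self):
        mz = np.linspace(100, 200, 30)
        inten = np.linspace(0, 5, 30)
        ref = build_reference_spectrum(dataset_from_spectra([(mz, inten.copy())] * 3))
        assert np.array_equal(ref.intensity, inten)

    def test_pointwise_maximum_of_two_spectra(self):
        mz = np.array([100.0, 101.0, 102.0])
        ds = dataset_from_spectra([
            (mz, np.array([0.0, 5.0, 0.0])),
            (mz, np.array([1.0, 1.0, 1.0])),
        ])
        ref = build_reference_spectrum(ds)
        assert np.array_equal(ref.intensity, [1.0, 5.0, 1.0])

    def test_adding_a_spectrum_never_decreases_the_reference(self, rng):
        mz = np.linspace(100, 200, 40)
        base = [(mz, rng.uniform(size=40)) for _ in range(3)]
        ref1 = build_reference_spectrum(dataset_from_spectra(base))
        ref2 = build_reference_spectrum(dataset_from_spectra(base + [(mz, rng.uniform(size=40))]))
        assert np.all(ref2.intensity >= ref1.intensity)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_reference_spectrum(dataset_from_spectra([]))


class TestPickPeaks:
    def test_single_noiseless_gaussian_gives_one_apex(self):
        mz = np.linspace(100, 200, 1024)
        bump = 50 * np.exp(-0.5 * ((mz - 150) / 1.0) ** 2)
        peaks = pick_peaks(ReferenceSpectrum(mz=mz, intensity=bump))
        assert len(peaks) == 1
        assert abs(peaks.mz[0] - 150.0) <= (mz[1] - mz[0])

    def test_two_planted_gaussians_recovered_near_centers(self):
        rng = np.random.default_rng(100)
        mz = np.linspace(100, 200, 1024)
        signal = (50 * np.exp(-0.5 * ((mz - 140) / 1.0) ** 2)
                  + 50 * np.exp(-0.5 * ((mz - 150) / 1.0) ** 2)
                  + rng.normal(0, 1, 1024))
        peaks = pick_peaks(ReferenceSpectrum(mz=mz, intensity=signal), snr=3)
        assert len(peaks) == 2
        # a centre falling between grid points can land the apex up to
        # 1.5 samples away; allow 2 to cover noise-induced drift
        step = mz[1] - mz[0]
        assert abs(peaks.mz[0] - 140.0) <= 2 * step
        assert abs(peaks.mz[1] - 150.0) <= 2 * step

    def test_constant_spectrum_yields_no_peaks(self):
        mz = np.linspace(100, 200, 256)
        assert len(pick_peaks(ReferenceSpectrum(mz=mz, intensity=np.ones(256)))) == 0

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="short"):
            pick_peaks(ReferenceSpectrum(mz=np.arange(4.0), intensity=np.arange(4.0)))


def peak_list(mzs):
    mzs = np.asarray(mzs, dtype=float)
    return PeakList(mz=mzs, intensity=np.ones_like(mzs), snr=3.0, noise_scale=0.0)


class TestAdaptiveBins:
    def test_close_peaks_merge_distant_do_not(self):
        scheme = build_adaptive_bins(peak_list([300.00, 300.03, 300.40]))
        assert len(scheme) == 2
        assert list(scheme.bins["origin"]) == ["merged", "peak"]
        assert scheme.bins.loc[0, "lower"] <= 300.00 and scheme.bins.loc[0, "upper"] >= 300.03

    def test_single_peak_single_bin(self):
        scheme = build_adaptive_bins(peak_list([350.0]))
        assert len(scheme) == 1 and scheme.bins.loc[0, "origin"] == "peak"

    def test_wide_gap_tiled_with_half_dalton_bins(self):
        scheme = build_adaptive_bins(peak_list([200.0, 210.0]))
        gaps = scheme.bins[scheme.bins["origin"] == "gap"]
        assert len(scheme) == 21 and len(gaps) == 19
        widths = (gaps["upper"] - gaps["lower"]).to_numpy()
        assert np.allclose(widths, 0.5)
        assert gaps["lower"].min() == pytest.approx(200.25)
        assert gaps["upper"].max() == pytest.approx(209.75)

    def test_bins_partition_without_overlap(self, rng):
        mzs = np.sort(rng.uniform(200, 400, 30))
        scheme = build_adaptive_bins(peak_list(mzs))
        b = scheme.bins
        assert np.all(b["lower"].to_numpy()[1:] >= b["upper"].to_numpy()[:-1] - 1e-12)

    def test_empty_peak_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_adaptive_bins(peak_list([]))


class TestBinnedFeatureTable:
    def make_pixel_dataset(self, peak_sets):
        """One synthetic profile spectrum per pixel with planted peaks."""
        mz = np.linspace(295, 305, 2048)
        spectra = []
        for peaks in peak_sets:
            inten = np.zeros_like(mz)
            for centre, apex in peaks:
                inten += apex * np.exp(-0.5 * ((mz - centre) / 0.01) ** 2)
            spectra.append((mz.copy(), inten))
        return dataset_from_spectra(spectra)

    def test_in_bin_peak_recorded_and_max_rule(self):
        ds = self.make_pixel_dataset([
            [(300.01, 7.0)],
            [(300.00, 3.0), (300.02, 9.0)],
            [(302.5, 5.0)],
        ])
        scheme = build_adaptive_bins(peak_list([300.0, 302.5]), gap_threshold=10.0)
        ft = binned_feature_table(ds, scheme)
        col0 = ft.column(0)
        assert col0[0] == pytest.approx(7.0, rel=0.05)
        assert col0[1] == pytest.approx(9.0, rel=0.05)  # max of in-bin apexes
        assert col0[2] == 0.0  # no in-bin peak


class TestCoverageFilter:
    def test_threshold_rule(self, rng):
        coords = grid_coords(10, 10)
        m = np.zeros((100, 2))
        m[:19, 0] = 1.0   # 19% coverage -> dropped
        m[:21, 1] = 1.0   # 21% coverage -> kept
        models = np.where(np.arange(100) % 2 == 0, "A", "B")
        ft = make_feature_table(m, coords, model_id=models)
        kept, report = filter_low_coverage(ft, min_frac=0.20)
        assert kept.n_bins == 1 and kept.centers[0] == 301.0
        assert report.loc[0, "reason"] == "low_coverage"

    def test_full_coverage_multi_model_unchanged(self, rng):
        coords = grid_coords(5, 5)
        models = np.where(np.arange(25) < 12, "A", "B")
        ft = make_feature_table(rng.uniform(1, 2, size=(25, 3)), coords, model_id=models)
        kept, report = filter_low_coverage(ft)
        assert kept.n_bins == 3 and len(report) == 0

    def test_single_model_bin_dropped_despite_high_coverage(self):
        coords = grid_coords(4, 4)
        models = np.where(np.arange(16) < 8, "M1", "M2")
        m = np.ones((16, 2))
        m[8:, 0] = 0.0  # bin 0 nonzero only in M1 (coverage 50%)
        ft = make_feature_table(m, coords, model_id=models)
        kept, report = filter_low_coverage(ft, min_frac=0.20)
        assert kept.n_bins == 1
        assert report.loc[0, "reason"] == "single_model"

    def test_idempotent(self, rng):
        coords = grid_coords(6, 6)
        models = np.where(np.arange(36) % 2 == 0, "A", "B")
        m = rng.uniform(size=(36, 4))
        m[:, 2] *= rng.uniform(size=36) > 0.9  # sparse bin
        ft = make_feature_table(m, coords, model_id=models)
        once, _ = filter_low_coverage(ft)
        twice, rep = filter_low_coverage(once)
        assert np.array_equal(once.matrix, twice.matrix) and len(rep) == 0


class TestSpatialClean:
    def test_constant_image_unchanged(self):
        ft = make_feature_table(np.full((25, 1), 3.0), grid_coords(5, 5))
        assert np.allclose(spatial_clean(ft).matrix, 3.0)

    def test_interior_spike_removed(self):
        m = np.ones((25, 1))
        m[12, 0] = 100.0  # centre pixel of the 5x5 grid
        ft = make_feature_table(m, grid_coords(5, 5))
        assert spatial_clean(ft).matrix[12, 0] == 1.0

    def test_rim_pixel_replaced_by_neighbor_median(self):
        m = np.full((25, 1), 2.0)
        m[0, 0] = 100.0  # corner pixel
        ft = make_feature_table(m, grid_coords(5, 5))
        assert spatial_clean(ft).matrix[0, 0] == 2.0

    def test_idempotent_on_constant_images(self):
        ft = make_feature_table(np.full((36, 2), 5.0), grid_coords(6, 6))
        once = spatial_clean(ft)
        twice = spatial_clean(once)
        assert np.array_equal(once.matrix, twice.matrix)


class TestNormalizeGlog:
    def test_glog_at_lam_zero_is_natural_log(self, rng):
        x = rng.uniform(0.1, 10.0, size=20)
        assert np.allclose(glog(x, lam=0.0), np.log(x), atol=1e-12)

    def test_pixel_medians_equalized(self, rng):
        ft = make_feature_table(rng.uniform(0.5, 10, size=(25, 7)), grid_coords(5, 5))
        out = normalize_glog(ft, lam=0.0)
        back = np.exp(out.matrix)  # undo glog(lam=0) = ln
        medians = np.median(back, axis=1)
        assert np.allclose(medians, medians[0], atol=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.tuples(st.floats(0.01, 1e3), st.floats(0.01, 1e3)),
           st.floats(0.0, 10.0))
    def test_glog_strictly_increasing(self, pair, lam):
        x1, x2 = sorted(pair)
        if x1 == x2:
            return
        assert glog(np.array([x1]), lam)[0] < glog(np.array([x2]), lam)[0]

    def test_all_zero_pixel_dropped_with_warning(self):
        m = np.ones((9, 2))
        m[4] = 0.0
        ft = make_feature_table(m, grid_coords(3, 3))
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_glog(ft)
        assert out.n_pixels == 8


class TestBatchEffectRemoval:
    def test_single_batch_is_identity(self, rng):
        ft = make_feature_table(rng.uniform(size=(16, 3)), grid_coords(4, 4))
        out = remove_batch_effect(ft, np.full(16, "b1"))
        assert np.allclose(out.matrix, ft.matrix)

    def test_constructed_offset_removed(self, rng):
        coords = grid_coords(4, 4)
        batch = np.where(np.arange(16) < 8, "A", "B")
        m = rng.uniform(size=(16, 3))
        m[batch == "B"] += 5.0
        ft = make_feature_table(m, coords)
        out = remove_batch_effect(ft, batch)
        mean_a = out.matrix[batch == "A"].mean(axis=0)
        mean_b = out.matrix[batch == "B"].mean(axis=0)
        assert np.allclose(mean_a, mean_b, atol=1e-10)

    def test_matches_indicator_regression_oracle(self, rng):
        coords = grid_coords(5, 5)
        batch = rng.choice(["A", "B", "C"], size=25)
        m = rng.normal(size=(25, 2))
        ft = make_feature_table(m, coords)
        out = remove_batch_effect(ft, batch)
        # oracle: residuals of one-hot batch regression plus the grand mean
        onehot = np.column_stack([(batch == b).astype(float) for b in ["A", "B", "C"]])
        proj = onehot @ np.linalg.lstsq(onehot, m, rcond=None)[0]
        oracle = m - proj + m.mean(axis=0)
        assert np.allclose(out.matrix, oracle, atol=1e-10)

    def test_confounded_batch_rejected(self, rng):
        coords = grid_coords(4, 4)
        batch = np.where(np.arange(16) < 8, "A", "B")
        ft = make_feature_table(rng.uniform(size=(16, 2)), coords)
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effect(ft, batch, protect=batch)


class TestDrugCorrelationFilter:
    def test_exact_copy_of_drug_removed(self, rng):
        drug = rng.uniform(size=25)
        m = np.column_stack([drug, drug, rng.uniform(size=25)])
        ft = make_feature_table(m, grid_coords(5, 5))
        out, report = drop_drug_correlated(ft, 0)
        assert 301.0 in report["center"].to_numpy()  # the copy
        assert out.drug_center == 300.0
        assert out.n_bins == 1

    def test_correlation_threshold_boundary(self, rng):
        n = 400
        drug = rng.normal(size=n)

        def with_corr(r):
            noise = rng.normal(size=n)
            noise -= noise @ drug / (drug @ drug) * drug  # orthogonalize
            zd = (drug - drug.mean()) / drug.std()
            zn = (noise - noise.mean()) / noise.std()
            return zd * r + zn * np.sqrt(1 - r * r)

        m = np.column_stack([drug, with_corr(0.95), with_corr(0.85)])
        ft = make_feature_table(m, grid_coords(20, 20))
        out, report = drop_drug_correlated(ft, 0, r_max=0.9)
        assert 301.0 in report["center"].to_numpy()      # r = 0.95 removed
        assert 302.0 in out.centers                       # r = 0.85 retained

    def test_drug_bin_absent_from_features_after_call(self, rng):
        m = rng.uniform(size=(16, 4))
        ft = make_feature_table(m, grid_coords(4, 4))
        out, _ = drop_drug_correlated(ft, 2)
        assert 302.0 not in out.centers
        assert out.drug_values is not None

    def test_zero_variance_feature_retained_with_warning(self, rng):
        m = np.column_stack([rng.uniform(size=16), np.full(16, 3.0)])
        ft = make_feature_table(m, grid_coords(4, 4))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = drop_drug_correlated(ft, 0)
        assert 301.0 in out.centers
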