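"""Densitometric calibration, linearization, binding arithmetic and
fingerprint construction against simulation truth."""

import numpy as np
import pandas as pd
import pytest

from hippomap import receptor_arch as ra, synthetic_data as sd


def _noiseless_standards(film=None):
    film = film or sd.FilmModel(noise_sd=0.0)
    return [(a, float(film.response(a))) for a in film.standard_activities], film


class TestCalibration:
    def test_linear_standards_fit_with_negligible_residual(self):
        dens = np.array([0.0, 100.0, 200.0, 300.0, 400.0])
        gray = 20.0 + 0.1 * dens
        curve = ra.fit_calibration(list(zip(dens, gray)))
        assert curve.residual_scale < 1e-3
        np.testing.assert_allclose(curve.to_density(gray), dens, atol=0.5)

    def test_noiseless_film_standards_recovered_exactly_at_knots(self):
        standards, film = _noiseless_standards()
        curve = ra.fit_calibration(standards)
        assert curve.kind == "saturating_exponential"
        for act, gray in standards:
            assert curve.to_density(gray) == pytest.approx(act, abs=1e-3 * max(act, 1.0))

    def test_monotone_between_knots(self):
        standards, film = _noiseless_standards()
        curve = ra.fit_calibration(standards)
        grays = np.linspace(curve.gray_domain[0], curve.gray_domain[1], 200)
        assert np.all(np.diff(curve.to_density(grays)) >= 0)

    def test_decreasing_film_polarity_supported(self):
        dens = np.array([0.0, 100.0, 200.0, 400.0, 600.0])
        gray = 250.0 - 0.3 * dens  # darker with more binding
        curve = ra.fit_calibration(list(zip(dens, gray)))
        assert curve.polarity == -1
        np.testing.assert_allclose(curve.to_density(gray), dens, atol=1.0)

    def test_non_monotone_standards_raise_with_diagnostics(self):
        pairs = [(0.0, 10.0), (100.0, 60.0), (200.0, 30.0), (300.0, 90.0)]
        with pytest.raises(ValueError, match="not monotone"):
            ra.fit_calibration(pairs)

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            ra.fit_calibration([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestLinearization:
    def test_constant_gray_maps_to_constant_density(self):
        standards, _ = _noiseless_standards()
        curve = ra.fit_calibration(standards)
        img = np.full((5, 5), standards[3][1])
        out = ra.linearize_image(img, curve)
        np.testing.assert_allclose(out, standards[3][0], atol=1e-2)

    def test_out_of_range_grays_clip_with_warning(self):
        standards, film = _noiseless_standards()
        curve = ra.fit_calibration(standards)
        img = np.full((3, 3), curve.gray_domain[1] + 50.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = ra.linearize_image(img, curve)
        assert np.all(np.isfinite(out))

    def test_simulated_section_recovered_within_five_percent(self):
        # 2% of dynamic-range gray noise, 8 standards
        film = sd.FilmModel(noise_sd=0.02 * 200.0)
        labels = np.zeros((80, 80), dtype=np.int16)
        truth = {}
        rng = np.random.default_rng(6)
        for i, code in enumerate(range(1, 9)):
            labels[(i // 4) * 40:(i // 4) * 40 + 40, (i % 4) * 20:(i % 4) * 20 + 20] = code
            truth[code] = float(rng.uniform(80, 650))
        gray, standards, rec = sd.simulate_autoradiograph(labels, truth, film, seed=7)
        pairs = [(s.activity, gray[s.rows[0]:s.rows[1], s.cols[0]:s.cols[1]].mean()) for s in standards]
        curve = ra.fit_calibration(pairs)
        density = ra.linearize_image(gray, curve)[: labels.shape[0], : labels.shape[1]]
        rel_errors = [abs(density[labels == c].mean() - d) / d for c, d in truth.items()]
        assert np.median(rel_errors) < 0.05


class TestSpecificBinding:
    def test_zero_nonspecific_passthrough(self):
        total = np.full((4, 4), 100.0)
        res = ra.specific_binding(total, np.zeros_like(total))
        np.testing.assert_array_equal(res.specific, total)
        assert res.nsb_fraction == 0.0 and res.negligible

    def test_ten_percent_nonspecific_is_flagged(self):
        total = np.full((4, 4), 100.0)
        nsb = np.full((4, 4), 10.0)
        with pytest.warns(UserWarning, match="must not be used"):
            res = ra.specific_binding(total, nsb)
        assert res.nsb_fraction == pytest.approx(0.10)
        assert not res.negligible
        assert res.specific.mean() == pytest.approx(90.0)

    def test_absent_nonspecific_reports_missing_fraction(self):
        res = ra.specific_binding(np.full((2, 2), 50.0))
        assert res.nsb_fraction is None and res.negligible is None

    def test_shortcut_error_below_five_percent_when_nsb_negligible(self):
        rng = np.random.default_rng(3)
        total = rng.uniform(100, 500, size=(30, 30))
        nsb = 0.03 * total  # 3% everywhere
        res = ra.specific_binding(total, nsb)
        assert res.negligible
        shortcut_err = abs(total.mean() - res.specific.mean()) / total.mean()
        assert shortcut_err < 0.05

    def test_negative_input_rejected_and_output_never_negative(self):
        with pytest.raises(ValueError, match="negative"):
            ra.specific_binding(np.array([[-1.0]]))
        res = ra.specific_binding(np.array([[5.0]]), np.array([[9.0]]))
        assert res.specific.min() >= 0.0


class TestRegionalProfile:
    def test_uniform_density_returns_that_density(self):
        img = np.full((6, 6), 42.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:4, 1:4] = True
        prof = ra.regional_profile(img, {(1, "pyr"): mask})
        assert prof.mean_density.iloc[0] == pytest.approx(42.0)

    def test_layer_means_combine_by_pixel_weighting(self):
        img = np.zeros((4, 6))
        m1 = np.zeros_like(img, dtype=bool)
        m2 = np.zeros_like(img, dtype=bool)
        m1[0, :4] = True   # 4 px at density 10
        m2[1, :2] = True   # 2 px at density 40
        img[m1], img[m2] = 10.0, 40.0
        prof = ra.regional_profile(img, {(1, "a"): m1, (1, "b"): m2})
        weighted = ra.region_mean(prof, weighted=True)
        assert weighted == pytest.approx(img[m1 | m2].mean())  # pixel-sum oracle
        assert ra.region_mean(prof, weighted=False) == pytest.approx(25.0)

    def test_empty_mask_flagged_missing(self):
        prof = ra.regional_profile(np.ones((3, 3)), {1: np.zeros((3, 3), dtype=bool)})
        assert prof.missing.iloc[0]
        assert np.isnan(prof.mean_density.iloc[0])

    def test_overlapping_masks_rejected(self):
        m = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            ra.regional_profile(np.ones((2, 2)), {1: m, 2: m})


class TestFingerprints:
    def test_canonical_panel_has_fifteen_entries(self):
        panel = ra.ReceptorPanel.canonical()
        assert len(panel) == 15
        assert panel.names[0] == "AMPA" and panel.names[-1] == "D1"
        assert all(e.concentration_nM > 0 for e in panel.entries)

    def test_single_subject_fingerprint_is_that_vector_with_zero_sem(self):
        vec = np.linspace(50, 700, 15)
        fp = ra.build_fingerprint(vec[None, :], region_code=5)
        np.testing.assert_allclose(fp.densities, vec)
        np.testing.assert_allclose(fp.sem, 0.0)
        assert fp.n == 1

    def test_sem_converges_as_sigma_over_sqrt_n(self):
        from scipy.special import gamma

        rng = np.random.default_rng(11)
        mu, sigma, n = 300.0, 45.0, 6
        sems = []
        for _ in range(200):
            draws = rng.normal(mu, sigma, size=(n, 15))
            fp = ra.build_fingerprint(np.abs(draws), region_code=1)
            sems.append(fp.sem.mean())
        # closed form: E[sample sd] = c4(n)·sigma for normal draws
        c4 = np.sqrt(2 / (n - 1)) * gamma(n / 2) / gamma((n - 1) / 2)
        assert np.mean(sems) == pytest.approx(c4 * sigma / np.sqrt(n), rel=0.02)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(10, 500, size=(5, 15))
        a = ra.build_fingerprint(arr, region_code=1)
        b = ra.build_fingerprint(arr[::-1], region_code=1)
        np.testing.assert_allclose(a.densities, b.densities)
        np.testing.assert_allclose(a.sem, b.sem)

    def test_receptor_missing_for_all_subjects_named(self):
        arr = np.ones((3, 15))
        arr[:, 4] = np.nan  # GABA_B column
        with pytest.raises(ValueError, match="GABA_B"):
            ra.build_fingerprint(arr, region_code=1)

    def test_comparison_metrics(self):
        rng = np.random.default_rng(8)
        vec = rng.uniform(50, 600, size=15)
        fa = ra.build_fingerprint(vec[None, :], region_code=1)
        fb = ra.build_fingerprint(2 * vec[None, :], region_code=2)
        size_same, shape_same = ra.compare_fingerprints(fa, fa)
        assert size_same == 0.0 and shape_same == 0.0
        size_diff, shape_diff = ra.compare_fingerprints(fb, fa)
        assert size_diff == pytest.approx(vec.mean())  # doubling adds one mean
        assert shape_diff == pytest.approx(0.0, abs=1e-12)
        # independent recomputation oracle on random vectors
        other = rng.uniform(50, 600, size=15)
        fc = ra.build_fingerprint(other[None, :], region_code=3)
        size, shape = ra.compare_fingerprints(fa, fc)
        assert size == pytest.approx(vec.mean() - other.mean())
        assert shape == pytest.approx(
            np.linalg.norm(vec / vec.mean() - other / other.mean())
        )

    def test_fingerprint_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        fp = ra.build_fingerprint(rng.uniform(10, 500, size=(4, 15)), region_code=7)
        path = tmp_path / "fp.csv"
        ra.write_fingerprint_csv(fp, path)
        back = ra.read_fingerprint_csv(path)
        np.testing.assert_allclose(back.densities, fp.densities)
        np.testing.assert_allclose(back.sem, fp.sem)
        assert (back.region_code, back.n) == (7, 4)

    def test_polar_plot_renders(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        fp = ra.build_fingerprint(np.abs(np.random.default_rng(0).normal(300, 40, (3, 15))), 1)
        ax = ra.plot_fingerprint(fp, label="CA1")
        ax.figure.savefig(tmp_path / "fp.png")
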