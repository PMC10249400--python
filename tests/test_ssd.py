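import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fishssd import (build_pdf_points, check_eligibility, cox_snell_r2,
                     evaluate_ssd, fit_all_regions, fit_ssd, nrmse)
from fishssd.ssd import (PDFPoints, STATUS_FITTED, STATUS_INSUFFICIENT,
                         transform_points_log10)


def _points_on_logistic(a, b, conc):
    conc = np.asarray(conc, dtype=float)
    pdf = evaluate_ssd(a, b, conc)
    return PDFPoints(concentration=conc, richness=np.zeros_like(conc),
                     pdf=pdf, sr_max=100)


class TestBuildPoints:
    def test_survivor_counting_example(self):
        pts = build_pdf_points([1, 2, 2, 4])
        np.testing.assert_array_equal(pts.concentration, [1, 2, 4])
        np.testing.assert_array_equal(pts.richness, [4, 3, 1])
        np.testing.assert_allclose(pts.pdf, [0.0, 0.25, 0.75])
        assert pts.sr_max == 4

    def test_single_species_has_zero_pdf(self):
        pts = build_pdf_points([3.0])
        assert len(pts) == 1
        assert pts.pdf[0] == 0.0 and pts.richness[0] == 1

    def test_distinct_thresholds_top_pdf(self):
        n = 17
        pts = build_pdf_points(np.arange(1.0, n + 1))
        assert pts.pdf[-1] == pytest.approx((n - 1) / n)
        assert pts.pdf[0] == 0.0

    def test_order_invariance_and_pdf_grid(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.5, 5.0, 30)
        a = build_pdf_points(t)
        b = build_pdf_points(t[::-1])
        np.testing.assert_array_equal(a.concentration, b.concentration)
        np.testing.assert_array_equal(a.pdf, b.pdf)
        # PDF values lie on the grid {0, 1/n, ..., (n-1)/n}
        np.testing.assert_allclose(a.pdf * a.sr_max,
                                   np.round(a.pdf * a.sr_max), atol=1e-12)

    def test_pdf_nondecreasing_in_concentration(self):
        pts = build_pdf_points([2, 2, 3, 1, 5, 5, 0.5])
        assert (np.diff(pts.pdf) >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pdf_points([])


class TestEligibility:
    @pytest.mark.parametrize("n, expected", [
        (0, STATUS_INSUFFICIENT), (3, STATUS_INSUFFICIENT),
        (4, "eligible"), (10, "eligible"),
    ])
    def test_four_pairs_required(self, n, expected):
        pts = _points_on_logistic(2, 0.5, np.linspace(1, 3, n) if n else [])
        assert check_eligibility(pts) == expected


class TestEvaluate:
    def test_half_of_species_disappeared_at_location(self):
        for a, b in [(2.0, 0.5), (0.3, 0.05), (40.0, 7.0)]:
            assert evaluate_ssd(a, b, a) == pytest.approx(0.5, abs=1e-15)

    def test_direct_evaluation(self):
        assert evaluate_ssd(2, 0.5, 3) == pytest.approx(1 / (1 + np.exp(-2)))

    def test_low_tail_near_zero(self):
        assert evaluate_ssd(5.0, 0.2, 0.0) < 1e-10

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            evaluate_ssd(2.0, 0.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(0.01, 10),
           c1=st.floats(0, 100), c2=st.floats(0, 100))
    def test_monotone_into_unit_interval(self, a, b, c1, c2):
        p1, p2 = evaluate_ssd(a, b, c1), evaluate_ssd(a, b, c2)
        assert 0.0 <= p1 <= 1.0
        if c1 < c2:
            assert p1 <= p2  # strictness checked on separated points below

    def test_strictly_increasing_on_separated_points(self):
        c = np.linspace(0.5, 3.5, 50)
        p = evaluate_ssd(2.0, 0.5, c)
        assert (np.diff(p) > 0).all()


class TestFit:
    def test_noise_free_recovery(self):
        pts = _points_on_logistic(2.0, 0.5, np.linspace(0.5, 4, 9))
        fit = fit_ssd(pts)
        assert fit.status == STATUS_FITTED
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)
        assert fit.pseudo_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.nrmse == pytest.approx(0.0, abs=1e-6)

    def test_insufficient_points_is_a_status_not_an_exception(self):
        pts = _points_on_logistic(2.0, 0.5, [1.0, 2.0, 3.0])
        fit = fit_ssd(pts)
        assert fit.status == STATUS_INSUFFICIENT
        assert np.isnan(fit.a)

    @pytest.mark.parametrize("seed", range(10))
    def test_optimum_matches_dense_grid_search(self, seed):
        """Brute-force oracle: the least-squares optimum is at least as good
        as the best point of a 200x200 (a, b) lattice."""
        rng = np.random.default_rng(seed)
        a_true = rng.uniform(2.0, 6.0)
        b_true = rng.uniform(0.3, 1.2)
        # concentrations covering the whole transition keep the optimum
        # well-conditioned and interior to the search lattice
        conc = a_true + b_true * np.linspace(-4, 4, 20)
        conc = np.clip(conc + rng.uniform(-0.1, 0.1, conc.size), 0.01, None)
        pdf = np.clip(evaluate_ssd(a_true, b_true, conc)
                      + rng.normal(0, 0.03, conc.size), 0, 1)
        pts = PDFPoints(conc, np.zeros_like(conc), pdf, 100)
        fit = fit_ssd(pts)
        assert fit.status == STATUS_FITTED

        a_grid = np.linspace(0.5, 8.0, 200)
        b_grid = np.linspace(0.05, 3.0, 200)
        A, B = np.meshgrid(a_grid, b_grid, indexing="ij")
        pred = 1 / (1 + np.exp(-(conc[None, None, :] - A[..., None]) / B[..., None]))
        rss = ((pred - pdf) ** 2).sum(axis=-1)
        best = rss.min()
        fit_rss = ((evaluate_ssd(fit.a, fit.b, conc) - pdf) ** 2).sum()
        assert fit_rss <= best + 1e-9
        # and the grid-search argmin is close to the fitted coefficients
        i, j = np.unravel_index(rss.argmin(), rss.shape)
        assert abs(fit.a - a_grid[i]) <= (a_grid[1] - a_grid[0])
        assert abs(fit.b - b_grid[j]) <= (b_grid[1] - b_grid[0])

    def test_parameter_recovery_from_sampled_thresholds(self):
        from fishssd.synthetic import sample_logistic_thresholds
        rng = np.random.default_rng(123)
        t = sample_logistic_thresholds(2.0, 0.5, 200, rng)
        fit = fit_ssd(build_pdf_points(t))
        assert fit.a == pytest.approx(2.0, rel=0.1)
        assert fit.b == pytest.approx(0.5, rel=0.1)

    def test_recovery_bias_shrinks_with_species_count(self):
        from fishssd.synthetic import sample_logistic_thresholds
        err = {}
        for n in (50, 500):
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                t = sample_logistic_thresholds(4.0, 0.8, n, rng)
                fit = fit_ssd(build_pdf_points(t))
                errs.append(abs(fit.a - 4.0) + abs(fit.b - 0.8))
            err[n] = np.mean(errs)
        assert err[500] < err[50]

    def test_log_concentration_switch(self):
        """Fitting on log10(C) recovers the location on the log scale."""
        conc = np.logspace(-1, 2, 15)
        pdf = evaluate_ssd(1.0, 0.3, np.log10(conc))
        pts = PDFPoints(conc, np.zeros_like(conc), pdf, 100)
        fit = fit_ssd(transform_points_log10(pts))
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(0.3, abs=1e-6)


class TestDiagnostics:
    def test_perfect_fit_r2_one_nrmse_zero(self):
        pts = _points_on_logistic(2.0, 0.5, np.linspace(1, 3, 6))
        fit = fit_ssd(pts)
        assert cox_snell_r2(pts, fit) == pytest.approx(1.0, abs=1e-12)
        assert nrmse(pts, fit) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_cox_snell_equals_rss_identity(self, seed):
        """The Gaussian-ML Cox-Snell value equals 1 - RSS1/RSS0 computed
        from explicit likelihoods."""
        rng = np.random.default_rng(seed)
        conc = np.sort(rng.uniform(0.5, 6, 8))
        pdf = np.clip(evaluate_ssd(3, 0.8, conc) + rng.normal(0, 0.08, 8), 0, 1)
        pts = PDFPoints(conc, np.zeros_like(conc), pdf, 100)
        fit = fit_ssd(pts)
        n = len(pts)
        rss1 = np.sum((pdf - evaluate_ssd(fit.a, fit.b, conc)) ** 2)
        rss0 = np.sum((pdf - pdf.mean()) ** 2)

        def gauss_loglik(rss):
            s2 = rss / n
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1)

        r2_likelihood = 1 - np.exp((gauss_loglik(rss0) - gauss_loglik(rss1))
                                   * 2 / n)
        value = cox_snell_r2(pts, fit)
        assert value == pytest.approx(1 - rss1 / rss0, abs=1e-12)
        assert value == pytest.approx(r2_likelihood, abs=1e-9)

    def test_fit_no_better_than_mean_gives_zero(self):
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        pdf = np.array([0.2, 0.4, 0.6, 0.8])
        pts = PDFPoints(conc, np.zeros(4), pdf, 10)
        fit = fit_ssd(pts)
        fit.a, fit.b = 100.0, 1e6  # nearly constant prediction ~0.4999
        r2 = cox_snell_r2(pts, fit)
        assert r2 == pytest.approx(0.0, abs=1e-4)

    def test_constant_pdf_makes_r2_undefined(self):
        pts = PDFPoints(np.array([1.0, 2.0]), np.zeros(2),
                        np.array([0.3, 0.3]), 10)
        fit = fit_ssd(_points_on_logistic(2, 0.5, np.linspace(1, 3, 5)))
        assert np.isnan(cox_snell_r2(pts, fit))

    def test_nrmse_closed_form(self):
        conc = np.array([1.0, 2.0, 3.0])
        r = 0.05
        pdf_true = evaluate_ssd(2.0, 0.5, conc)
        pts = PDFPoints(conc, np.zeros(3), pdf_true + r, 100)
        fit = fit_ssd(_points_on_logistic(2, 0.5, np.linspace(1, 3, 5)))
        fit.a, fit.b = 2.0, 0.5
        assert nrmse(pts, fit) == pytest.approx(r / (pdf_true + r).mean())

    def test_zero_mean_pdf_undefined(self):
        pts = PDFPoints(np.array([1.0]), np.ones(1), np.array([0.0]), 5)
        fit = fit_ssd(_points_on_logistic(2, 0.5, np.linspace(1, 3, 5)))
        assert np.isnan(nrmse(pts, fit))


class TestFitAllRegions:
    def test_statuses_and_good_fit_flags(self, small_world):
        from fishssd import (SynonymTable, match_concentration,
                             prepare_occurrences)
        from fishssd.exposure import derive_tolerances_both_levels
        w = small_world
        rec, _ = prepare_occurrences(w.occurrences, SynonymTable(w.synonyms),
                                     (w.config.year_first, w.config.year_last),
                                     w.config.grid)
        matched, _ = match_concentration(rec, w.concentrations)
        tol = derive_tolerances_both_levels(matched, w.ecoregion_raster,
                                            w.realm_raster)
        fits = fit_all_regions(tol)
        # 2 ecoregions + 1 realm-MHT
        assert len(fits) == 3
        assert (fits["status"] == STATUS_FITTED).all()
        assert fits["good_fit"].all()

    def test_insufficient_region_gets_status_row(self):
        tol = pd.DataFrame({
            "accepted_name": ["s1", "s2", "s3"],
            "level": "ecoregion",
            "region_id": 1,
            "threshold_mg_per_L": [1.0, 2.0, 3.0],
        })
        fits = fit_all_regions(tol)
        assert len(fits) == 1
        assert fits.loc[0, "status"] == STATUS_INSUFFICIENT
        assert not fits.loc[0, "good_fit"]

    def test_empty_tolerance_table_gives_empty_fit_table(self):
        fits = fit_all_regions(pd.DataFrame(
            columns=["accepted_name", "level", "region_id",
                     "threshold_mg_per_L"]))
        assert fits.empty
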