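"""Intensity MLE, PCF estimation, minimum-contrast fit, Diggle GOF."""

import warnings

import numpy as np
import pytest

from congalines import (
    CsrParams,
    ThomasParams,
    estimate_pcf,
    fit_csr,
    fit_thomas,
    select_model,
    simulate_csr,
    simulate_thomas,
)
from congalines.errors import InsufficientDataError
from congalines.fitting import (
    GofResult,
    SetCovariance,
    default_r_grid,
    diggle_gof,
    fit_thomas_from_pcf,
)
from congalines.nullmodels import thomas_pcf
from congalines.surfaces import SurfaceMap, Window, mask_holes

from conftest import H5_THOMAS, rect_window


class TestFitCsr:
    def test_mle_is_count_over_area(self, big_window):
        rng = np.random.default_rng(1)
        surf = SurfaceMap(points=rng.uniform(0, 2, (100, 2)), window=big_window)
        lam = fit_csr(surf).lam
        assert lam == pytest.approx(25.0)
        assert lam * big_window.area == pytest.approx(surf.n)  # exact identity

    def test_empty_pattern_rejected(self, big_window):
        with pytest.raises(InsufficientDataError):
            fit_csr(SurfaceMap(points=np.empty((0, 2)), window=big_window))

    def test_masking_raises_intensity(self):
        w = rect_window(2.0)
        pts = np.random.default_rng(2).uniform(0, 2, (200, 2))
        surf = SurfaceMap(points=pts, window=w)
        hole = np.array([[1.55, 1.55], [1.95, 1.55], [1.95, 1.95], [1.55, 1.95]])
        masked = mask_holes(surf, [hole])
        # removing area while keeping outside points raises lambda-hat
        expected = masked.n / (4.0 - 0.16)
        assert fit_csr(masked).lam == pytest.approx(expected)

    def test_unbiased_at_simulated_intensity(self, unit_window):
        lams = [
            fit_csr(simulate_csr(CsrParams(140.0), unit_window, 6000 + i)).lam
            for i in range(300)
        ]
        se = np.std(lams, ddof=1) / np.sqrt(len(lams))
        assert abs(np.mean(lams) - 140.0) <= 3 * se


class TestSetCovariance:
    def test_rectangle_closed_form(self, big_window):
        sc = SetCovariance(big_window)
        assert sc(0.0, 0.0) == pytest.approx(4.0)
        assert sc(0.5, 0.0) == pytest.approx(1.5 * 2.0)
        assert sc(2.5, 0.0) == 0.0

    def test_raster_path_matches_shapely(self, l_window):
        import shapely.affinity

        sc = SetCovariance(l_window, grid_size=512)
        poly = l_window.polygon
        for vx, vy in [(0.0, 0.0), (0.2, 0.1), (-0.3, 0.4), (0.8, -0.2)]:
            exact = poly.intersection(
                shapely.affinity.translate(poly, vx, vy)
            ).area
            assert float(sc(vx, vy)) == pytest.approx(exact, abs=0.02)


class TestEstimatePcf:
    def test_too_few_points_rejected(self, unit_window):
        with pytest.raises(InsufficientDataError):
            estimate_pcf(
                SurfaceMap(points=np.array([[0.5, 0.5]]), window=unit_window)
            )

    def test_csr_estimate_is_flat_at_one(self, big_window):
        sc = SetCovariance(big_window)
        grid = default_r_grid(big_window)
        gs = [
            estimate_pcf(
                simulate_csr(CsrParams(100.0), big_window, 7000 + i),
                r=grid, setcov=sc,
            ).g
            for i in range(50)
        ]
        gs = np.array(gs)
        sel = (grid >= 0.01) & (grid <= 0.2)
        mean = gs.mean(axis=0)[sel]
        se = gs.std(axis=0, ddof=1)[sel] / np.sqrt(len(gs))
        assert np.all(np.abs(mean - 1.0) <= 4 * se)

    def test_thomas_estimate_matches_closed_form(self, big_window):
        sc = SetCovariance(big_window)
        grid = default_r_grid(big_window)
        gs = [
            estimate_pcf(
                simulate_thomas(H5_THOMAS, big_window, 8000 + i),
                r=grid, setcov=sc,
            ).g
            for i in range(50)
        ]
        gs = np.array(gs)
        sel = (grid >= 0.01) & (grid <= 0.2)
        mean = gs.mean(axis=0)[sel]
        se = gs.std(axis=0, ddof=1)[sel] / np.sqrt(len(gs))
        target = thomas_pcf(grid, H5_THOMAS.kappa, H5_THOMAS.sigma)[sel]
        assert np.all(np.abs(mean - target) <= 4 * se + 0.02 * target)

    def test_duplicate_points_warn(self, unit_window):
        pts = np.vstack([np.random.default_rng(3).uniform(0, 1, (40, 2))] * 2)
        surf = SurfaceMap(points=pts, window=unit_window)
        with pytest.warns(UserWarning, match="duplicate"):
            estimate_pcf(surf)

    def test_small_pattern_warns(self, unit_window):
        surf = SurfaceMap(
            points=np.random.default_rng(4).uniform(0, 1, (10, 2)),
            window=unit_window,
        )
        with pytest.warns(UserWarning, match="noisy"):
            estimate_pcf(surf)


class TestFitThomas:
    def test_noise_free_curve_inverts_exactly(self, big_window):
        grid = default_r_grid(big_window)
        g = thomas_pcf(grid, 18.0, 0.07263)
        fit = fit_thomas_from_pcf(grid, g, 108.0)
        assert fit.params.kappa == pytest.approx(18.0, rel=1e-4)
        assert fit.params.sigma == pytest.approx(0.07263, rel=1e-4)
        assert fit.params.mu == pytest.approx(6.0, rel=1e-4)

    def test_parameter_recovery_on_simulations(self, big_window):
        """Median relative errors stay moderate at the fitted-surface
        conditions (strongly overlapping clusters)."""
        sc = SetCovariance(big_window)
        est = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(30):
                pat = simulate_thomas(H5_THOMAS, big_window, 9000 + i)
                f = fit_thomas(pat, setcov=sc)
                est.append([f.params.kappa, f.params.mu, f.params.sigma])
        est = np.array(est)
        true = np.array([18.0, 6.0, 0.07263])
        med_rel = np.median(np.abs(est - true) / true, axis=0)
        assert np.all(med_rel <= 0.40)

    def test_csr_input_flags_weak_clustering(self, big_window):
        sc = SetCovariance(big_window)
        flags = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(10):
                pat = simulate_csr(CsrParams(100.0), big_window, 9500 + i)
                flags.append(fit_thomas(pat, setcov=sc).weak_clustering)
        assert sum(flags) >= 5  # no silent confident fit on unclustered data


class TestDiggleGof:
    def test_p_value_definition_and_range(self, unit_window):
        pat = simulate_csr(CsrParams(80.0), unit_window, 11)
        g = diggle_gof(pat, fit_csr(pat), m=19, seed=1)
        assert isinstance(g, GofResult)
        assert 0.0 < g.p_d <= 1.0
        rank = 1 + sum(u >= g.u_obs for u in g.u_sim)
        assert g.p_d == pytest.approx(rank / (g.m + 1))

    def test_p_is_one_when_observed_fits_best(self, unit_window):
        # force u_obs to be the smallest by construction impossible; instead
        # check the identity on whichever replicate achieves minimal rank
        pat = simulate_csr(CsrParams(80.0), unit_window, 12)
        g = diggle_gof(pat, fit_csr(pat), m=19, seed=2)
        if all(u >= g.u_obs for u in g.u_sim):
            assert g.p_d == 1.0

    def test_rejects_wrong_model_on_clustered_data(self, big_window):
        """CSR fitted to strongly clustered data is thrown out."""
        rejected = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(20):
                pat = simulate_thomas(
                    ThomasParams(10.0, 10.0, 0.02), big_window, 10_000 + i
                )
                g = diggle_gof(pat, fit_csr(pat), m=19, seed=11_000 + i)
                rejected += g.p_d <= 0.05
        assert rejected >= 18

    def test_reproducible_under_seed(self, unit_window):
        pat = simulate_csr(CsrParams(80.0), unit_window, 13)
        a = diggle_gof(pat, fit_csr(pat), m=19, seed=99)
        b = diggle_gof(pat, fit_csr(pat), m=19, seed=99)
        assert a.p_d == b.p_d and a.u_obs == b.u_obs


class TestSelectModel:
    def test_thomas_data_selects_thomas(self, big_window):
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(10):
                pat = simulate_thomas(H5_THOMAS, big_window, 12_000 + i)
                hits += select_model(pat, seed=13_000 + i, m=19).selected == "thomas"
        assert hits >= 9

    def test_csr_data_not_systematically_disfavoured(self, big_window):
        """Thomas nests CSR, so on CSR data selection is near a coin flip;
        guard against a systematic bias away from the true model."""
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(20):
                pat = simulate_csr(CsrParams(100.0), big_window, 14_000 + i)
                hits += select_model(pat, seed=15_000 + i, m=19).selected == "csr"
        assert hits >= 6

    def test_selection_is_reproducible(self, big_window):
        pat = simulate_thomas(H5_THOMAS, big_window, 16_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = select_model(pat, seed=5, m=19)
            b = select_model(pat, seed=5, m=19)
        assert a.selected == b.selected
        assert a.csr_gof.p_d == b.csr_gof.p_d
        assert a.thomas_gof.p_d == b.thomas_gof.p_d

    def test_tie_breaks_toward_csr(self, big_window, monkeypatch):
        import congalines.fitting as F

        pat = simulate_thomas(H5_THOMAS, big_window, 17_000)
        fixed = GofResult(0.5, 1.0, (1.0,) * 19, "pcf", 19, (0.0, 0.5))

        def fake_gof(*args, **kwargs):
            return fixed

        monkeypatch.setattr(F, "diggle_gof", fake_gof)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = F.select_model(pat, seed=1, m=19)
        assert sel.selected == "csr" and sel.tie
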