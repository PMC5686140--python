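"""Ensemble-optimization tests: conformer pools, Debye scattering, chi^2,
GA sub-ensemble selection and Rg-distribution diagnostics.

Unit-scale fixtures (short chains, small pools) keep these fast; the
full-size two-population experiment lives in the acceptance suite.
"""

import numpy as np
import pytest

from idpkit.ensemble import (
    ANGLE_PRESETS,
    CA_BOND_LENGTH,
    EXCLUDED_RADIUS,
    Conformer,
    EnsembleFit,
    chi_squared,
    debye_curve,
    detect_bimodality,
    ga_select,
    generate_pool,
    pool_curves,
    rg_distribution,
)
from idpkit.exceptions import InputError
from idpkit.saxs import ScatteringCurve, guinier_fit

Q_SMALL = np.linspace(0.01, 0.3, 50)


@pytest.fixture(scope="module")
def small_pool():
    return generate_pool(60, 150, seed=3)


@pytest.fixture(scope="module")
def small_curves(small_pool):
    return pool_curves(small_pool, Q_SMALL)


class TestPoolGeneration:
    def test_geometry_invariants(self, small_pool):
        for conf in small_pool[:20]:
            bonds = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
            np.testing.assert_allclose(bonds, CA_BOND_LENGTH, atol=0.01)
            d = np.linalg.norm(
                conf.coords[:, None, :] - conf.coords[None, :, :], axis=-1
            )
            non_adjacent = np.abs(
                np.arange(60)[:, None] - np.arange(60)[None, :]
            ) >= 2
            assert d[non_adjacent].min() >= EXCLUDED_RADIUS - 1e-9

    def test_deterministic_under_seed(self):
        a = generate_pool(30, 5, seed=11)
        b = generate_pool(30, 5, seed=11)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coords, cb.coords)

    def test_minimum_chain_length(self):
        pool = generate_pool(10, 3, seed=1)
        assert all(c.n_residues == 10 for c in pool)
        with pytest.raises(InputError):
            generate_pool(5, 3, seed=1)

    def test_coil_preset_matches_flory_scale(self):
        """Mean pool Rg for a 143-residue coil lies within 25% of the
        Flory expectation 2.54*143**0.522 ~ 33.9 Å."""
        pool = generate_pool(143, 60, seed=5, preset="coil")
        mean_rg = np.mean([c.rg for c in pool])
        flory = 2.54 * 143**0.522
        assert abs(mean_rg - flory) / flory < 0.25

    def test_presets_are_ordered(self):
        rg = {}
        for preset in ("compact", "coil", "expanded"):
            pool = generate_pool(80, 30, seed=7, preset=preset)
            rg[preset] = np.mean([c.rg for c in pool])
        assert rg["compact"] < rg["coil"] < rg["expanded"]


class TestDebye:
    def test_single_point_is_form_factor_only(self):
        conf = Conformer(np.zeros((1, 3)))
        curve = debye_curve(conf, Q_SMALL, sigma_f=3.0)
        np.testing.assert_allclose(
            curve.intensity, np.exp(-(Q_SMALL**2) * 9.0), rtol=1e-12
        )

    def test_two_points_closed_form(self):
        d = 10.0
        conf = Conformer(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
        curve = debye_curve(conf, Q_SMALL, sigma_f=3.0)
        expected = (2.0 + 2.0 * np.sin(Q_SMALL * d) / (Q_SMALL * d)) * np.exp(
            -(Q_SMALL**2) * 9.0
        )
        np.testing.assert_allclose(curve.intensity, expected, rtol=1e-12)

    def test_straight_chain_matches_bruteforce_double_sum(self):
        n = 50
        coords = np.column_stack(
            [np.arange(n) * CA_BOND_LENGTH, np.zeros(n), np.zeros(n)]
        )
        q = np.linspace(0.02, 0.25, 10)
        curve = debye_curve(Conformer(coords), q, sigma_f=3.0)
        brute = np.zeros_like(q)
        for k, qk in enumerate(q):
            total = 0.0
            for i in range(n):
                for j in range(n):
                    r = abs(i - j) * CA_BOND_LENGTH
                    total += 1.0 if r == 0 else np.sin(qk * r) / (qk * r)
            brute[k] = total * np.exp(-(qk**2) * 9.0)
        np.testing.assert_allclose(curve.intensity, brute, rtol=1e-10)

    def test_forward_intensity_is_n_squared(self):
        conf = generate_pool(25, 1, seed=2)[0]
        q = np.array([1e-6])
        assert debye_curve(conf, q).intensity[0] == pytest.approx(25**2, rel=1e-6)

    def test_guinier_rg_tracks_coordinate_rg(self, small_pool):
        """Debye curves obey the Guinier law.  The Gaussian dummy-residue
        form factor adds 3*sigma_f^2 to the apparent Rg^2 (Guinier radii
        of Gaussian factors add in quadrature); with point scatterers the
        fitted Rg matches the coordinate Rg directly, and for
        production-size chains the form-factor correction is within the
        3% band."""
        for conf in small_pool[:5]:
            q = np.linspace(0.005, 1.0 / conf.rg, 60)
            fit0 = guinier_fit(debye_curve(conf, q, sigma_f=0.0))
            assert fit0.rg == pytest.approx(conf.rg, rel=0.01)
            fit = guinier_fit(debye_curve(conf, q, sigma_f=3.0))
            apparent = np.sqrt(conf.rg**2 + 3 * 3.0**2)
            assert fit.rg == pytest.approx(apparent, rel=0.01)
        big = generate_pool(143, 3, seed=8, preset="coil")
        for conf in big:
            q = np.linspace(0.004, 1.0 / conf.rg, 60)
            fit = guinier_fit(debye_curve(conf, q, sigma_f=3.0))
            assert fit.rg == pytest.approx(conf.rg, rel=0.03)


class TestChiSquared:
    def test_proportional_curves_give_zero(self):
        q = Q_SMALL
        i_exp = np.exp(-(q**2) * 100.0)
        curve = ScatteringCurve(q, i_exp, i_exp * 0.02)
        chi2, mu = chi_squared(5.0 * i_exp, curve)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert mu == pytest.approx(0.2)

    def test_one_sigma_noise_gives_unit_chi2(self):
        """I_exp = I_calc + 1-sigma noise over many points: mean reduced
        chi^2 ~ 1 (100 replicates)."""
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 0.4, 400)
        i_calc = np.exp(-(q**2) * 400.0) + 0.01
        sigma = 0.02 * i_calc
        chis = []
        for _ in range(100):
            i_exp = i_calc + rng.normal(0.0, sigma)
            chis.append(chi_squared(i_calc, ScatteringCurve(q, i_exp, sigma))[0])
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_mismatched_grid_rejected(self):
        curve = ScatteringCurve(Q_SMALL, np.ones_like(Q_SMALL))
        with pytest.raises(InputError):
            chi_squared(np.ones(10), curve)


class TestGaSelect:
    def test_planted_single_conformer_recovery(self, small_pool, small_curves):
        """Noiseless target built from one pool member: the selected
        ensemble reproduces it to chi^2 < 0.01 and its Rg distribution
        collapses onto that conformer."""
        target_i = small_curves[7]
        target = ScatteringCurve(Q_SMALL, target_i, np.maximum(target_i, 1.0) * 1e-3)
        rgs = np.array([c.rg for c in small_pool])
        fit = ga_select(
            small_curves, target, rgs, max_ensemble=20, generations=80,
            population=60, seed=4,
        )
        assert fit.chi2 < 0.01
        assert fit.selected_rg.std() < 0.05 * fit.selected_rg.mean()

    def test_pool_average_target_is_fit_trivially(self, small_pool, small_curves):
        avg = small_curves.mean(axis=0)
        target = ScatteringCurve(Q_SMALL, avg, np.maximum(avg, 1.0) * 1e-2)
        rgs = np.array([c.rg for c in small_pool])
        fit = ga_select(
            small_curves, target, rgs, max_ensemble=20, generations=80,
            population=60, seed=5,
        )
        assert fit.chi2 < 0.5

    def test_ensemble_never_worse_than_best_single(self, small_pool, small_curves):
        rng = np.random.default_rng(9)
        mix = small_curves[rng.choice(150, 5)].mean(axis=0)
        target = ScatteringCurve(Q_SMALL, mix, np.maximum(mix, 1.0) * 1e-2)
        rgs = np.array([c.rg for c in small_pool])
        singles = [chi_squared(small_curves[i], target)[0] for i in range(150)]
        fit = ga_select(
            small_curves, target, rgs, max_ensemble=20, generations=60,
            population=50, seed=6,
        )
        assert fit.chi2 <= min(singles) + 1e-12

    def test_reproducible_under_seed(self, small_pool, small_curves):
        target_i = small_curves[3]
        target = ScatteringCurve(Q_SMALL, target_i, np.maximum(target_i, 1.0) * 1e-3)
        rgs = np.array([c.rg for c in small_pool])
        kwargs = dict(max_ensemble=15, generations=40, population=40, seed=21)
        a = ga_select(small_curves, target, rgs, **kwargs)
        b = ga_select(small_curves, target, rgs, **kwargs)
        np.testing.assert_array_equal(a.indices, b.indices)
        assert a.chi2 == b.chi2

    def test_pool_smaller_than_ensemble_rejected(self, small_curves):
        target = ScatteringCurve(Q_SMALL, small_curves[0])
        with pytest.raises(InputError):
            ga_select(small_curves[:10], target, np.ones(10), max_ensemble=50)


class TestRgDistribution:
    @staticmethod
    def _fit_from_samples(selected, pool=None):
        pool = selected if pool is None else pool
        return EnsembleFit(
            indices=np.arange(len(selected)), chi2=0.0, mu=1.0,
            pool_rg=np.asarray(pool, float), selected_rg=np.asarray(selected, float),
            converged=True, generations_run=0,
        )

    def test_unimodal_sample_not_flagged(self):
        rng = np.random.default_rng(1)
        fit = self._fit_from_samples(rng.normal(40.0, 4.0, 500))
        *_, flag, modes = rg_distribution(fit)
        assert not flag
        assert modes == ()

    def test_two_separated_gaussians_flagged(self):
        rng = np.random.default_rng(2)
        sample = np.concatenate(
            [rng.normal(25.0, 3.0, 300), rng.normal(60.0, 4.0, 300)]
        )
        *_, flag, modes = rg_distribution(self._fit_from_samples(sample))
        assert flag
        assert modes[0] == pytest.approx(25.0, abs=2.0)
        assert modes[1] == pytest.approx(60.0, abs=2.0)

    def test_detect_bimodality_rejects_shallow_valley(self):
        hist = np.array([0.0, 5.0, 4.5, 5.0, 0.0])
        flag, _ = detect_bimodality(hist, smooth=False)
        assert not flag
        hist2 = np.array([0.0, 5.0, 1.0, 5.0, 0.0])
        flag2, peaks = detect_bimodality(hist2, smooth=False)
        assert flag2
        assert peaks == (1, 3)
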