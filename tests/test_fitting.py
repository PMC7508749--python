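"""Dispersion fitting: chi-square, model comparison, MC errors, pKa."""

import numpy as np
import pytest

from wobblefit.bloch import r1rho_grid
from wobblefit.fitting import (FitResult, FitSpec, RDDataset, chi_square,
                               compare_topologies, fit_dispersion,
                               mc_parameter_errors, pka_from_population)
from wobblefit.models import ExchangeModel

SMALL_GRID = np.array([(p, o) for p in (400.0, 1200.0)
                       for o in (-1200.0, -600.0, -300.0, 0.0, 300.0, 600.0, 1200.0)])


def exact_dataset(model, channel, sigma=0.2, grid=SMALL_GRID):
    calc = r1rho_grid(model, channel, grid)
    return RDDataset(channel.id, grid[:, 0], grid[:, 1], calc,
                     np.full(len(grid), sigma))


class TestChiSquare:
    def test_zero_on_exact_data(self, two_state_model, c13_channel):
        ds = exact_dataset(two_state_model, c13_channel)
        assert chi_square(two_state_model, {c13_channel.id: c13_channel},
                          {c13_channel.id: ds}) == pytest.approx(0.0, abs=1e-16)

    def test_unit_residual_gives_one(self, two_state_model, c13_channel):
        grid = SMALL_GRID[:1]
        calc = r1rho_grid(two_state_model, c13_channel, grid)
        ds = RDDataset(c13_channel.id, grid[:, 0], grid[:, 1],
                       calc + 0.3, [0.3])
        assert chi_square(two_state_model, {c13_channel.id: c13_channel},
                          {c13_channel.id: ds}) == pytest.approx(1.0)

    def test_sigma_weighting_law(self, two_state_model, c13_channel, rng):
        calc = r1rho_grid(two_state_model, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.3, calc.shape)
        d1 = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.3))
        d2 = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.6))
        c1 = chi_square(two_state_model, {c13_channel.id: c13_channel},
                        {c13_channel.id: d1})
        c2 = chi_square(two_state_model, {c13_channel.id: c13_channel},
                        {c13_channel.id: d2})
        assert c2 == pytest.approx(c1 / 4.0)

    def test_nonpositive_sigma_rejected(self, c13_channel):
        with pytest.raises(ValueError):
            RDDataset(c13_channel.id, [500.0], [0.0], [20.0], [0.0])


class TestFitDispersion:
    def test_all_fixed_matches_direct_chi_square(self, two_state_model,
                                                 c13_channel, rng):
        calc = r1rho_grid(two_state_model, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.2, calc.shape)
        ds = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.2))
        fixed = {"p_b": two_state_model.p_b, "kex_ab": two_state_model.kex_ab,
                 f"r1:{c13_channel.id}": c13_channel.r1,
                 f"r2:{c13_channel.id}": c13_channel.r2,
                 f"dw_ab:{c13_channel.id}": two_state_model.dw_ab[c13_channel.id]}
        spec = FitSpec(topology="two_state", fixed=fixed)
        fit = fit_dispersion({c13_channel.id: ds},
                             {c13_channel.id: c13_channel}, spec)
        direct = chi_square(two_state_model, {c13_channel.id: c13_channel},
                            {c13_channel.id: ds})
        assert fit.chi2 == pytest.approx(direct, rel=1e-12)
        assert fit.n_free == 0

    def test_noiseless_fit_recovers_truth(self, two_state_model, c13_channel):
        ds = exact_dataset(two_state_model, c13_channel, sigma=0.1)
        spec = FitSpec(topology="two_state", n_starts=4, seed=3,
                       initial={"p_b": 0.004, "kex_ab": 700.0,
                                f"dw_ab:{c13_channel.id}": 1.0})
        fit = fit_dispersion({c13_channel.id: ds},
                             {c13_channel.id: c13_channel}, spec)
        assert fit.chi2 < 1e-4
        assert fit.params["p_b"] == pytest.approx(0.002, rel=0.05)
        assert fit.params["kex_ab"] == pytest.approx(1000.0, rel=0.05)
        assert abs(fit.params[f"dw_ab:{c13_channel.id}"]) == pytest.approx(2.0, rel=0.05)

    def test_repeat_call_is_deterministic(self, two_state_model, c13_channel, rng):
        calc = r1rho_grid(two_state_model, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.2, calc.shape)
        ds = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.2))
        spec = FitSpec(topology="two_state", n_starts=3, seed=5)
        f1 = fit_dispersion({c13_channel.id: ds}, {c13_channel.id: c13_channel}, spec)
        f2 = fit_dispersion({c13_channel.id: ds}, {c13_channel.id: c13_channel}, spec)
        assert f1.params == f2.params
        assert f1.chi2 == f2.chi2

    def test_flat_profile_fits_null_exchange(self, c13_channel, rng):
        """p_b = 0 data: fitted exchange amplitude consistent with no
        dispersion and chi2/dof about 1."""
        null = ExchangeModel(topology="two_state", p_b=1e-12, kex_ab=1e-6,
                             dw_ab={c13_channel.id: 0.0})
        calc = r1rho_grid(null, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.1, calc.shape)
        ds = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.1))
        spec = FitSpec(topology="two_state", n_starts=4, seed=9,
                       check_dw_sign=False)
        fit = fit_dispersion({c13_channel.id: ds},
                             {c13_channel.id: c13_channel}, spec)
        # exchange broadening amplitude p_b * dw^2 indistinguishable from 0
        amp = fit.params["p_b"] * fit.params[f"dw_ab:{c13_channel.id}"] ** 2
        assert amp < 0.05
        assert fit.reduced_chi2 < 2.0

    def test_dw_sign_degeneracy_flagged_in_fast_exchange(self, c13_channel, rng):
        model = ExchangeModel(topology="two_state", p_b=0.01, kex_ab=20000.0,
                              dw_ab={c13_channel.id: 1.0})
        grid = np.array([(p, o) for p in (300.0, 900.0, 2700.0)
                         for o in np.linspace(-3000.0, 3000.0, 9)])
        calc = r1rho_grid(model, c13_channel, grid)
        ds = RDDataset(c13_channel.id, grid[:, 0], grid[:, 1],
                       calc, np.full(len(calc), 0.3))   # experiment-scale sigma
        spec = FitSpec(topology="two_state", n_starts=2, seed=2,
                       initial={"p_b": 0.01, "kex_ab": 20000.0,
                                f"dw_ab:{c13_channel.id}": 1.0})
        fit = fit_dispersion({c13_channel.id: ds},
                             {c13_channel.id: c13_channel}, spec)
        assert "dw_sign_degenerate" in fit.flags


class TestMonteCarloErrors:
    def test_same_seed_same_uncertainties(self, two_state_model, c13_channel, rng):
        calc = r1rho_grid(two_state_model, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.2, calc.shape)
        ds = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                       noisy, np.full(len(calc), 0.2))
        spec = FitSpec(topology="two_state", n_starts=2, seed=4,
                       check_dw_sign=False)
        fit = fit_dispersion({c13_channel.id: ds},
                             {c13_channel.id: c13_channel}, spec)
        u1 = mc_parameter_errors(fit, {c13_channel.id: ds},
                                 {c13_channel.id: c13_channel}, spec,
                                 n_mc=5, seed=8)
        u2 = mc_parameter_errors(fit, {c13_channel.id: ds},
                                 {c13_channel.id: c13_channel}, spec,
                                 n_mc=5, seed=8)
        assert u1 == u2

    def test_uncertainty_shrinks_with_duplicated_grid(self, two_state_model,
                                                      c13_channel, rng):
        """Duplicating every point shrinks MC SDs by about 1/sqrt(2)."""
        calc = r1rho_grid(two_state_model, c13_channel, SMALL_GRID)
        noisy = calc + rng.normal(0, 0.2, calc.shape)
        sig = np.full(len(calc), 0.2)
        ds1 = RDDataset(c13_channel.id, SMALL_GRID[:, 0], SMALL_GRID[:, 1],
                        noisy, sig)
        grid2 = np.vstack([SMALL_GRID, SMALL_GRID])
        ds2 = RDDataset(c13_channel.id, grid2[:, 0], grid2[:, 1],
                        np.concatenate([noisy, noisy]), np.concatenate([sig, sig]))
        spec = FitSpec(topology="two_state", n_starts=2, seed=4,
                       check_dw_sign=False)
        ratios = []
        for key in ("p_b", "kex_ab"):
            us = []
            for ds in (ds1, ds2):
                fit = fit_dispersion({c13_channel.id: ds},
                                     {c13_channel.id: c13_channel}, spec)
                u = mc_parameter_errors(fit, {c13_channel.id: ds},
                                        {c13_channel.id: c13_channel}, spec,
                                        n_mc=40, seed=8)
                us.append(u[key])
            ratios.append(us[1] / us[0])
        assert np.mean(ratios) == pytest.approx(1.0 / np.sqrt(2.0), abs=0.25)

    def test_n_mc_lower_bound(self, two_state_model, c13_channel):
        ds = exact_dataset(two_state_model, c13_channel)
        spec = FitSpec(topology="two_state")
        fake = FitResult(topology="two_state", params={}, chi2=0.0,
                         n_points=1, n_free=1, profiles=None)
        with pytest.raises(ValueError):
            mc_parameter_errors(fake, {c13_channel.id: ds},
                                {c13_channel.id: c13_channel}, spec, n_mc=1)


class TestCompareTopologies:
    @staticmethod
    def result(chi2, k, n=50):
        return FitResult(topology="x", params={}, chi2=chi2, n_points=n,
                         n_free=k, profiles=None)

    def test_equal_fits_equal_weights(self):
        df = compare_topologies({"a": self.result(10.0, 3),
                                 "b": self.result(10.0, 3)})
        assert df["aic_weight"].tolist() == pytest.approx([0.5, 0.5])
        assert df["bic_weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one(self):
        df = compare_topologies({"a": self.result(12.0, 3),
                                 "b": self.result(10.0, 4),
                                 "c": self.result(9.0, 6)})
        assert df["aic_weight"].sum() == pytest.approx(1.0)
        assert df["bic_weight"].sum() == pytest.approx(1.0)

    def test_delta_aic_two_gives_e_ratio(self):
        # same k, chi2 differing by 2 -> AIC difference 2 -> ratio e
        df = compare_topologies({"a": self.result(10.0, 3),
                                 "b": self.result(12.0, 3)})
        ratio = df.loc["a", "aic_weight"] / df.loc["b", "aic_weight"]
        assert ratio == pytest.approx(np.e, rel=1e-9)

    def test_unequal_data_rejected(self):
        with pytest.raises(ValueError):
            compare_topologies({"a": self.result(10.0, 3, n=50),
                                "b": self.result(10.0, 3, n=60)})


class TestPKa:
    def test_printed_anion_population(self):
        """8.019% anion at pH 8.8 -> pKa ~ 9.86 (rounds to 9.9)."""
        assert pka_from_population(0.08019, 8.8) == pytest.approx(9.86, abs=0.01)

    def test_half_population_gives_ph(self):
        assert pka_from_population(0.5, 7.4) == pytest.approx(7.4)

    def test_one_percent_at_ph7(self):
        assert pka_from_population(0.01, 7.0) == pytest.approx(7.0 + np.log10(99.0))

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            pka_from_population(0.0, 7.0)
        with pytest.raises(ValueError):
            pka_from_population(1.2, 7.0)
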