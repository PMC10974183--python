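import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixtox.dose_response import (
    CurveFamily,
    CurveParams,
    DoseResponseCurve,
    FitError,
    ec_with_oci,
    fit_curve,
    hill_effect,
    invert_curve,
    mass_to_molar,
    pec,
    select_model,
    weibull_effect,
)


class TestCurveEvaluation:
    def test_weibull_at_unit_concentration(self):
        # alpha + beta*log10(1) = 0 forces E = 1 - exp(-1)
        assert weibull_effect(0.0, 1.0, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-15)

    def test_weibull_low_concentration_limit(self):
        assert weibull_effect(0.0, 1.0, 1e-300) < 1e-12

    def test_weibull_hand_arithmetic(self):
        # direct evaluation of the printed formula at alpha=2, beta=1.5, x=1e-4
        expected = 1.0 - math.exp(-math.exp(2.0 + 1.5 * math.log10(1e-4)))
        assert weibull_effect(2.0, 1.5, 1e-4) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize(
        "alpha,beta,x,expected",
        [
            (1.0, 1e-4, 1e-4, 0.5),  # half-maximal at x = beta
            (1.0, 2e-4, 1e-4, 1.0 / 3.0),  # x/(beta+x) with beta = 2x
        ],
    )
    def test_hill_values(self, alpha, beta, x, expected):
        assert hill_effect(alpha, beta, x) == pytest.approx(expected, rel=1e-14)

    def test_hill_asymptote(self):
        assert hill_effect(0.8, 1e-5, 1e5) == pytest.approx(0.8, abs=1e-9)

    @pytest.mark.parametrize("bad_x", [0.0, -1e-6])
    def test_nonpositive_concentration_rejected(self, bad_x):
        with pytest.raises(ValueError):
            weibull_effect(0.0, 1.0, bad_x)
        with pytest.raises(ValueError):
            hill_effect(1.0, 1e-4, bad_x)

    @settings(derandomize=True, max_examples=100)
    @given(
        alpha=st.floats(-5, 15),
        beta=st.floats(0.3, 8.0),
    )
    def test_weibull_strictly_increasing(self, alpha, beta):
        x = np.geomspace(1e-9, 1e-2, 50)
        e = weibull_effect(alpha, beta, x)
        assert np.all(np.diff(e) >= 0)
        interior = (e > 1e-12) & (e < 1 - 1e-12)
        assert np.all(np.diff(e[interior]) > 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        alpha=st.floats(0.05, 1.0),
        log_beta=st.floats(-8, -2),
    )
    def test_hill_strictly_increasing(self, alpha, log_beta):
        x = np.geomspace(1e-9, 1e-2, 50)
        e = hill_effect(alpha, 10.0**log_beta, x)
        assert np.all(np.diff(e) > 0)


class TestInversion:
    def test_weibull_known_inverse(self):
        assert invert_curve(
            CurveParams("weibull", 0.0, 1.0), 1 - math.exp(-1)
        ) == pytest.approx(1.0, rel=1e-12)

    def test_hill_ec50_is_beta(self):
        assert invert_curve(CurveParams("hill", 1.0, 5e-5), 0.5) == pytest.approx(5e-5)

    def test_weibull_inverse_matches_bisection_oracle(self):
        # brute-force root-finding on the forward curve, independent of the
        # closed form under test
        params = CurveParams("weibull", 2.0, 1.5)
        lo, hi = 1e-12, 1e3
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if weibull_effect(2.0, 1.5, mid) < 0.5:
                lo = mid
            else:
                hi = mid
        assert invert_curve(params, 0.5) == pytest.approx(math.sqrt(lo * hi), rel=1e-12)

    @settings(derandomize=True, max_examples=250)
    @given(
        family=st.sampled_from(["weibull", "hill"]),
        a=st.floats(0.1, 0.99),
        b=st.floats(0.5, 5.0),
        e=st.floats(0.01, 0.95),
    )
    def test_round_trip(self, family, a, b, e):
        if family == "weibull":
            params = CurveParams("weibull", a * 10 - 5, b)
        else:
            params = CurveParams("hill", a, 10.0 ** (-b - 2))
            e = e * a * 0.999
        x = invert_curve(params, e)
        assert params.effect(x) == pytest.approx(e, abs=1e-10)

    def test_out_of_range_effect_raises(self):
        with pytest.raises(ValueError):
            invert_curve(CurveParams("weibull", 0.0, 1.0), 1.0)
        with pytest.raises(ValueError):
            invert_curve(CurveParams("hill", 0.8, 1e-4), 0.9)


class TestFitting:
    @pytest.mark.parametrize(
        "params",
        [CurveParams("weibull", 2.0, 1.5), CurveParams("hill", 0.9, 3e-5)],
        ids=["weibull", "hill"],
    )
    def test_noise_free_self_consistency(self, params):
        x = np.geomspace(1e-7, 1e-2, 7)
        y = np.asarray(params.effect(x))
        fit = fit_curve(x, y, params.family)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(params.alpha, rel=1e-6)
        assert fit.params.beta == pytest.approx(params.beta, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_noisy_pec50_recovery(self):
        from mixtox.io import effect_table
        from mixtox.simulate import SimulationScenario, simulate_single, weibull_from_ec50

        truth = weibull_from_ec50(1.18e-4, 3.0)
        scenario = SimulationScenario(
            truth={"AMP": truth}, fractions=(1.0,), noise_sd=0.02, seed=7
        )
        effs, _ = effect_table(simulate_single(scenario))
        fit = fit_curve(effs["concentration"], effs["effect"], "weibull")
        assert pec(invert_curve(fit.params, 0.5)) == pytest.approx(
            pec(1.18e-4), abs=0.1
        )

    def test_degenerate_constant_effects(self):
        x = np.geomspace(1e-6, 1e-4, 5)
        fit = fit_curve(x, np.full(5, 0.3), "weibull")
        assert math.isnan(fit.r_squared)  # SStot = 0 sentinel

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve([1e-5, 2e-5], [0.1, 0.2], "weibull")
        with pytest.raises(ValueError):
            fit_curve([1e-5] * 4, [0.1, 0.2, 0.3, 0.4], "weibull")


class TestModelSelection:
    @staticmethod
    def _fit(family, r2, rmse):
        params = CurveParams(family, 0.5, 1.0 if family == "weibull" else 1e-4)
        from mixtox.dose_response import FitResult

        return FitResult(params=params, r_squared=r2, rmse=rmse, n_points=7)

    def test_strict_maximum_r2(self):
        best = select_model([self._fit("weibull", 0.99, 0.03), self._fit("hill", 0.95, 0.02)])
        assert best.params.family is CurveFamily.WEIBULL

    def test_tie_broken_by_rmse(self):
        best = select_model([self._fit("weibull", 0.99, 0.03), self._fit("hill", 0.99, 0.02)])
        assert best.params.family is CurveFamily.HILL

    def test_single_fit_identity(self):
        only = self._fit("hill", 0.8, 0.1)
        assert select_model([only]) is only

    def test_all_failed_raises(self):
        bad = self._fit("weibull", 0.5, 0.1)
        bad.converged = False
        with pytest.raises(FitError):
            select_model([bad])


class TestBootstrapOCI:
    def _fit_noise_free(self):
        params = CurveParams("weibull", 2.0, 1.5)
        x = np.repeat(np.geomspace(1e-5, 1e-1, 7), 3)
        y = np.asarray(params.effect(x))
        return fit_curve(x, y, "weibull"), x, y

    def test_noise_free_interval_degenerates(self):
        fit, x, y = self._fit_noise_free()
        est = ec_with_oci(fit, x, y, 0.5, n_boot=50, seed=1)
        assert est.ec_low == pytest.approx(est.ec, rel=1e-9)
        assert est.ec_up == pytest.approx(est.ec, rel=1e-9)

    def test_zero_bootstrap_gives_no_bounds(self):
        fit, x, y = self._fit_noise_free()
        est = ec_with_oci(fit, x, y, 0.5, n_boot=0, seed=1)
        assert est.ec_low is None and est.ec_up is None

    def test_deterministic_given_seed(self):
        from mixtox.io import effect_table
        from mixtox.simulate import SimulationScenario, simulate_single, weibull_from_ec50

        scenario = SimulationScenario(
            truth={"A": weibull_from_ec50(1e-4, 3.0)}, noise_sd=0.02, seed=11
        )
        effs, _ = effect_table(simulate_single(scenario))
        fit = fit_curve(effs["concentration"], effs["effect"], "weibull")
        a = ec_with_oci(fit, effs["concentration"], effs["effect"], 0.5, n_boot=100, seed=5)
        b = ec_with_oci(fit, effs["concentration"], effs["effect"], 0.5, n_boot=100, seed=5)
        assert (a.ec, a.ec_low, a.ec_up) == (b.ec, b.ec_low, b.ec_up)
        assert a.ec_low <= a.ec <= a.ec_up

    def test_interval_covers_true_ec50(self):
        """95% bootstrap OCI should contain the generating EC50 in at least
        ~90% of simulated experiments."""
        from mixtox.io import effect_table
        from mixtox.simulate import SimulationScenario, simulate_single, weibull_from_ec50

        truth_ec50 = 1.18e-4
        truth = weibull_from_ec50(truth_ec50, 3.0)
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            scenario = SimulationScenario(
                truth={"A": truth}, noise_sd=0.02, seed=seed
            )
            effs, _ = effect_table(simulate_single(scenario))
            fit = fit_curve(effs["concentration"], effs["effect"], "weibull")
            est = ec_with_oci(
                fit, effs["concentration"], effs["effect"], 0.5, n_boot=300, seed=seed
            )
            hits += est.ec_low <= truth_ec50 <= est.ec_up
        assert hits / n_rep >= 0.90


class TestScalarHelpers:
    @pytest.mark.parametrize(
        "ec,expected",
        [(1.18e-4, 3.93), (1.99e-4, 3.70), (1e-5, 5.00)],
    )
    def test_pec_reporting(self, ec, expected):
        assert pec(ec, 2) == pytest.approx(expected, abs=5e-3)

    def test_pec_hill_identity(self):
        # pec(invert(hill(1, b), 0.5)) = -log10(b) exactly
        b = 3.7e-5
        assert pec(invert_curve(CurveParams("hill", 1.0, b), 0.5)) == -math.log10(b)

    @pytest.mark.parametrize(
        "mass,mm,expected",
        [
            (27.1e-6, 349.0, 7.77e-8),
            (14.2e-3, 349.0, 4.07e-5),
            (349.0, 349.0, 1.0),
        ],
    )
    def test_mass_to_molar(self, mass, mm, expected):
        assert mass_to_molar(mass, mm) == pytest.approx(expected, rel=5e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pec(0.0)
        with pytest.raises(ValueError):
            mass_to_molar(-1.0, 349.0)


class TestEstimator:
    def test_auto_selection_and_sklearn_contract(self):
        from sklearn.base import clone

        params = CurveParams("weibull", 2.0, 1.5)
        x = np.geomspace(1e-5, 1e-1, 9)
        model = DoseResponseCurve()
        assert clone(model).get_params() == model.get_params()
        model.fit(x.reshape(-1, 1), np.asarray(params.effect(x)))
        assert model.family_ is CurveFamily.WEIBULL
        assert model.alpha_ == pytest.approx(2.0, rel=1e-6)
        np.testing.assert_allclose(
            model.predict(x.reshape(-1, 1)), params.effect(x), atol=1e-9
        )
        assert model.score(x.reshape(-1, 1), np.asarray(params.effect(x))) == pytest.approx(1.0)

    def test_effect_concentration_and_pec50(self):
        truth = CurveParams("hill", 1.0, 5e-5)
        x = np.geomspace(1e-7, 1e-2, 9)
        model = DoseResponseCurve(family="hill").fit(x, np.asarray(truth.effect(x)))
        assert model.effect_concentration(0.5) == pytest.approx(5e-5, rel=1e-6)
        assert model.pec50(2) == pytest.approx(round(-math.log10(5e-5), 2))
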