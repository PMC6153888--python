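"""Error-model predictions, nesting identities, AICc, and the mixed-effects fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import distaniso as da
from distaniso.models import VARIANT_WEIGHTS, AnisotropyParams

weights = st.floats(0.05, 1.0)


def hv(w_h, w_v):
    return AnisotropyParams(variant="hv", w_h=w_h, w_v=w_v)


class TestPredictError:
    def test_equal_weights_reduce_to_constant(self):
        alpha = np.linspace(-180, 180, 73)
        np.testing.assert_allclose(da.predict_error(hv(0.3, 0.3), alpha), 0.3, atol=1e-12)

    def test_pure_axis_values(self):
        p = hv(0.36, 0.40)
        assert da.predict_error(p, 0) == pytest.approx(0.36)
        assert da.predict_error(p, 180) == pytest.approx(0.36)
        assert da.predict_error(p, 90) == pytest.approx(0.40)
        assert da.predict_error(p, -90) == pytest.approx(0.40)

    def test_oblique_hand_computed(self):
        # sqrt((0.36*cos30)^2 + (0.40*sin30)^2)
        assert da.predict_error(hv(0.36, 0.40), 30) == pytest.approx(0.3704, abs=5e-5)

    def test_isotropy_returns_intercept(self):
        p = AnisotropyParams(variant="isotropy", intercept=0.38)
        np.testing.assert_allclose(da.predict_error(p, np.arange(-150, 181, 30)), 0.38)

    @pytest.mark.parametrize("switch", [0.0, 90.0, -90.0, 180.0])
    def test_continuity_at_indicator_switches(self, switch):
        p = AnisotropyParams(variant="fbud", w_f=0.2, w_b=0.5, w_u=0.3, w_d=0.7)
        eps = 1e-7
        left = da.predict_error(p, switch - eps)
        right = da.predict_error(p, switch + eps)
        assert left == pytest.approx(right, abs=1e-5)

    @given(w_h=weights, w_v=weights)
    def test_nesting_ud_and_fb_collapse_to_hv(self, w_h, w_v):
        alpha = np.linspace(-179.5, 180, 144)
        base = da.predict_error(hv(w_h, w_v), alpha)
        ud = AnisotropyParams(variant="ud", w_h=w_h, w_u=w_v, w_d=w_v)
        fb = AnisotropyParams(variant="fb", w_f=w_h, w_b=w_h, w_v=w_v)
        fbud = AnisotropyParams(variant="fbud", w_f=w_h, w_b=w_h, w_u=w_v, w_d=w_v)
        np.testing.assert_allclose(da.predict_error(ud, alpha), base, atol=1e-12)
        np.testing.assert_allclose(da.predict_error(fb, alpha), base, atol=1e-12)
        np.testing.assert_allclose(da.predict_error(fbud, alpha), base, atol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            hv(-0.1, 0.4)

    def test_missing_weight_rejected(self):
        with pytest.raises(ValueError):
            AnisotropyParams(variant="ud", w_h=0.3, w_u=0.4)


class TestAicc:
    def test_direct_formula(self):
        assert da.aicc(0.0, 1, 3) == pytest.approx(6.0)
        assert da.aicc(-10.0, 2, 100) == pytest.approx(24.0 + 12.0 / 97.0)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-50.0) + 2 * 3
        assert da.aicc(-50.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            da.aicc(0.0, 3, 4)


class TestCompareModels:
    def _result(self, variant, aicc_value, n=100, checksum=1.0):
        return da.ModelFitResult(
            variant=variant,
            fixed_estimates=AnisotropyParams(variant="isotropy", intercept=0.3),
            random_effect_sd=0.1, residual_sd=0.2,
            loglik=0.0, k=3, n=n, aicc=aicc_value, converged=True,
            n_participants=10, data_checksum=checksum,
        )

    def test_equal_aicc_both_best(self):
        table = da.compare_models([self._result("hv", 10.0), self._result("ud", 10.0)])
        assert (table["daicc"] == 0).all()
        assert table["indistinguishable"].all()

    def test_reported_upright_pair(self):
        # best -63.5, null -57.9 -> daicc 5.6, beyond the <4 guideline
        table = da.compare_models([self._result("hv", -63.5), self._result("isotropy", -57.9)])
        iso = table.set_index("variant").loc["isotropy"]
        assert iso["daicc"] == pytest.approx(5.6)
        assert not iso["indistinguishable"]
        assert table.set_index("variant").loc["hv", "best"]

    def test_ranking_invariant_to_input_order(self):
        fits = [self._result(v, a) for v, a in [("hv", 3.0), ("ud", 1.0), ("fb", 2.0)]]
        t1 = da.compare_models(fits)
        t2 = da.compare_models(fits[::-1])
        assert list(t1["variant"]) == list(t2["variant"]) == ["ud", "fb", "hv"]

    def test_refuses_differing_observation_sets(self):
        with pytest.raises(ValueError, match="differing"):
            da.compare_models([self._result("hv", 1.0, n=100), self._result("ud", 2.0, n=99)])
        with pytest.raises(ValueError, match="differing"):
            da.compare_models(
                [self._result("hv", 1.0, checksum=1.0), self._result("ud", 2.0, checksum=2.0)]
            )


class TestFitMixedModel:
    def test_noiseless_constant_error_recovered_exactly(self):
        alphas = np.tile(np.arange(-150, 181, 30), 4)
        rows = []
        for i in range(4):
            rows.append(pd.DataFrame({
                "participant_id": f"p{i}", "direction_deg": alphas, "abs_error": 0.25,
            }))
        fit = da.fit_mixed_model(pd.concat(rows), "isotropy", n_starts=2)
        assert fit.fixed_estimates.intercept == pytest.approx(0.25, abs=1e-3)
        assert fit.residual_sd < 1e-3

    def test_recovers_generative_weights_on_one_cohort(self, upright_trials):
        fit = da.fit_mixed_model(upright_trials, "hv", seed=1)
        assert fit.converged
        assert fit.fixed_estimates.w_h == pytest.approx(0.36, abs=0.08)
        assert fit.fixed_estimates.w_v == pytest.approx(0.40, abs=0.08)
        assert fit.k == 4
        assert fit.n == len(upright_trials)

    def test_fbud_on_hv_data_shows_no_spurious_split(self, upright_trials):
        fit = da.fit_mixed_model(upright_trials, "fbud", seed=1)
        est = fit.fixed_estimates
        assert est.w_f == pytest.approx(est.w_b, abs=0.09)
        assert est.w_u == pytest.approx(est.w_d, abs=0.09)

    def test_optimum_beats_generative_truth(self, upright_trials):
        fit = da.fit_mixed_model(upright_trials, "hv", seed=1)
        ll_truth = da.marginal_loglik(
            upright_trials, hv(0.36, 0.40), 0.2, fit.residual_sd
        )
        assert fit.loglik >= ll_truth

    def test_unknown_variant_rejected(self, upright_trials):
        with pytest.raises(ValueError):
            da.fit_mixed_model(upright_trials, "radial")

    def test_single_participant_rejected(self, upright_trials):
        one = upright_trials[upright_trials["participant_id"] == "p00"]
        with pytest.raises(ValueError, match="participants"):
            da.fit_mixed_model(one, "hv")
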