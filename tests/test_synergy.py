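"""Median-effect fitting, combination index and isobologram analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import synscreen as ss
from synscreen.synergy import (
    MedianEffectModel,
    classify_ci,
    compute_ci,
    dose_for_fa,
    dose_for_fa_params,
    fa_for_dose,
    fit_median_effect,
    isobologram,
    single_agent_exceedance,
)


def noise_free_table(drug, dm, m, doses=(0.25, 0.5, 1, 2, 4)):
    return ss.simulate_dose_response(
        ss.DoseResponseSimParams(drug, dm, m, tuple(doses))
    )


class TestFitMedianEffect:
    @pytest.mark.parametrize("dm,m", [(1.0, 1.0), (2.0, 2.0), (0.3, 0.7)])
    def test_exact_recovery_noise_free(self, dm, m):
        fit = fit_median_effect(noise_free_table("d", dm, m), drug="d")
        assert fit.dm == pytest.approx(dm, abs=1e-9)
        assert fit.m == pytest.approx(m, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.monotone

    def test_two_point_hand_example(self):
        # (D=1, fa=0.5) -> logit 0; (D=10, fa=10/11) -> logit 1; slope 1, Dm 1
        records = pd.DataFrame({"dose": [1.0, 10.0], "fa": [0.5, 10 / 11]})
        fit = fit_median_effect(records, drug="x")
        assert fit.m == pytest.approx(1.0, abs=1e-12)
        assert fit.dm == pytest.approx(1.0, abs=1e-12)

    def test_boundary_fa_excluded_with_warning(self):
        records = pd.DataFrame(
            {"dose": [0.25, 0.5, 1, 2, 4], "fa": [0.0, 1 / 3, 0.5, 2 / 3, 1.0]}
        )
        with pytest.warns(UserWarning, match="excluded 2"):
            fit = fit_median_effect(records, drug="x")
        assert fit.n_points == 3
        assert fit.dm == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_median_effect(pd.DataFrame({"dose": [1.0, 2.0], "fa": [0.0, 0.5]}))

    def test_non_monotone_flagged(self):
        records = pd.DataFrame({"dose": [1, 2, 4], "fa": [0.8, 0.5, 0.2]})
        with pytest.warns(UserWarning, match="non-monotone"):
            fit = fit_median_effect(records, drug="x")
        assert not fit.monotone
        with pytest.raises(ValueError, match="non-monotone"):
            dose_for_fa(fit, 0.5)

    def test_noise_rmse_decreases_with_n(self):
        rng_seeds = range(30)

        def rmse(n_doses):
            errs = []
            doses = tuple(np.geomspace(0.1, 10, n_doses))
            for seed in rng_seeds:
                tab = ss.simulate_dose_response(
                    ss.DoseResponseSimParams("d", 1.0, 1.0, doses, noise_sd=0.2, seed=seed)
                )
                fit = fit_median_effect(tab)
                errs.append((np.log(fit.dm)) ** 2 + (fit.m - 1.0) ** 2)
            return np.sqrt(np.mean(errs))

        assert rmse(24) < rmse(4)

    def test_estimator_interface(self):
        tab = noise_free_table("d", 1.0, 1.0)
        model = MedianEffectModel(drug="d").fit(tab["dose"], tab["fa"])
        assert model.get_params() == {"drug": "d"}
        np.testing.assert_allclose(model.predict([1.0, 4.0]), [0.5, 0.8], atol=1e-9)
        assert model.dose_for_fa(0.5) == pytest.approx(1.0, abs=1e-9)


class TestDoseForFa:
    def test_median_dose_for_half_effect(self):
        for m in (0.5, 1.0, 3.0):
            assert dose_for_fa_params(2.5, m, 0.5) == pytest.approx(2.5)

    @pytest.mark.parametrize("m,fa,expect", [(1, 0.8, 4.0), (2, 0.8, 2.0)])
    def test_hand_values(self, m, fa, expect):
        assert dose_for_fa_params(1.0, m, fa) == pytest.approx(expect, abs=1e-12)

    def test_inversion_identity_over_grid(self):
        fa_grid = np.linspace(0.01, 0.99, 99)
        for dm, m in [(1.0, 1.0), (2.0, 2.0), (0.5, 3.0)]:
            doses = np.array([dose_for_fa_params(dm, m, fa) for fa in fa_grid])
            np.testing.assert_allclose(fa_for_dose(dm, m, doses), fa_grid, atol=1e-9)

    def test_monotone_in_fa(self):
        doses = [dose_for_fa_params(1.0, 1.7, fa) for fa in np.linspace(0.05, 0.95, 19)]
        assert (np.diff(doses) > 0).all()

    def test_boundary_fa_rejected(self):
        with pytest.raises(ValueError):
            dose_for_fa_params(1.0, 1.0, 1.0)


class TestComputeCI:
    def test_single_point_additive(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 1.0), drug="a")
        f2 = fit_median_effect(noise_free_table("b", 2.0, 1.0), drug="b")
        combo = pd.DataFrame({"d1": [0.5], "d2": [1.0], "fa": [0.5]})
        (res,) = compute_ci(f1, f2, combo)
        assert res.dx1 == pytest.approx(1.0, abs=1e-9)
        assert res.dx2 == pytest.approx(2.0, abs=1e-9)
        assert res.ci == pytest.approx(1.0, abs=1e-9)
        assert res.classification == "additive"

    def test_single_point_synergy(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 1.0), drug="a")
        f2 = fit_median_effect(noise_free_table("b", 2.0, 1.0), drug="b")
        combo = pd.DataFrame({"d1": [1.0], "d2": [2.0], "fa": [0.8]})
        (res,) = compute_ci(f1, f2, combo)
        assert res.ci == pytest.approx(0.5, abs=1e-9)
        assert res.classification == "synergy"

    @settings(max_examples=60, deadline=None)
    @given(
        dm=st.floats(0.1, 10), m=st.floats(0.3, 4),
        kappa=st.floats(0.01, 0.99), fa=st.floats(0.05, 0.95),
    )
    def test_sham_self_combination_is_additive(self, dm, m, kappa, fa):
        # a drug combined with itself at any dose split has CI exactly 1
        fit = fit_median_effect(noise_free_table("d", dm, m), drug="d")
        dx = dose_for_fa(fit, fa)
        combo = pd.DataFrame({"d1": [kappa * dx], "d2": [(1 - kappa) * dx], "fa": [fa]})
        (res,) = compute_ci(fit, fit, combo)
        assert res.ci == pytest.approx(1.0, abs=1e-9)

    def test_fixed_ratio_total_dose_input(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 1.0), drug="a")
        combo = pd.DataFrame({"dose": [1.0], "fa": [0.5]})
        (res,) = compute_ci(f1, f1, combo, ratio=1.0)
        assert res.d1 == pytest.approx(0.5)
        assert res.ci == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_interaction(self):
        doses = (0.25, 0.5, 1, 2, 4)
        p1 = ss.DoseResponseSimParams("a", 1.0, 1.0, doses)
        p2 = ss.DoseResponseSimParams("b", 3.0, 2.0, doses)
        f1 = fit_median_effect(ss.simulate_dose_response(p1), drug="a")
        f2 = fit_median_effect(ss.simulate_dose_response(p2), drug="b")
        for alpha in (0.5, 1.0, 2.0):
            combo = ss.simulate_combination(
                ss.ComboSimParams(p1, p2, ratio=1.0, interaction=alpha)
            )
            for res in compute_ci(f1, f2, combo):
                assert res.ci == pytest.approx(alpha, abs=1e-9)

    def test_recovers_interaction_under_noise(self):
        doses = tuple(np.geomspace(0.1, 10, 8))
        p1 = ss.DoseResponseSimParams("a", 1.0, 1.0, doses)
        p2 = ss.DoseResponseSimParams("b", 2.0, 1.5, doses)
        f1 = fit_median_effect(ss.simulate_dose_response(p1), drug="a")
        f2 = fit_median_effect(ss.simulate_dose_response(p2), drug="b")
        combo = ss.simulate_combination(
            ss.ComboSimParams(p1, p2, ratio=1.0, interaction=0.5, noise_sd=0.05, seed=21)
        )
        cis = [r.ci for r in compute_ci(f1, f2, combo)]
        assert np.mean(cis) == pytest.approx(0.5, abs=0.05)

    def test_boundary_fa_skipped_with_warning(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 1.0), drug="a")
        combo = pd.DataFrame({"d1": [0.5, 0.5], "d2": [0.5, 0.5], "fa": [1.0, 0.5]})
        with pytest.warns(UserWarning, match="skipping"):
            res = compute_ci(f1, f1, combo)
        assert len(res) == 1


class TestClassification:
    @pytest.mark.parametrize(
        "ci,label",
        [(0.5, "synergy"), (0.949, "synergy"), (0.96, "additive"), (1.0, "additive"),
         (1.04, "additive"), (1.06, "antagonism"), (2.0, "antagonism")],
    )
    def test_tolerance_band(self, ci, label):
        assert classify_ci(ci) == label


class TestIsobologram:
    def test_intercepts_and_flags(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 1.0), drug="a")
        f2 = fit_median_effect(noise_free_table("b", 2.0, 1.0), drug="b")
        points = pd.DataFrame(
            {"d1": [0.5, 0.25, 1.0], "d2": [1.0, 0.5, 2.0]}  # CI 1, 0.5, 2 at fa=0.5
        )
        iso = isobologram(f1, f2, 0.5, points)
        assert iso["intercepts"][0][0] == pytest.approx(1.0, abs=1e-9)
        assert iso["intercepts"][1][1] == pytest.approx(2.0, abs=1e-9)
        assert [p["flag"] for p in iso["points"]] == ["on", "below", "above"]

    def test_flags_consistent_with_ci(self):
        f1 = fit_median_effect(noise_free_table("a", 1.0, 2.0), drug="a")
        f2 = fit_median_effect(noise_free_table("b", 0.5, 1.0), drug="b")
        combo = pd.DataFrame({"d1": [0.3], "d2": [0.1], "fa": [0.6]})
        (res,) = compute_ci(f1, f2, combo)
        iso = isobologram(f1, f2, 0.6, combo[["d1", "d2"]])
        flag = iso["points"][0]["flag"]
        expected = {"synergy": "below", "additive": "on", "antagonism": "above"}
        assert flag == expected[res.classification]


class TestSingleAgentExceedance:
    @pytest.mark.parametrize(
        "combo,f1,f2,expect",
        [(0.92, 0.30, 0.10, 0.62), (0.6, 0.6, 0.2, 0.0), (0.5, 0.6, 0.2, -0.1)],
    )
    def test_hand_values(self, combo, f1, f2, expect):
        assert single_agent_exceedance(combo, f1, f2) == pytest.approx(expect)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            single_agent_exceedance(1.2, 0.5, 0.5)
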