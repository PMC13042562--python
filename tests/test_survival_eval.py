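"""KM, log-rank, Cox, frailty, concordance, time-dependent AUC, heterogeneity."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathomil import (
    CohortSpec,
    StratificationError,
    cox_fit,
    cox_score_test,
    gen_cohort,
    harrells_c,
    heterogeneity_meta,
    km_estimate,
    logrank_test,
    mixed_effects_cox,
    optimal_cutoff,
    subgroup_analysis,
    time_dependent_auc,
)
from conftest import outcome_arrays


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_fraction(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        km = km_estimate((t, np.ones(4, int)))
        for x, frac in [(1.0, 1.0), (2.0, 0.75), (5.0, 0.5), (9.0, 0.0)]:
            assert km.at(x) == pytest.approx(frac)

    def test_hand_product(self):
        km = km_estimate((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])))
        assert km.at(2.0) == pytest.approx(1 / 3)  # (2/3)*(1/2)

    def test_monotone_from_one(self):
        rng = np.random.default_rng(0)
        km = km_estimate((rng.exponential(10, 50), rng.integers(0, 2, 50)))
        assert km.at(0.0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate((np.array([5.0, 10.0]), np.array([0, 0])))
        assert km.at(100.0) == 1.0
        assert not km.median_reached

    def test_median_definition(self):
        km = km_estimate((np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int)))
        assert km.median == 2.0  # smallest t with S(t) <= 0.5


class TestLogRank:
    def test_identical_groups_give_zero(self):
        g = (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))
        chi2, p = logrank_test({"a": g, "b": g})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_risk_table(self):
        # group A: events at 1, 3; censored 5.  group B: events at 2, 6; censored 4.
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 6.0, 4.0]), np.array([1, 1, 0])
        chi2, _ = logrank_test({"A": (ta, ea), "B": (tb, eb)})
        # brute-force risk table over distinct event times
        t_all = np.concatenate([ta, tb])
        e_all = np.concatenate([ea, eb])
        grp = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e, var = 0.0, 0.0
        for t in sorted(t_all[e_all == 1]):
            at_risk = t_all >= t
            n, n0 = at_risk.sum(), (at_risk & (grp == 0)).sum()
            d = ((t_all == t) & (e_all == 1)).sum()
            d0 = ((t_all == t) & (e_all == 1) & (grp == 0)).sum()
            o_minus_e += d0 - d * n0 / n
            if n > 1:
                var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(1)
        a = (rng.exponential(10, 30), rng.integers(0, 2, 30))
        b = (rng.exponential(20, 30), rng.integers(0, 2, 30))
        assert logrank_test({"a": a, "b": b})[0] == pytest.approx(
            logrank_test({"a": b, "b": a})[0]
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test({"a": (np.ones(3), np.ones(3, int))})


class TestOptimalCutoff:
    def test_separated_toy_example(self):
        scores = np.array([1, 1, 1, 10, 10, 10], float)
        t = np.array([3.0, 4.0, 6.0, 60.0, 60.0, 60.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        strat = optimal_cutoff(scores, (t, e))
        assert 1 < strat.cutoff < 10
        assert strat.high_risk_side == "below"
        assert (strat.groups[:3] == "high").all() and (strat.groups[3:] == "low").all()

    def test_constant_scores_rejected(self):
        with pytest.raises(StratificationError):
            optimal_cutoff(np.ones(6), (np.arange(1.0, 7.0), np.ones(6, int)))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        scores = rng.normal(size=n)
        t = np.exp(2 - scores + rng.normal(0, 1, n))
        e = rng.integers(0, 2, n)
        e[:10] = 1
        strat = optimal_cutoff(scores, (t, e), min_group_frac=0.10)
        # independent brute force over every candidate midpoint
        uniq = np.unique(scores)
        best_chi, best_cut = -np.inf, None
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            mask = scores <= cut
            if mask.sum() < 5 or (~mask).sum() < 5:
                continue
            chi, _ = logrank_test({"lo": (t[mask], e[mask]), "hi": (t[~mask], e[~mask])})
            if chi > best_chi + 1e-12:
                best_chi, best_cut = chi, cut
        assert strat.cutoff == pytest.approx(best_cut)
        assert strat.chi2 == pytest.approx(best_chi)

    def test_chi2_consistent_with_logrank_of_own_groups(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        t = np.exp(1.5 - scores + rng.normal(0, 1, 40))
        e = np.ones(40, int)
        strat = optimal_cutoff(scores, (t, e))
        hi = strat.groups == "high"
        chi2, _ = logrank_test({"h": (t[hi], e[hi]), "l": (t[~hi], e[~hi])})
        assert strat.chi2 == pytest.approx(chi2)


class TestCoxFit:
    def test_matches_independent_newton_on_five_patients(self):
        t = np.array([2.0, 3.0, 5.0, 7.0, 11.0])
        e = np.array([1, 0, 1, 1, 1])
        x = np.array([[0.5], [1.2], [-0.3], [0.8], [-1.0]])
        fit = cox_fit((t, e), pd.DataFrame({"x": x[:, 0]}))

        # independent Newton-Raphson written straight from the Breslow formulas
        def derivs(b):
            ll = g = h = 0.0
            for i in np.flatnonzero(e == 1):
                risk = t >= t[i]
                w = np.exp(b * x[risk, 0])
                s0, s1, s2 = w.sum(), (w * x[risk, 0]).sum(), (w * x[risk, 0] ** 2).sum()
                ll += b * x[i, 0] - np.log(s0)
                g += x[i, 0] - s1 / s0
                h += s2 / s0 - (s1 / s0) ** 2
            return ll, g, h

        b = 0.0
        for _ in range(50):
            _, g, h = derivs(b)
            b += g / h
        assert fit.loc["x", "coef"] == pytest.approx(b, abs=1e-8)
        _, _, h = derivs(b)
        assert fit.loc["x", "se"] == pytest.approx(1 / np.sqrt(h), abs=1e-8)

    def test_score_test_equals_logrank_for_binary_split(self):
        rng = np.random.default_rng(2)
        n = 80
        g = rng.integers(0, 2, n)
        t = np.exp(2 - 0.8 * g + rng.normal(0, 1, n))
        e = rng.integers(0, 2, n)
        e[:30] = 1
        chi2, _ = logrank_test({"a": (t[g == 0], e[g == 0]), "b": (t[g == 1], e[g == 1])})
        assert cox_score_test((t, e), g.astype(float)) == pytest.approx(chi2, rel=1e-10)

    def test_chemo_effect_ci_coverage_in_high_risk_half(self):
        hits = 0
        for seed in range(20):
            cohort = gen_cohort(
                CohortSpec(n_patients=600, patches_per_patient=1, risk_effect_theta=1.0,
                           chemo_benefit_high=-0.6, censor_rate=0.3, seed=seed)
            )
            t, e = outcome_arrays(cohort.bags)
            chemo = np.array([b.covariates["chemo"] for b in cohort.bags], float)
            hi = np.array([b.covariates["latent_high"] for b in cohort.bags], bool)
            fit = cox_fit((t[hi], e[hi]), pd.DataFrame({"chemo": chemo[hi]}))
            hits += fit.loc["chemo", "ci_low"] <= np.exp(-0.6) <= fit.loc["chemo", "ci_high"]
        assert hits >= 18  # >= 90% of 20 seeds

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit((np.arange(1.0, 5.0), np.array([1, 0, 0, 0])),
                    pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]}))


class TestMixedEffectsCox:
    def test_null_frailty_variance_near_zero(self):
        ests = []
        for seed in range(10):
            cohort = gen_cohort(
                CohortSpec(n_patients=600, patches_per_patient=1, risk_effect_theta=1.0,
                           n_centers=12, center_sd=0.0, censor_rate=0.3, seed=seed)
            )
            res = mixed_effects_cox(
                outcome_arrays(cohort.bags),
                pd.DataFrame({"risk": cohort.latent_risk}),
                [b.covariates["center"] for b in cohort.bags],
            )
            ests.append(res.random_effect_variance)
        assert np.mean(ests) < 0.05

    def test_frailty_variance_recovery(self):
        ests = []
        for seed in range(10):
            cohort = gen_cohort(
                CohortSpec(n_patients=600, patches_per_patient=1, risk_effect_theta=1.0,
                           n_centers=12, center_sd=0.5, censor_rate=0.3, seed=seed)
            )
            res = mixed_effects_cox(
                outcome_arrays(cohort.bags),
                pd.DataFrame({"risk": cohort.latent_risk}),
                [b.covariates["center"] for b in cohort.bags],
            )
            ests.append(res.random_effect_variance)
        assert 0.1 <= np.mean(ests) <= 0.6  # truth 0.25

    def test_fixed_effect_direction_agrees_with_plain_cox(self):
        cohort = gen_cohort(
            CohortSpec(n_patients=300, patches_per_patient=1, risk_effect_theta=1.0,
                       n_centers=5, center_sd=0.4, censor_rate=0.3, seed=3)
        )
        out = outcome_arrays(cohort.bags)
        x = pd.DataFrame({"risk": cohort.latent_risk})
        centers = [b.covariates["center"] for b in cohort.bags]
        mixed = mixed_effects_cox(out, x, centers)
        plain = cox_fit(out, x)
        assert np.sign(mixed.summary.loc["risk", "coef"]) == np.sign(plain.loc["risk", "coef"])

    def test_single_center_falls_back_with_warning(self):
        cohort = gen_cohort(CohortSpec(n_patients=100, patches_per_patient=1, seed=5))
        with pytest.warns(UserWarning, match="single center"):
            res = mixed_effects_cox(
                outcome_arrays(cohort.bags),
                pd.DataFrame({"risk": cohort.latent_risk}),
                np.zeros(100, int),
            )
        assert res.random_effect_variance == 0.0


class TestHarrellsC:
    def test_perfect_ordering(self):
        t = np.array([10.0, 8.0, 6.0, 4.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrells_c(risk, (t, np.ones(4, int))) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(20, 1000)
        e = np.ones(1000, int)
        assert 0.47 <= harrells_c(rng.normal(size=1000), (t, e)) <= 0.53

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        n = 200
        risk = np.round(rng.normal(size=n), 1)  # ties in score
        t = rng.exponential(20, n)
        e = rng.integers(0, 2, n)
        e[:50] = 1
        c = harrells_c(risk, (t, e))
        conc = ties = usable = 0.0
        for i in range(n):
            for j in range(n):
                if i == j or e[i] != 1 or t[i] >= t[j]:
                    continue  # i must be the earlier, observed event
                usable += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
        assert c == pytest.approx((conc + 0.5 * ties) / usable, abs=1e-12)

    def test_negation_flips_concordance(self):
        rng = np.random.default_rng(8)
        risk = rng.normal(size=60)  # continuous: no ties
        t = rng.exponential(10, 60)
        e = np.ones(60, int)
        assert harrells_c(-risk, (t, e)) == pytest.approx(1.0 - harrells_c(risk, (t, e)))


class TestTimeDependentAUC:
    def test_perfect_separation_no_censoring(self):
        n = 100
        risk = np.arange(n, dtype=float)
        t = 100.0 - risk  # higher risk fails strictly earlier
        auc = time_dependent_auc(risk, (t, np.ones(n, int)), [20.0, 50.0])
        assert auc[20.0] == pytest.approx(1.0)
        assert auc[50.0] == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        n = 1000
        risk = rng.normal(size=n)
        t = rng.exponential(20, n)
        auc = time_dependent_auc(risk, (t, np.ones(n, int)), [15.0])
        assert 0.45 <= auc[15.0] <= 0.55

    def test_no_censoring_reduces_to_binary_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        n = 300
        risk = rng.normal(size=n)
        t = np.exp(2 - risk + rng.normal(0, 0.5, n))
        for hz in (5.0, 10.0):
            auc = time_dependent_auc(risk, (t, np.ones(n, int)), [hz])[hz]
            assert auc == pytest.approx(roc_auc_score(t <= hz, risk), abs=1e-10)

    def test_horizon_beyond_followup_is_missing(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 50)
        auc = time_dependent_auc(rng.normal(size=50), (t, np.ones(50, int)), [1e6])
        assert np.isnan(auc[1e6])


class TestHeterogeneity:
    def test_identical_effects(self):
        res = heterogeneity_meta([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert res.Q == pytest.approx(0.0)
        assert res.I2 == 0.0

    def test_formula_arithmetic(self):
        # two effects 0 and 1 with se = 0.5: Q = 2 * (0.5)^2 / 0.25 = 2, df = 1 -> I2 = 50%
        res = heterogeneity_meta([0.0, 1.0], [0.5, 0.5])
        assert res.Q == pytest.approx(2.0)
        assert res.I2 == pytest.approx(50.0)

    def test_three_center_hand_example(self):
        res = heterogeneity_meta([0.2, 0.5, 0.8], [0.2, 0.2, 0.2])
        assert res.Q == pytest.approx(4.5)  # sum((theta - 0.5)^2) / 0.04
        assert res.I2 == pytest.approx((4.5 - 2) / 4.5 * 100)
        assert res.pooled_ci[0] < res.pooled_log_hr < res.pooled_ci[1]

    def test_single_center_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_meta([0.5], [0.1])


class TestSubgroupAnalysis:
    def test_interaction_pattern_recovered(self):
        hits = 0
        for seed in range(20):
            cohort = gen_cohort(
                CohortSpec(n_patients=800, patches_per_patient=1, risk_effect_theta=1.0,
                           ca199_assoc=0.5, ca199_effect_low=0.9, ca199_effect_high=0.0,
                           censor_rate=0.2, seed=seed)
            )
            t, e = outcome_arrays(cohort.bags)
            ca = np.array([b.covariates["ca199_group"] for b in cohort.bags], float)
            half = np.array(
                ["high" if b.covariates["latent_high"] else "low" for b in cohort.bags]
            )
            tab = subgroup_analysis((t, e), ca, half)
            hits += (
                tab.loc["low", "ci_low"] > 1.0
                and tab.loc["high", "ci_low"] <= 1.0 <= tab.loc["high", "ci_high"]
            )
        assert hits >= 16  # >= 80% of 20 seeds

    def test_constant_covariate_stratum_skipped(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        e = np.ones(40, int)
        cov = np.concatenate([np.zeros(20), rng.integers(0, 2, 20)])
        strata = np.repeat(["a", "b"], 20)
        with pytest.warns(UserWarning, match="constant"):
            tab = subgroup_analysis((t, e), cov, strata)
        assert "a" not in tab.index and "b" in tab.index

    def test_homogeneous_strata_match_marginal_fit(self):
        rng = np.random.default_rng(4)
        n = 600
        x = rng.integers(0, 2, n).astype(float)
        t = np.exp(2 - 0.7 * x + rng.normal(0, 0.8, n))
        e = np.ones(n, int)
        strata = np.repeat(["s1", "s2"], n // 2)
        tab = subgroup_analysis((t, e), x, strata)
        marginal = cox_fit((t, e), pd.DataFrame({"x": x})).loc["x", "HR"]
        for s in ("s1", "s2"):
            assert abs(tab.loc[s, "HR"] - marginal) / marginal < 0.10
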