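"""Generators: marginal laws, mixture structure, category truncation,
treatment response, determinism."""

import numpy as np
import pytest

from phenocut.classifier import classify_cohort, classify_index, reference_cutoffs
from phenocut.synthetic_cohorts import (
    CategoryModel,
    MixtureSpec,
    StressScenario,
    naive_mixture_spec,
    scenario_from_yaml,
    scenario_to_yaml,
    simulate_naive_marginal,
    simulate_naive_mixture,
    simulate_stressed_cohort,
    simulate_treatment_response,
    stress_scenario,
)


class TestNaiveMarginal:
    def test_beta_gamma_sample_means_match_analytic(self):
        cohort = simulate_naive_marginal(10_000, seed=1)
        spt = np.asarray(cohort.values("spt_rate"))
        fst = np.asarray(cohort.values("fst_immobility_s"))
        assert abs(spt.mean() - 2.53 / 3.61) < 0.01      # Beta mean a/(a+b)
        assert abs(fst.mean() - 2.29 / 0.0264) < 2.0     # Gamma mean shape/rate
        assert (spt >= 0).all() and (spt <= 1).all() and (fst >= 0).all()

    def test_same_seed_same_cohort(self):
        a = simulate_naive_marginal(50, seed=7)
        b = simulate_naive_marginal(50, seed=7)
        assert a.records == b.records

    @pytest.mark.parametrize("bad", [(-1.0, 1.08), (2.53, 0.0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_naive_marginal(10, beta_params=bad, seed=0)


class TestNaiveMixture:
    def test_single_class_reduces_to_gaussian_sampling(self):
        spec = MixtureSpec(
            weights=[1.0], means=[(0.6, 100.0)], variances=(0.01, 400.0)
        )
        cohort, labels = simulate_naive_mixture(20_000, spec, seed=2)
        assert set(labels) == {0}
        spt = np.asarray(cohort.values("spt_rate"))
        fst = np.asarray(cohort.values("fst_immobility_s"))
        assert abs(spt.mean() - 0.6) < 0.005
        assert abs(fst.mean() - 100.0) < 0.5
        assert abs(fst.std() - 20.0) < 0.5

    def test_published_class_weights_recovered_in_counts(self):
        # class 1 holds 44/309 of the naive population; a draw of n=309
        # should land within ~4 binomial SDs of 44
        spec = naive_mixture_spec()
        _, labels = simulate_naive_mixture(309, spec, seed=3)
        count1 = int((labels == 0).sum())
        sd = np.sqrt(309 * (44 / 309) * (1 - 44 / 309))
        assert abs(count1 - 44) < 4 * sd

    def test_per_class_means_match_spec_at_large_n(self):
        spec = MixtureSpec(
            weights=[0.3, 0.7],
            means=[(0.3, 200.0), (0.8, 60.0)],
            variances=[(0.0025, 100.0), (0.0025, 100.0)],
        )
        cohort, labels = simulate_naive_mixture(50_000, spec, seed=4)
        spt = np.asarray(cohort.values("spt_rate"))
        fst = np.asarray(cohort.values("fst_immobility_s"))
        for k, (m_spt, m_fst) in enumerate(spec.means):
            sel = labels == k
            assert abs(spt[sel].mean() - m_spt) / m_spt < 0.005
            assert abs(fst[sel].mean() - m_fst) / m_fst < 0.005

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(weights=[0.5, 0.6], means=[(0, 0), (1, 1)],
                        variances=(1.0, 1.0))
        with pytest.raises(ValueError):
            MixtureSpec(weights=[1.0], means=[(0, 0)], variances=(0.0, 1.0))


class TestStressedCohort:
    def test_affected_fraction_matches_scenario(self):
        scenario = stress_scenario("MD+CUS", n=9_900)
        cohort = simulate_stressed_cohort(scenario, seed=5)
        calls = classify_cohort(cohort, scenario.cutoffs)
        frac = np.mean(
            [c.categories["spt_rate"] == "affected" for c in calls.calls]
        )
        assert abs(frac - 75 / 99) < 0.011

    def test_degenerate_probabilities_yield_all_affected(self):
        scenario = stress_scenario("CUS", n=50)
        for cat, m in scenario.anhedonia.items():
            m.prob = 1.0 if cat == "affected" else 0.0
        cohort = simulate_stressed_cohort(scenario, seed=6)
        calls = classify_cohort(cohort, scenario.cutoffs)
        assert all(c.categories["spt_rate"] == "affected" for c in calls.calls)

    def test_reclassification_reproduces_sampled_categories_exactly(self):
        # truncation to the category interval makes the loop closed at 100%
        for group in ("NOR", "MD", "CUS", "MD+CUS"):
            scenario = stress_scenario(group, n=400)
            cohort = simulate_stressed_cohort(scenario, seed=7)
            calls = classify_cohort(cohort, scenario.cutoffs)
            assert not calls.excluded
            for index in ("spt_rate", "fst_immobility_s"):
                for rec, call in zip(cohort, calls.calls):
                    assert call.categories[index] == classify_index(
                        getattr(rec, index), scenario.cutoffs[index]
                    )

    def test_conditional_mean_outside_interval_rejected(self):
        scenario = stress_scenario("MD")
        with pytest.raises(ValueError, match="outside"):
            StressScenario(
                group="MD",
                n=10,
                anhedonia={
                    # mean 0.5 is on the resilient side of the 0.28 cutoff
                    "affected": CategoryModel(prob=0.3, mean=0.5, sd=0.05),
                    "sub": CategoryModel(prob=0.2, mean=0.35, sd=0.05),
                    "resilient": CategoryModel(prob=0.5, mean=0.7, sd=0.1),
                },
                despair=scenario.despair,
            )

    def test_scenario_yaml_round_trip(self):
        scenario = stress_scenario("CUS")
        back = scenario_from_yaml(scenario_to_yaml(scenario))
        assert back == scenario


class TestTreatmentResponse:
    @staticmethod
    def _treated_setup(group, n, seed):
        scenario = stress_scenario(group, n=n)
        cohort = simulate_stressed_cohort(scenario, seed=seed)
        calls = classify_cohort(cohort, scenario.cutoffs)
        return scenario, cohort, calls.calls

    def test_certain_recovery_crosses_the_criterion(self):
        scenario, cohort, calls = self._treated_setup("CUS", 200, 8)
        for m in list(scenario.anhedonia.values()) + list(scenario.despair.values()):
            m.recovery_prob = 1.0
        treated = simulate_treatment_response(cohort, calls, scenario, seed=9)
        cutoffs = scenario.cutoffs
        for rec, call in zip(treated, calls):
            if call.categories["spt_rate"] != "resilient":
                assert rec.post_spt_rate > cutoffs["spt_rate"].mild_cutoff
            if call.categories["fst_immobility_s"] != "resilient":
                assert (
                    rec.post_fst_immobility_s
                    < cutoffs["fst_immobility_s"].mild_cutoff
                )

    def test_zero_recovery_probability_yields_no_recoveries(self):
        from phenocut.classifier import classify_recovery

        scenario, cohort, calls = self._treated_setup("MD", 150, 10)
        for m in list(scenario.anhedonia.values()) + list(scenario.despair.values()):
            m.recovery_prob = 0.0
        treated = simulate_treatment_response(cohort, calls, scenario, seed=11)
        for rec, call in zip(treated, calls):
            if rec.arm != "escitalopram":
                continue
            statuses = classify_recovery(
                call, rec.post_spt_rate, rec.post_fst_immobility_s,
                scenario.cutoffs,
            )
            assert set(statuses.values()) <= {"treatment_resilient"}

    def test_recovered_fraction_tracks_category_probability(self):
        # CUS anhedonia-affected recovery probability is 21/50 = 0.42
        from phenocut.classifier import classify_recovery

        scenario = stress_scenario("CUS", n=12_000)
        # force everyone into the anhedonia-affected category
        for cat, m in scenario.anhedonia.items():
            m.prob = 1.0 if cat == "affected" else 0.0
        cohort = simulate_stressed_cohort(scenario, seed=12)
        calls = classify_cohort(cohort, scenario.cutoffs).calls
        treated = simulate_treatment_response(cohort, calls, scenario, seed=13)
        outcomes = []
        for rec, call in zip(treated, calls):
            status = classify_recovery(
                call, rec.post_spt_rate, rec.post_fst_immobility_s,
                scenario.cutoffs,
            )
            outcomes.append(status["spt_rate"] == "recovered")
        assert abs(np.mean(outcomes) - 0.42) < 0.02

    def test_missing_call_is_contract_error(self):
        scenario, cohort, calls = self._treated_setup("MD", 20, 14)
        with pytest.raises(ValueError, match="no phenotype call"):
            simulate_treatment_response(cohort, calls[:-1], scenario, seed=15)
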