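"""Bayesian models vs closed-form oracles, parameter recovery, priors."""

import numpy as np
import pytest

from metd.compare import kde_mode
from metd.datagen import CohortConfig, GroupConfig, generate_cohort
from metd.models import (ChangeScoreAncova, InterceptOnlyModel, McmcConfig,
                         NestedMetaModel, PriorSpec, conjugate_oracle,
                         prior_from_posterior, prior_from_summary)


class TestConjugateOracle:
    def test_zero_sample(self):
        assert conjugate_oracle([0, 0, 0, 0]).location == 0.0

    def test_location_is_sample_mean(self):
        post = conjugate_oracle([1, 2, 3])
        assert post.location == 2.0
        assert post.scale == pytest.approx(1.0 / np.sqrt(3))
        assert post.df == 2

    def test_moment_matched_survey_recovers_published_mean(self, survey_frame):
        vals = survey_frame.loc[survey_frame.outcome == "Total", "value_kg"]
        post = conjugate_oracle(vals)
        assert post.location == pytest.approx(17.5, abs=1e-9)
        assert post.scale == pytest.approx(12.1 / np.sqrt(137), abs=1e-9)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            conjugate_oracle([5.0])

    def test_hdi_is_symmetric_student_t(self):
        post = conjugate_oracle(np.arange(20.0))
        lo, hi = post.hdi(0.95)
        assert (lo + hi) / 2 == pytest.approx(post.location)
        assert hi > post.location


class TestPriorConstruction:
    def test_prior_from_summary_identity(self):
        prior = prior_from_summary(10.0, 5.0)
        assert (prior.family, prior.location, prior.scale) == ("normal", 10.0,
                                                               5.0)

    def test_prior_from_summary_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            prior_from_summary(10.0, 0.0)

    def test_prior_from_posterior_uses_draw_moments(self, rng):
        draws = rng.standard_normal(4000)
        prior = prior_from_posterior(draws)
        assert prior.location == pytest.approx(0.0, abs=0.05)
        assert prior.scale == pytest.approx(1.0, abs=0.05)

    def test_prior_from_constant_draws_gets_floor_scale(self):
        prior = prior_from_posterior(np.full(200, 3.0))
        assert prior.location == 3.0
        assert 0 < prior.scale <= 1e-6

    def test_prior_from_posterior_needs_draws(self):
        with pytest.raises(ValueError):
            prior_from_posterior(np.ones(50))


class TestInterceptOnlyModel:
    def test_degenerate_data_concentrates_at_constant(self, fast_mcmc):
        res = InterceptOnlyModel(np.full(137, 17.5)).fit(fast_mcmc)
        assert kde_mode(res.intercept_draws) == pytest.approx(17.5, abs=0.1)

    def test_posterior_matches_conjugate_oracle_on_survey(self, survey_frame,
                                                          fast_mcmc):
        model = InterceptOnlyModel.from_dataframe(survey_frame, "Total")
        res = model.fit(fast_mcmc)
        oracle = conjugate_oracle(
            survey_frame.loc[survey_frame.outcome == "Total", "value_kg"])
        d = res.intercept_draws
        ess = res.diagnostics["beta[0]"]["ess_bulk"]
        mcse = 3 * d.std(ddof=1) / np.sqrt(ess)
        assert abs(d.mean() - oracle.location) < mcse

    def test_hand_sized_input_matches_oracle(self, fast_mcmc):
        res = InterceptOnlyModel([10, 15, 20, 25]).fit(fast_mcmc)
        d = res.intercept_draws
        ess = res.diagnostics["beta[0]"]["ess_bulk"]
        assert abs(d.mean() - 17.5) < 3 * d.std(ddof=1) / np.sqrt(ess)

    def test_mcmc_agrees_with_oracle_across_random_datasets(self, rng,
                                                            fast_mcmc):
        """Posterior mean/SD within 3 Monte-Carlo SEs on 20 random samples."""
        for i in range(20):
            n = int(rng.integers(10, 120))
            y = rng.normal(rng.uniform(-20, 40), rng.uniform(1, 20), size=n)
            res = InterceptOnlyModel(y).fit(
                McmcConfig(chains=4, warmup=300, draws=400, seed=100 + i))
            oracle = conjugate_oracle(y)
            d = res.intercept_draws
            ess = res.diagnostics["beta[0]"]["ess_bulk"]
            mcse = d.std(ddof=1) / np.sqrt(ess)
            # oracle is Student-t: slight heavy-tail slack on the SD check
            assert abs(d.mean() - oracle.location) < 3 * mcse + 0.05
            assert d.std(ddof=1) == pytest.approx(oracle.sd, rel=0.15)

    def test_retained_draw_count_is_chains_times_draws(self, survey_frame):
        mcmc = McmcConfig(chains=4, warmup=150, draws=250, seed=1)
        res = InterceptOnlyModel.from_dataframe(survey_frame, "Total").fit(mcmc)
        assert res.intercept_draws.size == 1000

    def test_rope_accessor_tags_source(self, survey_frame, fast_mcmc):
        res = InterceptOnlyModel.from_dataframe(survey_frame, "Total").fit(
            fast_mcmc)
        rope = res.rope()
        assert rope.source == "subjective"
        assert rope.draws.size == fast_mcmc.total_draws

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            InterceptOnlyModel([17.5])

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(chains=1)
        with pytest.raises(ValueError):
            McmcConfig(warmup=50)


class TestChangeScoreAncova:
    def test_recovers_separated_group_means(self, two_arm_cohort, fast_mcmc):
        res = ChangeScoreAncova(two_arm_cohort, "Total").fit(fast_mcmc)
        emm = res.emm_draws
        assert kde_mode(emm["MAX"]) == pytest.approx(10.0, abs=1.0)
        assert kde_mode(emm["MAX_BOFF"]) == pytest.approx(30.0, abs=1.0)

    def test_zero_noise_pins_slope_and_emms(self, fast_mcmc):
        cfg = CohortConfig(groups=(
            GroupConfig(label="A", n=10, true_change={"SQ": 3, "BP": 3,
                                                      "DL": 4},
                        change_sd={"SQ": 0, "BP": 0, "DL": 0}),
            GroupConfig(label="B", n=10, true_change={"SQ": 10, "BP": 10,
                                                      "DL": 10},
                        change_sd={"SQ": 0, "BP": 0, "DL": 0})), seed=3)
        res = ChangeScoreAncova(generate_cohort(cfg), "Total").fit(fast_mcmc)
        assert abs(res.draws("pre_slope").mean()) < 0.01
        assert res.emm_draws["A"].mean() == pytest.approx(10.0, abs=0.5)
        assert res.emm_draws["B"].mean() == pytest.approx(30.0, abs=0.5)

    def test_emm_contrast_identity(self, two_arm_cohort, fast_mcmc):
        """EMM(other) - EMM(reference) draws equal the contrast draws."""
        res = ChangeScoreAncova(two_arm_cohort, "Total").fit(fast_mcmc)
        emm = res.emm_draws
        np.testing.assert_allclose(emm["MAX_BOFF"] - emm["MAX"],
                                   res.contrast_draws("MAX_BOFF"))

    def test_informed_prior_influence_vanishes_with_n(self):
        """The informed prior pulls the EMM at n=10 but not at n=400."""
        prior = PriorSpec(family="normal", location=0.0, scale=3.0)
        shifts = []
        for n, seed in ((10, 31), (100, 32), (1000, 33)):
            cfg = CohortConfig(groups=(
                GroupConfig(label="A", n=n,
                            true_change={"SQ": 10, "BP": 10, "DL": 10},
                            change_sd={"SQ": 6, "BP": 5, "DL": 7}),
                GroupConfig(label="B", n=n,
                            true_change={"SQ": 3, "BP": 3, "DL": 4},
                            change_sd={"SQ": 6, "BP": 5, "DL": 7})),
                seed=seed)
            cohort = generate_cohort(cfg)
            mcmc = McmcConfig(chains=4, warmup=300, draws=400, seed=seed)
            informed = ChangeScoreAncova(cohort, "Total",
                                         prior=prior).fit(mcmc)
            default = ChangeScoreAncova(cohort, "Total").fit(mcmc)
            shifts.append(abs(informed.emm_draws["A"].mean()
                              - default.emm_draws["A"].mean()))
        assert shifts[0] > shifts[-1]
        assert shifts[-1] < 0.5

    def test_participant_intercept_variant_matches_default(self,
                                                           two_arm_cohort):
        """With one observation per athlete the u0i variant is exchangeable
        with the residual: EMM modes agree within MCMC error."""
        mcmc = McmcConfig(chains=4, warmup=300, draws=400, seed=9)
        plain = ChangeScoreAncova(two_arm_cohort, "Total").fit(mcmc)
        nested = ChangeScoreAncova(two_arm_cohort, "Total",
                                   include_participant=True).fit(mcmc)
        for g in ("MAX", "MAX_BOFF"):
            assert kde_mode(plain.emm_draws[g]) == pytest.approx(
                kde_mode(nested.emm_draws[g]), abs=0.5)

    def test_single_group_rejected(self, two_arm_cohort):
        scores = two_arm_cohort.scores
        with pytest.raises(ValueError):
            ChangeScoreAncova(scores[scores.group == "MAX"], "Total")

    def test_unknown_reference_rejected(self, two_arm_cohort):
        with pytest.raises(ValueError):
            ChangeScoreAncova(two_arm_cohort, "Total", reference="nope")

    def test_summary_contains_all_parameters(self, two_arm_cohort, fast_mcmc):
        res = ChangeScoreAncova(two_arm_cohort, "Total").fit(fast_mcmc)
        table = res.summary()
        assert {"intercept", "pre_slope", "contrast[MAX_BOFF]",
                "sigma"} <= set(table.index)
        assert (table["rhat"] < 1.01).all()


class TestNestedMetaModel:
    def _pooled(self, truths, seed):
        cohorts = []
        for i, t in enumerate(truths):
            cfg = CohortConfig(study=f"study{i + 1}", groups=(
                GroupConfig(label=f"g{i}a", n=8,
                            true_change={"SQ": t / 3, "BP": t / 3,
                                         "DL": t / 3},
                            change_sd={"SQ": 1.2, "BP": 1.2, "DL": 1.2}),
                GroupConfig(label=f"g{i}b", n=8,
                            true_change={"SQ": t / 3, "BP": t / 3,
                                         "DL": t / 3},
                            change_sd={"SQ": 1.2, "BP": 1.2, "DL": 1.2})),
                seed=seed + i)
            cohorts.append(generate_cohort(cfg).scores)
        import pandas as pd
        return pd.concat(cohorts, ignore_index=True)

    def test_homogeneous_groups_recover_common_change(self, meta_mcmc):
        scores = self._pooled([15, 15], seed=41)
        res = NestedMetaModel(scores, "Total").fit(meta_mcmc)
        assert kde_mode(res.overall_draws) == pytest.approx(15.0, abs=1.5)
        # between-group spread is near zero under homogeneity
        assert np.median(res.variance_components["sd_group"]) < 5.0

    def test_heterogeneous_overall_lies_between_group_truths(self, meta_mcmc):
        scores = self._pooled([10, 30], seed=51)
        res = NestedMetaModel(scores, "Total").fit(meta_mcmc)
        assert 10.0 < kde_mode(res.overall_draws) < 30.0

    def test_variance_components_are_nonnegative(self, meta_mcmc):
        res = NestedMetaModel(self._pooled([15, 20], seed=61),
                              "Total").fit(meta_mcmc)
        for draws in res.variance_components.values():
            assert (draws >= 0).all()

    def test_missing_nesting_labels_rejected(self, two_arm_cohort):
        scores = two_arm_cohort.scores.drop(columns=["study"])
        with pytest.raises(ValueError):
            NestedMetaModel(scores, "Total")
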