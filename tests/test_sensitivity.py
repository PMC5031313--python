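"""Survey bootstrap, cost-parameter draws, and the PSA loop."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from damburden.costs import CostDistribution, CostParameterSet
from damburden.diseases import DISEASES
from damburden.prevalence import weighted_domain_prevalence
from damburden.sensitivity import (
    PsaConfig,
    bootstrap_resample_survey,
    draw_cost_parameters,
    merge_singleton_strata,
    rao_wu_multipliers,
    run_psa,
)
from damburden.synthetic import DesignSpec, generate_examination_survey


class TestRaoWuBootstrap:
    def test_two_cluster_stratum_multipliers(self):
        # n_h = 2: one cluster drawn once -> multiplier 2, the other 0
        rng = np.random.default_rng(0)
        for _ in range(20):
            mult = rao_wu_multipliers(np.array([0, 0]), rng)
            assert sorted(mult) == [0.0, 2.0]

    def test_multipliers_preserve_expected_weight(self):
        # E[m_c * n_h/(n_h-1)] = 1 per cluster
        rng = np.random.default_rng(1)
        strata = np.repeat(np.arange(4), [2, 3, 5, 7])
        acc = np.zeros(len(strata))
        reps = 5000
        for _ in range(reps):
            acc += rao_wu_multipliers(strata, rng)
        # per-cluster multiplier SD is ~1, so the mean over 5000 draws has
        # SE ~0.014; 0.07 is a 5-sigma bound
        np.testing.assert_allclose(acc / reps, 1.0, atol=0.07)

    def test_record_set_unchanged_only_weights_move(self, small_exam):
        rng = np.random.default_rng(2)
        boot = bootstrap_resample_survey(small_exam, rng)
        assert len(boot) == len(small_exam)
        pd.testing.assert_frame_equal(boot.drop(columns=["sample_weight"]),
                                      small_exam.drop(columns=["sample_weight"]))
        assert not np.allclose(boot["sample_weight"], small_exam["sample_weight"])
        # total weight unbiased across replicates
        totals = [bootstrap_resample_survey(small_exam, rng)["sample_weight"].sum()
                  for _ in range(300)]
        assert np.mean(totals) == pytest.approx(small_exam["sample_weight"].sum(), rel=0.01)

    def test_singleton_strata_merged_deterministically(self):
        # stratum 1 has a single cluster; merged with the next stratum in order
        cs = np.array([0, 0, 1, 2, 2])
        merged = merge_singleton_strata(cs)
        assert (np.bincount(merged)[np.unique(merged)] >= 2).all()
        np.testing.assert_array_equal(merged, merge_singleton_strata(cs))
        with pytest.raises(ValueError, match="single cluster"):
            merge_singleton_strata(np.array([0]))

    def test_bootstrap_se_tracks_monte_carlo_se(self, truth):
        """Simulation oracle: bootstrap SE within 30% of the across-survey SE."""
        clustered = replace(
            truth,
            exam_design=DesignSpec(n_strata=15, clusters_per_stratum=4,
                                   weight_dispersion=0.3, cluster_disease_sd=0.4),
        )
        n = 2_500

        def prevalence_of(df):
            ind = df["malnourished_true"].to_numpy(dtype=float)
            return weighted_domain_prevalence(df, ind)[0]

        mc = [prevalence_of(generate_examination_survey(clustered, n, seed=500 + s))
              for s in range(60)]
        mc_se = np.std(mc)

        df = generate_examination_survey(clustered, n, seed=999)
        rng = np.random.default_rng(7)
        boot = [prevalence_of(bootstrap_resample_survey(df, rng)) for _ in range(200)]
        boot_se = np.std(boot)
        assert boot_se == pytest.approx(mc_se, rel=0.30)


class TestCostDraws:
    def test_gamma_method_of_moments(self):
        # mean 100, se 10 -> shape 100, scale 1; check draw moments
        dist = CostDistribution("gamma", se=10.0)
        rng = np.random.default_rng(3)
        draws = np.array([dist.draw(100.0, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(100.0, rel=0.01)
        assert draws.std() == pytest.approx(10.0, rel=0.05)
        assert (draws > 0).all()

    def test_uniform_bounds_twenty_percent(self):
        dist = CostDistribution("uniform", pct=0.2)
        rng = np.random.default_rng(4)
        draws = np.array([dist.draw(50.0, rng) for _ in range(5_000)])
        assert draws.min() >= 40.0 and draws.max() <= 60.0
        assert draws.mean() == pytest.approx(50.0, rel=0.02)

    def test_degenerate_specs_return_mean(self):
        rng = np.random.default_rng(5)
        assert CostDistribution("gamma", se=0.0).draw(123.0, rng) == 123.0
        assert CostDistribution("uniform", pct=0.0).draw(123.0, rng) == 123.0

    def test_delta_held_unless_varied(self, truth):
        rng = np.random.default_rng(6)
        held = draw_cost_parameters(truth.cost_params, rng, vary_global_delta=False)
        assert held.delta_mn == truth.cost_params.delta_mn
        varied = [draw_cost_parameters(truth.cost_params,
                                       np.random.default_rng(s),
                                       vary_global_delta=True).delta_mn
                  for s in range(20)]
        assert len(set(varied)) > 1
        lo, hi = 0.8 * truth.cost_params.delta_mn, 1.2 * truth.cost_params.delta_mn
        assert all(lo <= v <= hi for v in varied)

    def test_costs_always_redraw(self, truth):
        rng = np.random.default_rng(8)
        drawn = draw_cost_parameters(truth.cost_params, rng)
        assert drawn.mean_cost != truth.cost_params.mean_cost


def _degenerate_costs(params):
    return CostParameterSet(
        mean_cost=dict(params.mean_cost),
        cost_dist={d: CostDistribution("uniform", pct=0.0) for d in DISEASES},
        delta_mn=params.delta_mn,
    )


class TestRunPsa:
    def test_all_randomness_off_collapses_to_point(self, small_exam, small_interview,
                                                   population, truth):
        config = PsaConfig(n_reps=1, seed=1, resample_surveys=False)
        res = run_psa(small_exam, small_interview, population,
                      _degenerate_costs(truth.cost_params), config)
        lo, hi = res.national_interval
        pt = res.point.national_total()
        assert lo == pytest.approx(pt, rel=1e-12)
        assert hi == pytest.approx(pt, rel=1e-12)
        assert res.national_replicate_mean == pytest.approx(pt, rel=1e-12)

    def test_same_seed_identical_intervals(self, small_exam, small_interview,
                                           population, truth):
        config = PsaConfig(n_reps=25, seed=42)
        r1 = run_psa(small_exam, small_interview, population, truth.cost_params, config)
        r2 = run_psa(small_exam, small_interview, population, truth.cost_params, config)
        assert r1.national_interval == r2.national_interval
        pd.testing.assert_frame_equal(r1.state_intervals, r2.state_intervals)

    def test_interval_brackets_point_on_healthy_run(self, small_exam, small_interview,
                                                    population, truth):
        config = PsaConfig(n_reps=60, seed=3)
        res = run_psa(small_exam, small_interview, population, truth.cost_params, config)
        lo, hi = res.national_interval
        assert lo < res.point.national_total() < hi
        assert res.n_failures == 0
        assert res.n_replicates_used == 60
        # interval tables cover every state and National
        assert set(res.state_intervals["state"]) == set(res.point.states) | {"National"}

    def test_interval_width_shrinks_with_survey_size(self, truth, population):
        """Stochastic trend: larger examination survey, narrower interval."""
        costs = _degenerate_costs(truth.cost_params)
        widths = {}
        for n in (1_500, 12_000):
            exam = generate_examination_survey(truth, n, seed=77)
            from damburden.synthetic import generate_interview_survey

            interview = generate_interview_survey(truth, 2 * n, seed=78)
            res = run_psa(exam, interview, population, costs,
                          PsaConfig(n_reps=80, seed=5))
            lo, hi = res.national_interval
            widths[n] = hi - lo
        assert widths[12_000] < widths[1_500]

    def test_vary_global_delta_widens_national_interval(self, small_exam, small_interview,
                                                        population, truth):
        held = run_psa(small_exam, small_interview, population, truth.cost_params,
                       PsaConfig(n_reps=80, seed=9, vary_global_delta=False))
        varied = run_psa(small_exam, small_interview, population, truth.cost_params,
                         PsaConfig(n_reps=80, seed=9, vary_global_delta=True))
        w_held = held.national_interval[1] - held.national_interval[0]
        w_varied = varied.national_interval[1] - varied.national_interval[0]
        assert w_varied > w_held
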