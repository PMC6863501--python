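"""Serial coalescent simulator, mutation dropper and rejection ABC."""

import numpy as np
import pytest
from scipy import stats as sps

from tempodiv.coalescent_abc import (
    SUMMARY_NAMES,
    DemographicModel,
    PriorConfig,
    ReferenceTable,
    abc_reject,
    build_reference_table,
    compute_summaries,
    drop_mutations,
    posterior_summary,
    sample_prior,
    simulate_genealogy,
    simulate_summaries,
    summaries_from_genotypes,
)

CONSTANT_N = DemographicModel(
    n_cur=500.0, n_anc=500.0, t_decline=0.0, mu=1e-6, L=10_000,
    sampling=((0.0, 10),),
)


class TestPriors:
    def test_mu_draws_within_bounds_with_midpoint_mean(self):
        prior = PriorConfig(seed=0)
        rng = np.random.default_rng(0)
        draws = np.array([sample_prior(prior, rng).mu for _ in range(20_000)])
        lo, hi = prior.mu_bounds
        assert draws.min() >= lo and draws.max() <= hi
        assert draws.mean() == pytest.approx((lo + hi) / 2, rel=0.005)

    def test_decline_years_to_generations(self):
        prior = PriorConfig(decline_years=(90, 120), g=3.0)
        rng = np.random.default_rng(1)
        t = np.array([sample_prior(prior, rng).t_decline for _ in range(2_000)])
        assert t.min() >= 30 and t.max() <= 40

    def test_degenerate_prior_constant(self):
        prior = PriorConfig(
            n_cur_bounds=(100, 100), n_anc_bounds=(5000, 5000),
            decline_years=(105, 105), mu_bounds=(2e-7, 2e-7),
        )
        rng = np.random.default_rng(2)
        m = sample_prior(prior, rng)
        assert m.n_cur == pytest.approx(100)
        assert m.n_anc == pytest.approx(5000)
        assert m.mu == pytest.approx(2e-7)
        assert m.t_decline == pytest.approx(35.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(n_cur_bounds=(0, 100))
        with pytest.raises(ValueError):
            PriorConfig(retention=0)


class TestSimulator:
    def test_pairwise_tmrca_matches_constant_n(self):
        """E[TMRCA] = N for two tips in a constant haploid population."""
        model = DemographicModel(
            n_cur=1000, n_anc=1000, t_decline=0, mu=0, L=100, sampling=((0.0, 2),)
        )
        rng = np.random.default_rng(10)
        t = np.array([simulate_genealogy(model, rng).tmrca for _ in range(10_000)])
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 1000) < 3 * se

    def test_tmrca_closed_form_many_tips(self):
        """E[TMRCA] = 2N(1 - 1/n) for n tips, constant N."""
        rng = np.random.default_rng(11)
        t = np.array([simulate_genealogy(CONSTANT_N, rng).tmrca for _ in range(5_000)])
        expect = 2 * 500 * (1 - 1 / 10)
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - expect) < 3 * se

    def test_genealogy_invariants(self):
        rng = np.random.default_rng(12)
        model = DemographicModel(
            n_cur=200, n_anc=2000, t_decline=30, mu=1e-7, L=1000,
            sampling=((0.0, 5), (40.0, 4)),
        )
        for _ in range(50):
            g = simulate_genealogy(model, rng)
            assert g.n_nodes == 2 * g.n_tips - 1
            non_root = g.parent >= 0
            assert non_root.sum() == g.n_nodes - 1  # n-1 coalescences
            assert np.all(g.times[g.parent[non_root]] > g.times[non_root])
            assert np.all(g.branch_lengths >= 0)
            # historical tips activate at t = 40
            assert np.all(g.times[5:9] == 40.0)

    def test_serial_tips_cannot_coalesce_before_activation(self):
        rng = np.random.default_rng(13)
        model = DemographicModel(
            n_cur=50, n_anc=50, t_decline=0, mu=0, L=100,
            sampling=((0.0, 3), (25.0, 3)),
        )
        for _ in range(100):
            g = simulate_genealogy(model, rng)
            parents_of_old = g.parent[3:6]
            assert np.all(g.times[parents_of_old] > 25.0)

    def test_two_epoch_tmrca_matches_msprime(self):
        """Pairwise TMRCA distribution vs an independent simulator."""
        msprime = pytest.importorskip("msprime")
        model = DemographicModel(
            n_cur=220, n_anc=3650, t_decline=35, mu=0, L=100,
            sampling=((0.0, 1), (40.0, 1)),
        )
        rng = np.random.default_rng(14)
        mine = np.array([simulate_genealogy(model, rng).tmrca for _ in range(2_000)])

        dem = msprime.Demography()
        dem.add_population(initial_size=220)
        dem.add_population_parameters_change(time=35, initial_size=3650)
        reps = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(1, time=0, ploidy=1),
                msprime.SampleSet(1, time=40, ploidy=1),
            ],
            demography=dem, ploidy=1, num_replicates=2_000, random_seed=99,
        )
        theirs = np.array([ts.first().time(ts.first().root) for ts in reps])
        assert sps.ks_2samp(mine, theirs).pvalue > 0.01


class TestMutations:
    def test_watterson_expectation(self):
        """Mean S ~ mu L 2N sum(1/i) for constant N."""
        rng = np.random.default_rng(20)
        s = []
        for _ in range(3_000):
            tree = simulate_genealogy(CONSTANT_N, rng)
            s.append(drop_mutations(tree, CONSTANT_N.mu, CONSTANT_N.L, rng).n_mutations)
        s = np.array(s, dtype=float)
        expect = CONSTANT_N.mu * CONSTANT_N.L * 2 * 500 * sum(1 / i for i in range(1, 10))
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert abs(s.mean() - expect) < 3 * se

    def test_zero_rate_no_mutations(self):
        rng = np.random.default_rng(21)
        tree = simulate_genealogy(CONSTANT_N, rng)
        muts = drop_mutations(tree, 0.0, 10_000, rng)
        assert muts.n_mutations == 0
        stats = summaries_from_genotypes(
            muts.genotypes, ["historical"] * 5 + ["modern"] * 5, 10_000
        )
        assert dict(zip(SUMMARY_NAMES, stats))["n_hap_modern"] == 1.0

    def test_identity_probability_two_tips(self):
        """P(no mutation) = exp(-mu L 2 t) for a pair coalescing at depth t."""
        model = DemographicModel(
            n_cur=300, n_anc=300, t_decline=0, mu=5e-6, L=1_000, sampling=((0.0, 2),)
        )
        rng = np.random.default_rng(22)
        same = depth = 0.0
        n_rep = 4_000
        expected = []
        observed = []
        for _ in range(n_rep):
            tree = simulate_genealogy(model, rng)
            muts = drop_mutations(tree, model.mu, model.L, rng)
            expected.append(np.exp(-model.mu * model.L * 2 * tree.tmrca))
            observed.append(1.0 if muts.n_mutations == 0 else 0.0)
        expected = np.mean(expected)
        observed = np.mean(observed)
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert abs(observed - expected) < 4 * se

    def test_finite_sites_fallback_warns(self):
        rng = np.random.default_rng(23)
        model = DemographicModel(
            n_cur=5000, n_anc=5000, t_decline=0, mu=0.05, L=10, sampling=((0.0, 4),)
        )
        tree = simulate_genealogy(model, rng)
        with pytest.warns(RuntimeWarning, match="sites"):
            muts = drop_mutations(tree, model.mu, model.L, rng)
        assert muts.n_mutations > 10


class TestSummaries:
    def test_toy_enumeration(self, toy_aln):
        vals = dict(zip(SUMMARY_NAMES, compute_summaries(toy_aln)))
        assert vals == {
            "n_hap_historical": 1.0, "hd_historical": 0.0, "pi_historical": 0.0,
            "n_hap_modern": 2.0, "hd_modern": 1.0, "pi_modern": 0.25,
            "n_shared": 0.0,
        }

    def test_identical_groups_share_everything(self, aln_factory):
        aln = aln_factory(
            ["AAAA", "CCCC", "AAAA", "CCCC"],
            periods=["historical", "historical", "modern", "modern"],
        )
        vals = dict(zip(SUMMARY_NAMES, compute_summaries(aln)))
        assert vals["n_shared"] == vals["n_hap_modern"] == vals["n_hap_historical"] == 2.0

    def test_missing_period_rejected(self, aln_factory):
        aln = aln_factory(["AAAA", "CCCC"], periods=["modern", "modern"])
        with pytest.raises(ValueError, match="historical"):
            compute_summaries(aln)

    def test_simulated_equals_alignment_route(self):
        """Lean genotype-matrix summaries == alignment-path summaries."""
        from tempodiv.synthetic_data import generate_bottleneck_dataset, DEFAULT_MODEL

        for seed in (1, 2, 3):
            bundle = generate_bottleneck_dataset(DEFAULT_MODEL, seed=seed)
            aln = bundle.alignment()
            via_alignment = compute_summaries(aln)
            rng = np.random.default_rng(seed)
            tree = simulate_genealogy(DEFAULT_MODEL, rng)
            muts = drop_mutations(tree, DEFAULT_MODEL.mu, DEFAULT_MODEL.L, rng)
            from tempodiv.coalescent_abc import tip_periods

            lean = summaries_from_genotypes(
                muts.genotypes, tip_periods(DEFAULT_MODEL), DEFAULT_MODEL.L
            )
            assert np.allclose(via_alignment, lean)


class TestReferenceTableAndRejection:
    def test_reference_table_deterministic(self):
        prior = PriorConfig(n_sims=100, seed=77, L=2_000)
        t1 = build_reference_table(prior)
        t2 = build_reference_table(prior)
        assert np.array_equal(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)

    def test_degenerate_prior_constant_columns(self):
        prior = PriorConfig(
            n_cur_bounds=(100, 100), n_anc_bounds=(1000, 1000),
            decline_years=(105, 105), mu_bounds=(2e-7, 2e-7),
            n_sims=50, L=2_000, seed=5,
        )
        table = build_reference_table(prior)
        assert table.params.nunique().tolist() == [1, 1, 1, 1]

    def test_csv_round_trip(self, tmp_path):
        prior = PriorConfig(n_sims=30, seed=8, L=2_000)
        table = build_reference_table(prior)
        path = tmp_path / "ref.csv"
        table.to_csv(path)
        back = ReferenceTable.from_csv(path)
        assert back.statistics == table.statistics
        assert np.allclose(back.stats, table.stats)

    def test_observed_row_has_zero_distance(self):
        prior = PriorConfig(n_sims=200, seed=9, L=2_000)
        table = build_reference_table(prior)
        result = abc_reject(table.stats[17], table, retention=0.05)
        assert result.distances[17] == 0.0
        assert 17 in result.accepted.index

    def test_toy_table_ranking_matches_brute_force(self):
        params = np.arange(5, dtype=float)
        stats = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3], [10, 10]])
        table = ReferenceTable(
            params=__import__("pandas").DataFrame(
                {"n_cur": params, "n_anc": params, "t_decline": params, "mu": params}
            ),
            stats=stats, statistics=("a", "b"), seed=0,
        )
        obs = np.array([1.2, 1.2])
        result = abc_reject(obs, table, retention=0.4)
        sd = stats.std(axis=0, ddof=1)
        dists = np.sqrt((((stats - obs) / sd) ** 2).sum(axis=1))
        expect = np.argsort(dists, kind="stable")[:2]
        assert list(result.accepted.index) == list(expect)

    def test_retention_one_returns_prior_sample(self):
        prior = PriorConfig(n_sims=50, seed=10, L=2_000)
        table = build_reference_table(prior)
        result = abc_reject(table.stats[0], table, retention=1.0)
        assert result.n_accepted == 50

    def test_acceptance_distances_are_sorted_prefix(self):
        prior = PriorConfig(n_sims=300, seed=11, L=2_000)
        table = build_reference_table(prior)
        result = abc_reject(np.zeros(7), table, retention=0.1)
        cutoff = result.accepted["distance"].max()
        rejected = np.delete(result.distances, result.accepted.index)
        assert (rejected >= cutoff).all()

    def test_zero_variance_statistic_dropped_with_warning(self):
        import pandas as pd

        stats = np.column_stack([np.ones(20), np.arange(20.0)])
        table = ReferenceTable(
            params=pd.DataFrame(
                {"n_cur": np.arange(20.0), "n_anc": np.arange(20.0),
                 "t_decline": np.zeros(20), "mu": np.zeros(20)}
            ),
            stats=stats, statistics=("flat", "slope"), seed=0,
        )
        with pytest.warns(RuntimeWarning, match="flat"):
            result = abc_reject(np.array([1.0, 3.0]), table, retention=0.1)
        assert result.n_accepted == 2


def test_posterior_intervals_are_calibrated(recovery_experiment):
    """Rejection ABC with an adequate table is approximately calibrated:
    over 20 pseudo-observed datasets at known truth, at least 80% of the
    95% posterior intervals for each size parameter cover the truth."""
    truth = recovery_experiment["truth"]
    cover_anc = cover_cur = 0
    for post in recovery_experiment["posteriors"]:
        cover_anc += post.loc["n_anc", "q2.5"] <= truth.n_anc <= post.loc["n_anc", "q97.5"]
        cover_cur += post.loc["n_cur", "q2.5"] <= truth.n_cur <= post.loc["n_cur", "q97.5"]
    assert cover_anc >= 16
    assert cover_cur >= 16


class TestPosterior:
    def test_constant_parameter_constant_quantiles(self):
        import pandas as pd

        acc = pd.DataFrame(
            {"n_cur": [100.0] * 10, "n_anc": [1000.0] * 10,
             "t_decline": [35.0] * 10, "mu": [2e-7] * 10,
             "distance": np.linspace(0, 1, 10)}
        )
        from tempodiv.coalescent_abc import ABCResult

        res = ABCResult(accepted=acc, distances=np.zeros(10), retention=0.1,
                        statistics=SUMMARY_NAMES)
        post = posterior_summary(res)
        assert (post.loc["n_cur"] == 100.0).all()
        assert (post.loc["fold_decline"] == 10.0).all()

    def test_symmetric_sample_median_near_mean(self):
        import pandas as pd

        rng = np.random.default_rng(30)
        vals = rng.normal(50, 5, size=2_000)
        acc = pd.DataFrame(
            {"n_cur": vals, "n_anc": vals * 10, "t_decline": vals / 2,
             "mu": vals * 1e-9, "distance": rng.random(2_000)}
        )
        from tempodiv.coalescent_abc import ABCResult

        res = ABCResult(accepted=acc, distances=np.zeros(2_000), retention=0.1,
                        statistics=SUMMARY_NAMES)
        post = posterior_summary(res)
        assert post.loc["n_cur", "q50"] == pytest.approx(vals.mean(), abs=0.5)
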