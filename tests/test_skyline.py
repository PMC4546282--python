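"""Genealogy estimation, coalescent intervals and the Bayesian skyline."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from mesodemog.simulate import (
    DemographicModel,
    Genealogy,
    SimulationConfig,
    evolve_sequences,
    simulate_genealogy,
)
from mesodemog.skyline import (
    ClockConfig,
    CoalescentIntervals,
    SkylineError,
    SkylineModel,
    classic_skyline,
    coalescent_intervals,
    estimate_genealogy,
    hky_corrected_distance,
    mcmc_skyline,
    pooled_constant_mle,
    skyline_log_likelihood,
    skyline_trajectory,
    subsample_robustness,
)


def balanced_four_tip(h1=10.0, h2=10.0, h3=25.0):
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    heights = np.array([0.0, 0.0, 0.0, 0.0, h1, h2, h3])
    return Genealogy(parent, heights, ["a", "b", "c", "d"])


class TestClock:
    def test_unit_conversion_round_trip(self):
        clock = ClockConfig()
        gens = 1234.56789
        years = gens * clock.generation_years
        assert years / clock.generation_years == pytest.approx(gens, abs=1e-9)

    def test_positivity_enforced(self):
        with pytest.raises(SkylineError):
            ClockConfig(mu=0.0)


class TestCoalescentIntervals:
    def test_two_tip_single_interval(self):
        parent = np.array([2, 2, -1])
        tree = Genealogy(parent, np.array([0.0, 0.0, 100.0]), ["a", "b"])
        ivs = coalescent_intervals(tree)
        assert list(ivs.ks) == [2]
        assert ivs.durations[0] == pytest.approx(100.0)

    def test_simultaneous_heights_give_zero_interval(self):
        ivs = coalescent_intervals(balanced_four_tip())
        assert list(ivs.ks) == [4, 3, 2]
        assert ivs.durations[0] == pytest.approx(10.0)
        assert ivs.durations[1] == pytest.approx(0.0)
        assert ivs.durations[2] == pytest.approx(15.0)

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_always_n_minus_one_events(self, n):
        tree = simulate_genealogy(DemographicModel(sizes=(400.0,)), n, seed=n)
        ivs = coalescent_intervals(tree)
        assert ivs.n_events == n - 1
        assert ivs.tmrca == pytest.approx(tree.tmrca)


class TestClassicSkyline:
    def test_two_lineages(self):
        ivs = CoalescentIntervals(2, np.array([2]), np.array([100.0]))
        assert classic_skyline(ivs)[0] == pytest.approx(100.0)

    def test_ten_lineages(self):
        ivs = CoalescentIntervals(
            10, np.arange(10, 1, -1), np.array([2.0] + [1.0] * 8)
        )
        assert classic_skyline(ivs)[0] == pytest.approx(90.0)

    def test_pooled_estimate_recovers_constant_size(self):
        truth = 1000.0
        estimates = []
        for rep in range(100):
            tree = simulate_genealogy(DemographicModel(sizes=(truth,)), 30, seed=7000 + rep)
            estimates.append(pooled_constant_mle([coalescent_intervals(tree)]))
        assert abs(np.mean(estimates) - truth) / truth < 0.25


class TestEstimateGenealogy:
    def test_identical_pair_coalesces_at_zero(self):
        seqs = {"a": "ACGT" * 100, "b": "ACGT" * 100, "c": "ACGA" * 100}
        tree = estimate_genealogy(seqs)
        ivs_heights = np.sort(tree.heights[3:])
        assert ivs_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_is_degenerate_star(self):
        seqs = {f"s{i}": "ACGT" * 50 for i in range(4)}
        tree = estimate_genealogy(seqs)
        assert tree.degenerate

    def test_saturated_pair_named_in_error(self):
        seqs = {"x": "A" * 400, "y": "C" * 400, "z": "A" * 399 + "C"}
        with pytest.raises(SkylineError, match="x"):
            estimate_genealogy(seqs)

    def test_topology_recovery_on_long_branches(self):
        """UPGMA recovers the true topology (RF=0) in >=90% of replicates for
        8 tips on a known ultrametric tree whose internal edges are all long
        (every edge carries several expected substitutions)."""
        import dendropy

        # balanced 8-tip tree, cherry heights 1000-2500, joins 5000/6500, root 9500
        parent = np.array([8, 8, 9, 9, 10, 10, 11, 11, 12, 12, 13, 13, 14, 14, -1])
        heights = np.array([0.0] * 8 + [1000.0, 1500.0, 2000.0, 2500.0,
                                        5000.0, 6500.0, 9500.0])
        true_tree = Genealogy(parent, heights, [f"t{i}" for i in range(8)])
        cfg = SimulationConfig(mu=3.02e-7)
        clock = ClockConfig(mu=cfg.mu)
        wins = 0
        reps = 50
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=true_tree.to_newick(), schema="newick",
                               taxon_namespace=tns)
        for rep in range(reps):
            seqs = evolve_sequences(true_tree, cfg, seed=rep)
            est = estimate_genealogy(seqs, clock)
            t2 = dendropy.Tree.get(data=est.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            wins += rf == 0
        assert wins / reps >= 0.9

    def test_distance_is_consistent_at_low_divergence(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=2000))
        b = list(a)
        changed = rng.choice(2000, size=20, replace=False)
        for i in changed:
            b[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[i]]
        d = hky_corrected_distance(a, "".join(b))
        assert d == pytest.approx(0.01, rel=0.15)


class TestLikelihood:
    def test_matches_hand_coded_sum(self):
        tree = simulate_genealogy(DemographicModel(sizes=(1000.0,)), 12, seed=5)
        ivs = coalescent_intervals(tree)
        model = SkylineModel(group_sizes=(3, 4, 4), nefs=(500.0, 900.0, 2000.0))
        nef_of_event = [500.0] * 3 + [900.0] * 4 + [2000.0] * 4
        w = ivs.weights
        expected = sum(
            -w[j] / nef_of_event[j] - math.log(nef_of_event[j]) for j in range(11)
        )
        assert skyline_log_likelihood(ivs, model) == pytest.approx(expected, abs=1e-10)

    def test_group_sizes_must_cover_events(self):
        ivs = CoalescentIntervals(4, np.array([4, 3, 2]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(SkylineError):
            skyline_log_likelihood(ivs, SkylineModel(group_sizes=(2,), nefs=(10.0,)))

    def test_multiple_genealogies_add(self):
        t1 = simulate_genealogy(DemographicModel(sizes=(800.0,)), 6, seed=1)
        t2 = simulate_genealogy(DemographicModel(sizes=(800.0,)), 6, seed=2)
        i1, i2 = coalescent_intervals(t1), coalescent_intervals(t2)
        m1 = SkylineModel(group_sizes=(5,), nefs=(700.0,))
        m_joint = SkylineModel(group_sizes=(10,), nefs=(700.0,))
        joint = skyline_log_likelihood([i1, i2], m_joint)
        assert joint == pytest.approx(
            skyline_log_likelihood(i1, m1) + skyline_log_likelihood(i2, m1), abs=1e-10
        )


class TestMcmc:
    def test_single_interval_matches_closed_form_posterior(self):
        """n=2, one interval of length T: with the log-uniform prior the exact
        posterior is N = T/U with U ~ Exp(1), so the posterior median is
        T/ln 2 and the log-space mode sits at the MLE N=T."""
        T = 500.0
        ivs = CoalescentIntervals(2, np.array([2]), np.array([T]))
        post = mcmc_skyline(ivs, m=1, iterations=100_000, thin=50, seed=3)
        med = float(np.median(post.nefs[:, 0]))
        assert abs(med - T / math.log(2)) / (T / math.log(2)) < 0.15
        # upper quartile: N = T/ln(4/3)
        q75 = float(np.quantile(post.nefs[:, 0], 0.75))
        assert abs(q75 - T / math.log(4 / 3)) / (T / math.log(4 / 3)) < 0.2

    def test_posterior_median_near_mle_many_events(self):
        tree = simulate_genealogy(DemographicModel(sizes=(5000.0,)), 30, seed=77)
        ivs = coalescent_intervals(tree)
        post = mcmc_skyline(ivs, m=1, iterations=80_000, thin=40, seed=4)
        mle = pooled_constant_mle([ivs])
        med = float(np.median(post.nefs[:, 0]))
        assert abs(med - mle) / mle < 0.1

    def test_flat_likelihood_recovers_prior(self):
        """With the likelihood switched off the chain samples the log-uniform
        prior (detailed-balance sanity check)."""
        tree = simulate_genealogy(DemographicModel(sizes=(1000.0,)), 10, seed=9)
        ivs = coalescent_intervals(tree)
        lo, hi = (2.0, 10.0)
        post = mcmc_skyline(ivs, m=1, iterations=200_000, thin=40, seed=5,
                            prior_log_bounds=(lo, hi), flat_likelihood=True,
                            proposal_scale=2.0)
        draws = np.log(post.nefs[:, 0])
        # thinned draws remain autocorrelated; subsample before the KS test
        draws = draws[:: max(1, int(len(draws) / post.diagnostics["ess_nef_recent"]))]
        _, p = stats.kstest(draws, "uniform", args=(lo, hi - lo))
        assert p > 0.01

    def test_classic_and_full_resolution_bayesian_agree_in_rank(self):
        """With one group per event the posterior medians track the classic
        per-interval skyline (Spearman rho > 0.7) on a smooth history."""
        model = DemographicModel(sizes=(500.0, 5000.0), change_times=(150.0,))
        tree = simulate_genealogy(model, 30, seed=21)
        ivs = coalescent_intervals(tree)
        keep = ivs.durations > 0
        classic = classic_skyline(ivs)[keep]
        post = mcmc_skyline(ivs, m=ivs.n_events, iterations=150_000, thin=100, seed=6)
        med = np.median(post.nefs, axis=0)[keep]
        rho, _ = stats.spearmanr(classic, med)
        assert rho > 0.7

    def test_config_errors(self):
        ivs = CoalescentIntervals(3, np.array([3, 2]), np.array([1.0, 1.0]))
        with pytest.raises(SkylineError):
            mcmc_skyline(ivs, m=5, iterations=1000, thin=10, seed=1)
        with pytest.raises(SkylineError):
            mcmc_skyline(ivs, m=1, iterations=1000, thin=10, seed=1, proposal_scale=-1)


class TestTrajectory:
    def synthetic_posterior(self, nefs, sizes, times):
        from mesodemog.skyline import SkylinePosterior

        return SkylinePosterior(
            event_times=np.asarray(times, dtype=float),
            group_sizes=np.asarray(sizes, dtype=int),
            nefs=np.asarray(nefs, dtype=float),
            log_likelihoods=np.zeros(len(nefs)),
        )

    def test_identical_draws_zero_width(self):
        post = self.synthetic_posterior(
            nefs=[[100.0, 300.0]] * 5, sizes=[[2, 2]] * 5, times=[10.0, 20.0, 30.0, 40.0]
        )
        traj = skyline_trajectory(post, grid=np.array([5.0, 25.0, 40.0]))
        assert np.allclose(traj.median, [100.0, 300.0, 300.0])
        assert np.allclose(traj.hpd_low, traj.hpd_high)

    def test_two_draw_even_weighting(self):
        post = self.synthetic_posterior(
            nefs=[[100.0], [300.0]], sizes=[[3], [3]], times=[5.0, 10.0, 20.0]
        )
        traj = skyline_trajectory(post, grid=np.array([0.0, 15.0]))
        assert np.allclose(traj.median, 200.0)

    def test_grid_beyond_root_truncated_with_warning(self):
        post = self.synthetic_posterior(nefs=[[50.0]], sizes=[[2]], times=[5.0, 12.0])
        with pytest.warns(UserWarning, match="beyond the root"):
            traj = skyline_trajectory(post, grid=np.array([0.0, 6.0, 99.0]))
        assert traj.times_gen.max() <= 12.0

    def test_growth_signal_detected(self):
        """Two-epoch 10x growth: recent median exceeds ancient median in most
        replicates."""
        model = DemographicModel(sizes=(5000.0, 500.0), change_times=(200.0,))
        wins = 0
        for rep in range(10):
            tree = simulate_genealogy(model, 30, seed=9100 + rep)
            post = mcmc_skyline(coalescent_intervals(tree), m=5,
                                iterations=60_000, thin=60, seed=rep)
            traj = skyline_trajectory(post, grid=np.array([0.0, 400.0]))
            wins += traj.median[0] > traj.median[1]
        assert wins >= 8


class TestSubsampleRobustness:
    @pytest.fixture(scope="class")
    def alignment40(self):
        tree = simulate_genealogy(DemographicModel(sizes=(3000.0,)), 40, seed=31)
        return evolve_sequences(tree, SimulationConfig(), seed=31)

    def test_three_trajectories_emitted(self, alignment40):
        out = subsample_robustness(alignment40, [10, 20, 40], seed=1,
                                   iterations=20_000, thin=40)
        assert sorted(out) == [10, 20, 40]

    def test_small_sizes_skipped(self, alignment40):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = subsample_robustness(alignment40, [2], seed=1, iterations=5000, thin=10)
        assert out == {}
        assert any("skipped" in str(w.message) for w in rec)

    def test_constant_size_medians_within_order_of_magnitude(self, alignment40):
        out = subsample_robustness(alignment40, [20, 40], seed=2,
                                   iterations=40_000, thin=40)
        t_max = min(out[20].times_gen.max(), out[40].times_gen.max())
        grid = np.linspace(0, t_max, 20)
        a = np.interp(grid, out[20].times_gen, out[20].median)
        b = np.interp(grid, out[40].times_gen, out[40].median)
        assert np.all(np.abs(np.log10(a) - np.log10(b)) < 1.0)
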