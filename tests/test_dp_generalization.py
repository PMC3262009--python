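"""DP-mixture learner: closed forms, oracle equivalence, trajectory behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from ambigen import dp_generalization as dp

from conftest import make_trials


def counts_from(pairs):
    """CueCounts holding the given (k, n) per cue."""
    c = dp.CueCounts()
    for idx, (k, n) in enumerate(pairs):
        cue = f"c{idx}"
        for i in range(n):
            c.observe(cue, 1 if i < k else 0)
    return c


class TestBetaBinomialMarginal:
    @pytest.mark.parametrize(
        "k,n,expected", [(0, 0, 1.0), (3, 7, 1 / 8), (7, 7, 1 / 8), (0, 4, 1 / 5)]
    )
    def test_closed_form(self, k, n, expected):
        assert dp.beta_binomial_marginal(k, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k,n", [(2, 5), (0, 3), (6, 9)])
    def test_matches_quadrature(self, k, n):
        val, _ = integrate.quad(lambda th: stats.binom.pmf(k, n, th), 0, 1)
        assert dp.beta_binomial_marginal(k, n) == pytest.approx(val, rel=1e-8)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dp.beta_binomial_marginal(5, 3)


class TestCRPWeights:
    def test_no_history_all_mass_on_base(self):
        assert dp.crp_predictive_weights([], 2.0) == pytest.approx([1.0])

    def test_three_atoms_unit_alpha(self):
        w = dp.crp_predictive_weights([0.2, 0.5, 0.9], 1.0)
        assert w == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_large_alpha_favors_new(self):
        w = dp.crp_predictive_weights([0.5] * 3, 1e9)
        assert w[-1] == pytest.approx(1.0, abs=1e-8)

    @given(
        m=st.integers(min_value=0, max_value=20),
        alpha=st.floats(min_value=1e-3, max_value=50.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_weights_sum_to_one(self, m, alpha):
        w = dp.crp_predictive_weights([0.5] * m, alpha)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()


class TestRunChain:
    def test_single_cue_conjugacy(self):
        # m = 1: no other atoms, so every sweep draws i.i.d. from Beta(1+k, 1+n-k)
        counts = counts_from([(8, 10)])
        ens = dp.run_chain(counts, dp.DPConfig(n_samples=4000, burn_in=50, seed=0))
        theta = ens.predictive_samples("c0")
        target = stats.beta(9, 3)
        se_mean = target.std() / math.sqrt(4000)
        assert theta.mean() == pytest.approx(target.mean(), abs=4 * se_mean)
        assert theta.var() == pytest.approx(target.var(), rel=0.15)

    def test_prior_recovery_no_observations(self):
        ens = dp.run_chain(dp.CueCounts(), dp.DPConfig(n_samples=4000, seed=1))
        rng = np.random.default_rng(2)
        theta = ens.predictive_samples(dp.NEW, rng=rng)
        assert theta.mean() == pytest.approx(0.5, abs=4 * 0.2887 / math.sqrt(4000))

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            dp.run_chain(dp.CueCounts(), dp.DPConfig(n_samples=0))

    def test_same_seed_same_ensemble(self):
        counts = counts_from([(2, 3), (1, 3)])
        cfg = dp.DPConfig(n_samples=200, burn_in=50, seed=42)
        a = dp.run_chain(counts, cfg)
        b = dp.run_chain(counts, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_coclustering_tracks_count_similarity(self):
        cfg = dp.DPConfig(n_samples=3000, burn_in=200, thinning=2, seed=3)
        same = dp.run_chain(counts_from([(9, 10), (9, 10)]), cfg)
        diff = dp.run_chain(counts_from([(9, 10), (1, 10)]), cfg)
        co_same = (same.samples[:, 0] == same.samples[:, 1]).mean()
        co_diff = (diff.samples[:, 0] == diff.samples[:, 1]).mean()
        ex_same = dp.exact_partition_posterior([9, 9], [10, 10], 1.0)["cocluster"][0, 1]
        ex_diff = dp.exact_partition_posterior([9, 1], [10, 10], 1.0)["cocluster"][0, 1]
        assert co_same > co_diff
        assert ex_same > ex_diff
        for est, exact in [(co_same, ex_same), (co_diff, ex_diff)]:
            se = math.sqrt(max(exact * (1 - exact), 1e-4) / 3000)
            assert est == pytest.approx(exact, abs=max(3 * se, 0.02))

    def test_unknown_cue_lookup_error(self):
        ens = dp.run_chain(counts_from([(1, 2)]), dp.DPConfig(n_samples=100, seed=0))
        with pytest.raises(KeyError):
            ens.predictive_samples("nope")


class TestOracleEquivalence:
    """Gibbs estimates vs exhaustive set-partition enumeration at small m."""

    def test_partition_and_predictive_match_enumeration(self):
        k = np.array([2, 3, 0, 1])
        n = np.array([3, 3, 2, 3])
        exact = dp.exact_partition_posterior(k, n, 1.0)
        S = 3000
        cfg = dp.DPConfig(n_samples=S, burn_in=300, thinning=4, seed=9)
        ens = dp.run_chain(counts_from(list(zip(k, n))), cfg)
        # cluster-count pmf
        counts = np.bincount(ens.n_clusters_per_sample, minlength=len(k) + 1)[1:]
        for c, p_exact in exact["n_clusters_pmf"].items():
            p_hat = counts[c - 1] / S
            se = math.sqrt(p_exact * (1 - p_exact) / S)
            assert p_hat == pytest.approx(p_exact, abs=max(3 * se, 0.015))
        # per-cue predictive means
        for j in range(len(k)):
            sd = ens.samples[:, j].std()
            assert ens.samples[:, j].mean() == pytest.approx(
                exact["predictive_mean"][j], abs=max(3 * sd / math.sqrt(S), 0.01)
            )

    def test_predictive_for_new_cue_matches_enumeration(self):
        k, n = np.array([3, 3, 0]), np.array([3, 3, 3])
        exact = dp.exact_partition_posterior(k, n, 1.0)
        cfg = dp.DPConfig(n_samples=4000, burn_in=300, thinning=3, seed=4)
        ens = dp.run_chain(counts_from(list(zip(k, n))), cfg)
        draws = ens.predictive_samples(dp.NEW, rng=np.random.default_rng(5))
        se = draws.std() / math.sqrt(len(draws))
        assert draws.mean() == pytest.approx(
            exact["predictive_mean_new"], abs=max(3 * se, 0.015)
        )

    def test_exchangeability_of_cue_labels(self):
        pairs = [(3, 3), (0, 3), (1, 2)]
        cfg = dp.DPConfig(n_samples=4000, burn_in=300, thinning=2, seed=6)
        a = dp.run_chain(counts_from(pairs), cfg)
        b = dp.run_chain(counts_from(pairs[::-1]), dp.DPConfig(**{**cfg.__dict__, "seed": 7}))
        da = a.predictive_samples(dp.NEW, rng=np.random.default_rng(1))
        db = b.predictive_samples(dp.NEW, rng=np.random.default_rng(2))
        se = math.sqrt(da.var() / len(da) + db.var() / len(db))
        assert da.mean() == pytest.approx(db.mean(), abs=max(3 * se, 0.01))


class TestGibbsSweep:
    def test_empty_state_noop(self):
        out = dp.gibbs_sweep(np.array([]), dp.CueCounts(), dp.DPConfig())
        assert out.size == 0

    def test_sweep_moves_state_within_bounds(self):
        counts = counts_from([(2, 3), (1, 3)])
        state = np.array([0.5, 0.5])
        out = dp.gibbs_sweep(state, counts, dp.DPConfig(), seed=1, n_sweeps=5)
        assert out.shape == (2,)
        assert ((out >= 0) & (out <= 1)).all()


class TestEntropyAndValue:
    def test_point_mass_and_single_bin_are_zero(self):
        assert dp.shannon_entropy(np.full(100, 0.3), 10) == 0.0
        assert dp.shannon_entropy(np.random.default_rng(0).random(100), 1) == 0.0

    def test_uniform_samples_reach_log_bins(self):
        x = np.random.default_rng(1).random(100_000)
        assert dp.shannon_entropy(x, 10) == pytest.approx(math.log(10), abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            dp.shannon_entropy([], 10)
        with pytest.raises(ValueError):
            dp.expected_value([])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200),
        st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_entropy_bounds(self, samples, bins):
        h = dp.shannon_entropy(samples, bins)
        assert 0.0 <= h <= math.log(bins) + 1e-12

    def test_expected_value_is_mean(self):
        assert dp.expected_value(np.full(50, 0.7)) == pytest.approx(0.7)


class TestTrajectory:
    def test_first_trial_is_prior(self, m1_trajectory):
        first = m1_trajectory.iloc[0]
        assert first["value"] == pytest.approx(0.5, abs=0.08)
        assert first["entropy"] == pytest.approx(math.log(10), abs=0.25)
        assert first["risk"] == pytest.approx(0.25, abs=0.02)

    def test_surprise_matches_value(self, m1_trajectory, default_task):
        trials, _ = default_task
        lam = trials["outcome"].to_numpy()
        v = m1_trajectory["value"].to_numpy()
        p = np.where(lam == 1, v, 1 - v)
        assert np.allclose(m1_trajectory["surprise"], -np.log(np.maximum(p, 1e-12)))

    def test_risk_is_outcome_variance(self, m1_trajectory):
        v = m1_trajectory["value"]
        assert np.allclose(m1_trajectory["risk"], v * (1 - v))

    def test_trajectory_deterministic(self, default_task):
        trials, _ = default_task
        head = trials.head(40)
        cfg = dp.DPConfig(n_samples=150, burn_in=30, seed=8)
        a = dp.run_m1_trajectory(head, cfg)
        b = dp.run_m1_trajectory(head, cfg)
        assert a.equals(b)

    def test_unordered_trials_rejected(self, default_task):
        trials, _ = default_task
        shuffled = trials.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            dp.run_m1_trajectory(shuffled, dp.DPConfig(n_samples=10, burn_in=1))

    def test_pooled_variant_shares_counts_across_contexts(self):
        # 3 GC blocks of purple outcomes then a new AC cue: M1 starts the AC
        # context from the prior (value ~0.5) while M4 generalizes (~>0.6)
        recs = [("g1", "GC", 1)] * 5 + [("g2", "GC", 1)] * 5 + [("a1", "AC", 1)]
        trials = make_trials(recs)
        cfg = dp.DPConfig(n_samples=2000, burn_in=200, seed=12)
        m1_val = dp.run_m1_trajectory(trials, cfg)["value"].iloc[-1]
        cfg4 = dp.DPConfig(n_samples=2000, burn_in=200, seed=12, pool_contexts=True)
        m4_val = dp.run_m1_trajectory(trials, cfg4)["value"].iloc[-1]
        assert m1_val == pytest.approx(0.5, abs=0.06)
        assert m4_val > 0.6
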