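import numpy as np
import pytest
from scipy import stats

from btspcam import network, patterns, plasticity
from btspcam.plasticity import (
    PlasticityConfig,
    btsp_step,
    core_btsp_step,
    draw_plateaus,
    learn_sequence,
    multi_release_site_change,
)


class TestPlateaus:
    @pytest.mark.parametrize("f_q,expect_all", [(0.0, False), (1.0, True)])
    def test_degenerate_probabilities(self, f_q, expect_all):
        sched = draw_plateaus(10, 50, f_q, seed=0)
        assert sched.masks.all() == expect_all and sched.masks.any() == expect_all

    def test_mean_plateau_count(self):
        sched = draw_plateaus(1000, 39_000, 0.005, seed=1)
        counts = sched.masks.sum(axis=1)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 195.0) <= 3 * se


class TestBtspStep:
    def _tiny(self):
        mask = np.ones((3, 4), dtype=bool)
        W = np.zeros((3, 4), dtype=np.uint8)
        x = np.array([1, 1, 0, 1], dtype=np.uint8)
        return W, mask, x

    def test_ltd_depresses_strong_active_synapse(self):
        W, mask, x = self._tiny()
        W[0] = 1
        out = core_btsp_step(W, mask, x, Q=np.array([0]))
        assert out[0].tolist() == [0, 0, 1, 0]  # active inputs flipped down, x=0 kept

    def test_no_plateau_no_change(self):
        W, mask, x = self._tiny()
        W[1, 0] = 1
        out = btsp_step(W, mask, x, Q=np.array([0]), seed=0)
        assert np.array_equal(out[1], W[1]) and np.array_equal(out[2], W[2])

    def test_double_core_step_restores_weights(self):
        W, mask, x = self._tiny()
        W[0, 0] = 1
        once = core_btsp_step(W, mask, x, Q=np.array([0, 2]))
        twice = core_btsp_step(once, mask, x, Q=np.array([0, 2]))
        assert np.array_equal(twice, W)

    def test_three_updates_leave_synapse_strong(self):
        # parity: an odd number of flips on a zero-initialised weight ends at 1
        W, mask, x = self._tiny()
        out = W
        for _ in range(3):
            out = core_btsp_step(out, mask, x, Q=np.array([1]))
        assert out[1].tolist() == [1, 1, 0, 1]

    def test_wrong_item_length_rejected(self):
        W, mask, _ = self._tiny()
        with pytest.raises(ValueError):
            btsp_step(W, mask, np.ones(5, dtype=np.uint8), Q=np.array([0]))

    def test_weights_never_escape_connectivity(self):
        rng = np.random.default_rng(3)
        mask = rng.random((20, 30)) < 0.5
        W = np.zeros((20, 30), dtype=np.uint8)
        for k in range(20):
            x = (rng.random(30) < 0.3).astype(np.uint8)
            Q = rng.random(20) < 0.3
            W = btsp_step(W, mask, x, Q, PlasticityConfig(gating="synapse"), seed=k)
        assert not (W.astype(bool) & ~mask).any()

    def test_asymmetric_probabilities_bias_direction(self):
        # p_ltd=1, p_ltp=0: strong active synapses always depressed, weak never potentiated
        mask = np.ones((1, 6), dtype=bool)
        W = np.array([[1, 1, 1, 0, 0, 0]], dtype=np.uint8)
        x = np.ones(6, dtype=np.uint8)
        cfg = PlasticityConfig(p_ltp=0.0, p_ltd=1.0)
        out = btsp_step(W, mask, x, Q=np.array([0]), cfg=cfg, seed=0)
        assert not out.any()


class TestLearnSequence:
    def test_empty_sequence_leaves_zero_weights(self):
        ens = patterns.PatternEnsemble(items=np.zeros((0, 10), dtype=np.uint8), f_p=0.1)
        plats = plasticity.PlateauSchedule(masks=np.zeros((0, 5), dtype=bool), f_q=0.1)
        res = learn_sequence(ens, plats, np.ones((5, 10), dtype=bool), seed=0)
        assert not res.network.W.any()

    def test_final_weights_equal_parity_of_logged_updates(self, learned_small):
        _, _, _, res = learned_small
        assert np.array_equal(res.network.W, (res.update_counts % 2).astype(np.uint8))

    def test_strong_weight_density_matches_parity_closed_form(self, small_scale):
        # density among connected synapses = (1 - (1 - f_p f_q)^M) / 2
        p = small_scale
        M = 400
        fractions = []
        for s in range(5):
            ens = patterns.gen_random_patterns(M, p["m"], p["f_p"], seed=100 + s)
            plats = draw_plateaus(M, p["n"], p["f_q"], seed=200 + s)
            mask = network.build_connectivity(p["m"], p["n"], p["f_w"], seed=300 + s)
            res = learn_sequence(ens, plats, mask, seed=400 + s)
            fractions.append(network.strong_weight_fraction(res.network))
        expected = 0.5 * (1.0 - (1.0 - p["f_p"] * p["f_q"]) ** M)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - expected) <= 3 * se

    def test_mismatched_sequence_lengths_rejected(self):
        ens = patterns.gen_random_patterns(4, 10, 0.3, seed=0)
        plats = draw_plateaus(5, 6, 0.5, seed=1)
        with pytest.raises(ValueError):
            learn_sequence(ens, plats, np.ones((6, 10), dtype=bool))


class TestCoreEquivalence:
    def test_core_rule_at_half_fq_matches_stochastic_rule(self, small_scale):
        # the stochastic rule (one update coin per neuron and item) is
        # equivalent in law to the deterministic core rule driven at f_q/2
        p = small_scale
        M = 300
        t_eq1, t_core = [], []
        for s in range(20):
            ens = patterns.gen_random_patterns(M, p["m"], p["f_p"], seed=500 + s)
            mask = network.build_connectivity(p["m"], p["n"], p["f_w"], seed=600 + s)
            plats = draw_plateaus(M, p["n"], p["f_q"], seed=700 + s)
            res1 = learn_sequence(ens, plats, mask, PlasticityConfig(rule="eq1"), seed=800 + s, v_th=8)
            resc = learn_sequence(
                ens, plats.halved(seed=900 + s), mask, PlasticityConfig(rule="core"),
                seed=1000 + s, v_th=8,
            )
            t_eq1.append(network.trace_size(res1.network, ens))
            t_core.append(network.trace_size(resc.network, ens))
        diff = np.array(t_eq1) - np.array(t_core)
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) <= 3 * se

    def test_update_count_distributions_agree(self):
        # chi-square on per-synapse update counts: eq1 at (f_q, 0.5) vs core
        # at f_q/2.  Counts within a row share the neuron's plateau draws, so
        # only the diagonal synapses (distinct row and column) are collected
        # across independent runs — those are i.i.d. samples.
        m, n, M, f_q = 40, 40, 120, 0.3
        ens = patterns.gen_random_patterns(M, m, 0.3, seed=1)
        mask = np.ones((n, m), dtype=bool)
        diag = np.arange(min(n, m))

        def counts(rule, f_q_eff, base_seed):
            out = []
            for r in range(30):
                plats = draw_plateaus(M, n, f_q_eff, seed=base_seed + 2 * r)
                res = learn_sequence(
                    ens, plats, mask, PlasticityConfig(rule=rule), seed=base_seed + 2 * r + 1
                )
                out.append(res.update_counts[diag, diag])
            return np.concatenate(out)

        c1 = counts("eq1", f_q, base_seed=100)
        c2 = counts("core", f_q / 2, base_seed=300)
        hi = int(max(c1.max(), c2.max()))
        h1 = np.bincount(c1, minlength=hi + 1)
        h2 = np.bincount(c2, minlength=hi + 1)
        keep = (h1 + h2) >= 10
        _, pval, _, _ = stats.chi2_contingency(np.stack([h1[keep], h2[keep]]))
        assert pval > 0.001


class TestMultiReleaseSites:
    def test_expected_changes_by_initial_sum(self):
        # E[change | initial sum s] = p_update (n_sites - 2 s): +4 / 0 / -4
        df = multi_release_site_change(n_sites=8, n_trials=200_000, seed=0)
        by = df.set_index("initial_sum")
        for s, expected in ((0, 4.0), (4, 0.0), (8, -4.0)):
            row = by.loc[s]
            tol = 3 * 4.0 / np.sqrt(row["n_trials"])  # change is bounded by +-8
            assert abs(row["mean_change"] - expected) <= max(tol, 0.15)

    def test_site_count_validated(self):
        with pytest.raises(ValueError):
            multi_release_site_change(n_sites=0)
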