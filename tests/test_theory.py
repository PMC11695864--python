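import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btspcam import theory
from btspcam.theory import (
    TheoryParams,
    expected_hd_masked,
    expected_hd_pairs,
    optimize_threshold,
    overlapping_predictions,
    p_e,
    p_favg,
    p_f1,
    p_f2,
    p_hat_e,
    p_hat_o,
    p_o,
    prob_even,
    prob_odd,
)

REDUCED = TheoryParams(m=2500, n=3900, M=1000, f_p=0.02, f_q=0.01, f_w=0.6, v_th=10)


class TestParityLemma:
    def test_zero_trials_and_fair_coin(self):
        assert prob_even(0, 0.7) == 1.0
        assert prob_even(5, 0.5) == pytest.approx(0.5)
        assert prob_odd(5, 0.5) == pytest.approx(0.5)

    def test_two_trial_enumeration(self):
        # P(0) + P(2) = 0.49 + 0.09 = 0.58
        assert prob_even(2, 0.3) == pytest.approx(0.58)

    @given(st.integers(0, 60), st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_complementarity_and_bounds(self, N, p):
        e, o = prob_even(N, p), prob_odd(N, p)
        assert e + o == pytest.approx(1.0)
        assert 0.0 <= e <= 1.0


class TestActiveWeightProbabilities:
    def test_single_item_has_no_interference(self):
        assert p_e(1, 0.3, 0.4) == 1.0
        assert p_o(1, 0.3, 0.4) == 0.0

    def test_complementarity(self):
        assert p_e(500, 0.02, 0.01) + p_o(500, 0.02, 0.01) == pytest.approx(1.0)

    def test_full_scale_value_against_direct_enumeration(self):
        # independent oracle: sum the binomial pmf over even counts directly
        M, f_p, f_q = 30_000, 0.005, 0.005
        from scipy.stats import binom

        k = np.arange(0, M)
        pmf = binom.pmf(k, M - 1, f_p * f_q / 2.0)
        direct = float(pmf[k % 2 == 0].sum())
        assert p_e(M, f_p, f_q) == pytest.approx(direct, abs=1e-12)
        assert p_e(M, f_p, f_q) == pytest.approx(0.7362, abs=5e-5)


class TestFiringProbabilities:
    def test_support_smaller_than_threshold_cannot_fire(self):
        assert p_f1(5, 5, 0.6, 1.0) == 0.0

    def test_single_input_survival(self):
        assert p_f1(1, 0, 1.0, 0.6) == pytest.approx(0.6)

    def test_plateau_branch_dominates(self):
        pe, po = 0.8, 0.2
        I = np.arange(0, 60)
        assert np.all(p_f1(I, 7, 0.6, pe) >= p_f2(I, 7, 0.6, po) - 1e-15)

    def test_p_favg_monotone_in_threshold(self):
        vals = [p_favg(replace(REDUCED, v_th=v)) for v in range(0, 30, 3)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_no_plateaus_single_item_never_fires(self):
        p = replace(REDUCED, f_q=0.0, M=1, v_th=0)
        assert p_favg(p) == pytest.approx(0.0, abs=1e-12)


class TestExpectedHammingDistances:
    def test_masked_hd_monotone_in_masking(self):
        a = expected_hd_masked(replace(REDUCED, f_d=0.0))
        b = expected_hd_masked(replace(REDUCED, f_d=0.33))
        c = expected_hd_masked(replace(REDUCED, f_d=0.66))
        assert a <= b <= c

    def test_full_masking_reduces_to_trace_size(self):
        # with every 1 masked the cue recalls nothing: E[HD] = n * p_favg
        p = replace(REDUCED, f_d=1.0)
        assert expected_hd_masked(p) == pytest.approx(p.n * p_favg(p), rel=1e-12)

    def test_pairwise_hd_formula(self):
        p = REDUCED
        pf = p_favg(p)
        assert expected_hd_pairs(p) == pytest.approx(2 * p.n * pf * (1 - pf))


class TestOverlappingItems:
    def test_conditional_probabilities_edge_cases(self):
        assert p_hat_e(1, 0.2) == 1.0
        assert p_hat_o(0, 0.2) == 0.0
        assert p_hat_e(3, 0.1) == pytest.approx(0.905)
        with pytest.raises(ValueError):
            p_hat_e(0, 0.2)

    def test_zero_common_bits_reduces_exactly(self):
        p = replace(REDUCED, c=0)
        pred = overlapping_predictions(p)
        assert pred.p_favg == pytest.approx(p_favg(p), abs=1e-12)
        assert pred.expected_hd_masked == pytest.approx(expected_hd_masked(p), abs=1e-9)
        assert pred.expected_hd_pairs == pytest.approx(expected_hd_pairs(p), abs=1e-9)

    def test_relative_dissimilarity_grows_with_overlap(self):
        ratios = []
        for f_c in (0.0, 0.1, 0.2, 0.3):
            c = int(math.floor(REDUCED.m * f_c * REDUCED.f_p))
            p = replace(REDUCED, c=c)
            pred = overlapping_predictions(p)
            ratios.append(pred.expected_hd_masked / pred.expected_hd_pairs)
        assert all(a <= b + 1e-12 for a, b in zip(ratios, ratios[1:]))


class TestThresholdOptimization:
    def test_matches_exhaustive_scan(self):
        v = optimize_threshold(REDUCED, f_d=0.33, M=REDUCED.M, v_max=40)
        objs = {}
        for vt in range(1, 41):
            p = replace(REDUCED, v_th=vt, f_d=0.33)
            den = expected_hd_pairs(p)
            if den > 0:
                objs[vt] = expected_hd_masked(p) / den
        assert v == min(objs, key=objs.get)

    def test_local_optimality(self):
        v = optimize_threshold(REDUCED, f_d=0.33, M=REDUCED.M, v_max=60)

        def obj(vt):
            p = replace(REDUCED, v_th=vt, f_d=0.33)
            return expected_hd_masked(p) / expected_hd_pairs(p)

        assert obj(v) <= obj(v + 1) and (v == 1 or obj(v) <= obj(v - 1))

    def test_default_masking_fraction_is_one_third(self):
        import inspect

        sig = inspect.signature(optimize_threshold)
        assert sig.parameters["f_d"].default == 0.33


class TestSmallInstanceOracle:
    def test_closed_forms_match_exhaustive_probability_sums(self):
        # m, n <= 20, M <= 6: enumerate update-count outcomes directly with
        # exact combinatorics instead of the parity closed form
        for M, f_p, f_q in itertools.product((2, 4, 6), (0.2, 0.5), (0.3, 0.7)):
            q = f_p * f_q / 2.0
            pe_direct = sum(
                math.comb(M - 1, k) * q**k * (1 - q) ** (M - 1 - k)
                for k in range(0, M, 2)
            )
            assert abs(p_e(M, f_p, f_q) - pe_direct) <= 1e-12
            assert abs(p_o(M, f_p, f_q) - (1 - pe_direct)) <= 1e-12

        # p_favg via explicit total-probability sums at m, n <= 20
        m, n, M, f_p, f_q, f_w, v_th = 12, 8, 4, 0.3, 0.4, 0.7, 2
        params = TheoryParams(m=m, n=n, M=M, f_p=f_p, f_q=f_q, f_w=f_w, v_th=v_th)
        pe, po = p_e(M, f_p, f_q), p_o(M, f_p, f_q)

        def binom_sf(v, nn, pp):
            return sum(
                math.comb(nn, k) * pp**k * (1 - pp) ** (nn - k) for k in range(v + 1, nn + 1)
            )

        direct = sum(
            math.comb(m, I) * f_p**I * (1 - f_p) ** (m - I)
            * (f_q * binom_sf(v_th, I, f_w * pe) + (1 - f_q) * binom_sf(v_th, I, f_w * po))
            for I in range(m + 1)
        )
        assert abs(p_favg(params) - direct) <= 1e-9
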