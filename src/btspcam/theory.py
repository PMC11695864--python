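"""Closed-form theory of the memory traces created by binary BTSP.

The analysis rests on a parity argument: starting from weight 0, a synapse is
strong after learning iff it was flipped an odd number of times, and flip
events across the M one-shot presentations are (approximately) independent
Bernoulli trials.  The probability that a Binomial(N, p) count is even is
(1 + (1-2p)^N)/2 (the parity lemma), which yields:

* ``p_e`` / ``p_o`` — probability that a synapse from an active input is
  strong at recall, conditioned on the memory neuron having (resp. not
  having) had a plasticity event for the item;
* ``p_f1`` / ``p_f2`` — firing probabilities given the item's support size,
  as binomial survival functions at the firing threshold;
* ``p_favg`` — unconditional firing probability (total probability over the
  support-size distribution);
* ``expected_hd_masked`` / ``expected_hd_pairs`` — expected Hamming distances
  between traces of an item and its masked cue, and between traces of two
  distinct items;
* ``overlapping_predictions`` — the same three quantities for ensembles
  sharing c common 1's, where the common-bit synapses of a neuron share one
  parity variable and contribute an all-or-nothing Binomial(c, f_w) block to
  the weighted sum;
* ``optimize_threshold`` — the integer threshold minimizing the predicted
  relative dissimilarity at a reference masking fraction.

``expected_hd_masked`` factorizes the joint event "fires for the full item,
silent for the masked cue" into a product of marginals, which systematically
overestimates the distance when the two sums are strongly correlated.  The
``effective_*`` variants provide this package's sharper prediction: the
masked-cue sum and its complement from the masked-out bits are independent
binomials, so the joint can be computed exactly by convolution; they also use
the effective plasticity-event rate f_q * p_update as the mixture weight,
matching the stochastic rule (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom

__all__ = [
    "TheoryParams",
    "prob_even",
    "prob_odd",
    "p_e",
    "p_o",
    "p_f1",
    "p_f2",
    "p_favg",
    "expected_hd_masked",
    "expected_hd_pairs",
    "p_hat_e",
    "p_hat_o",
    "OverlapPredictions",
    "overlapping_predictions",
    "optimize_threshold",
    "effective_p_favg",
    "effective_expected_hd_masked",
    "effective_expected_hd_pairs",
]

#: half-widths of the support-size summation window, in binomial SDs.  The
#: neglected tail mass is below 2*exp(-10**2/2) ~ 4e-22 (Hoeffding), far under
#: double-precision resolution of the reported sums.
_I_WINDOW_SDS = 10.0


@dataclass(frozen=True)
class TheoryParams:
    """All parameters of the closed-form analysis.

    m, n        input / memory population sizes
    M           number of stored items
    f_p         input density (fraction of 1's per item)
    f_q         plateau-potential probability per neuron per item
    f_w         connection probability
    f_d         masking fraction of recall cues
    v_th        integer firing threshold (strict ">")
    c           number of common 1's shared by all items (0 = random items)
    p_update    update probability of the stochastic rule (0.5)
    """

    m: int
    n: int
    M: int
    f_p: float
    f_q: float
    f_w: float
    f_d: float = 0.33
    v_th: int = 1
    c: int = 0
    p_update: float = 0.5

    def __post_init__(self) -> None:
        for name in ("f_p", "f_q", "f_w", "f_d", "p_update"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.m < 1 or self.n < 1 or self.M < 1:
            raise ValueError("m, n, M must be >= 1")
        if self.c < 0 or self.c >= self.m:
            raise ValueError("c must satisfy 0 <= c < m")
        if self.v_th < 0:
            raise ValueError("v_th must be >= 0")
        if not (0.0 <= self.f_hat_p <= 1.0):
            raise ValueError("c inconsistent with (m, f_p): remaining density out of [0, 1]")

    @property
    def f_hat_p(self) -> float:
        """Density of the non-common bits keeping the mean ones count at m*f_p."""
        return (self.m * self.f_p - self.c) / (self.m - self.c)


def _pow_1m(x: float, N: float) -> float:
    """(1 - x)^N computed in log space; exact at the edge cases."""
    if N == 0:
        return 1.0
    if x >= 1.0:
        return 0.0
    return math.exp(N * math.log1p(-x))


def prob_even(N: int, p: float) -> float:
    """P(Binomial(N, p) is even) = (1 + (1-2p)^N) / 2."""
    if N < 0:
        raise ValueError("N must be >= 0")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if 2.0 * p <= 1.0:
        base_pow = _pow_1m(2.0 * p, N)
    else:
        base_pow = (-1.0 if N % 2 else 1.0) * _pow_1m(2.0 - 2.0 * p, N)
    return 0.5 * (1.0 + base_pow)


def prob_odd(N: int, p: float) -> float:
    """P(Binomial(N, p) is odd)."""
    return 1.0 - prob_even(N, p)


def p_e(M: int, f_p: float, f_q: float) -> float:
    """Probability that a synapse from an active input is strong at recall,
    given the neuron had a plasticity event for the item:
    (1 + (1 - f_p f_q)^(M-1)) / 2."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return 0.5 * (1.0 + _pow_1m(f_p * f_q, M - 1))


def p_o(M: int, f_p: float, f_q: float) -> float:
    """Complement of ``p_e``: the neuron had no event for the item."""
    return 0.5 * (1.0 - _pow_1m(f_p * f_q, M - 1))


def p_f1(I, v_th: int, f_w: float, pe: float):
    """P(weighted sum > v_th | support size I, plateau): Binomial(I, f_w*p_e)
    survival function at v_th."""
    return binom.sf(v_th, I, f_w * pe)


def p_f2(I, v_th: int, f_w: float, po: float):
    """As ``p_f1`` for neurons without a plasticity event for the item."""
    return binom.sf(v_th, I, f_w * po)


def _support_grid(n_trials: int, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Support sizes within +-10 SD of the mean and their binomial pmf."""
    mean = n_trials * p
    sd = math.sqrt(max(n_trials * p * (1.0 - p), 1.0))
    lo = max(0, int(math.floor(mean - _I_WINDOW_SDS * sd)))
    hi = min(n_trials, int(math.ceil(mean + _I_WINDOW_SDS * sd)))
    I = np.arange(lo, hi + 1)
    return I, binom.pmf(I, n_trials, p)


def _kept_ones(I: np.ndarray, f_d: float) -> np.ndarray:
    """Ones remaining in a masked cue: I minus round-half-even(f_d * I),
    matching the simulator's masked count."""
    return I - np.round(f_d * I).astype(np.int64)


def p_favg(params: TheoryParams) -> float:
    """Unconditional firing probability of a memory neuron for a stored item
    (total-probability mixture of ``p_f1``/``p_f2`` over support sizes)."""
    pe = p_e(params.M, params.f_p, params.f_q)
    po = p_o(params.M, params.f_p, params.f_q)
    I, pmf = _support_grid(params.m, params.f_p)
    mix = params.f_q * p_f1(I, params.v_th, params.f_w, pe) + (1.0 - params.f_q) * p_f2(
        I, params.v_th, params.f_w, po
    )
    return float(np.sum(pmf * mix))


def expected_hd_masked(params: TheoryParams) -> float:
    """Expected Hamming distance between the traces of an item and its masked
    cue (product-of-marginals approximation of the joint firing event)."""
    pe = p_e(params.M, params.f_p, params.f_q)
    po = p_o(params.M, params.f_p, params.f_q)
    I, pmf = _support_grid(params.m, params.f_p)
    Im = _kept_ones(I, params.f_d)
    v = params.v_th
    term_e = binom.cdf(v, Im, params.f_w * pe) * binom.sf(v, I, params.f_w * pe)
    term_o = binom.cdf(v, Im, params.f_w * po) * binom.sf(v, I, params.f_w * po)
    return float(params.n * np.sum(pmf * (params.f_q * term_e + (1.0 - params.f_q) * term_o)))


def expected_hd_pairs(params: TheoryParams) -> float:
    """Expected Hamming distance between traces of two distinct random items:
    2 n p_favg (1 - p_favg)."""
    p = p_favg(params)
    return 2.0 * params.n * p * (1.0 - p)


# ---------------------------------------------------------------------------
# overlapping memory items


def p_hat_e(s: int, f_hat_p: float) -> float:
    """Strong-synapse probability for a non-common active input, conditioned
    on the neuron's plasticity-event count s (which includes the item's own
    event; s >= 1): (1 + (1 - f_hat_p)^(s-1)) / 2."""
    if s < 1:
        raise ValueError("conditioning on the item's own event requires s >= 1")
    return 0.5 * (1.0 + _pow_1m(f_hat_p, s - 1))


def p_hat_o(s: int, f_hat_p: float) -> float:
    """As ``p_hat_e`` for a neuron with s events, none of them the item's own:
    (1 - (1 - f_hat_p)^s) / 2."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return 0.5 * (1.0 - _pow_1m(f_hat_p, s))


@dataclass(frozen=True)
class OverlapPredictions:
    p_favg: float
    expected_hd_masked: float
    expected_hd_pairs: float


def _sf_block_sum(v: int, c: int, p_block: float, J: np.ndarray, p_rest: float) -> np.ndarray:
    """P(A + B > v) for A ~ Binomial(c, p_block), B ~ Binomial(J, p_rest),
    vectorized over the array of B trial counts J."""
    if c == 0:
        return binom.sf(v, J, p_rest)
    a = np.arange(0, min(c, v) + 1)
    pmf_a = binom.pmf(a, c, p_block)
    sf_b = binom.sf(v - a[None, :], J[:, None], p_rest)  # (len(J), len(a))
    out = sf_b @ pmf_a
    out += binom.sf(v, c, p_block)  # A alone already exceeds v (a > v terms)
    return out


def _cdf_block_sum(v: int, c: int, p_block: float, J: np.ndarray, p_rest: float) -> np.ndarray:
    return 1.0 - _sf_block_sum(v, c, p_block, J, p_rest)


def overlapping_predictions(params: TheoryParams) -> OverlapPredictions:
    """Firing probability and expected HDs for items with c common 1's.

    Every item contains the same c common 1-positions, so within one memory
    neuron all c common-bit synapses are updated by exactly the same
    plasticity events and share a single parity: with the parity odd they are
    all strong and contribute a Binomial(c, f_w) block to the weighted sum,
    otherwise they contribute nothing.  The remaining bits (density f_hat_p)
    behave like random-item synapses with f_p replaced by f_hat_p.  With
    c = 0 every formula reduces exactly to the random-item expressions.
    """
    c = params.c
    fq, fw, v = params.f_q, params.f_w, params.v_th
    fhp = params.f_hat_p
    # non-common bits: marginalizing the event-count distribution reproduces
    # the random-item conditional probabilities with density f_hat_p
    pe = 0.5 * (1.0 + _pow_1m(fhp * fq, params.M - 1))
    po = 0.5 * (1.0 - _pow_1m(fhp * fq, params.M - 1))
    # shared parity of the common-bit block: the item's own event contributes
    # one update deterministically; each other item contributes one with
    # probability f_q * p_update
    q_eff = fq * params.p_update
    odd_e = 0.5 * (1.0 + _pow_1m(2.0 * q_eff, params.M - 1))
    odd_o = 0.5 * (1.0 - _pow_1m(2.0 * q_eff, params.M - 1))

    J, pmf = _support_grid(params.m - c, fhp)  # non-common ones per item
    I = J + c
    kept = _kept_ones(I, params.f_d)
    c_kept = int(np.round(c * (1.0 - params.f_d)))
    J_kept = np.clip(kept - c_kept, 0, None)

    def branch(p_syn: float, odd: float):
        full_f = _sf_block_sum(v, c, fw, J, fw * p_syn)
        full_nb = binom.sf(v, J, fw * p_syn)
        mask_f = _cdf_block_sum(v, c_kept, fw, J_kept, fw * p_syn)
        mask_nb = binom.cdf(v, J_kept, fw * p_syn)
        fire = odd * full_f + (1.0 - odd) * full_nb
        # parity is shared between the full and the masked evaluation
        hd = odd * full_f * mask_f + (1.0 - odd) * full_nb * mask_nb
        return fire, hd

    fire_e, hd_e = branch(pe, odd_e)
    fire_o, hd_o = branch(po, odd_o)
    pf = float(np.sum(pmf * (fq * fire_e + (1.0 - fq) * fire_o)))
    ehd_masked = float(params.n * np.sum(pmf * (fq * hd_e + (1.0 - fq) * hd_o)))

    # pairwise HD: mix the firing probability over the shared parity state
    odd_shared = fq * odd_e + (1.0 - fq) * odd_o
    pf_odd = float(np.sum(pmf * (fq * _sf_block_sum(v, c, fw, J, fw * pe)
                                 + (1.0 - fq) * _sf_block_sum(v, c, fw, J, fw * po))))
    pf_even = float(np.sum(pmf * (fq * binom.sf(v, J, fw * pe)
                                  + (1.0 - fq) * binom.sf(v, J, fw * po))))
    ehd_pairs = 2.0 * params.n * (
        odd_shared * pf_odd * (1.0 - pf_odd) + (1.0 - odd_shared) * pf_even * (1.0 - pf_even)
    )
    return OverlapPredictions(p_favg=pf, expected_hd_masked=ehd_masked,
                              expected_hd_pairs=float(ehd_pairs))


def optimize_threshold(
    params: TheoryParams,
    f_d: float = 0.33,
    M: int | None = None,
    v_max: int = 200,
) -> int:
    """Integer threshold minimizing the predicted relative dissimilarity
    (expected masked HD / expected pairwise HD) at masking fraction ``f_d``
    and load ``M`` (default: the params' own M).  Ties break toward the
    smaller threshold."""
    M = params.M if M is None else M
    best_v, best_obj = None, math.inf
    for v in range(1, v_max + 1):
        pp = replace(params, v_th=v, f_d=f_d, M=M)
        if pp.c > 0:
            pred = overlapping_predictions(pp)
            num, den = pred.expected_hd_masked, pred.expected_hd_pairs
        else:
            num, den = expected_hd_masked(pp), expected_hd_pairs(pp)
        if den <= 0.0:
            continue
        obj = num / den
        if obj < best_obj:
            best_v, best_obj = v, obj
    if best_v is None:
        raise RuntimeError("all thresholds gave a degenerate predicted ratio")
    return best_v


# ---------------------------------------------------------------------------
# effective-rate refinements (this package's sharper predictions; see
# docs/methods.md).  The stochastic rule commits a plasticity event in a
# neuron with probability phi = f_q * p_update per item.  Conditioned on a
# neuron's event count s (Binomial over the other M-1 items), its synapses
# from active inputs are strong independently with probability
# (1 +- (1-2 f_p)^s)/2 (+ when the item's own event occurred), so the
# weighted sums are exactly binomial given s.  Marginalizing over s instead
# of plugging in the mean active probability captures the heavy leak of
# high-event-count neurons, and the joint "fires for the full item, silent
# for the masked cue" event is computed exactly (the masked-cue sum and the
# masked-out bits' contribution are independent binomials).


def _phi(params: TheoryParams) -> float:
    return params.f_q * params.p_update


def _event_count_grid(params: TheoryParams) -> tuple[np.ndarray, np.ndarray]:
    phi = _phi(params)
    s, pmf = _support_grid(params.M - 1, phi) if params.M > 1 else (np.array([0]), np.array([1.0]))
    return s, pmf


def _active_probs(params: TheoryParams, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strong-synapse probabilities given the event count s, with and without
    the item's own event."""
    base = np.exp(s * np.log1p(-2.0 * params.f_p)) if params.f_p < 0.5 else (
        np.sign(1.0 - 2.0 * params.f_p) ** s * np.exp(s * np.log(abs(1.0 - 2.0 * params.f_p)))
        if params.f_p != 0.5
        else np.where(s == 0, 1.0, 0.0)
    )
    return 0.5 * (1.0 + base), 0.5 * (1.0 - base)


def effective_p_favg(params: TheoryParams) -> float:
    """Firing probability under the effective event rate, marginalized over
    the per-neuron event count."""
    phi = _phi(params)
    s, pmf_s = _event_count_grid(params)
    pe_s, po_s = _active_probs(params, s)
    I, pmf_I = _support_grid(params.m, params.f_p)
    sf_e = binom.sf(params.v_th, I[None, :], params.f_w * pe_s[:, None])
    sf_o = binom.sf(params.v_th, I[None, :], params.f_w * po_s[:, None])
    per_s = phi * (sf_e @ pmf_I) + (1.0 - phi) * (sf_o @ pmf_I)
    return float(pmf_s @ per_s)


def _joint_fire_full_fail_masked(
    v: int, I: np.ndarray, Im: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """P(sum_full > v and sum_masked <= v), exactly, for each event count.

    ``p`` is the per-synapse strong probability per event count (len S); the
    result has shape (len S, len I)."""
    k = np.arange(0, v + 1)
    pmf_masked = binom.pmf(k[None, None, :], Im[None, :, None], p[:, None, None])
    sf_extra = binom.sf(v - k[None, None, :], (I - Im)[None, :, None], p[:, None, None])
    return np.sum(pmf_masked * sf_extra, axis=2)


def effective_expected_hd_masked(params: TheoryParams) -> float:
    """Expected masked-cue HD with exact joint firing events, marginalized
    over the per-neuron event count."""
    phi = _phi(params)
    s, pmf_s = _event_count_grid(params)
    pe_s, po_s = _active_probs(params, s)
    I, pmf_I = _support_grid(params.m, params.f_p)
    Im = _kept_ones(I, params.f_d)
    v = params.v_th
    term_e = _joint_fire_full_fail_masked(v, I, Im, params.f_w * pe_s)
    term_o = _joint_fire_full_fail_masked(v, I, Im, params.f_w * po_s)
    per_s = phi * (term_e @ pmf_I) + (1.0 - phi) * (term_o @ pmf_I)
    return float(params.n * (pmf_s @ per_s))


def effective_expected_hd_pairs(params: TheoryParams) -> float:
    """Expected pairwise HD, marginalizing the shared event count: traces of
    two items disagree at a neuron with event count s with probability
    2 p(s) (1 - p(s))."""
    phi = _phi(params)
    s, pmf_s = _event_count_grid(params)
    pe_s, po_s = _active_probs(params, s)
    I, pmf_I = _support_grid(params.m, params.f_p)
    sf_e = binom.sf(params.v_th, I[None, :], params.f_w * pe_s[:, None])
    sf_o = binom.sf(params.v_th, I[None, :], params.f_w * po_s[:, None])
    p_s = phi * (sf_e @ pmf_I) + (1.0 - phi) * (sf_o @ pmf_I)
    return float(2.0 * params.n * (pmf_s @ (p_s * (1.0 - p_s))))
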