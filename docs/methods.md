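# Methods

## The model

Memory items are sparse binary vectors **x** of length m (input density f_p:
each bit is 1 independently with probability f_p).  A pool of n disconnected
McCulloch–Pitts memory neurons receives the items through a random binary
connectivity mask (connection probability f_w) and binary synaptic weights
W ∈ {0,1}^{n×m}, initialised to zero.  The memory trace of an item is
z(**x**) with z_j = 1 iff Σ_i w_ji x_i > v_th (strict inequality; ties do not
fire).

Learning is one-shot: each item is presented once, in sequence.  When item
**x** is presented, each memory neuron independently receives a plateau
potential with probability f_q.  A plateau opens a seconds-long plasticity
window; whether the item's synaptic input falls into the potentiating or the
depressing part of that window is stochastic, and with probability
p_update = 0.5 the weights of that neuron's synapses from active inputs
(x_i = 1, connected) are *flipped*: 0 → 1 (LTP) if currently weak, 1 → 0
(LTD) if currently strong.  Neither direction depends on postsynaptic firing.

### Gating granularity

The update coin is drawn **once per (neuron, item)** by default
(`PlasticityConfig(gating="neuron")`): the item's arrival time relative to
*this* neuron's plateau onset is a single quantity, so all of the neuron's
active synapses share the outcome.  This choice makes the stochastic rule
exactly equivalent in law to the deterministic "core" rule (flip always)
driven at plateau probability f_q/2 — an equivalence the package tests
directly.  A per-synapse coin (`gating="synapse"`) is also provided; it
leaves all *unconditional* statistics unchanged (per-synapse flip counts are
identical in distribution) but halves the conditional active-weight
probability of a recruited neuron's synapses to exactly 1/2, which destroys
the margin between the full-cue and masked-cue input sums and with it
masked-cue recall.  An asymmetric variant with separate LTP/LTD flip
probabilities conditions the coin on the current weight.

## The parity theory

Because weights are binary and start at zero, a synapse is strong after
learning iff it was flipped an odd number of times.  Flip events at synapse
(j, i) across the M items are Bernoulli trials: the item's own presentation
contributes one event when neuron j commits a plasticity event for it, and
each of the other M−1 items contributes one with probability f_p·f_q/2.  The
parity lemma P(Binomial(N, p) even) = (1 + (1−2p)^N)/2 then gives the
marginal active-weight probabilities

- p_e = (1 + (1−f_p f_q)^{M−1})/2, conditioned on the neuron's own event,
- p_o = (1 − (1−f_p f_q)^{M−1})/2 otherwise,

firing probabilities as binomial survival functions
p_f1 = 1 − F(v_th; I, f_w p_e) and p_f2 = 1 − F(v_th; I, f_w p_o) given the
item's support size I, the unconditional firing probability p_favg by total
probability over I ~ Binomial(m, f_p), the expected masked-cue Hamming
distance as a product of marginal fire/fail probabilities, and the expected
pairwise distance 2 n p_favg (1 − p_favg).  These marginal forms are
implemented verbatim in `theory.p_e/p_o/p_f1/p_f2/p_favg/expected_hd_*`.

Numerics: (1−x)^N is evaluated in log space (stable at m = 2.5×10⁶,
M = 800,000); the I-summation is truncated to ±10 binomial SDs around the
mean (neglected tail mass < 4×10⁻²²); the non-integer masked trial count
I(1−f_d) is realised as I minus the round-half-to-even of f_d·I, matching
the cue generator exactly.

### Internal inconsistency of the marginal forms, and the refined predictions

The conditional probability p_e is derived given that the item's own update
*occurred* — an event of probability f_q·p_update per neuron — while the
mixture weights in the firing and distance formulas use f_q.  No memoryless
binary rule realises both simultaneously: matching p_e/p_o and the
strong-weight density (1−(1−f_p f_q)^M)/2 forces the effective recruitment
rate φ = f_q·p_update, making the simulated trace size about half the
marginal-form prediction.  The product-of-marginals approximation in the
masked-distance formula additionally overestimates the distance wherever the
full-cue and masked-cue sums are strongly correlated (always, since one
contains the other).

The package therefore also provides `theory.effective_*`, its own refined
predictions, which are **exact** for the default rule:

1. the mixture weight is φ = f_q·p_update;
2. the per-neuron plasticity-event count s ~ Binomial(M−1, φ) is
   marginalized explicitly instead of plugging its mean into the parity
   formula — conditional on s the synapses are i.i.d. with active
   probability (1 ± (1−2 f_p)^s)/2, so the weighted sums are exactly
   binomial given s, and the heavy leak of high-event-count neurons is
   captured (a Jensen effect the marginal forms miss);
3. the joint event "fires for the full item, silent for the masked cue" is
   computed exactly: the masked-cue sum and the masked-out bits' contribution
   are independent binomials, so the joint is a short convolution.

At the reduced preset the refined predictions agree with simulation within
~1.5 SE for trace size, strong-weight fraction, masked-cue distance and
pairwise distance across loads (see `tests/test_network.py`), while the
marginal forms agree for the strong-weight fraction only.  Both sets are
reported side by side by `experiments.run_masking_sweep`
(`pred_*` vs `pred_*_eff` columns).

### Overlapping items

Ensembles sharing c = ⌊m f_c f_p⌋ common 1's are generated with the
remaining bits at density f̂_p = (m f_p − c)/(m − c), keeping the expected
ones count at m f_p.  Within one memory neuron all c common-bit synapses are
updated by exactly the same events and share one parity: with the parity odd
they contribute an all-or-nothing Binomial(c, f_w) block to the weighted
sum.  `theory.overlapping_predictions` mixes that block over the parity
state (own event deterministic for the conditioned branch, rate f_q·p_update
per other item), treats the non-common bits through the marginal
probabilities with f_p → f̂_p, and keeps the parity state shared between the
full-cue and masked-cue evaluations of the same neuron.  With c = 0 every
expression reduces to the random-item formulas at machine precision (tested).

## Threshold selection

`theory.optimize_threshold` scans integer thresholds and minimizes the
predicted relative dissimilarity (expected masked-cue HD divided by expected
pairwise HD) at a reference masking fraction of 0.33 and the maximal load,
ties broken toward the smaller threshold.  The repulsion protocol does not
use masked cues, so its threshold is instead placed midway between the two
theory-derived input-sum clusters that the effect depends on: the intact
trace mean f_w·ι·p_e and the LTD-depressed mean f_w·(c·p_o + (ι−c)·p_e) of a
neuron recruited by both items of a similar pair (ι = m·f_p ones per item,
c the pair's common ones).

## Synthetic data and what it does/doesn't show

All inputs are synthetic: i.i.d. sparse Bernoulli items, overlap-constructed
ensembles, masked cues (exactly round(f_d·ι) ones removed, uniformly without
replacement), two-sided noisy cues (the same removals plus Bernoulli
additions calibrated so the expected ones count is unchanged), and 50×50
binary line drawings (five axis-aligned 8-pixel segments per image; the last
two images form a planted pair sharing exactly three segments; the masking
helper zeroes the last 20 rows).  Real population codes have correlations,
rate (not binary) coding, and structured overlap that none of these
generators emulate; passing tests demonstrate the internal consistency of
rule, theory and baselines under the stated generative assumptions, not
performance on biological recordings.

## Scales

Defaults follow the biology: m = 25,000 and n = 39,000 (a 1/10-scale rat
CA3→CA1), f_p = 0.005, f_q = 0.005 (plateau rate ≈ 5×10⁻⁴/s × 10 s window),
f_w = 0.6 (≈15,000 synapses per memory neuron).  All tests and the
acceptance runs use a reduced preset m = 2,500, n = 3,900, f_p = 0.02,
f_q = 0.01, M ≤ 2,000, which keeps the ones per item (50), plateaus per item
(39) and threshold-to-fan-in ratios proportionate so the closed forms remain
the oracle while a full run takes seconds.  Two deliberate departures:

- the repulsion runs keep the full-scale ones count ι = 125 (m = 6,250 at
  f_p = 0.02) with the reduced memory layer, because at ι = 50 the
  depressed/intact cluster gap shrinks below ~1.5 binomial SDs and the
  effect cannot be resolved at any threshold; several pairs (20) are planted
  per sequence and averaged within a trial because a single pair's trace
  overlap at n = 3,900 is an integer of order one;
- the brain-scale analysis (m = 2.5×10⁶, f_p = 5×10⁻⁵, M up to 800,000,
  two-thirds masking) is closed-form only; `run_scaleup(simulate=True)` is
  refused.

The completion runs fit the adaptive linear thresholds (v = α·x + β with x
the cues' mean ones fraction, per layer) by grid-scanning threshold pairs on
a 20% item sample per masking fraction; at the reduced scale the scan covers
[1, 50] (the fan-in bounds useful thresholds well below 50) with up to 50
sampled items.

## Baselines

The random projection control is a fixed binary matrix drawn on the same
connectivity paradigm with its weight density matched to the learned BTSP
strong-weight density, read out either through a grid-searched fixed
threshold (criterion: minimal relative dissimilarity at f_d = 0.33, the same
criterion as for BTSP) or through a Top-K competition with K = ⌊n f_q⌋ (ties
to the lowest index; zero cues give zero traces).  The Hopfield baseline
stores the input patterns themselves with the covariance rule
w_ji = (1/m) Σ_h (x_hi − f_p)(x_hj − f_p), zero diagonal, optionally pruned
by a symmetric mask, and is recalled by synchronous thresholded updates
(≤100 iterations, fixed points and 2-cycles detected); its state threshold
is grid-searched over 101 values on [0, 0.02] maximizing the count of items
recalled within HD ≤ m·0.001 from one-third-masked cues.  Sign-binarization
of the Hopfield weights preserves zeros and the mean nonzero magnitude so
the same threshold grid applies; note that with sparse 0/1 patterns the
binarized variant is not reliably worse than the continuous one at testable
scale (clipping the many small negative weights yields a strong uniform
inhibition, Willshaw-style), so no test asserts a capacity collapse.
Generic-readout robustness uses thresholded linear readouts with integer
weights uniform on [−8, 8] and threshold 0, averaged over 20 readouts.

## Known limitations

- The continuous-weight biophysical plasticity rule is out of scope; only
  binary weights (optionally several binary release sites per connection)
  are modelled.
- The theory module's marginal forms are the model's published face but are
  internally inconsistent by the recruitment factor described above; use the
  `effective_*` refinements for quantitative comparison with simulation.
- The pairwise-distance denominator is estimated from 1,000 sampled distinct
  pairs (unbiased; the full M² average is wasteful).
- Feedback completion uses a single reconstruction step; no iterated
  feedforward–feedback cycling.
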