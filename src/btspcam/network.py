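"""Feedforward recall and trace-level metrics.

Memory neurons are disconnected McCulloch–Pitts units: neuron j fires for cue
x iff its weighted input sum exceeds the firing threshold strictly
(sum_i w_ji x_i > v_th).  The memory trace z(x) is the binary vector of
firing neurons.  Metrics defined here: Hamming distance, relative
dissimilarity (the masked-cue HD scaled by the mean HD between traces of
distinct stored items; 0.5 means the cue's trace is indistinguishable from an
unrelated item's trace), trace size, strong-weight fraction, trace overlap
ratio and the repulsion index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BTSPNetwork",
    "DegenerateResultError",
    "build_connectivity",
    "recall",
    "recall_many",
    "weighted_sums",
    "hamming",
    "relative_dissimilarity",
    "trace_size",
    "strong_weight_fraction",
    "overlap_ratio",
    "repulsion_index",
    "weighted_sum_histogram",
]


class DegenerateResultError(RuntimeError):
    """A metric's denominator is zero (e.g. no two traces ever differ)."""


@dataclass
class BTSPNetwork:
    """Binary feedforward network: (n, m) connectivity mask, (n, m) binary
    weights constrained to the mask, and an integer firing threshold."""

    mask: np.ndarray
    W: np.ndarray
    v_th: int

    def __post_init__(self) -> None:
        if self.W.shape != self.mask.shape:
            raise ValueError("weights and connectivity mask must share a shape")
        if self.v_th < 0:
            raise ValueError("v_th must be >= 0")
        if np.any(self.W.astype(bool) & ~self.mask.astype(bool)):
            raise ValueError("weights present outside the connectivity mask")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    def effective_weights(self) -> np.ndarray:
        return (self.W.astype(np.uint8) & self.mask.astype(np.uint8))


def build_connectivity(m: int, n: int, f_w: float, seed: int) -> np.ndarray:
    """(n, m) boolean connectivity mask, entries i.i.d. Bernoulli(f_w)."""
    if not (0.0 <= f_w <= 1.0):
        raise ValueError("f_w must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random((n, m)) < f_w


def weighted_sums(net: BTSPNetwork, X: np.ndarray) -> np.ndarray:
    """Weighted input sums u(x) for one cue (m,) or a batch (M, m)."""
    X = np.atleast_2d(np.asarray(X))
    if X.shape[1] != net.m:
        raise ValueError(f"cue length {X.shape[1]} != m={net.m}")
    # float32 GEMM is far faster than integer matmul at these sizes and exact
    # for sums below 2**24.
    U = X.astype(np.float32) @ net.effective_weights().T.astype(np.float32)
    return U.astype(np.int64)


def recall(net: BTSPNetwork, x: np.ndarray) -> np.ndarray:
    """Memory trace z(x): z_j = 1 iff sum_i w_ji x_i > v_th (strict)."""
    return (weighted_sums(net, x)[0] > net.v_th).astype(np.uint8)


def recall_many(net: BTSPNetwork, X: np.ndarray) -> np.ndarray:
    """Traces for a batch of cues, shape (M, n)."""
    return (weighted_sums(net, X) > net.v_th).astype(np.uint8)


def hamming(z1: np.ndarray, z2: np.ndarray) -> int:
    """Hamming distance between two binary vectors."""
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("vectors must share a shape")
    return int(np.count_nonzero(z1 != z2))


def mean_pairwise_hd(traces: np.ndarray, n_pairs: int = 1000, seed: int = 0) -> float:
    """Mean Hamming distance between traces of distinct stored items,
    estimated from ``n_pairs`` uniformly sampled distinct pairs."""
    M = traces.shape[0]
    if M < 2:
        raise ValueError("need at least two traces")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, M, size=n_pairs)
    b = rng.integers(0, M - 1, size=n_pairs)
    b = np.where(b >= a, b + 1, b)  # distinct by construction
    return float((traces[a] != traces[b]).sum(axis=1).mean())


def relative_dissimilarity(
    net: BTSPNetwork,
    ensemble,
    cues: np.ndarray,
    n_pairs: int = 1000,
    seed: int = 0,
    traces: np.ndarray | None = None,
) -> float:
    """HD(z(x), z(x')) averaged over items, divided by the mean HD between
    traces of two distinct stored items.

    ``cues`` is an (M, m) array paired row-by-row with the ensemble's items.
    All traces are computed with the final weights (after the whole sequence
    has been learned).  Values well below 0.5 mean the cue's trace still
    identifies the stored item.
    """
    items = ensemble.items if hasattr(ensemble, "items") else np.asarray(ensemble)
    if traces is None:
        traces = recall_many(net, items)
    cue_traces = recall_many(net, np.asarray(cues))
    if cue_traces.shape != traces.shape:
        raise ValueError("cues must pair one-to-one with stored items")
    numerator = float((traces != cue_traces).sum(axis=1).mean())
    denominator = mean_pairwise_hd(traces, n_pairs=n_pairs, seed=seed)
    if denominator == 0.0:
        raise DegenerateResultError("all stored items map to identical traces")
    return numerator / denominator


def trace_size(net: BTSPNetwork, ensemble) -> float:
    """Mean number of memory neurons firing for the full (unmasked) items."""
    items = ensemble.items if hasattr(ensemble, "items") else np.asarray(ensemble)
    return float(recall_many(net, items).sum(axis=1).mean())


def strong_weight_fraction(net: BTSPNetwork) -> float:
    """Fraction of existing connections whose weight is 1."""
    mask = net.mask.astype(bool)
    total = int(mask.sum())
    if total == 0:
        return 0.0
    return float(net.W.astype(bool)[mask].mean())


def overlap_ratio(z1: np.ndarray, z2: np.ndarray, ensemble_traces: np.ndarray) -> float:
    """Number of common 1's of two traces divided by the mean ones count per
    trace over the whole ensemble (the trace-similarity measure of the
    repulsion analysis)."""
    mean_ones = float(np.asarray(ensemble_traces).sum(axis=1).mean())
    if mean_ones == 0.0:
        raise DegenerateResultError("mean trace size is zero")
    common = float(np.count_nonzero(np.asarray(z1).astype(bool) & np.asarray(z2).astype(bool)))
    return common / mean_ones


def repulsion_index(
    overlap_unrelated: float, overlap_similar: float
) -> float:
    """Overlap ratio of traces of an unrelated pair divided by that of a
    similar (e.g. 40%-overlap) pair.  Values above 1 indicate repulsion:
    similar items were pulled further apart than unrelated ones."""
    if overlap_similar == 0.0:
        raise DegenerateResultError("similar-pair overlap ratio is zero")
    return overlap_unrelated / overlap_similar


def weighted_sum_histogram(
    net: BTSPNetwork,
    ensemble,
    plateau_masks: np.ndarray,
    neuron: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted input sums of one memory neuron for every stored item, split
    by whether the neuron had a plasticity event for that item.

    Returns (sums for plateau items, sums for non-plateau items, separation),
    where separation is the gap between the smallest plateau-item sum and the
    largest non-plateau-item sum (positive = perfectly separable clusters).
    """
    items = ensemble.items if hasattr(ensemble, "items") else np.asarray(ensemble)
    U = weighted_sums(net, items)[:, neuron]
    in_q = np.asarray(plateau_masks)[:, neuron].astype(bool)
    plateau, other = U[in_q], U[~in_q]
    if plateau.size == 0 or other.size == 0:
        sep = float("nan")
    else:
        sep = float(plateau.min() - other.max())
    return plateau, other, sep
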