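"""Baseline memory models: random projections and Hopfield networks.

The random projection (RP) is the non-learned control: a fixed binary matrix
whose 1-density matches the strong-weight density a BTSP network reaches
after learning, followed by a fixed threshold or a Top-K competition.  The
Hopfield network (HFN) is the classical content-addressable memory baseline,
trained with the covariance rule on the same sparse patterns and recalled by
synchronous thresholded updates.  A generic-readout robustness probe measures
how often masking a cue changes the classification of its memory trace by a
random integer-weight linear readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from btspcam.network import DegenerateResultError, mean_pairwise_hd

__all__ = [
    "HopfieldNet",
    "RandomProjection",
    "hfn_store",
    "hfn_recall",
    "hfn_optimize_theta",
    "hfn_binarize",
    "rp_build",
    "rp_recall",
    "rp_recall_many",
    "rp_optimize_threshold",
    "rp_topk",
    "readout_robustness",
]


@dataclass
class HopfieldNet:
    """Recurrent net with continuous symmetric weights, zero diagonal."""

    W: np.ndarray
    theta: float = 0.0
    max_iter: int = 100
    binary: bool = False

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class RandomProjection:
    """Fixed binary projection matrix with a scalar output threshold."""

    R: np.ndarray
    threshold: float = 0.0
    seed: int | None = field(default=None, repr=False)

    @property
    def density(self) -> float:
        return float(self.R.mean())


def _symmetric_mask(n: int, f_w: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < f_w
    mask = np.triu(upper, k=1)
    return mask | mask.T


def hfn_store(patterns, f_p: float, mask: np.ndarray | None = None) -> HopfieldNet:
    """Covariance-rule weights for the stored patterns:
    w_ji = (1/m) * sum_h (x_hi - f_p)(x_hj - f_p), zero diagonal.

    The HFN stores the input patterns themselves, so its state dimension is
    the pattern length m.  ``mask`` optionally prunes connections (symmetric,
    density f_w)."""
    items = patterns.items if hasattr(patterns, "items") else np.asarray(patterns)
    m = items.shape[1]
    centered = items.astype(np.float64) - f_p
    W = (centered.T @ centered) / m
    np.fill_diagonal(W, 0.0)
    if mask is not None:
        W = W * mask
    return HopfieldNet(W=W)


def hfn_binarize(net: HopfieldNet) -> HopfieldNet:
    """Quantize weights to sign * (mean nonzero magnitude), preserving zeros.

    Keeping the original magnitude scale lets the same state-update threshold
    grid apply to the quantized network."""
    nonzero = net.W != 0.0
    scale = float(np.abs(net.W[nonzero]).mean()) if nonzero.any() else 1.0
    Wb = np.sign(net.W) * scale
    return HopfieldNet(W=Wb, theta=net.theta, max_iter=net.max_iter, binary=True)


def hfn_recall(
    net: HopfieldNet, cue: np.ndarray, theta: float | None = None
) -> tuple[np.ndarray, bool]:
    """Synchronous recall: s <- [W s > theta], iterated up to ``max_iter``
    times or until a fixed point; a 2-cycle is detected and flagged.

    Returns (final state, converged)."""
    theta = net.theta if theta is None else theta
    s = np.asarray(cue, dtype=np.float64)
    prev = None
    for _ in range(net.max_iter):
        s_new = (net.W @ s > theta).astype(np.float64)
        if np.array_equal(s_new, s):
            return s_new.astype(np.uint8), True
        if prev is not None and np.array_equal(s_new, prev):
            return s_new.astype(np.uint8), False  # 2-cycle under synchronous updates
        prev, s = s, s_new
    return s.astype(np.uint8), False


def hfn_optimize_theta(
    net: HopfieldNet,
    items: np.ndarray,
    cues: np.ndarray,
    grid: np.ndarray | None = None,
    tol_factor: float = 0.001,
) -> float:
    """State-update threshold maximizing the number of items recalled from
    their masked cues within Hamming distance m * tol_factor.

    The default grid is 101 evenly spaced values on [0, 0.02]."""
    if grid is None:
        grid = np.linspace(0.0, 0.02, 101)
    m = items.shape[1]
    tol = m * tol_factor
    best_theta, best_count = float(grid[0]), -1
    for theta in grid:
        count = 0
        for x, cue in zip(items, cues):
            state, _ = hfn_recall(net, cue, theta=float(theta))
            if np.count_nonzero(state != x) <= tol:
                count += 1
        if count > best_count:
            best_theta, best_count = float(theta), count
    return best_theta


def rp_build(density: float, m: int, n: int, seed: int, f_w: float = 1.0) -> RandomProjection:
    """Binary projection matrix with weight density ``density`` among the
    connections of a Bernoulli(f_w) connectivity mask, mirroring the
    structure of a learned BTSP weight matrix."""
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, m)) < f_w
    R = (mask & (rng.random((n, m)) < density)).astype(np.uint8)
    return RandomProjection(R=R, seed=seed)


def rp_recall_many(rp: RandomProjection, X: np.ndarray, threshold: float | None = None) -> np.ndarray:
    threshold = rp.threshold if threshold is None else threshold
    X = np.atleast_2d(np.asarray(X))
    U = X.astype(np.float32) @ rp.R.T.astype(np.float32)
    return (U > threshold).astype(np.uint8)


def rp_recall(rp: RandomProjection, cue: np.ndarray, threshold: float | None = None) -> np.ndarray:
    return rp_recall_many(rp, cue, threshold=threshold)[0]


def rp_optimize_threshold(
    rp: RandomProjection,
    items: np.ndarray,
    cues: np.ndarray,
    n_pairs: int = 1000,
    seed: int = 0,
) -> float:
    """Grid-search the output threshold minimizing the relative dissimilarity
    between full-item and masked-cue projections (the same criterion used to
    set the BTSP firing threshold)."""
    U_full = np.asarray(items).astype(np.float32) @ rp.R.T.astype(np.float32)
    U_cue = np.asarray(cues).astype(np.float32) @ rp.R.T.astype(np.float32)
    hi = int(U_full.max())
    best_t, best_ratio = None, np.inf
    for t in range(0, hi + 1):
        Z = U_full > t
        Zc = U_cue > t
        den = mean_pairwise_hd(Z, n_pairs=n_pairs, seed=seed)
        if den == 0.0:
            continue
        ratio = float((Z != Zc).sum(axis=1).mean()) / den
        if ratio < best_ratio:
            best_t, best_ratio = t, ratio
    if best_t is None:
        raise DegenerateResultError("no threshold produced distinct traces")
    return float(best_t)


def rp_topk_many(rp: RandomProjection, X: np.ndarray, K: int) -> np.ndarray:
    """Top-K traces for a batch of cues (rows of X); see ``rp_topk``."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X = np.atleast_2d(np.asarray(X))
    U = X.astype(np.float32) @ rp.R.T.astype(np.float32)
    K = min(K, U.shape[1])
    order = np.argsort(-U, axis=1, kind="stable")
    out = np.zeros(U.shape, dtype=np.uint8)
    np.put_along_axis(out, order[:, :K], 1, axis=1)
    out[~X.any(axis=1)] = 0
    return out


def rp_topk(rp: RandomProjection, cue: np.ndarray, K: int) -> np.ndarray:
    """Top-K output: exactly the K units with the largest projection values
    are active (ties broken toward the lowest index); a zero cue gives a zero
    trace."""
    if K < 1:
        raise ValueError("K must be >= 1")
    cue = np.asarray(cue)
    if not cue.any():
        return np.zeros(rp.R.shape[0], dtype=np.uint8)
    u = rp.R.astype(np.int64) @ cue.astype(np.int64)
    K = min(K, u.size)
    # stable sort on descending value, ascending index
    order = np.lexsort((np.arange(u.size), -u))
    out = np.zeros(u.size, dtype=np.uint8)
    out[order[:K]] = 1
    return out


def readout_robustness(
    traces_full: np.ndarray,
    traces_masked: np.ndarray,
    seed: int = 0,
    n_readouts: int = 20,
    weight_range: int = 8,
) -> float:
    """Error rate of a generic downstream classification under cue masking.

    Each readout has integer weights uniform on [-8, 8] and threshold 0; the
    error is the fraction of items whose binary label differs between the
    full-item trace and the masked-cue trace, averaged over readouts."""
    Zf = np.asarray(traces_full, dtype=np.int64)
    Zm = np.asarray(traces_masked, dtype=np.int64)
    if Zf.shape != Zm.shape:
        raise ValueError("trace arrays must pair one-to-one")
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_readouts):
        w = rng.integers(-weight_range, weight_range + 1, size=Zf.shape[1])
        errs.append(float(np.mean((Zf @ w > 0) != (Zm @ w > 0))))
    return float(np.mean(errs))
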