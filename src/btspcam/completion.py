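"""Feedback connections, one-shot Hebbian completion, and input reconstruction.

During learning each item persists for two steps: first the feedforward
weights are updated by BTSP, then the memory trace of the *same* item (with
the current weights) drives a saturating Hebbian update of random feedback
connections from the memory layer back to the input layer.  At recall, a
masked cue evokes a trace which is projected back through the feedback
weights; an input neuron turns on when its feedback sum exceeds a threshold.
The quality measure is the scaled reconstruction error
HD(r(x'), x) / HD(x, x'): values below 1 mean the completed pattern is closer
to the stored item than the cue was.

Both layers' firing thresholds can be set adaptively as a linear function
v = alpha * (mean ones fraction of the cues) + beta, fitted by grid-scanning
threshold pairs at several masking fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from btspcam.network import BTSPNetwork, DegenerateResultError, recall_many
from btspcam.plasticity import PlasticityConfig, PlateauSchedule, _flips_for_item
from btspcam.patterns import mask_pattern

__all__ = [
    "FeedbackNet",
    "LinearThreshold",
    "learn_feedback",
    "learn_with_completion",
    "reconstruct",
    "reconstruct_many",
    "scaled_reconstruction_error",
    "fit_adaptive_thresholds",
]


@dataclass
class FeedbackNet:
    """Binary (m, n) feedback weights constrained to a random connectivity mask."""

    mask: np.ndarray
    W: np.ndarray

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]


@dataclass
class LinearThreshold:
    """Threshold as a linear function of the cues' mean ones fraction."""

    alpha: float
    beta: float

    def __call__(self, ones_fraction: float) -> float:
        return self.alpha * ones_fraction + self.beta


def build_feedback(m: int, n: int, seed: int, density: float = 0.6) -> FeedbackNet:
    rng = np.random.default_rng(seed)
    mask = rng.random((m, n)) < density
    return FeedbackNet(mask=mask, W=np.zeros((m, n), dtype=np.uint8))


def learn_feedback(fb: FeedbackNet, x: np.ndarray, z: np.ndarray) -> FeedbackNet:
    """Saturating Hebb: fb_ij <- min(1, fb_ij + [x_i = 1 and z_j = 1]),
    applied only where a feedback connection exists.  Idempotent for a
    repeated (x, z) pair."""
    x = np.asarray(x).astype(bool)
    z = np.asarray(z).astype(bool)
    if x.shape[0] != fb.m or z.shape[0] != fb.n:
        raise ValueError("item/trace dimensions do not match the feedback net")
    fb.W |= (np.outer(x, z) & fb.mask).astype(np.uint8)
    return fb


def learn_with_completion(
    patterns,
    plateaus: PlateauSchedule,
    ff_mask: np.ndarray,
    v_th_mem: int,
    cfg: PlasticityConfig | None = None,
    seed: int | None = None,
    fb_density: float = 0.6,
) -> tuple[BTSPNetwork, FeedbackNet]:
    """Two-step learning protocol: BTSP on the feedforward weights, then the
    item's own trace (current weights, threshold ``v_th_mem``) drives the
    Hebbian feedback update, before the next item is presented."""
    cfg = cfg or PlasticityConfig()
    items = patterns.items if hasattr(patterns, "items") else np.asarray(patterns)
    M, m = items.shape
    n = plateaus.n
    rng = np.random.default_rng(seed)
    fb = build_feedback(m, n, seed=int(rng.integers(2**31)), density=fb_density)
    W = np.zeros((n, m), dtype=np.uint8)
    for k in range(M):
        rows = np.flatnonzero(plateaus.masks[k])
        eff, flips = _flips_for_item(W, ff_mask, items[k], rows, cfg, rng)
        W[eff] ^= flips.astype(np.uint8)
        supp = np.flatnonzero(items[k])
        u = (W[:, supp] & ff_mask[:, supp]).sum(axis=1, dtype=np.int64)
        z = u > v_th_mem
        learn_feedback(fb, items[k], z)
    net = BTSPNetwork(mask=ff_mask, W=W, v_th=v_th_mem)
    return net, fb


def reconstruct_many(fb: FeedbackNet, Z: np.ndarray, v_f: float) -> np.ndarray:
    """Reconstructed inputs for a batch of traces: r_i = [sum_j fb_ij z_j > v_f]."""
    Z = np.atleast_2d(np.asarray(Z))
    V = Z.astype(np.float32) @ fb.W.T.astype(np.float32)
    return (V > v_f).astype(np.uint8)


def reconstruct(fb: FeedbackNet, z_cue: np.ndarray, v_f: float) -> np.ndarray:
    return reconstruct_many(fb, z_cue, v_f)[0]


def scaled_reconstruction_error(x: np.ndarray, x_cue: np.ndarray, r: np.ndarray) -> float:
    """HD(r, x) / HD(x, x'); < 1 means completion recovered information."""
    x = np.asarray(x)
    denom = int(np.count_nonzero(x != np.asarray(x_cue)))
    if denom == 0:
        raise DegenerateResultError("cue equals the item; scaled error undefined")
    return float(np.count_nonzero(np.asarray(r) != x)) / denom


@dataclass
class ThresholdFits:
    memory: LinearThreshold
    input: LinearThreshold
    scan_points: list[tuple[float, int, int]]  # (ones fraction, best t_mem, best t_in)


def fit_adaptive_thresholds(
    net: BTSPNetwork,
    fb: FeedbackNet,
    ensemble,
    masking_fractions=(0.1, 0.2, 0.33, 0.5),
    sample_fraction: float = 0.2,
    scan_range: tuple[int, int] = (1, 100),
    scan_step: int = 1,
    seed: int = 0,
    max_sample: int | None = None,
) -> ThresholdFits:
    """Fit per-layer linear threshold functions.

    For each masking fraction, a random subset of items is masked and every
    (memory threshold, input threshold) pair in the scan range is evaluated
    by the mean HD(x, r(x')); the best pair and the cues' mean ones fraction
    form one fitting point, and a least-squares line is fitted per layer.
    """
    items = ensemble.items if hasattr(ensemble, "items") else np.asarray(ensemble)
    rng = np.random.default_rng(seed)
    M, m = items.shape
    s = max(2, int(round(sample_fraction * M)))
    if max_sample is not None:
        s = min(s, max_sample)
    Wf = net.effective_weights().T.astype(np.float32)
    lo, hi = scan_range
    t_grid = np.arange(lo, hi + 1, scan_step)
    points: list[tuple[float, int, int]] = []
    for fd in masking_fractions:
        idx = rng.choice(M, size=min(s, M), replace=False)
        cues = np.stack(
            [mask_pattern(items[i], fd, seed=int(rng.integers(2**31))).vector for i in idx]
        )
        ones_frac = float(cues.mean())
        U = cues.astype(np.float32) @ Wf
        best = (np.inf, int(t_grid[0]), int(t_grid[0]))
        for t_mem in t_grid:
            Z = (U > t_mem).astype(np.float32)
            V = Z @ fb.W.T.astype(np.float32)
            for t_in in t_grid:
                hd = float(np.mean(np.sum((V > t_in) != items[idx].astype(bool), axis=1)))
                if hd < best[0]:
                    best = (hd, int(t_mem), int(t_in))
        points.append((ones_frac, best[1], best[2]))
    if np.ptp([p[0] for p in points]) == 0.0:
        raise DegenerateResultError("masking fractions produced identical ones fractions")
    xs = np.array([p[0] for p in points])
    mem_a, mem_b = np.polyfit(xs, np.array([p[1] for p in points], dtype=float), 1)
    in_a, in_b = np.polyfit(xs, np.array([p[2] for p in points], dtype=float), 1)
    return ThresholdFits(
        memory=LinearThreshold(float(mem_a), float(mem_b)),
        input=LinearThreshold(float(in_a), float(in_b)),
        scan_points=points,
    )
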