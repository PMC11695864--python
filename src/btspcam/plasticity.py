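"""The binary BTSP rule and one-shot learning of a pattern sequence.

The rule: when memory neuron j receives a plateau potential while item x is
presented, the weights of its synapses from active inputs (x_i = 1) are
updated — potentiated (0 -> 1) if currently weak, depressed (1 -> 0) if
currently strong.  Whether the update happens at all is stochastic: the
item's arrival time falls into the potentiating/depressing part of the
roughly 10 s plasticity window opened by the plateau with probability
``p_update`` (default 0.5), otherwise nothing changes.

Two gating granularities are supported.  The default, ``gating="neuron"``,
draws the update coin once per (neuron, item): the pattern arrives at one
time relative to that neuron's plateau onset, so all of the neuron's active
synapses share the outcome.  This makes the stochastic rule exactly
equivalent in law to the deterministic "core" rule applied with half the
plateau probability.  ``gating="synapse"`` draws an independent coin per
synapse, the simplifying assumption used in the closed-form analysis.

An asymmetric variant with separate LTP/LTD probabilities (``p_ltp``,
``p_ltd``) conditions the coin on the current weight; it is always resolved
per synapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from btspcam.network import BTSPNetwork

__all__ = [
    "PlateauSchedule",
    "PlasticityConfig",
    "draw_plateaus",
    "btsp_step",
    "core_btsp_step",
    "learn_sequence",
    "LearnResult",
    "multi_release_site_change",
]


@dataclass
class PlateauSchedule:
    """Per-item plateau-potential masks Q(x): (M, n) boolean, i.i.d. Bernoulli(f_q)."""

    masks: np.ndarray
    f_q: float
    seed: int | None = None

    @property
    def M(self) -> int:
        return self.masks.shape[0]

    @property
    def n(self) -> int:
        return self.masks.shape[1]

    def halved(self, seed: int) -> "PlateauSchedule":
        """Thin the schedule by keeping each plateau with probability 1/2.

        Used to drive the core rule at the effective rate f_q/2."""
        rng = np.random.default_rng(seed)
        keep = rng.random(self.masks.shape) < 0.5
        return PlateauSchedule(masks=self.masks & keep, f_q=self.f_q / 2.0, seed=seed)


@dataclass
class PlasticityConfig:
    rule: str = "eq1"          # "eq1" (stochastic) or "core" (deterministic)
    p_update: float = 0.5      # update probability of the eq1 rule
    gating: str = "neuron"     # "neuron" or "synapse"
    p_ltp: float | None = None  # asymmetric variant: flip probability for 0 -> 1
    p_ltd: float | None = None  # asymmetric variant: flip probability for 1 -> 0

    def __post_init__(self) -> None:
        if self.rule not in ("eq1", "core"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.gating not in ("neuron", "synapse"):
            raise ValueError(f"unknown gating {self.gating!r}")
        if not (0.0 <= self.p_update <= 1.0):
            raise ValueError("p_update must lie in [0, 1]")
        for name in ("p_ltp", "p_ltd"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def asymmetric(self) -> bool:
        return self.p_ltp is not None or self.p_ltd is not None


def draw_plateaus(M: int, n: int, f_q: float, seed: int) -> PlateauSchedule:
    """Draw plateau potentials i.i.d. Bernoulli(f_q) per neuron per item."""
    if not (0.0 <= f_q <= 1.0):
        raise ValueError("f_q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return PlateauSchedule(masks=rng.random((M, n)) < f_q, f_q=f_q, seed=seed)


def _flips_for_item(
    W: np.ndarray,
    mask: np.ndarray,
    x: np.ndarray,
    rows: np.ndarray,
    cfg: PlasticityConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows with an effective plasticity event and the boolean flip matrix for them."""
    active = x.astype(bool)
    if cfg.rule == "core":
        eff = rows
        cand = active[None, :] & mask[eff]
        return eff, cand
    if cfg.asymmetric:
        p_ltp = cfg.p_ltp if cfg.p_ltp is not None else cfg.p_update
        p_ltd = cfg.p_ltd if cfg.p_ltd is not None else cfg.p_update
        cand = active[None, :] & mask[rows]
        u = rng.random(cand.shape)
        w = W[rows].astype(bool)
        flips = cand & np.where(w, u < p_ltd, u < p_ltp)
        return rows, flips
    if cfg.gating == "neuron":
        eff = rows[rng.random(rows.size) < cfg.p_update]
        return eff, active[None, :] & mask[eff]
    # per-synapse gate
    cand = active[None, :] & mask[rows]
    flips = cand & (rng.random(cand.shape) < cfg.p_update)
    return rows, flips


def btsp_step(
    W: np.ndarray,
    mask: np.ndarray,
    x: np.ndarray,
    Q: np.ndarray,
    cfg: PlasticityConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Apply one BTSP learning step for item ``x`` and plateau set ``Q``.

    Returns a new weight matrix; ``W`` is not modified.  ``Q`` may be a
    boolean mask of length n or an integer index array.
    """
    cfg = cfg or PlasticityConfig()
    x = np.asarray(x)
    if x.shape[0] != W.shape[1]:
        raise ValueError(f"item length {x.shape[0]} != number of inputs {W.shape[1]}")
    Q = np.asarray(Q)
    rows = np.flatnonzero(Q) if Q.dtype == bool else Q.astype(np.int64)
    rng = np.random.default_rng(seed)
    out = W.copy()
    eff, flips = _flips_for_item(out, mask, x, rows, cfg, rng)
    out[eff] ^= flips.astype(W.dtype)
    return out


def core_btsp_step(
    W: np.ndarray,
    mask: np.ndarray,
    x: np.ndarray,
    Q: np.ndarray,
) -> np.ndarray:
    """Deterministic core rule: flip every (j in Q, x_i = 1, connected) weight.

    Intended to be driven by plateau schedules at half the f_q of the
    stochastic rule, which leaves the effective learning rate unchanged.
    """
    return btsp_step(W, mask, x, Q, PlasticityConfig(rule="core"))


@dataclass
class LearnResult:
    network: BTSPNetwork
    update_counts: np.ndarray       # (n, m) number of flip events per synapse
    effective_plateaus: np.ndarray  # (M, n) neurons with an actual plasticity event
    plateaus: np.ndarray            # (M, n) the raw plateau schedule


def learn_sequence(
    patterns,
    plateaus: PlateauSchedule,
    mask: np.ndarray,
    cfg: PlasticityConfig | None = None,
    seed: int | None = None,
    v_th: int = 0,
) -> LearnResult:
    """One-shot learning of a pattern sequence starting from zero weights.

    Each item is presented once, in order.  Returns the learned network plus
    an update log: per-synapse flip counts (the final weight always equals the
    parity of its flip count) and the per-item effective plasticity events.
    """
    cfg = cfg or PlasticityConfig()
    items = patterns.items if hasattr(patterns, "items") else np.asarray(patterns)
    M = items.shape[0]
    if M != plateaus.M:
        raise ValueError(f"patterns have M={M} but plateau schedule has M={plateaus.M}")
    n, m = plateaus.n, items.shape[1]
    if mask.shape != (n, m):
        raise ValueError(f"connectivity mask shape {mask.shape} != {(n, m)}")
    rng = np.random.default_rng(seed)
    W = np.zeros((n, m), dtype=np.uint8)
    counts = np.zeros((n, m), dtype=np.uint32)
    eff_plateaus = np.zeros((M, n), dtype=bool)
    for k in range(M):
        rows = np.flatnonzero(plateaus.masks[k])
        eff, flips = _flips_for_item(W, mask, items[k], rows, cfg, rng)
        W[eff] ^= flips.astype(np.uint8)
        counts[eff] += flips
        eff_plateaus[k, eff] = True
    net = BTSPNetwork(mask=mask, W=W, v_th=v_th)
    return LearnResult(network=net, update_counts=counts,
                       effective_plateaus=eff_plateaus, plateaus=plateaus.masks)


def multi_release_site_change(
    n_sites: int = 8,
    n_trials: int = 10_000,
    cfg: PlasticityConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Net change of the summed weight across several binary release sites.

    Two neurons connected by ``n_sites`` release sites, each with a binary
    weight initialised i.i.d. Bernoulli(0.5); one gated BTSP event is applied
    per trial.  Returns mean net change of the summed weight stratified by
    the initial sum.  With symmetric updates the expectation for initial sum
    s is p_update * (n_sites - 2s): purely potentiating at 0, purely
    depressing at n_sites, balanced in the middle — the signature by which a
    population of binary sites emulates a graded weight change.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    cfg = cfg or PlasticityConfig()
    rng = np.random.default_rng(seed)
    w0 = (rng.random((n_trials, n_sites)) < 0.5).astype(np.int8)
    if cfg.rule == "core":
        flips = np.ones((n_trials, n_sites), dtype=bool)
    elif cfg.asymmetric:
        p_ltp = cfg.p_ltp if cfg.p_ltp is not None else cfg.p_update
        p_ltd = cfg.p_ltd if cfg.p_ltd is not None else cfg.p_update
        u = rng.random((n_trials, n_sites))
        flips = np.where(w0 == 1, u < p_ltd, u < p_ltp)
    elif cfg.gating == "neuron":
        flips = (rng.random(n_trials) < cfg.p_update)[:, None] & np.ones(n_sites, dtype=bool)
    else:
        flips = rng.random((n_trials, n_sites)) < cfg.p_update
    w1 = w0 ^ flips
    change = w1.sum(axis=1).astype(np.int64) - w0.sum(axis=1).astype(np.int64)
    df = pd.DataFrame({"initial_sum": w0.sum(axis=1), "change": change})
    out = df.groupby("initial_sum")["change"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_change", "count": "n_trials"})
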