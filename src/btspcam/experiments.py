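"""Figure-level experiments at configurable scale.

Each runner orchestrates the pattern generators, the learning rule, the
metrics and the closed-form predictions into a tidy table, fully reproducible
from (config, seed).  The default parameter set is the biologically motivated
full scale (m=25,000, n=39,000, f_p=f_q=0.005, f_w=0.6); all tests and the
acceptance runs use ``REDUCED_PRESET``, a 1/10-linear-size preset chosen so
that the expected ones per item (50), plateau neurons per item (39) and
threshold-to-fan-in ratios stay in a statistically testable regime on one
CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from btspcam import baselines, completion, network, patterns, plasticity, theory
from btspcam.theory import TheoryParams

__all__ = [
    "FULL_SCALE",
    "REDUCED_PRESET",
    "SCALEUP_PARAMS",
    "ExperimentConfig",
    "run_masking_sweep",
    "run_baseline_comparison",
    "run_overlap_sweep",
    "run_completion",
    "run_repulsion",
    "run_release_sites",
    "run_scaleup",
]

FULL_SCALE = TheoryParams(m=25_000, n=39_000, M=30_000, f_p=0.005, f_q=0.005, f_w=0.6)

#: reduced preset: linear sizes /10, densities x4 (f_p) and x2 (f_q) keep the
#: expected ones per item (m*f_p = 50) and plateaus per item (n*f_q = 39)
#: proportionate to full scale.
REDUCED_PRESET = TheoryParams(m=2_500, n=3_900, M=2_000, f_p=0.02, f_q=0.01, f_w=0.6)

#: human-brain-scale evaluation (theory only): inputs 100x longer than the
#: default, density reduced by 1/100 so the ones count per item is unchanged.
SCALEUP_PARAMS = TheoryParams(
    m=2_500_000, n=39_000, M=800_000, f_p=5e-5, f_q=0.005, f_w=0.6, f_d=2.0 / 3.0
)

#: plateau-probability sweep of the full-scale masking experiment
FQ_SWEEP_FULL = (0.001, 0.005, 0.01)


@dataclass
class ExperimentConfig:
    params: TheoryParams = REDUCED_PRESET
    replicates: int = 5
    seed: int = 0
    f_d: float = 0.33
    rule: plasticity.PlasticityConfig = field(default_factory=plasticity.PlasticityConfig)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _spawn_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


def _learn_network(
    p: TheoryParams, cfg: plasticity.PlasticityConfig, seed: int, v_th: int, ens=None
):
    s_pat, s_plat, s_mask, s_learn = _spawn_seeds(seed, 4)
    if ens is None:
        ens = patterns.gen_random_patterns(p.M, p.m, p.f_p, seed=s_pat)
    plats = plasticity.draw_plateaus(ens.M, p.n, p.f_q, seed=s_plat)
    mask = network.build_connectivity(p.m, p.n, p.f_w, seed=s_mask)
    res = plasticity.learn_sequence(ens, plats, mask, cfg=cfg, seed=s_learn, v_th=v_th)
    return ens, res


def _masked_cues(ens, f_d: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.stack(
        [
            patterns.mask_pattern(x, f_d, seed=int(rng.integers(2**31))).vector
            for x in ens.items
        ]
    )


def run_masking_sweep(
    cfg: ExperimentConfig,
    M_grid: tuple[int, ...] | None = None,
    fq_values: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Trace size, strong-weight fraction and relative dissimilarity as a
    function of load M and plateau probability f_q, with the closed-form
    predictions (both as printed and with the effective event rate) alongside
    the simulation."""
    p0 = cfg.params
    M_grid = M_grid or (max(1, p0.M // 4), p0.M // 2, p0.M)
    fq_values = fq_values or (p0.f_q,)
    rows = []
    seeds = _spawn_seeds(cfg.seed, cfg.replicates * len(M_grid) * len(fq_values))
    i = 0
    for fq in fq_values:
        for M in M_grid:
            p = replace(p0, M=M, f_q=fq, f_d=cfg.f_d)
            v_th = theory.optimize_threshold(p, f_d=cfg.f_d, M=M)
            p = replace(p, v_th=v_th)
            pred = {
                "pred_trace_size": p0.n * theory.p_favg(p),
                "pred_trace_size_eff": p0.n * theory.effective_p_favg(p),
                "pred_strong_fraction": theory.p_o(M + 1, p.f_p, p.f_q),
                "pred_hd_masked": theory.expected_hd_masked(p),
                "pred_hd_masked_eff": theory.effective_expected_hd_masked(p),
                "pred_hd_pairs": theory.expected_hd_pairs(p),
                "pred_hd_pairs_eff": theory.effective_expected_hd_pairs(p),
            }
            for r in range(cfg.replicates):
                seed = seeds[i]
                i += 1
                ens, res = _learn_network(p, cfg.rule, seed, v_th)
                net = res.network
                cues = _masked_cues(ens, cfg.f_d, seed + 1)
                traces = network.recall_many(net, ens.items)
                cue_traces = network.recall_many(net, cues)
                hd_masked = float((traces != cue_traces).sum(axis=1).mean())
                hd_pairs = network.mean_pairwise_hd(traces, seed=seed)
                rows.append(
                    {
                        "f_q": fq,
                        "M": M,
                        "v_th": v_th,
                        "replicate": r,
                        "seed": seed,
                        "trace_size": float(traces.sum(axis=1).mean()),
                        "strong_fraction": network.strong_weight_fraction(net),
                        "hd_masked": hd_masked,
                        "hd_pairs": hd_pairs,
                        "relative_dissimilarity": hd_masked / hd_pairs if hd_pairs else np.nan,
                        **pred,
                    }
                )
    return pd.DataFrame(rows)


def run_baseline_comparison(
    cfg: ExperimentConfig,
    f_d_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.52, 0.02), 2)),
    n_sample_neurons: int = 20,
) -> pd.DataFrame:
    """BTSP vs a density-matched random projection: relative dissimilarity
    over a masking sweep, readout robustness, and the separation of the
    per-neuron weighted-sum clusters (bimodal for BTSP, unimodal for RP)."""
    p = cfg.params
    rows = []
    for r, seed in enumerate(_spawn_seeds(cfg.seed, cfg.replicates)):
        v_th = theory.optimize_threshold(p, f_d=cfg.f_d, M=p.M)
        ens, res = _learn_network(p, cfg.rule, seed, v_th)
        net = res.network
        density = network.strong_weight_fraction(net)
        rp = baselines.rp_build(density, p.m, p.n, seed=seed + 17, f_w=p.f_w)
        cues_ref = _masked_cues(ens, cfg.f_d, seed + 3)
        rp.threshold = baselines.rp_optimize_threshold(rp, ens.items, cues_ref, seed=seed)
        traces_btsp = network.recall_many(net, ens.items)
        traces_rp = baselines.rp_recall_many(rp, ens.items)
        # weighted-sum separation for a few sample neurons
        rng = np.random.default_rng(seed)
        sample = rng.choice(p.n, size=n_sample_neurons, replace=False)
        seps = []
        for j in sample:
            plateau, other, sep = network.weighted_sum_histogram(
                net, ens, res.effective_plateaus, int(j)
            )
            if np.isfinite(sep):
                seps.append(sep)
        sep_mean = float(np.mean(seps)) if seps else np.nan
        for fd in f_d_grid:
            cues = _masked_cues(ens, float(fd), seed + 1000 + int(fd * 100))
            cue_btsp = network.recall_many(net, cues)
            cue_rp = baselines.rp_recall_many(rp, cues)
            den_b = network.mean_pairwise_hd(traces_btsp, seed=seed)
            den_r = network.mean_pairwise_hd(traces_rp, seed=seed)
            rows.append(
                {
                    "replicate": r,
                    "seed": seed,
                    "f_d": float(fd),
                    "v_th": v_th,
                    "rp_threshold": rp.threshold,
                    "btsp_relative_dissimilarity": float(
                        (traces_btsp != cue_btsp).sum(axis=1).mean()
                    ) / den_b if den_b else np.nan,
                    "rp_relative_dissimilarity": float(
                        (traces_rp != cue_rp).sum(axis=1).mean()
                    ) / den_r if den_r else np.nan,
                    "btsp_readout_error": baselines.readout_robustness(
                        traces_btsp, cue_btsp, seed=seed
                    ),
                    "rp_readout_error": baselines.readout_robustness(
                        traces_rp, cue_rp, seed=seed
                    ),
                    "btsp_sum_separation": sep_mean,
                }
            )
    return pd.DataFrame(rows)


def run_overlap_sweep(
    cfg: ExperimentConfig, f_c_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
) -> pd.DataFrame:
    """Relative dissimilarity for overlapping memory items (simulation and
    the overlapping-item theory) over a grid of overlap fractions f_c."""
    p0 = cfg.params
    rows = []
    seeds = _spawn_seeds(cfg.seed, cfg.replicates * len(f_c_grid))
    i = 0
    for fc in f_c_grid:
        c = int(np.floor(p0.m * fc * p0.f_p))
        p = replace(p0, c=c, f_d=cfg.f_d)
        v_th = theory.optimize_threshold(p, f_d=cfg.f_d, M=p.M)
        p = replace(p, v_th=v_th)
        pred = theory.overlapping_predictions(p)
        pred_ratio = (
            pred.expected_hd_masked / pred.expected_hd_pairs
            if pred.expected_hd_pairs
            else np.nan
        )
        for r in range(cfg.replicates):
            seed = seeds[i]
            i += 1
            ens = patterns.gen_overlapping_patterns(p.M, p.m, p.f_p, fc, seed=seed)
            _, res = _learn_network(p, cfg.rule, seed + 1, v_th, ens=ens)
            net = res.network
            cues = _masked_cues(ens, cfg.f_d, seed + 2)
            ratio = network.relative_dissimilarity(net, ens, cues, seed=seed)
            rows.append(
                {
                    "f_c": fc,
                    "c": c,
                    "v_th": v_th,
                    "replicate": r,
                    "seed": seed,
                    "relative_dissimilarity": ratio,
                    "pred_relative_dissimilarity": pred_ratio,
                }
            )
    return pd.DataFrame(rows)


def run_completion(
    cfg: ExperimentConfig,
    f_d_grid: tuple[float, ...] = (0.1, 0.2, 0.33, 0.5),
    head_tail: int = 100,
    scan_range: tuple[int, int] = (1, 50),
    scan_step: int = 1,
    fit_max_sample: int = 50,
) -> pd.DataFrame:
    """Input reconstruction through learned feedback connections: scaled
    reconstruction error per masking fraction, plus the early-vs-late item
    comparison (first and last ``head_tail`` items of the sequence)."""
    p = cfg.params
    rows = []
    for r, seed in enumerate(_spawn_seeds(cfg.seed, cfg.replicates)):
        s_pat, s_plat, s_mask, s_learn, s_fit = _spawn_seeds(seed, 5)
        ens = patterns.gen_random_patterns(p.M, p.m, p.f_p, seed=s_pat)
        plats = plasticity.draw_plateaus(p.M, p.n, p.f_q, seed=s_plat)
        mask = network.build_connectivity(p.m, p.n, p.f_w, seed=s_mask)
        v_th = theory.optimize_threshold(p, f_d=cfg.f_d, M=p.M)
        net, fb = completion.learn_with_completion(
            ens, plats, mask, v_th_mem=v_th, cfg=cfg.rule, seed=s_learn
        )
        fits = completion.fit_adaptive_thresholds(
            net, fb, ens, masking_fractions=f_d_grid, scan_range=scan_range,
            scan_step=scan_step, seed=s_fit, max_sample=fit_max_sample,
        )
        rng = np.random.default_rng(seed)
        for fd in f_d_grid:
            cues = _masked_cues(ens, float(fd), int(rng.integers(2**31)))
            ones_frac = float(cues.mean())
            t_mem = fits.memory(ones_frac)
            t_in = fits.input(ones_frac)
            Z = (cues.astype(np.float32) @ net.effective_weights().T.astype(np.float32)) > t_mem
            R = completion.reconstruct_many(fb, Z.astype(np.uint8), t_in)
            hd_cue = (ens.items != cues).sum(axis=1)
            hd_rec = (ens.items != R).sum(axis=1)
            valid = hd_cue > 0
            scaled = hd_rec[valid] / hd_cue[valid]
            rows.append(
                {
                    "replicate": r,
                    "seed": seed,
                    "f_d": float(fd),
                    "t_mem": t_mem,
                    "t_in": t_in,
                    "scaled_error": float(scaled.mean()),
                    "scaled_error_first": float(scaled[:head_tail].mean()),
                    "scaled_error_last": float(scaled[-head_tail:].mean()),
                }
            )
    return pd.DataFrame(rows)


def separating_threshold(p: TheoryParams, overlap_fraction: float = 0.4) -> int:
    """Firing threshold for the repulsion protocol, from the parity theory.

    A neuron with plasticity events for *both* items of a similar pair has its
    shared-bit synapses flipped twice (LTP then LTD): its expected recall sum
    drops to f_w (c p_o + (iota - c) p_e), while intact trace neurons sit at
    f_w iota p_e.  The threshold is placed midway between these two cluster
    means, which is what makes the LTD-induced repulsion observable; recall
    in this protocol uses the full (unmasked) items, so no masking margin is
    needed."""
    iota = p.m * p.f_p
    pe = theory.p_e(p.M, p.f_p, p.f_q)
    po = theory.p_o(p.M, p.f_p, p.f_q)
    c = overlap_fraction * iota
    u_depressed = p.f_w * (c * po + (iota - c) * pe)
    u_intact = p.f_w * iota * pe
    return max(1, int(np.floor(0.5 * (u_depressed + u_intact))))


def _planted_pairs(
    rng: np.random.Generator, m: int, f_p: float, M: int, n_pairs: int, overlap_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """M random items plus, for each of ``n_pairs`` bases, one partner with
    the given fraction of overlapping 1's and one partner with no common 1's.

    Returns (items, base indices, similar-partner indices, unrelated-partner
    indices) before shuffling."""
    items = (rng.random((M, m)) < f_p).astype(np.uint8)
    partners = []
    for b in range(n_pairs):
        base = items[b]
        ones = np.flatnonzero(base)
        zeros = np.flatnonzero(base == 0)
        n_common = int(round(overlap_fraction * ones.size))
        sim = np.zeros(m, dtype=np.uint8)
        sim[rng.choice(ones, size=n_common, replace=False)] = 1
        sim[rng.choice(zeros, size=ones.size - n_common, replace=False)] = 1
        unr = np.zeros(m, dtype=np.uint8)
        unr[rng.choice(zeros, size=ones.size, replace=False)] = 1
        partners.extend([sim, unr])
    all_items = np.vstack([items, np.stack(partners)])
    base_idx = np.arange(n_pairs)
    sim_idx = M + 2 * np.arange(n_pairs)
    unr_idx = M + 2 * np.arange(n_pairs) + 1
    return all_items, base_idx, sim_idx, unr_idx


def run_repulsion(
    cfg: ExperimentConfig,
    overlap_fraction: float = 0.4,
    n_trials: int = 20,
    f_q: float = 0.02,
    n_pairs: int = 20,
) -> pd.DataFrame:
    """The repulsion experiment: sequences of unrelated items containing
    planted pairs with 40% overlapping 1's (and matched zero-overlap pairs),
    learned in random order.  Per trial, the trace overlap ratio is averaged
    over the planted pairs; the repulsion index divides the unrelated-pair
    overlap by the similar-pair overlap (> 1 = repulsion).  The same cues are
    mapped through a Top-K random projection as the non-learned control.

    Several pairs are planted per sequence because at reduced scale a single
    pair's trace overlap is a count of order one; averaging within a trial
    makes the per-trial sign well defined without changing the per-pair
    protocol."""
    p = replace(cfg.params, f_q=f_q)
    v_th = separating_threshold(p, overlap_fraction)
    K = max(1, int(np.floor(p.n * f_q)))
    rows = []
    for t, seed in enumerate(_spawn_seeds(cfg.seed, n_trials)):
        rng = np.random.default_rng(seed)
        items, base_idx, sim_idx, unr_idx = _planted_pairs(
            rng, p.m, p.f_p, p.M, n_pairs, overlap_fraction
        )
        order = rng.permutation(items.shape[0])
        pos = np.argsort(order)
        shuffled = patterns.PatternEnsemble(items=items[order], f_p=p.f_p, seed=seed)
        pp = replace(p, M=items.shape[0])
        _, res = _learn_network(pp, cfg.rule, seed + 1, v_th, ens=shuffled)
        net = res.network
        traces_btsp = network.recall_many(net, shuffled.items)
        density = network.strong_weight_fraction(net)
        rp = baselines.rp_build(density, p.m, p.n, seed=seed + 17, f_w=p.f_w)
        traces_rp = baselines.rp_topk_many(rp, shuffled.items, K)
        for model, tr in (("btsp", traces_btsp), ("rp_topk", traces_rp)):
            mean_ones = float(tr.sum(axis=1).mean())
            if mean_ones == 0.0:
                ov_sim = ov_unr = idx_val = np.nan
            else:
                b, s, u = pos[base_idx], pos[sim_idx], pos[unr_idx]
                common_sim = (tr[b] & tr[s]).sum(axis=1).mean()
                common_unr = (tr[b] & tr[u]).sum(axis=1).mean()
                ov_sim = float(common_sim) / mean_ones
                ov_unr = float(common_unr) / mean_ones
                idx_val = ov_unr / ov_sim if ov_sim > 0 else np.inf
            rows.append(
                {
                    "trial": t,
                    "seed": seed,
                    "model": model,
                    "v_th": v_th,
                    "K": K,
                    "n_pairs": n_pairs,
                    "overlap_similar": ov_sim,
                    "overlap_unrelated": ov_unr,
                    "repulsion_index": idx_val,
                }
            )
    return pd.DataFrame(rows)


def run_release_sites(cfg: ExperimentConfig, n_sites: int = 8, n_trials: int = 10_000) -> pd.DataFrame:
    """Mean net change of the summed weight of several binary release sites
    under one gated BTSP event, stratified by the initial summed weight."""
    return plasticity.multi_release_site_change(
        n_sites=n_sites, n_trials=n_trials, cfg=cfg.rule, seed=cfg.seed
    )


def run_scaleup(cfg: ExperimentConfig | None = None, simulate: bool = False) -> pd.DataFrame:
    """Theory-only evaluation at human-brain input scale (m = 2.5e6 inputs,
    up to 800,000 items, 2/3 masking).  Simulation at this size is refused:
    use the reduced preset or full-scale defaults instead."""
    if simulate:
        raise ValueError(
            "simulation at m=2.5e6 is not supported; the scale-up analysis is "
            "closed-form only (use REDUCED_PRESET or FULL_SCALE for simulations)"
        )
    p = SCALEUP_PARAMS
    v_th = theory.optimize_threshold(p, f_d=p.f_d, M=p.M)
    p = replace(p, v_th=v_th)
    hd_m = theory.expected_hd_masked(p)
    hd_p = theory.expected_hd_pairs(p)
    return pd.DataFrame(
        [
            {
                "m": p.m,
                "M": p.M,
                "f_p": p.f_p,
                "f_d": p.f_d,
                "v_th": v_th,
                "pred_trace_size": p.n * theory.p_favg(p),
                "pred_hd_masked": hd_m,
                "pred_hd_pairs": hd_p,
                "pred_relative_dissimilarity": hd_m / hd_p,
            }
        ]
    )
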