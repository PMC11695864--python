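"""Synthetic memory items: sparse random patterns, overlapping patterns,
masked/perturbed recall cues, and binary line drawings.

All generators are deterministic under a fixed seed and produce {0,1} vectors
of length ``m``.  The number of 1's per item is governed by the input density
``f_p`` (the fraction of input neurons firing for a memory item; the
biologically motivated default at full scale is 0.005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternEnsemble",
    "Cue",
    "gen_random_patterns",
    "gen_overlapping_patterns",
    "mask_pattern",
    "perturb_pattern",
    "gen_line_drawings",
    "mask_line_drawing",
]

LINE_DRAWING_SIDE = 50
LINE_LENGTH = 8
LINES_PER_DRAWING = 5


@dataclass
class PatternEnsemble:
    """A set of M binary memory items of length m.

    ``items`` is an (M, m) uint8 array.  ``overlap_count`` is the number of
    positions that are 1 in *every* item (0 for plain random ensembles);
    ``common_positions`` stores those positions.  ``segments`` carries the
    line-segment metadata for line-drawing ensembles.
    """

    items: np.ndarray
    f_p: float
    overlap_count: int = 0
    seed: int | None = None
    common_positions: np.ndarray | None = None
    segments: list[list[tuple[str, int, int]]] | None = field(default=None, repr=False)

    @property
    def M(self) -> int:
        return self.items.shape[0]

    @property
    def m(self) -> int:
        return self.items.shape[1]

    def ones_per_item(self) -> np.ndarray:
        return self.items.sum(axis=1)


@dataclass
class Cue:
    """A recall cue derived from a stored item.

    ``mode`` is "masked" (1's deleted only) or "two_sided" (1's deleted and an
    expectation-matching number of 0's flipped to 1).
    """

    vector: np.ndarray
    masking_fraction: float
    mode: str = "masked"
    source_index: int | None = None


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def gen_random_patterns(M: int, m: int, f_p: float, seed: int) -> PatternEnsemble:
    """Draw M independent items with each bit i.i.d. Bernoulli(f_p)."""
    if M < 1 or m < 1:
        raise ValueError(f"M and m must be >= 1, got M={M}, m={m}")
    _check_prob(f_p, "f_p")
    rng = np.random.default_rng(seed)
    items = (rng.random((M, m)) < f_p).astype(np.uint8)
    return PatternEnsemble(items=items, f_p=f_p, overlap_count=0, seed=seed)


def gen_overlapping_patterns(
    M: int, m: int, f_p: float, f_c: float, seed: int
) -> PatternEnsemble:
    """Draw M items sharing c = floor(m*f_c*f_p) common 1-positions.

    The shared positions are 1 in every item; the remaining m-c bits are
    i.i.d. Bernoulli(f_hat_p) with f_hat_p = (m*f_p - c)/(m - c), so the
    expected ones count per item stays at m*f_p for any overlap fraction f_c.
    """
    if M < 1 or m < 1:
        raise ValueError(f"M and m must be >= 1, got M={M}, m={m}")
    _check_prob(f_p, "f_p")
    _check_prob(f_c, "f_c")
    c = int(np.floor(m * f_c * f_p))
    if c >= m:
        raise ValueError("overlap count c must be smaller than m")
    f_hat_p = (m * f_p - c) / (m - c)
    if not (0.0 <= f_hat_p <= 1.0):
        raise ValueError(f"derived remaining-bit density f_hat_p={f_hat_p} out of [0, 1]")
    rng = np.random.default_rng(seed)
    common = rng.choice(m, size=c, replace=False) if c > 0 else np.empty(0, dtype=np.int64)
    items = (rng.random((M, m)) < f_hat_p).astype(np.uint8)
    items[:, common] = 1
    return PatternEnsemble(
        items=items, f_p=f_p, overlap_count=c, seed=seed, common_positions=np.sort(common)
    )


def remaining_bit_density(m: int, f_p: float, c: int) -> float:
    """Density of the non-common bits that keeps the mean ones count at m*f_p."""
    return (m * f_p - c) / (m - c)


def masked_count(n_ones: int, f_d: float) -> int:
    """Number of 1's removed by masking: round-half-to-even of f_d * ones."""
    return int(np.round(f_d * n_ones))


def mask_pattern(x: np.ndarray, f_d: float, seed: int, source_index: int | None = None) -> Cue:
    """Set a random fraction f_d of the 1's of ``x`` to 0 (one-sided cue).

    Exactly round(f_d * ones(x)) distinct 1-positions, chosen uniformly
    without replacement, are zeroed.
    """
    _check_prob(f_d, "f_d")
    x = np.asarray(x, dtype=np.uint8)
    ones = np.flatnonzero(x)
    k = masked_count(ones.size, f_d)
    out = x.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        out[rng.choice(ones, size=k, replace=False)] = 0
    return Cue(vector=out, masking_fraction=f_d, mode="masked", source_index=source_index)


def perturb_pattern(x: np.ndarray, f_d: float, seed: int, source_index: int | None = None) -> Cue:
    """Two-sided noisy cue: delete k = round(f_d * ones) 1's, and flip each
    0-position to 1 independently with probability k/(m - ones), so the
    expected ones count of the cue equals that of the original item."""
    _check_prob(f_d, "f_d")
    x = np.asarray(x, dtype=np.uint8)
    ones = np.flatnonzero(x)
    zeros = np.flatnonzero(x == 0)
    k = masked_count(ones.size, f_d)
    out = x.copy()
    rng = np.random.default_rng(seed)
    if k > 0:
        out[rng.choice(ones, size=k, replace=False)] = 0
    if zeros.size == 0:
        if k > 0:
            warnings.warn("pattern has no zero positions; only removals applied", stacklevel=2)
        return Cue(vector=out, masking_fraction=f_d, mode="two_sided", source_index=source_index)
    p_add = k / zeros.size
    if p_add > 0:
        out[zeros[rng.random(zeros.size) < p_add]] = 1
    return Cue(vector=out, masking_fraction=f_d, mode="two_sided", source_index=source_index)


def _random_segment(rng: np.random.Generator) -> tuple[str, int, int]:
    # (orientation, row, col) of the segment's first pixel; 8 pixels long,
    # entirely inside the 50x50 frame.
    horizontal = bool(rng.integers(2))
    if horizontal:
        row = int(rng.integers(LINE_DRAWING_SIDE))
        col = int(rng.integers(LINE_DRAWING_SIDE - LINE_LENGTH + 1))
        return ("h", row, col)
    row = int(rng.integers(LINE_DRAWING_SIDE - LINE_LENGTH + 1))
    col = int(rng.integers(LINE_DRAWING_SIDE))
    return ("v", row, col)


def _render(segments: list[tuple[str, int, int]]) -> np.ndarray:
    img = np.zeros((LINE_DRAWING_SIDE, LINE_DRAWING_SIDE), dtype=np.uint8)
    for orient, row, col in segments:
        if orient == "h":
            img[row, col : col + LINE_LENGTH] = 1
        else:
            img[row : row + LINE_LENGTH, col] = 1
    return img


def gen_line_drawings(M: int, seed: int) -> PatternEnsemble:
    """Binary 50x50 line drawings, flattened row-major to length 2500.

    Each drawing is the union of 5 axis-aligned 8-pixel segments placed
    uniformly inside the frame.  The last two drawings form a planted pair
    sharing exactly 3 segments (the similar-item pair used in the completion
    task).  Segment metadata is stored per drawing.
    """
    if M < 2:
        raise ValueError("need M >= 2 to plant a similar pair")
    rng = np.random.default_rng(seed)
    all_segments: list[list[tuple[str, int, int]]] = [
        [_random_segment(rng) for _ in range(LINES_PER_DRAWING)] for _ in range(M - 1)
    ]
    # Planted partner of the second-to-last drawing: keep 3 segments, redraw 2
    # (redraws are rejected if they coincide with a kept segment, so the pair
    # shares exactly 3 segments in the metadata).
    base = all_segments[-1]
    shared = [base[i] for i in rng.choice(LINES_PER_DRAWING, size=3, replace=False)]
    fresh: list[tuple[str, int, int]] = []
    while len(fresh) < LINES_PER_DRAWING - 3:
        seg = _random_segment(rng)
        if seg not in shared and seg not in fresh:
            fresh.append(seg)
    all_segments.append(shared + fresh)
    items = np.stack([_render(segs).ravel() for segs in all_segments])
    f_p = float(items.mean())
    return PatternEnsemble(
        items=items, f_p=f_p, overlap_count=0, seed=seed, segments=all_segments
    )


def mask_line_drawing(x: np.ndarray, n_rows: int = 20) -> np.ndarray:
    """Zero the last ``n_rows`` rows of a flattened 50x50 drawing."""
    img = np.asarray(x, dtype=np.uint8).reshape(LINE_DRAWING_SIDE, LINE_DRAWING_SIDE).copy()
    img[LINE_DRAWING_SIDE - n_rows :, :] = 0
    return img.ravel()
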