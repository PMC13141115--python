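"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: plain
pixel-by-pixel loops over padded arrays.
"""

from __future__ import annotations

import numpy as np


def ball_profile(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy**2 + xx**2
    mask = d2 <= radius * radius
    prof = np.where(mask, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return mask, prof


def rolling_ball_oracle(plane: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a ball cap by explicit min/max loops
    (edge-replicated boundary), rounded and clipped like the pipeline."""
    mask, prof = ball_profile(radius)
    arr = np.asarray(plane, dtype=np.float64)
    h, w = arr.shape
    pad = np.pad(arr, radius, mode="edge")
    eroded = np.empty_like(arr)
    for i in range(h):
        for j in range(w):
            win = pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            eroded[i, j] = np.min(win[mask] - prof[mask])
    pad2 = np.pad(eroded, radius, mode="edge")
    opened = np.empty_like(arr)
    for i in range(h):
        for j in range(w):
            win = pad2[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            opened[i, j] = np.max(win[mask] + prof[mask])
    return np.clip(np.floor(opened + 0.5), 0, 65535).astype(np.uint16)


def mean_projection_oracle(slices: list[np.ndarray]) -> np.ndarray:
    """Per-pixel arithmetic mean by explicit accumulation."""
    acc = np.zeros_like(np.asarray(slices[0], dtype=np.float64))
    for s in slices:
        acc += np.asarray(s, dtype=np.float64)
    return acc / len(slices)


def overlap_fraction_oracle(labels: np.ndarray, mask: np.ndarray) -> dict[int, float]:
    """Per-cell overlap fraction by per-pixel counting."""
    out: dict[int, list[int]] = {}
    h, w = labels.shape
    for i in range(h):
        for j in range(w):
            lab = int(labels[i, j])
            if lab == 0:
                continue
            tot_in = out.setdefault(lab, [0, 0])
            tot_in[0] += 1
            if mask[i, j]:
                tot_in[1] += 1
    return {lab: n_in / tot for lab, (tot, n_in) in out.items()}


def otsu_scan_oracle(values: np.ndarray) -> float:
    """Exhaustive between-class-variance scan over candidate thresholds."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    candidates = np.unique(vals)
    best_t, best_v = candidates[0], -np.inf
    for t in candidates[1:]:
        lo, hi = vals[vals < t], vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(best_t)
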