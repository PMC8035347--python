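"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written by direct definition (explicit loops, no shared
code with the package) so agreement is a real check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def match_score_direct(I: np.ndarray, T: np.ndarray, method: str) -> np.ndarray:
    """Template-matching scores by direct summation over (u, v)."""
    I = np.asarray(I, float)
    T = np.asarray(T, float)
    h, w = T.shape
    H, W = I.shape
    n = w * h
    out = np.empty((H - h + 1, W - w + 1))
    for y in range(H - h + 1):
        for x in range(W - w + 1):
            win = I[y : y + h, x : x + w]
            if method == "SD":
                out[y, x] = ((T - win) ** 2).sum()
            elif method == "NSD":
                denom = math.sqrt((T**2).sum() * (win**2).sum())
                out[y, x] = ((T - win) ** 2).sum() / denom if denom > 1e-12 else 2.0
            elif method == "C":
                out[y, x] = (T * win).sum()
            elif method == "NC":
                denom = math.sqrt((T**2).sum() * (win**2).sum())
                out[y, x] = (T * win).sum() / denom if denom > 1e-12 else 0.0
            elif method == "CC":
                tp = T - T.sum() / n
                ip = win - win.sum() / n
                out[y, x] = (tp * ip).sum()
            elif method == "NcC":
                tp = T - T.sum() / n
                ip = win - win.sum() / n
                denom = math.sqrt((tp**2).sum() * (ip**2).sum())
                out[y, x] = (tp * ip).sum() / denom if denom > 1e-12 else -1.0
            else:
                raise ValueError(method)
    return out


def erode_direct(src: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale erosion: min over the reflected-boundary neighbourhood."""
    return _morph_direct(src, footprint, min)


def dilate_direct(src: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return _morph_direct(src, footprint, max)


def _morph_direct(src, footprint, reducer):
    src = np.asarray(src, float)
    H, W = src.shape
    fh, fw = footprint.shape
    ry, rx = fh // 2, fw // 2
    out = np.empty_like(src)
    for y in range(H):
        for x in range(W):
            vals = []
            for dy in range(-ry, fh - ry):
                for dx in range(-rx, fw - rx):
                    if not footprint[dy + ry, dx + rx]:
                        continue
                    yy, xx = _reflect(y + dy, H), _reflect(x + dx, W)
                    vals.append(src[yy, xx])
            out[y, x] = reducer(vals)
    return out


def _reflect(i: int, n: int) -> int:
    # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - i - 1
    return i


def flood_fill_components(mask: np.ndarray, min_size: int = 1):
    """8-connected components by BFS; returns list of pixel-index sets."""
    mask = np.asarray(mask).astype(bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for y in range(H):
        for x in range(W):
            if not mask[y, x] or seen[y, x]:
                continue
            queue = [(y, x)]
            seen[y, x] = True
            comp = set()
            while queue:
                cy, cx = queue.pop()
                comp.add((cy, cx))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            if len(comp) >= min_size:
                comps.append(comp)
    return comps


def greedy_pairs_direct(f_positions, t_positions):
    """Sort-and-prune pairing by repeated full scans (no pre-sorting).

    Positions are (x, y, z) μm tuples; returns the accepted index pairs
    with the same tie-break the pipeline promises: (distance, f idx, t idx).
    """
    remaining = [
        (math.dist(f, t), fi, ti)
        for fi, f in enumerate(f_positions)
        for ti, t in enumerate(t_positions)
    ]
    accepted = []
    while remaining:
        best = min(remaining)
        accepted.append((best[1], best[2]))
        remaining = [
            c for c in remaining if c[1] != best[1] and c[2] != best[2]
        ]
    return accepted


def local_maxima_direct(volume, mask_per_layer, floor):
    """Per-layer up-to-24-neighbour maxima by exhaustive comparison."""
    out = []
    for li, mask in mask_per_layer.items():
        img = volume[li]
        H, W = img.shape
        for y in range(H):
            for x in range(W):
                if not mask[y, x] or img[y, x] <= floor:
                    continue
                is_max = True
                for dy in range(-2, 3):
                    for dx in range(-2, 3):
                        if dy == 0 and dx == 0:
                            continue
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx]:
                            if img[ny, nx] > img[y, x]:
                                is_max = False
                if is_max:
                    out.append((x, y, li))
    return out
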