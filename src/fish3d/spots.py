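"""Gene-signal detection inside segmented nuclei.

A voxel is a candidate signal coordinate when its intensity is maximal over
its up-to-24 in-plane neighbours (the 5×5 window minus the centre; fewer
where the window leaves the nucleus mask) and exceeds an intensity floor of
mean + k·SD of the channel inside the nucleus. Candidates within one spot
diameter of each other in μm space — including across layers — belong to
the same physical signal and are collapsed to the single highest-intensity
coordinate. Pixel indices are converted to μm exactly once, here:
X = x_px·pixel_size, Y = y_px·pixel_size, Z = layer·z_interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .segmentation import Nucleus3D


@dataclass(frozen=True)
class Spot:
    """One detected gene signal reduced to its peak coordinate."""

    nucleus_id: int
    channel: str  # "FITC" | "TRITC"
    x_px: int
    y_px: int
    layer: int
    position_um: tuple[float, float, float]
    intensity: float
    id: int = -1  # per-nucleus, per-channel index


@dataclass(frozen=True)
class Candidate:
    x_px: int
    y_px: int
    layer: int
    intensity: float


_WINDOW = np.ones((5, 5), dtype=bool)


def detect_candidates(
    channel_stack: np.ndarray, nucleus: Nucleus3D, config: RunConfig
) -> list[Candidate]:
    """In-plane local maxima above the intensity floor, inside the nucleus.

    ``channel_stack`` is the (layer, row, column) volume of one channel.
    The floor is background mean + k·SD computed over all in-nucleus voxels
    of the channel across the nucleus's layer span (k =
    ``config.intensity_floor_k``). Plateau ties all become candidates; the
    3D merge collapses them.
    """
    if nucleus.qc != "clear":
        raise ValueError(f"nucleus {nucleus.id} is not clear (qc={nucleus.qc})")
    values = np.concatenate(
        [channel_stack[li][m] for li, m in sorted(nucleus.masks.items())]
    )
    if values.size == 0:
        return []
    floor = float(values.mean() + config.intensity_floor_k * values.std())

    out: list[Candidate] = []
    for li in sorted(nucleus.masks):
        img = np.asarray(channel_stack[li], dtype=float)
        mask = nucleus.masks[li]
        masked = np.where(mask, img, -np.inf)
        local_max = ndimage.maximum_filter(masked, footprint=_WINDOW, mode="constant", cval=-np.inf)
        sel = mask & (img == local_max) & (img > floor)
        ys, xs = np.nonzero(sel)
        for y, x in zip(ys, xs):
            out.append(Candidate(int(x), int(y), li, float(img[y, x])))
    return out


def merge_3d(
    candidates: list[Candidate],
    config: RunConfig,
    nucleus_id: int,
    channel: str,
) -> list[Spot]:
    """Collapse candidate groups within one spot diameter into single Spots.

    Grouping is single-linkage over μm distance ≤ ``spot_diameter_um``; each
    group keeps its maximum-intensity member, ties broken by lowest
    (layer, y_px, x_px).
    """
    if not candidates:
        return []
    pos = np.array(
        [
            (
                c.x_px * config.pixel_size_xy,
                c.y_px * config.pixel_size_xy,
                c.layer * config.z_interval,
            )
            for c in candidates
        ]
    )
    n = len(candidates)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    thresh2 = config.spot_diameter_um**2 + 1e-12
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= thresh2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    spots: list[Spot] = []
    for members in groups.values():
        best = min(
            members,
            key=lambda i: (
                -candidates[i].intensity,
                candidates[i].layer,
                candidates[i].y_px,
                candidates[i].x_px,
            ),
        )
        c = candidates[best]
        spots.append(
            Spot(
                nucleus_id=nucleus_id,
                channel=channel,
                x_px=c.x_px,
                y_px=c.y_px,
                layer=c.layer,
                position_um=tuple(pos[best]),
                intensity=c.intensity,
            )
        )
    # deterministic order + per-nucleus/channel ids
    spots.sort(key=lambda s: (s.layer, s.y_px, s.x_px))
    return [
        Spot(**{**s.__dict__, "id": i}) for i, s in enumerate(spots)
    ]


def detect_spots(
    channel_stack: np.ndarray,
    nucleus: Nucleus3D,
    channel: str,
    config: RunConfig,
) -> list[Spot]:
    """Candidates → merged Spots for one nucleus and channel."""
    cands = detect_candidates(channel_stack, nucleus, config)
    return merge_3d(cands, config, nucleus.id, channel)
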