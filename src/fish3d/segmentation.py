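"""Nucleus segmentation by template matching and 3D linking.

A bank of filled-ellipse templates is slid over each preprocessed DAPI
layer. For a W×H source image I and a w×h template T the score matrix R has
shape (H−h+1, W−w+1) (``R[y, x]``, y the row offset, x the column offset).
Six scores are supported:

* SD   — sum of squared differences, Σ(T−I)²; 0 is a perfect match.
* NSD  — SD normalized by √(ΣT²·ΣI²).
* C    — raw cross-correlation, Σ(T·I).
* NC   — C normalized by √(ΣT²·ΣI²); in [0, 1] for non-negative images.
* CC   — correlation of mean-subtracted T′ and I′ (per-window mean).
* NcC  — CC normalized by √(ΣT′²·ΣI′²); the Pearson correlation of the
  window with the template, in [−1, 1]. This is the default scoring method:
  it is invariant to intensity offset and gain, which matters for
  fluorescence staining variability.

Accepted template footprints (after greedy non-maximum suppression),
intersected with an Otsu foreground mask, form the per-layer nucleus mask.
Per-layer components are then linked across adjacent layers into 3D nuclei,
and nuclei failing QC (touching the border, overlapping a neighbour in
projection, or outside the volume bounds) are flagged discarded — they are
counted in the report but never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .config import MATCH_METHODS, RunConfig

_EPS = 1e-12


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------

def ellipse_template(
    semi_major_px: float, semi_minor_px: float, angle_deg: float = 0.0
) -> np.ndarray:
    """Binary filled ellipse (as float 0/1) cropped to its bounding box."""
    if semi_major_px <= 0 or semi_minor_px <= 0:
        raise ValueError("semi-axes must be > 0")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # bounding half-extents of the rotated ellipse
    hx = np.sqrt((semi_major_px * c) ** 2 + (semi_minor_px * s) ** 2)
    hy = np.sqrt((semi_major_px * s) ** 2 + (semi_minor_px * c) ** 2)
    nx, ny = int(np.ceil(hx)), int(np.ceil(hy))
    yy, xx = np.mgrid[-ny : ny + 1, -nx : nx + 1].astype(float)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    return ((u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0).astype(float)


@dataclass
class TemplateSet:
    """Bank of nucleus templates with their binary footprints."""

    templates: list[np.ndarray]
    footprints: list[np.ndarray]
    provenance: str = "parametric"

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.footprints):
            raise ValueError("templates and footprints must align")
        for t in self.templates:
            if t.ndim != 2 or min(t.shape) < 1:
                raise ValueError("templates must be non-empty 2D arrays")

    def __len__(self) -> int:
        return len(self.templates)

    @classmethod
    def parametric(cls, config: RunConfig) -> "TemplateSet":
        """Filled ellipses over the configured radius/aspect/orientation grid,
        rendered at the configured pixel size."""
        templates: list[np.ndarray] = []
        for r_um in config.template_radii_um:
            r_px = r_um / config.pixel_size_xy
            for aspect in config.template_aspects:
                if aspect == 1.0:
                    angles: list[float] = [0.0]
                else:
                    step = config.template_orientation_step_deg
                    angles = list(np.arange(0.0, 180.0, step))
                for ang in angles:
                    t = ellipse_template(r_px, r_px / aspect, ang)
                    templates.append(t)
        footprints = [t > 0.5 for t in templates]
        return cls(templates, footprints, provenance="parametric")

    @classmethod
    def from_dir(cls, path: str | Path) -> "TemplateSet":
        """Load user-supplied grayscale template images from a directory."""
        import tifffile
        from skimage.io import imread

        path = Path(path)
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise ValueError(f"no template images found in {path}")
        templates = []
        for f in files:
            img = tifffile.imread(f) if f.suffix.lower() in (".tif", ".tiff") else imread(f)
            img = np.asarray(img, dtype=float)
            if img.ndim != 2:
                raise ValueError(f"{f}: templates must be single-channel 2D")
            templates.append(img)
        footprints = [t > 0.5 * t.max() if t.max() > 0 else t > 0 for t in templates]
        return cls(templates, footprints, provenance="user_supplied")


# --------------------------------------------------------------------------
# template matching
# --------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Score matrix of one template against one image.

    ``scores[y, x]`` is the score of the template placed with its top-left
    corner at row y, column x; shape is (H−h+1, W−w+1).
    """

    scores: np.ndarray
    method: str
    template_shape: tuple[int, int]

    @property
    def higher_is_better(self) -> bool:
        return self.method not in ("SD", "NSD")


def _window_sums(image: np.ndarray, shape: tuple[int, int]):
    """Per-window Σ I and Σ I² via 'valid' correlation with a ones kernel."""
    ones = np.ones(shape, dtype=float)
    s1 = signal.correlate(image, ones, mode="valid", method="auto")
    s2 = signal.correlate(image * image, ones, mode="valid", method="auto")
    return s1, s2


def match_template(I: np.ndarray, T: np.ndarray, method: str = "NcC") -> MatchResult:
    """Score every placement of template T over image I.

    Degenerate windows (zero energy in a normalized method's denominator) are
    assigned the method's worst score (2 for NSD, 0 for NC, −1 for NcC).
    """
    if method not in MATCH_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {MATCH_METHODS}")
    I = np.asarray(I, dtype=float)
    T = np.asarray(T, dtype=float)
    if I.ndim != 2 or T.ndim != 2:
        raise ValueError("image and template must be 2D")
    h, w = T.shape
    H, W = I.shape
    if h > H or w > W:
        raise ValueError(f"template {T.shape} larger than image {I.shape}")

    n = float(w * h)
    cross = signal.correlate(I, T, mode="valid", method="auto")

    if method == "C":
        return MatchResult(cross, method, T.shape)

    sum_t = T.sum()
    sum_t2 = float((T * T).sum())
    s1, s2 = _window_sums(I, T.shape)

    if method == "SD":
        r = sum_t2 + s2 - 2.0 * cross
        return MatchResult(np.maximum(r, 0.0), method, T.shape)

    if method == "NSD":
        num = np.maximum(sum_t2 + s2 - 2.0 * cross, 0.0)
        denom = np.sqrt(np.maximum(sum_t2 * s2, 0.0))
        bad = denom <= _EPS
        r = np.where(bad, 2.0, num / np.where(bad, 1.0, denom))
        return MatchResult(r, method, T.shape)

    if method == "NC":
        denom = np.sqrt(np.maximum(sum_t2 * s2, 0.0))
        bad = denom <= _EPS
        r = np.where(bad, 0.0, cross / np.where(bad, 1.0, denom))
        return MatchResult(r, method, T.shape)

    # mean-subtracted forms. Σ T'·I' = Σ T'·I  because Σ T' = 0.
    t_prime = T - sum_t / n
    cc = signal.correlate(I, t_prime, mode="valid", method="auto")
    if method == "CC":
        return MatchResult(cc, method, T.shape)

    # NcC: normalize by the mean-subtracted energies
    sum_tp2 = float((t_prime * t_prime).sum())
    win_var = np.maximum(s2 - (s1 * s1) / n, 0.0)  # Σ I'² per window
    denom = np.sqrt(sum_tp2 * win_var)
    bad = denom <= _EPS
    r = np.where(bad, -1.0, cc / np.where(bad, 1.0, denom))
    return MatchResult(np.clip(r, -1.0, 1.0), method, T.shape)


# --------------------------------------------------------------------------
# per-layer segmentation
# --------------------------------------------------------------------------

def _peaks(result: MatchResult, threshold: float) -> list[tuple[float, int, int]]:
    """Local optima of the score matrix passing the threshold."""
    r = result.scores
    if result.higher_is_better:
        local = ndimage.maximum_filter(r, size=3, mode="nearest")
        sel = (r == local) & (r >= threshold)
    else:
        local = ndimage.minimum_filter(r, size=3, mode="nearest")
        sel = (r == local) & (r <= threshold)
    ys, xs = np.nonzero(sel)
    return [(float(r[y, x]), int(y), int(x)) for y, x in zip(ys, xs)]


def segment_layer(
    dapi: np.ndarray,
    templates: TemplateSet,
    config: RunConfig,
    return_contested: bool = False,
) -> np.ndarray:
    """Segment one preprocessed DAPI layer into a binary nucleus mask.

    Every template is matched with the configured method; peaks passing the
    threshold compete in a greedy non-maximum suppression that rejects any
    footprint overlapping an already accepted one by more than
    ``config.nms_overlap`` (intersection over the smaller footprint). The
    union of accepted footprints is intersected with the Otsu foreground.

    With ``return_contested=True`` also returns a mask of areas where a
    suppressed peak's centre fell outside every accepted footprint — the
    signature of two touching nuclei competing for one region. Nuclei built
    over contested area are not "clear individuals" and are discarded.
    """
    if len(templates) == 0:
        raise ValueError("template set is empty")
    dapi = np.asarray(dapi, dtype=float)
    H, W = dapi.shape

    candidates: list[tuple[float, int, int, int]] = []  # score, y, x, template idx
    for ti, T in enumerate(templates.templates):
        if T.shape[0] > H or T.shape[1] > W:
            continue
        res = match_template(dapi, T, config.match_method)
        for score, y, x in _peaks(res, config.match_threshold):
            candidates.append((score, y, x, ti))

    if not candidates:
        empty = np.zeros((H, W), dtype=bool)
        return (empty, empty.copy()) if return_contested else empty

    better = (lambda s: -s) if config.match_method not in ("SD", "NSD") else (lambda s: s)
    candidates.sort(key=lambda c: (better(c[0]), c[1], c[2], c[3]))

    min_center_sep_px = 1.0 / config.pixel_size_xy  # 1 μm
    accepted = np.zeros((H, W), dtype=bool)
    contested = np.zeros((H, W), dtype=bool)
    centers: list[tuple[float, float]] = []
    for score, y, x, ti in candidates:
        fp = templates.footprints[ti]
        fh, fw = fp.shape
        region = accepted[y : y + fh, x : x + fw]
        area = int(fp.sum())
        if area == 0:
            continue
        inter = int((region & fp).sum())
        if inter > config.nms_overlap * area:
            # suppressed: if its centre is outside every accepted footprint
            # and away from every accepted peak, a second nucleus touches here
            cy, cx = y + fh // 2, x + fw // 2
            far = all(
                np.hypot(cy - ay, cx - ax) > min_center_sep_px
                for ay, ax in centers
            )
            if far and not accepted[cy, cx]:
                contested[y : y + fh, x : x + fw] |= fp
            continue
        accepted[y : y + fh, x : x + fw] |= fp
        centers.append((y + fh / 2.0, x + fw / 2.0))

    fg = _otsu_foreground(dapi)
    mask = accepted & fg
    return (mask, contested) if return_contested else mask


def _otsu_foreground(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= _EPS:
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


# --------------------------------------------------------------------------
# labeling
# --------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def connected_components(mask: np.ndarray, min_size: int = 1) -> np.ndarray:
    """Label 8-connected foreground components in raster-scan order.

    Components smaller than ``min_size`` pixels — isolated vertices in the
    component hypergraph — are erased to background. Labels are positive
    integers assigned by the raster order of each surviving component's
    first pixel.
    """
    mask = np.asarray(mask).astype(bool)
    raw, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    sizes = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1))
    keep = sizes >= min_size

    # raster order of first occurrence
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]

    mapping = np.zeros(n + 1, dtype=np.int32)
    order = sorted(
        (int(lbl) for lbl in range(1, n + 1) if keep[lbl - 1]),
        key=lambda lbl: first[lbl],
    )
    for new, lbl in enumerate(order, start=1):
        mapping[lbl] = new
    return mapping[raw]


# --------------------------------------------------------------------------
# 3D linking
# --------------------------------------------------------------------------

@dataclass
class Nucleus3D:
    """One segmented nucleus spanning consecutive z layers."""

    id: int
    masks: dict[int, np.ndarray]  # layer -> 2D bool mask
    centroid_um: tuple[float, float, float]  # (X, Y, Z)
    layer_span: tuple[int, int]
    area_per_layer: dict[int, int]
    qc: str = "clear"  # "clear" | "discarded"
    discard_reason: str | None = None  # border | overlap | low_score | size

    @property
    def volume_px(self) -> int:
        return int(sum(self.area_per_layer.values()))

    def projection(self, shape: tuple[int, int]) -> np.ndarray:
        proj = np.zeros(shape, dtype=bool)
        for m in self.masks.values():
            proj |= m
        return proj


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_3d(labeled_layers: list[np.ndarray], config: RunConfig) -> list[Nucleus3D]:
    """Merge per-layer components into 3D nuclei and apply QC.

    Components on adjacent layers are merged when their pixel overlap,
    measured as intersection over the smaller area, exceeds
    ``config.link_overlap``. QC then discards nuclei that (a) touch the
    image border, (b) overlap another nucleus in z projection, or (c) fall
    outside the configured volume bounds.
    """
    if not labeled_layers:
        return []
    shape = labeled_layers[0].shape
    for lab in labeled_layers:
        if lab.shape != shape:
            raise ValueError("all layers must share extents")

    uf = _UnionFind()
    masks: dict[tuple[int, int], np.ndarray] = {}
    for li, lab in enumerate(labeled_layers):
        for lbl in np.unique(lab):
            if lbl > 0:
                masks[(li, int(lbl))] = lab == lbl
    for li in range(len(labeled_layers) - 1):
        a, b = labeled_layers[li], labeled_layers[li + 1]
        for lbl_a in np.unique(a):
            if lbl_a <= 0:
                continue
            ma = masks[(li, int(lbl_a))]
            for lbl_b in np.unique(b[ma]):
                if lbl_b <= 0:
                    continue
                mb = masks[(li + 1, int(lbl_b))]
                inter = int((ma & mb).sum())
                smaller = min(int(ma.sum()), int(mb.sum()))
                if smaller > 0 and inter / smaller > config.link_overlap:
                    uf.union((li, int(lbl_a)), (li + 1, int(lbl_b)))

    groups: dict = {}
    for key in masks:
        groups.setdefault(uf.find(key), []).append(key)

    # deterministic id order: by (first layer, raster position of first pixel)
    def group_key(members):
        li, lbl = min(members)
        ys, xs = np.nonzero(masks[(li, lbl)])
        return (li, int(ys[0]), int(xs[0]))

    nuclei: list[Nucleus3D] = []
    for nid, members in enumerate(
        sorted(groups.values(), key=group_key), start=1
    ):
        layer_masks: dict[int, np.ndarray] = {}
        for li, lbl in members:
            m = masks[(li, lbl)]
            layer_masks[li] = layer_masks.get(li, np.zeros(shape, bool)) | m
        layers = sorted(layer_masks)
        area = {li: int(layer_masks[li].sum()) for li in layers}
        tot = sum(area.values())
        cx = cy = cz = 0.0
        for li in layers:
            ys, xs = np.nonzero(layer_masks[li])
            cx += xs.sum()
            cy += ys.sum()
            cz += li * len(xs)
        centroid = (
            cx / tot * config.pixel_size_xy,
            cy / tot * config.pixel_size_xy,
            cz / tot * config.z_interval,
        )
        nuclei.append(
            Nucleus3D(
                id=nid,
                masks=layer_masks,
                centroid_um=centroid,
                layer_span=(layers[0], layers[-1]),
                area_per_layer=area,
            )
        )

    _apply_qc(nuclei, shape, config)
    return nuclei


def _apply_qc(nuclei: list[Nucleus3D], shape: tuple[int, int], config: RunConfig) -> None:
    H, W = shape
    border = np.zeros(shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True

    projections = {n.id: n.projection(shape) for n in nuclei}
    for n in nuclei:
        if any((m & border).any() for m in n.masks.values()):
            n.qc, n.discard_reason = "discarded", "border"
    for i, a in enumerate(nuclei):
        for b in nuclei[i + 1 :]:
            if (projections[a.id] & projections[b.id]).any():
                for n in (a, b):
                    if n.qc == "clear":
                        n.qc, n.discard_reason = "discarded", "overlap"
    if config.nucleus_volume_bounds is not None:
        lo, hi = config.nucleus_volume_bounds
        for n in nuclei:
            if n.qc == "clear" and not (lo <= n.volume_px <= hi):
                n.qc, n.discard_reason = "discarded", "size"


def segment_stack(
    dapi_layers: np.ndarray, templates: TemplateSet, config: RunConfig
) -> tuple[list[Nucleus3D], np.ndarray]:
    """Full DAPI segmentation: per-layer matching, labeling, 3D linking.

    Returns the nuclei plus a (layer, row, column) label volume for export.
    """
    min_size = config.min_size_px()
    labeled = []
    contested_any = np.zeros(dapi_layers.shape[1:], dtype=bool)
    for li in range(dapi_layers.shape[0]):
        mask, contested = segment_layer(
            dapi_layers[li], templates, config, return_contested=True
        )
        contested_any |= contested
        labeled.append(connected_components(mask, min_size))
    nuclei = link_3d(labeled, config)
    for n in nuclei:
        if n.qc == "clear" and (n.projection(contested_any.shape) & contested_any).any():
            n.qc, n.discard_reason = "discarded", "overlap"
    labels = np.zeros(dapi_layers.shape, dtype=np.uint16)
    for n in nuclei:
        for li, m in n.masks.items():
            labels[li][m] = n.id
    return nuclei, labels
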