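"""Synthetic confocal FISH z-stacks with known ground truth.

The generator emulates the acquisition geometry of a confocal whole-slide
scan: 7 focal planes 0.6 μm apart at 0.16 μm/pixel, a DAPI channel holding
ellipsoidal nuclei, and FITC/TRITC channels holding sub-resolution gene
signals rendered as isotropic (in μm) Gaussian blobs on the anisotropic
voxel grid. Every nucleus carries one of the five scoring patterns and the
spot constellation that defines it:

* co-localized partners are separated by at most half the break-apart
  cutoff (≤ 0.6 μm),
* break-apart partners by 1.5–3 cutoffs (1.8–3.6 μm),
* distinct signal sites by at least 2 μm,

so ground-truth labels sit far from the 1.2 μm decision boundary and stay
unambiguous. Spot centers lie on the voxel grid (pixel centers in XY,
layer planes in Z): the detector reports peak voxels, not sub-voxel fits,
so grid-aligned truth isolates method error from quantization error.

Same ``SynthParams`` (including seed) ⇒ bit-identical stack and truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .pairing import BREAKAPART, call_pairs, greedy_match
from .scoring import (
    BREAK_PATTERNS,
    MULTIPLE_COPY,
    NONTYPICAL_BREAK,
    NORMAL,
    OTHER,
    TYPICAL_BREAK,
    classify_nucleus,
)
from .spots import Spot
from .stack import ZStack

PATTERN_LABELS = (NORMAL, MULTIPLE_COPY, TYPICAL_BREAK, NONTYPICAL_BREAK, OTHER)

#: clinically negative-looking default mix (5% abnormal)
DEFAULT_MIX = {
    NORMAL: 0.85,
    MULTIPLE_COPY: 0.05,
    TYPICAL_BREAK: 0.025,
    NONTYPICAL_BREAK: 0.025,
    OTHER: 0.05,
}

_SITE_MIN_SEP = 2.0  # μm between distinct signal sites
_SPOT_SCALE = 0.7  # spots stay inside this fraction of the nucleus ellipsoid


class PlacementError(RuntimeError):
    """Geometry cannot accommodate the requested nuclei or spots."""


@dataclass
class SynthParams:
    """Knobs of the synthetic scanner; defaults match the target assay."""

    image_size: tuple[int, int] = (256, 256)  # (rows, columns)
    n_layers: int = 7
    pixel_size_xy: float = 0.16
    z_interval: float = 0.6
    n_nuclei: int = 4
    nucleus_radii_um: tuple[float, float] = (3.0, 4.5)  # semi-major range
    nucleus_max_aspect: float = 1.3
    nucleus_intensity: float = 8000.0
    spot_sigma_um: float = 0.3  # PSF σ = spot_diameter / 2
    spot_intensity: float = 20000.0
    background_level: float = 100.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sigma: float = 50.0
    pattern_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    overlap_pair: bool = False  # deliberately place two touching nuclei (QC tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or min(self.image_size) < 8:
            raise ValueError("image geometry too small")
        if self.pixel_size_xy <= 0 or self.z_interval <= 0:
            raise ValueError("calibration must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none|gaussian|poisson")
        bad = set(self.pattern_mix) - set(PATTERN_LABELS)
        if bad:
            raise ValueError(f"unknown pattern labels: {sorted(bad)}")
        total = sum(self.pattern_mix.values())
        if self.pattern_mix and abs(total - 1.0) > 1e-9:
            raise ValueError("pattern_mix proportions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "n_layers": self.n_layers,
            "pixel_size_xy": self.pixel_size_xy,
            "z_interval": self.z_interval,
            "n_nuclei": self.n_nuclei,
            "nucleus_radii_um": list(self.nucleus_radii_um),
            "nucleus_max_aspect": self.nucleus_max_aspect,
            "nucleus_intensity": self.nucleus_intensity,
            "spot_sigma_um": self.spot_sigma_um,
            "spot_intensity": self.spot_intensity,
            "background_level": self.background_level,
            "noise_model": self.noise_model,
            "noise_sigma": self.noise_sigma,
            "pattern_mix": dict(self.pattern_mix),
            "overlap_pair": self.overlap_pair,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        d = dict(d)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        if "nucleus_radii_um" in d:
            d["nucleus_radii_um"] = tuple(d["nucleus_radii_um"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthParams":
        import yaml

        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data or {})


@dataclass(frozen=True)
class NucleusGeometry:
    """Axis-rotated (in XY) ellipsoid in μm coordinates."""

    id: int
    center_um: tuple[float, float, float]  # (X, Y, Z)
    semi_axes_um: tuple[float, float, float]  # (a major-XY, b minor-XY, c z)
    angle_deg: float = 0.0

    def contains(self, p: tuple[float, float, float], scale: float = 1.0) -> bool:
        """Whether a μm point lies inside the scale-shrunk ellipsoid."""
        a, b, c = self.semi_axes_um
        if min(a, b, c) <= 0 or scale <= 0:
            return False
        dx = p[0] - self.center_um[0]
        dy = p[1] - self.center_um[1]
        dz = p[2] - self.center_um[2]
        th = np.deg2rad(self.angle_deg)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 + (
            dz / (c * scale)
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class GTSpot:
    nucleus_id: int
    channel: str
    index: int  # per-nucleus, per-channel
    position_um: tuple[float, float, float]


@dataclass(frozen=True)
class GTPair:
    nucleus_id: int
    fitc_index: int
    tritc_index: int
    distance_um: float
    colocalized: bool


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a synthetic case."""

    nuclei: list[NucleusGeometry]
    patterns: dict[int, str]  # nucleus id -> pattern label
    spots: list[GTSpot]
    expected_pairs: list[GTPair]
    expected_diagnosis: str | None  # None when there is nothing to score
    unclear_ids: tuple[int, ...] = ()  # deliberately overlapping nuclei

    def spots_of(self, nucleus_id: int, channel: str) -> list[GTSpot]:
        return [
            s
            for s in self.spots
            if s.nucleus_id == nucleus_id and s.channel == channel
        ]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "nuclei": [
                {
                    "id": n.id,
                    "center_um": list(n.center_um),
                    "semi_axes_um": list(n.semi_axes_um),
                    "angle_deg": n.angle_deg,
                    "pattern": self.patterns[n.id],
                }
                for n in self.nuclei
            ],
            "spots": [
                {
                    "nucleus_id": s.nucleus_id,
                    "channel": s.channel,
                    "index": s.index,
                    "position_um": list(s.position_um),
                }
                for s in self.spots
            ],
            "expected_pairs": [
                {
                    "nucleus_id": p.nucleus_id,
                    "fitc_index": p.fitc_index,
                    "tritc_index": p.tritc_index,
                    "distance_um": p.distance_um,
                    "colocalized": p.colocalized,
                }
                for p in self.expected_pairs
            ],
            "expected_diagnosis": self.expected_diagnosis,
            "unclear_ids": list(self.unclear_ids),
        }
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        nuclei = [
            NucleusGeometry(
                id=n["id"],
                center_um=tuple(n["center_um"]),
                semi_axes_um=tuple(n["semi_axes_um"]),
                angle_deg=n["angle_deg"],
            )
            for n in data["nuclei"]
        ]
        patterns = {n["id"]: n["pattern"] for n in data["nuclei"]}
        spots = [
            GTSpot(
                nucleus_id=s["nucleus_id"],
                channel=s["channel"],
                index=s["index"],
                position_um=tuple(s["position_um"]),
            )
            for s in data["spots"]
        ]
        pairs = [
            GTPair(
                nucleus_id=p["nucleus_id"],
                fitc_index=p["fitc_index"],
                tritc_index=p["tritc_index"],
                distance_um=p["distance_um"],
                colocalized=p["colocalized"],
            )
            for p in data["expected_pairs"]
        ]
        return cls(
            nuclei=nuclei,
            patterns=patterns,
            spots=spots,
            expected_pairs=pairs,
            expected_diagnosis=data["expected_diagnosis"],
            unclear_ids=tuple(data.get("unclear_ids", ())),
        )


# --------------------------------------------------------------------------
# spot placement
# --------------------------------------------------------------------------

def _quantize(
    p: tuple[float, float, float], params: SynthParams
) -> tuple[float, float, float]:
    px, zi = params.pixel_size_xy, params.z_interval
    return (
        round(p[0] / px) * px,
        round(p[1] / px) * px,
        round(p[2] / zi) * zi,
    )


def _dist(a, b) -> float:
    return float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))


def _sample_in_ellipsoid(
    nucleus: NucleusGeometry, rng: np.random.Generator, scale: float
) -> tuple[float, float, float]:
    a, b, c = nucleus.semi_axes_um
    th = np.deg2rad(nucleus.angle_deg)
    for _ in range(200):
        u, v, w = rng.uniform(-1, 1, size=3)
        if u * u + v * v + w * w > 1.0:
            continue
        dx = (u * np.cos(th) - v * np.sin(th)) * a * scale
        dy = (u * np.sin(th) + v * np.cos(th)) * b * scale
        dz = w * c * scale
        return (
            nucleus.center_um[0] + dx,
            nucleus.center_um[1] + dy,
            nucleus.center_um[2] + dz,
        )
    raise PlacementError("could not sample a point inside the nucleus")


def _pattern_recipe(pattern: str, rng: np.random.Generator) -> dict:
    """Counts of co-localized sites, lone FITC and lone TRITC sites.

    ``partner`` marks whether the first lone FITC and first lone TRITC site
    are a designated break-apart partner pair (constrained 1.8–3.6 μm
    apart).
    """
    if pattern == NORMAL:
        return {"coloc": 2, "lone_f": 0, "lone_t": 0, "partner": False}
    if pattern == MULTIPLE_COPY:
        return {"coloc": int(rng.integers(3, 5)), "lone_f": 0, "lone_t": 0, "partner": False}
    if pattern == TYPICAL_BREAK:
        return {"coloc": 1, "lone_f": 1, "lone_t": 1, "partner": True}
    if pattern == NONTYPICAL_BREAK:
        variant = rng.integers(0, 3)
        if variant == 0:
            return {"coloc": 1, "lone_f": 2, "lone_t": 1, "partner": True}
        if variant == 1:
            return {"coloc": 1, "lone_f": 1, "lone_t": 2, "partner": True}
        return {"coloc": 2, "lone_f": 1, "lone_t": 1, "partner": True}
    if pattern == OTHER:
        variant = rng.integers(0, 3)
        if variant == 0:
            return {"coloc": 1, "lone_f": 2, "lone_t": 0, "partner": False}
        if variant == 1:
            return {"coloc": 1, "lone_f": 0, "lone_t": 0, "partner": False}
        return {"coloc": 0, "lone_f": 1, "lone_t": 0, "partner": False}
    raise ValueError(f"unknown pattern {pattern!r}")


def place_pattern(
    pattern: str,
    nucleus: NucleusGeometry,
    rng: np.random.Generator,
    params: SynthParams | None = None,
) -> list[tuple[str, tuple[float, float, float]]]:
    """Place the spot constellation of one pattern inside a nucleus.

    Returns (channel, μm position) tuples, positions on the voxel grid.
    Raises :class:`PlacementError` when the nucleus cannot hold the
    required sites at the required separations.
    """
    params = params or SynthParams()
    recipe = _pattern_recipe(pattern, rng)
    cutoff = 1.2  # μm; decision constant of the assay
    coloc_max = 0.5 * cutoff
    band = (1.5 * cutoff, 3.0 * cutoff)

    for _restart in range(60):
        sites: list[tuple[float, float, float]] = []
        kinds: list[str] = []
        ok = True
        plan = (
            ["coloc"] * recipe["coloc"]
            + ["lone_f"] * recipe["lone_f"]
            + ["lone_t"] * recipe["lone_t"]
        )
        partner_base: tuple[float, float, float] | None = None
        for kind in plan:
            placed = False
            needs_partner_band = (
                recipe["partner"]
                and kind == "lone_t"
                and kinds.count("lone_t") == 0
                and "lone_f" in kinds
            )
            for _ in range(300):
                if needs_partner_band and partner_base is not None:
                    theta = rng.uniform(0, 2 * np.pi)
                    dz = float(rng.choice([-params.z_interval, 0.0, params.z_interval]))
                    length = rng.uniform(*band)
                    lxy = np.sqrt(max(length**2 - dz**2, 0.0))
                    p = (
                        partner_base[0] + lxy * np.cos(theta),
                        partner_base[1] + lxy * np.sin(theta),
                        partner_base[2] + dz,
                    )
                else:
                    p = _sample_in_ellipsoid(nucleus, rng, 0.65)
                q = _quantize(p, params)
                if not nucleus.contains(q, scale=_SPOT_SCALE):
                    continue
                if any(_dist(q, s) < _SITE_MIN_SEP for s in sites):
                    continue
                if needs_partner_band and partner_base is not None:
                    d = _dist(q, partner_base)
                    if not (band[0] <= d <= band[1] + 0.2):
                        continue
                sites.append(q)
                kinds.append(kind)
                if recipe["partner"] and kind == "lone_f" and partner_base is None:
                    partner_base = q
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        # expand sites into spots
        spots: list[tuple[str, tuple[float, float, float]]] = []
        feasible = True
        for kind, site in zip(kinds, sites):
            if kind == "lone_f":
                spots.append(("FITC", site))
            elif kind == "lone_t":
                spots.append(("TRITC", site))
            else:
                spots.append(("FITC", site))
                placed_t = False
                for _ in range(100):
                    sep = rng.uniform(0.0, coloc_max)
                    theta = rng.uniform(0, 2 * np.pi)
                    t = _quantize(
                        (
                            site[0] + sep * np.cos(theta),
                            site[1] + sep * np.sin(theta),
                            site[2],
                        ),
                        params,
                    )
                    if _dist(t, site) > coloc_max + 0.15:
                        continue
                    if not nucleus.contains(t, scale=_SPOT_SCALE):
                        continue
                    spots.append(("TRITC", t))
                    placed_t = True
                    break
                if not placed_t:
                    feasible = False
                    break
        if feasible:
            return spots
    raise PlacementError(
        f"nucleus {nucleus.id} too small for pattern {pattern!r} "
        f"(semi-axes {nucleus.semi_axes_um} μm)"
    )


# --------------------------------------------------------------------------
# case generation
# --------------------------------------------------------------------------

def _sample_nuclei(
    params: SynthParams, rng: np.random.Generator
) -> list[NucleusGeometry]:
    rows, cols = params.image_size
    extent_x = (cols - 1) * params.pixel_size_xy
    extent_y = (rows - 1) * params.pixel_size_xy
    mid_z = (params.n_layers - 1) * params.z_interval / 2.0
    r_lo, r_hi = params.nucleus_radii_um

    if params.overlap_pair and params.n_nuclei >= 2:
        if (params.n_layers - 1) * params.z_interval < 3.0:
            raise PlacementError("overlap_pair needs >= 3 μm of axial range")

    nuclei: list[NucleusGeometry] = []
    for i in range(params.n_nuclei):
        a = rng.uniform(r_lo, r_hi)
        aspect = rng.uniform(1.0, params.nucleus_max_aspect)
        b = a / aspect
        c = min(b, 1.3)
        angle = rng.uniform(0.0, 180.0)
        margin = a + 1.0
        if 2 * margin >= min(extent_x, extent_y):
            raise PlacementError("field too small for the requested nuclei")
        # the overlap pair sits at the same XY position, stacked axially:
        # the two nuclei overlap in z projection (XY separation well under
        # one semi-axis) without sharing any adjacent layer
        in_pair = params.overlap_pair and i in (0, 1) and params.n_nuclei >= 2
        if in_pair:
            c = 1.0
        force_overlap = in_pair and i == 1
        placed = False
        for _ in range(2000):
            if force_overlap:
                base = nuclei[0]
                theta = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(0.0, 0.2 * base.semi_axes_um[0])
                x = base.center_um[0] + d * np.cos(theta)
                y = base.center_um[1] + d * np.sin(theta)
                if not (margin <= x <= extent_x - margin and margin <= y <= extent_y - margin):
                    continue
            else:
                x = rng.uniform(margin, extent_x - margin)
                y = rng.uniform(margin, extent_y - margin)
            if in_pair:
                z = mid_z - 1.25 if i == 0 else mid_z + 1.25
            else:
                z = mid_z + rng.uniform(-0.3, 0.3)
            others = nuclei if not force_overlap else nuclei[1:]
            too_close = any(
                np.hypot(x - n.center_um[0], y - n.center_um[1])
                < a + n.semi_axes_um[0] + 2.0
                for n in others
            )
            if too_close:
                continue
            nuclei.append(
                NucleusGeometry(
                    id=i + 1,
                    center_um=(x, y, z),
                    semi_axes_um=(a, b, c),
                    angle_deg=angle,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1} of {params.n_nuclei} "
                f"in a {extent_x:.1f}×{extent_y:.1f} μm field"
            )
    return nuclei


def ground_truth_spots(
    gt: GroundTruth, nucleus_id: int
) -> tuple[list[Spot], list[Spot]]:
    """Ground-truth spots of one nucleus as pairing-ready Spot objects."""
    out = []
    for channel in ("FITC", "TRITC"):
        spots = []
        for s in gt.spots_of(nucleus_id, channel):
            x, y, z = s.position_um
            spots.append(
                Spot(
                    nucleus_id=nucleus_id,
                    channel=channel,
                    x_px=0,
                    y_px=0,
                    layer=0,
                    position_um=(x, y, z),
                    intensity=1.0,
                    id=s.index,
                )
            )
        out.append(spots)
    return out[0], out[1]


def _expected_pairs(
    gt_spots: list[GTSpot], nucleus_id: int, cutoff: float = 1.2
) -> list[GTPair]:
    fitc = [s for s in gt_spots if s.channel == "FITC"]
    tritc = [s for s in gt_spots if s.channel == "TRITC"]
    f_objs = [
        Spot(nucleus_id, "FITC", 0, 0, 0, s.position_um, 1.0, id=s.index)
        for s in fitc
    ]
    t_objs = [
        Spot(nucleus_id, "TRITC", 0, 0, 0, s.position_um, 1.0, id=s.index)
        for s in tritc
    ]
    pairs, _, _ = greedy_match(f_objs, t_objs)
    return [
        GTPair(
            nucleus_id=nucleus_id,
            fitc_index=p.fitc.id,
            tritc_index=p.tritc.id,
            distance_um=p.distance_um,
            colocalized=p.distance_um < cutoff,
        )
        for p in pairs
    ]


def generate_case(params: SynthParams) -> tuple[ZStack, GroundTruth]:
    """Render one synthetic case and its ground truth.

    Deterministic in ``params`` (including the seed). The rendered DAPI
    channel holds each nucleus as a per-layer filled ellipse cross-section;
    FITC/TRITC hold Gaussian spot profiles; noise (if any) is applied last.
    """
    rng = np.random.default_rng(params.seed)
    nuclei = _sample_nuclei(params, rng)

    labels = list(params.pattern_mix) or [NORMAL]
    probs = [params.pattern_mix[k] for k in labels] if params.pattern_mix else [1.0]
    patterns: dict[int, str] = {}
    gt_spots: list[GTSpot] = []
    for n in nuclei:
        pattern = str(rng.choice(labels, p=probs))
        patterns[n.id] = pattern
        idx = {"FITC": 0, "TRITC": 0}
        for channel, pos in place_pattern(pattern, n, rng, params):
            gt_spots.append(GTSpot(n.id, channel, idx[channel], pos))
            idx[channel] += 1
        # defensive: the constellation must satisfy the pattern's predicate
        placed = [s for s in gt_spots if s.nucleus_id == n.id]
        pairs = _expected_pairs(placed, n.id)
        n_coloc = sum(1 for p in pairs if p.colocalized)
        n_break = len(pairs) - n_coloc
        g = sum(1 for s in placed if s.channel == "FITC") - len(pairs) + n_break
        r = sum(1 for s in placed if s.channel == "TRITC") - len(pairs) + n_break
        label = classify_nucleus(n_coloc, g, r)
        if label != pattern:
            raise PlacementError(
                f"internal inconsistency: placed {pattern}, classifies as {label}"
            )

    expected_pairs: list[GTPair] = []
    for n in nuclei:
        expected_pairs.extend(
            _expected_pairs([s for s in gt_spots if s.nucleus_id == n.id], n.id)
        )

    diagnosis: str | None = None
    if nuclei:
        n_break_nuclei = sum(
            1 for p in patterns.values() if p in BREAK_PATTERNS
        )
        ratio = 100.0 * n_break_nuclei / len(nuclei)
        diagnosis = "negative" if ratio <= 10.0 else "positive"

    stack = _render(params, nuclei, gt_spots, rng)
    unclear = (1, 2) if params.overlap_pair and len(nuclei) >= 2 else ()
    gt = GroundTruth(
        nuclei=nuclei,
        patterns=patterns,
        spots=gt_spots,
        expected_pairs=expected_pairs,
        expected_diagnosis=diagnosis,
        unclear_ids=unclear,
    )
    return stack, gt


def _render(
    params: SynthParams,
    nuclei: list[NucleusGeometry],
    gt_spots: list[GTSpot],
    rng: np.random.Generator,
) -> ZStack:
    rows, cols = params.image_size
    L = params.n_layers
    px, zi = params.pixel_size_xy, params.z_interval
    vol = np.zeros((L, rows, cols, 3), dtype=float)
    vol += params.background_level

    # DAPI: per-layer filled ellipse cross-sections
    for n in nuclei:
        a, b, c = n.semi_axes_um
        th = np.deg2rad(n.angle_deg)
        for li in range(L):
            dz = li * zi - n.center_um[2]
            if abs(dz) >= c:
                continue
            s = np.sqrt(1.0 - (dz / c) ** 2)
            aa, bb = a * s, b * s
            cx, cy = n.center_um[0] / px, n.center_um[1] / px
            half = int(np.ceil(max(aa, bb) / px)) + 1
            x0, x1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(rows, int(cy) + half + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dx = (xx - cx) * px
            dy = (yy - cy) * px
            u = dx * np.cos(th) + dy * np.sin(th)
            v = -dx * np.sin(th) + dy * np.cos(th)
            inside = (u / aa) ** 2 + (v / bb) ** 2 <= 1.0
            region = vol[li, y0:y1, x0:x1, 0]
            region[inside] = np.maximum(region[inside], params.nucleus_intensity)

    # FITC / TRITC: isotropic-in-μm Gaussian blobs on the anisotropic grid
    chan_idx = {"FITC": 1, "TRITC": 2}
    sig = params.spot_sigma_um
    half_xy = int(np.ceil(4 * sig / px))
    half_z = int(np.ceil(4 * sig / zi))
    for s in gt_spots:
        X, Y, Z = s.position_um
        ci = chan_idx[s.channel]
        cx, cy, cl = X / px, Y / px, Z / zi
        x0, x1 = max(0, int(round(cx)) - half_xy), min(cols, int(round(cx)) + half_xy + 1)
        y0, y1 = max(0, int(round(cy)) - half_xy), min(rows, int(round(cy)) + half_xy + 1)
        l0, l1 = max(0, int(round(cl)) - half_z), min(L, int(round(cl)) + half_z + 1)
        for li in range(l0, l1):
            dz = li * zi - Z
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = ((xx * px - X) ** 2 + (yy * px - Y) ** 2 + dz**2) / (2 * sig**2)
            vol[li, y0:y1, x0:x1, ci] += params.spot_intensity * np.exp(-d2)

    if params.noise_model == "gaussian":
        vol = vol + rng.normal(0.0, params.noise_sigma, size=vol.shape)
    elif params.noise_model == "poisson":
        vol = rng.poisson(np.maximum(vol, 0.0)).astype(float)

    vol = np.clip(np.round(vol), 0, 65535).astype(np.uint16)
    return ZStack(
        voxels=vol,
        pixel_size_xy=px,
        z_interval=zi,
        channel_names=("DAPI", "FITC", "TRITC"),
    )
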