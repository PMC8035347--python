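"""FITC–TRITC pairing by ranked 3D distance.

Inside one nucleus, every FITC–TRITC spot pair defines an edge of a
weighted bipartite network whose weight is the 3D vector length

    |FITC TRITC| = √((X_F−X_T)² + (Y_F−Y_T)² + (Z_F−Z_T)²)   [μm]

Pairs are selected greedily: all candidates are sorted by increasing
distance, the shortest is accepted as an interaction, every remaining
candidate sharing either of its signals is removed, and the process repeats
until no candidates remain ("non-repetitive signals"). The greedy prune
always exhausts the smaller channel, so the accepted pair count is
min(|FITC|, |TRITC|).

An accepted pair is called co-localized when its distance is below the
break-apart cutoff and break-apart when it is at or above it — the cutoff
(default 1.2 μm) is defined as twice or more the 0.6 μm signal diameter,
so the boundary itself is break-apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from .config import RunConfig
from .spots import Spot

COLOCALIZED = "colocalized"
BREAKAPART = "breakapart"


@dataclass(frozen=True)
class PairCandidate:
    """One FITC–TRITC edge of the distance network."""

    fitc: Spot
    tritc: Spot
    distance_um: float


@dataclass(frozen=True)
class MatchedPair:
    """An accepted interaction with its co-localization call."""

    candidate: PairCandidate
    call: str  # COLOCALIZED | BREAKAPART

    @property
    def distance_um(self) -> float:
        return self.candidate.distance_um


def distance_3d(a: Spot, b: Spot) -> float:
    """Euclidean 3D vector length between two spots, in μm."""
    (xa, ya, za), (xb, yb, zb) = a.position_um, b.position_um
    return sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)


def greedy_match(
    fitc: list[Spot], tritc: list[Spot]
) -> tuple[list[PairCandidate], list[Spot], list[Spot]]:
    """Ranked greedy selection of non-repetitive FITC–TRITC interactions.

    Returns (accepted pairs in acceptance order, unpaired FITC, unpaired
    TRITC). Ties in distance are broken by (fitc id, tritc id) so the result
    is invariant to input ordering.
    """
    candidates = sorted(
        (
            PairCandidate(f, t, distance_3d(f, t))
            for f in fitc
            for t in tritc
        ),
        key=lambda c: (c.distance_um, c.fitc.id, c.tritc.id),
    )
    accepted: list[PairCandidate] = []
    used_f: set[int] = set()
    used_t: set[int] = set()
    for cand in candidates:
        if cand.fitc.id in used_f or cand.tritc.id in used_t:
            continue
        accepted.append(cand)
        used_f.add(cand.fitc.id)
        used_t.add(cand.tritc.id)
    unpaired_f = [s for s in fitc if s.id not in used_f]
    unpaired_t = [s for s in tritc if s.id not in used_t]
    return accepted, unpaired_f, unpaired_t


def call_pairs(
    pairs: list[PairCandidate], config: RunConfig
) -> list[MatchedPair]:
    """Co-localized vs break-apart call for each accepted pair.

    Break-apart iff distance ≥ ``breakapart_cutoff_um`` (boundary inclusive:
    the cutoff is defined as "twice or more" the signal diameter).
    """
    cutoff = config.breakapart_cutoff_um
    if cutoff <= 0:
        raise ValueError("break-apart cutoff must be > 0")
    return [
        MatchedPair(c, BREAKAPART if c.distance_um >= cutoff else COLOCALIZED)
        for c in pairs
    ]


def match_nucleus(
    fitc: list[Spot], tritc: list[Spot], config: RunConfig
) -> tuple[list[MatchedPair], list[Spot], list[Spot]]:
    """greedy_match + call_pairs in one step."""
    pairs, un_f, un_t = greedy_match(fitc, tritc)
    return call_pairs(pairs, config), un_f, un_t
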