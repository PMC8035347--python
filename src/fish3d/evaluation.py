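"""Behavioral sweeps that recover the pipeline's decision constants.

These run the package's own machinery on controlled synthetic inputs and
locate the change points of its decisions: the separation at which a pair
flips to break-apart, the abnormal fraction at which a case flips to
positive, and the fusion count that defines the normal pattern.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .pairing import BREAKAPART, match_nucleus
from .scoring import (
    NORMAL,
    TYPICAL_BREAK,
    NONTYPICAL_BREAK,
    classify_nucleus,
    score_case,
    score_nucleus,
)
from .spots import Spot
from .synth import NucleusGeometry, place_pattern


def _spot(channel: str, pos, spot_id: int, nucleus_id: int = 1) -> Spot:
    return Spot(
        nucleus_id=nucleus_id,
        channel=channel,
        x_px=0,
        y_px=0,
        layer=0,
        position_um=tuple(pos),
        intensity=1.0,
        id=spot_id,
    )


def breakapart_change_point(
    separations_um: np.ndarray, config: RunConfig | None = None
) -> float:
    """Smallest separation (μm) at which a FITC–TRITC pair is called
    break-apart, over a sweep of synthetic pairs at the given separations."""
    config = config or RunConfig()
    flipped = []
    for s in separations_um:
        fitc = [_spot("FITC", (0.0, 0.0, 0.0), 0)]
        tritc = [_spot("TRITC", (float(s), 0.0, 0.0), 0)]
        pairs, _, _ = match_nucleus(fitc, tritc, config)
        if pairs[0].call == BREAKAPART:
            flipped.append(float(s))
    if not flipped:
        raise ValueError("no separation in the sweep was called break-apart")
    return min(flipped)


def _nucleus_score_from_pattern(
    pattern: str,
    nucleus_id: int,
    rng: np.random.Generator,
    config: RunConfig,
    geometry: NucleusGeometry | None = None,
):
    """Place one pattern's spots and push them through pairing + scoring."""
    geometry = geometry or NucleusGeometry(
        id=nucleus_id, center_um=(12.0, 12.0, 1.8), semi_axes_um=(4.0, 3.2, 1.3)
    )
    placed = place_pattern(pattern, geometry, rng)
    fitc = [
        _spot("FITC", p, i, nucleus_id)
        for i, (ch, p) in enumerate(s for s in placed if s[0] == "FITC")
    ]
    tritc = [
        _spot("TRITC", p, i, nucleus_id)
        for i, (ch, p) in enumerate(s for s in placed if s[0] == "TRITC")
    ]
    pairs, un_f, un_t = match_nucleus(fitc, tritc, config)
    return score_nucleus(nucleus_id, pairs, un_f, un_t)


def diagnosis_change_point(
    abnormal_percents: np.ndarray,
    n_nuclei: int = 100,
    seed: int = 0,
    config: RunConfig | None = None,
) -> float:
    """Largest abnormal-pattern percentage still diagnosed negative.

    For each percentage f, a case of ``n_nuclei`` nuclei is synthesized in
    which round(f·n/100) nuclei carry break-apart patterns (alternating
    typical and non-typical) and the rest are normal; each nucleus's spots
    are placed geometrically and run through matching, classification and
    case scoring.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    negatives = []
    for f in abnormal_percents:
        k = int(round(f * n_nuclei / 100.0))
        scores = []
        for i in range(n_nuclei):
            if i < k:
                pattern = TYPICAL_BREAK if i % 2 == 0 else NONTYPICAL_BREAK
            else:
                pattern = NORMAL
            scores.append(_nucleus_score_from_pattern(pattern, i + 1, rng, config))
        report = score_case(scores, config)
        if report.diagnosis == "negative":
            negatives.append(float(f))
    if not negatives:
        raise ValueError("no fraction in the sweep was diagnosed negative")
    return max(negatives)


def normal_pattern_fusion_counts(k_values: range | list[int]) -> list[int]:
    """Which fusion counts k (k co-localized pairs, no unpaired signals)
    classify as the normal pattern."""
    return [int(k) for k in k_values if classify_nucleus(int(k), 0, 0) == NORMAL]
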