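"""Nucleus pattern classification and case-level diagnosis.

Each scored nucleus reduces to a triple (C, G, R):

* C — number of co-localized (fusion) FITC–TRITC pairs,
* G — split FITC signals: unpaired FITC plus the FITC member of every
  break-apart-called pair,
* R — split TRITC signals, likewise.

Patterns:

* ``normal``            C = 2, G = R = 0 (two intact alleles)
* ``multiple_copy``     C > 2, G = R = 0 (all signals fused)
* ``typical_break``     C = 1, G = 1, R = 1 (one intact, one split allele)
* ``nontypical_break``  G ≥ 1 and R ≥ 1, not typical (variant rearrangements
  from truncation, deletion, extra copies, ...)
* ``other``             any remaining combination with at least one signal
  (e.g. a lone fusion, or split signals of only one color)

A nucleus with no signals at all is dropped from counting (``discarded``).
The case is negative when at most ``abnormal_fraction_cutoff`` percent
(default 10%) of counted nuclei show a break-apart pattern, positive
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .config import RunConfig
from .pairing import BREAKAPART, COLOCALIZED, MatchedPair
from .spots import Spot

NORMAL = "normal"
MULTIPLE_COPY = "multiple_copy"
TYPICAL_BREAK = "typical_break"
NONTYPICAL_BREAK = "nontypical_break"
OTHER = "other"
DISCARDED = "discarded"

PATTERNS = (NORMAL, MULTIPLE_COPY, TYPICAL_BREAK, NONTYPICAL_BREAK, OTHER)
BREAK_PATTERNS = (TYPICAL_BREAK, NONTYPICAL_BREAK)


class NoScoreableNucleiError(RuntimeError):
    """Raised when a case has no counted nuclei to diagnose."""


@dataclass(frozen=True)
class NucleusScore:
    """Signal counts and the resulting pattern for one nucleus."""

    nucleus_id: int
    n_coloc: int
    n_break_pairs: int
    n_unpaired_fitc: int
    n_unpaired_tritc: int
    pattern: str

    @property
    def split_fitc(self) -> int:
        return self.n_unpaired_fitc + self.n_break_pairs

    @property
    def split_tritc(self) -> int:
        return self.n_unpaired_tritc + self.n_break_pairs


def classify_nucleus(C: int, G: int, R: int) -> str:
    """Pattern label from (fusion count, split FITC count, split TRITC count).

    Total on non-negative triples; zero-signal nuclei map to ``discarded``.
    """
    if min(C, G, R) < 0:
        raise ValueError("counts must be non-negative")
    if C == 2 and G == 0 and R == 0:
        return NORMAL
    if C > 2 and G == 0 and R == 0:
        return MULTIPLE_COPY
    if C == 1 and G == 1 and R == 1:
        return TYPICAL_BREAK
    if G >= 1 and R >= 1:
        return NONTYPICAL_BREAK
    if C + G + R > 0:
        return OTHER
    return DISCARDED


def score_nucleus(
    nucleus_id: int,
    pairs: list[MatchedPair],
    unpaired_fitc: list[Spot],
    unpaired_tritc: list[Spot],
) -> NucleusScore:
    """Reduce one nucleus's matching result to counts and a pattern.

    A break-apart-called pair contributes one split FITC and one split
    TRITC signal; a co-localized pair contributes one fusion.
    """
    n_coloc = sum(1 for p in pairs if p.call == COLOCALIZED)
    n_break = sum(1 for p in pairs if p.call == BREAKAPART)
    g = len(unpaired_fitc) + n_break
    r = len(unpaired_tritc) + n_break
    return NucleusScore(
        nucleus_id=nucleus_id,
        n_coloc=n_coloc,
        n_break_pairs=n_break,
        n_unpaired_fitc=len(unpaired_fitc),
        n_unpaired_tritc=len(unpaired_tritc),
        pattern=classify_nucleus(n_coloc, g, r),
    )


@dataclass(frozen=True)
class CaseReport:
    """Per-pattern counts, ratios and the case diagnosis.

    ``discarded`` counts segmentation-discarded nuclei, zero-signal nuclei
    and manually removed nuclei; none of them enter the ratios.
    """

    scores: tuple[NucleusScore, ...]
    abnormal_fraction_cutoff: float
    abnormal_includes_other: bool = False
    n_discarded_segmentation: int = 0
    removed_ids: frozenset[int] = frozenset()

    def _counted(self) -> list[NucleusScore]:
        return [
            s
            for s in self.scores
            if s.pattern != DISCARDED and s.nucleus_id not in self.removed_ids
        ]

    @property
    def total_counted(self) -> int:
        return len(self._counted())

    @property
    def discarded(self) -> int:
        zero_signal = sum(1 for s in self.scores if s.pattern == DISCARDED)
        removed = sum(
            1
            for s in self.scores
            if s.nucleus_id in self.removed_ids and s.pattern != DISCARDED
        )
        return self.n_discarded_segmentation + zero_signal + removed

    @property
    def pattern_counts(self) -> dict[str, int]:
        counted = self._counted()
        return {p: sum(1 for s in counted if s.pattern == p) for p in PATTERNS}

    @property
    def pattern_percent(self) -> dict[str, float]:
        n = self.total_counted
        if n == 0:
            return {p: 0.0 for p in PATTERNS}
        return {p: 100.0 * c / n for p, c in self.pattern_counts.items()}

    @property
    def breakapart_ratio(self) -> float:
        """Percent of counted nuclei with an abnormal (break-apart) pattern."""
        n = self.total_counted
        if n == 0:
            raise NoScoreableNucleiError("no counted nuclei in case")
        abnormal = set(BREAK_PATTERNS)
        if self.abnormal_includes_other:
            abnormal.add(OTHER)
        k = sum(1 for s in self._counted() if s.pattern in abnormal)
        return 100.0 * k / n

    @property
    def normal_multiple_ratio(self) -> float:
        n = self.total_counted
        if n == 0:
            raise NoScoreableNucleiError("no counted nuclei in case")
        k = sum(
            1 for s in self._counted() if s.pattern in (NORMAL, MULTIPLE_COPY)
        )
        return 100.0 * k / n

    @property
    def diagnosis(self) -> str:
        """negative iff the abnormal fraction is at or below the cutoff."""
        return (
            "negative"
            if self.breakapart_ratio <= self.abnormal_fraction_cutoff
            else "positive"
        )

    def to_dict(self) -> dict:
        return {
            "total_counted": self.total_counted,
            "discarded": self.discarded,
            "pattern_counts": self.pattern_counts,
            "pattern_percent": {
                p: round(v, 1) for p, v in self.pattern_percent.items()
            },
            "breakapart_ratio": round(self.breakapart_ratio, 1),
            "normal_multiple_ratio": round(self.normal_multiple_ratio, 1),
            "diagnosis": self.diagnosis,
            "abnormal_fraction_cutoff": self.abnormal_fraction_cutoff,
            "abnormal_includes_other": self.abnormal_includes_other,
            "removed_ids": sorted(self.removed_ids),
            "nuclei": [
                {
                    "nucleus_id": s.nucleus_id,
                    "n_coloc": s.n_coloc,
                    "n_break_pairs": s.n_break_pairs,
                    "n_unpaired_fitc": s.n_unpaired_fitc,
                    "n_unpaired_tritc": s.n_unpaired_tritc,
                    "pattern": s.pattern,
                    "removed": s.nucleus_id in self.removed_ids,
                }
                for s in self.scores
            ],
        }


def score_case(
    scores: list[NucleusScore],
    config: RunConfig,
    n_discarded_segmentation: int = 0,
) -> CaseReport:
    """Aggregate per-nucleus scores into a CaseReport with a diagnosis."""
    report = CaseReport(
        scores=tuple(scores),
        abnormal_fraction_cutoff=config.abnormal_fraction_cutoff,
        abnormal_includes_other=config.abnormal_includes_other,
        n_discarded_segmentation=n_discarded_segmentation,
    )
    if report.total_counted == 0:
        raise NoScoreableNucleiError("no counted nuclei in case")
    return report


def remove_nucleus(report: CaseReport, nucleus_id: int) -> CaseReport:
    """Move one nucleus to discarded and recompute all ratios.

    Idempotent; unknown ids raise KeyError.
    """
    known = {s.nucleus_id for s in report.scores}
    if nucleus_id not in known:
        raise KeyError(f"unknown nucleus id {nucleus_id}")
    if nucleus_id in report.removed_ids:
        return report
    return replace(report, removed_ids=report.removed_ids | {nucleus_id})
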