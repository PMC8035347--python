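"""End-to-end orchestration: stack → preprocess → segment → spots →
pairing → scoring, plus the tabular/report artifacts of one run.

Artifacts written per case directory: ``spots.csv``, ``pairs.csv``,
``nuclei.csv``, ``report.json``, ``report.csv``, ``labels.tiff`` (16-bit
nucleus label volume for inspection) and ``run.log``. All CSV/JSON output
is deterministic given (input files, config, seed); timestamps go to the
log only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .pairing import MatchedPair, match_nucleus
from .preprocess import preprocess_stack
from .scoring import CaseReport, NucleusScore, score_case, score_nucleus
from .segmentation import Nucleus3D, TemplateSet, segment_stack
from .spots import Spot, detect_spots
from .stack import ZStack, read_stack

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class PipelineResult:
    """Everything one scoring run produced."""

    report: CaseReport
    nuclei: list[Nucleus3D]
    spots: list[Spot]
    pairs: list[tuple[int, MatchedPair]]  # (nucleus id, pair)
    labels: np.ndarray
    log_records: list[StageRecord] = field(default_factory=list)


def run_pipeline(
    stack: ZStack | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Score one case end to end.

    ``stack`` may be a ZStack or a path to a multi-page TIFF. When
    ``out_dir`` is given, all artifacts are written there.
    """
    config = config or RunConfig()
    records: list[StageRecord] = []

    def record(stage: str, n_in: int, n_out: int, t0: float) -> None:
        rec = StageRecord(stage, n_in, n_out, time.perf_counter() - t0)
        records.append(rec)
        log.info("stage=%s in=%d out=%d t=%.2fs", stage, n_in, n_out, rec.seconds)

    t0 = time.perf_counter()
    if not isinstance(stack, ZStack):
        try:
            stack = read_stack(stack, config)
        except Exception as exc:
            raise StageError("read", str(exc)) from exc
    for name in ("DAPI", "FITC", "TRITC"):
        if name not in stack.channel_names:
            raise StageError("read", f"required channel {name!r} missing from stack")
    record("read", 1, stack.n_layers, t0)

    t0 = time.perf_counter()
    pre = preprocess_stack(stack, config)
    record("preprocess", stack.n_layers, pre.n_layers, t0)

    t0 = time.perf_counter()
    try:
        if config.template_dir:
            templates = TemplateSet.from_dir(config.template_dir)
        else:
            templates = TemplateSet.parametric(config)
        nuclei, labels = segment_stack(pre.channel("DAPI"), templates, config)
    except Exception as exc:
        raise StageError("segment", str(exc)) from exc
    clear = [n for n in nuclei if n.qc == "clear"]
    record("segment", pre.n_layers, len(nuclei), t0)

    t0 = time.perf_counter()
    all_spots: list[Spot] = []
    spots_by_nucleus: dict[int, dict[str, list[Spot]]] = {}
    for n in clear:
        per = {}
        for channel in ("FITC", "TRITC"):
            per[channel] = detect_spots(pre.channel(channel), n, channel, config)
            all_spots.extend(per[channel])
        spots_by_nucleus[n.id] = per
    record("spots", len(clear), len(all_spots), t0)

    t0 = time.perf_counter()
    scores: list[NucleusScore] = []
    all_pairs: list[tuple[int, MatchedPair]] = []
    for n in clear:
        pairs, un_f, un_t = match_nucleus(
            spots_by_nucleus[n.id]["FITC"],
            spots_by_nucleus[n.id]["TRITC"],
            config,
        )
        all_pairs.extend((n.id, p) for p in pairs)
        scores.append(score_nucleus(n.id, pairs, un_f, un_t))
    record("pairing", len(all_spots), len(all_pairs), t0)

    t0 = time.perf_counter()
    n_discarded = sum(1 for n in nuclei if n.qc == "discarded")
    try:
        report = score_case(scores, config, n_discarded_segmentation=n_discarded)
    except Exception as exc:
        raise StageError("scoring", str(exc)) from exc
    record("scoring", len(scores), report.total_counted, t0)

    result = PipelineResult(
        report=report,
        nuclei=nuclei,
        spots=all_spots,
        pairs=all_pairs,
        labels=labels,
        log_records=records,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir), config)
    return result


# --------------------------------------------------------------------------
# artifact export
# --------------------------------------------------------------------------

def spots_table(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": s.nucleus_id,
                "channel": s.channel,
                "spot_id": s.id,
                "x_px": s.x_px,
                "y_px": s.y_px,
                "layer": s.layer,
                "X_um": round(s.position_um[0], 4),
                "Y_um": round(s.position_um[1], 4),
                "Z_um": round(s.position_um[2], 4),
                "intensity": round(s.intensity, 2),
            }
            for s in spots
        ],
        columns=[
            "nucleus_id", "channel", "spot_id", "x_px", "y_px", "layer",
            "X_um", "Y_um", "Z_um", "intensity",
        ],
    )


def pairs_table(pairs: list[tuple[int, MatchedPair]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": nid,
                "fitc_id": p.candidate.fitc.id,
                "tritc_id": p.candidate.tritc.id,
                "distance_um": round(p.distance_um, 4),
                "call": p.call,
            }
            for nid, p in pairs
        ],
        columns=["nucleus_id", "fitc_id", "tritc_id", "distance_um", "call"],
    )


def nuclei_table(nuclei: list[Nucleus3D]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": n.id,
                "X_um": round(n.centroid_um[0], 4),
                "Y_um": round(n.centroid_um[1], 4),
                "Z_um": round(n.centroid_um[2], 4),
                "first_layer": n.layer_span[0],
                "last_layer": n.layer_span[1],
                "volume_px": n.volume_px,
                "qc": n.qc,
                "discard_reason": n.discard_reason or "",
            }
            for n in nuclei
        ],
        columns=[
            "nucleus_id", "X_um", "Y_um", "Z_um", "first_layer", "last_layer",
            "volume_px", "qc", "discard_reason",
        ],
    )


def report_csv(report: CaseReport) -> pd.DataFrame:
    d = report.to_dict()
    rows = [
        {"metric": "total_counted", "value": d["total_counted"]},
        {"metric": "discarded", "value": d["discarded"]},
    ]
    for p, c in d["pattern_counts"].items():
        rows.append({"metric": f"count_{p}", "value": c})
        rows.append({"metric": f"percent_{p}", "value": d["pattern_percent"][p]})
    rows += [
        {"metric": "breakapart_ratio", "value": d["breakapart_ratio"]},
        {"metric": "normal_multiple_ratio", "value": d["normal_multiple_ratio"]},
        {"metric": "diagnosis", "value": d["diagnosis"]},
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_report(report: CaseReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    report_csv(report).to_csv(out_dir / "report.csv", index=False)


def write_artifacts(result: PipelineResult, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    spots_table(result.spots).to_csv(out_dir / "spots.csv", index=False)
    pairs_table(result.pairs).to_csv(out_dir / "pairs.csv", index=False)
    nuclei_table(result.nuclei).to_csv(out_dir / "nuclei.csv", index=False)
    write_report(result.report, out_dir)
    tifffile.imwrite(out_dir / "labels.tiff", result.labels.astype(np.uint16))
    config.to_file(out_dir / "config_used.yaml")
    with open(out_dir / "run.log", "w") as fh:
        for rec in result.log_records:
            fh.write(
                f"stage={rec.stage} in={rec.n_in} out={rec.n_out} "
                f"t={rec.seconds:.3f}s\n"
            )


def load_report(out_dir: str | Path) -> CaseReport:
    """Rebuild a CaseReport from a previously written report.json."""
    d = json.loads((Path(out_dir) / "report.json").read_text())
    scores = tuple(
        NucleusScore(
            nucleus_id=n["nucleus_id"],
            n_coloc=n["n_coloc"],
            n_break_pairs=n["n_break_pairs"],
            n_unpaired_fitc=n["n_unpaired_fitc"],
            n_unpaired_tritc=n["n_unpaired_tritc"],
            pattern=n["pattern"],
        )
        for n in d["nuclei"]
    )
    counted_patterns = {
        n["nucleus_id"] for n in d["nuclei"] if n["pattern"] != "discarded"
    }
    removed = frozenset(d.get("removed_ids", []))
    # discarded = segmentation + zero-signal + removed; invert for the field
    zero_signal = sum(1 for n in d["nuclei"] if n["pattern"] == "discarded")
    n_removed = len(removed & counted_patterns)
    return CaseReport(
        scores=scores,
        abnormal_fraction_cutoff=d["abnormal_fraction_cutoff"],
        abnormal_includes_other=d["abnormal_includes_other"],
        n_discarded_segmentation=d["discarded"] - zero_signal - n_removed,
        removed_ids=removed,
    )
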