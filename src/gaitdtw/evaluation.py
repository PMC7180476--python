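"""Event-level scoring of detections against annotated stance intervals.

A detected step is correct when the mean of its start and end times lies
inside an annotated step; an annotated step may be claimed by at most one
detection, and when several detections fall inside the same annotation
only the one whose midpoint is closest to the annotation's midpoint
survives (tie to the earlier detection). Recall uses the symmetric rule
with the roles swapped: an annotated step is detected when its midpoint
lies inside a detected step, again one-to-one.

Timing errors ΔStart, ΔEnd and ΔDuration are the per-correct-step
absolute differences between detected and annotated IC, FC and duration,
reported in milliseconds (samples x 1000 / sampling rate); signed values
are retained for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Detection, EvalReport, StepAnnotation, validate_annotations

__all__ = ["Matching", "match_detections", "precision_recall", "timing_errors",
           "evaluate", "evaluate_cohort"]


@dataclass
class Matching:
    """One-to-one correspondence between detections and annotations."""

    pairs: list[tuple[Detection, StepAnnotation]] = field(default_factory=list)
    false_detections: list[Detection] = field(default_factory=list)
    missed_annotations: list[StepAnnotation] = field(default_factory=list)


def _midpoint_inside(mid: float, lo: int, hi: int) -> bool:
    return lo <= mid <= hi  # both endpoints inclusive; midpoints compared as reals


def match_detections(
    detected: Sequence[Detection], annotated: Sequence[StepAnnotation]
) -> Matching:
    """Match each detection to the annotation containing its midpoint.

    Annotations must be non-overlapping, so a detection midpoint lies in
    at most one annotation. Duplicates resolve to the detection whose
    midpoint is closest to the annotation midpoint, tie to the earlier
    detection; the rest are false.
    """
    anns = validate_annotations(annotated)
    dets = sorted(detected, key=lambda d: (d.ic, d.fc))
    claims: dict[int, list[Detection]] = {}
    false: list[Detection] = []
    for d in dets:
        hit = None
        for ai, a in enumerate(anns):
            if _midpoint_inside(d.midpoint, a.ic, a.fc):
                hit = ai
                break
        if hit is None:
            false.append(d)
        else:
            claims.setdefault(hit, []).append(d)
    pairs: list[tuple[Detection, StepAnnotation]] = []
    for ai, cands in claims.items():
        a = anns[ai]
        keep = min(cands, key=lambda d: (abs(d.midpoint - a.midpoint), d.ic))
        pairs.append((keep, a))
        false.extend(d for d in cands if d is not keep)
    matched_anns = {id(a) for _, a in pairs}
    missed = [a for a in anns if id(a) not in matched_anns]
    pairs.sort(key=lambda p: p[0].ic)
    return Matching(pairs=pairs, false_detections=false, missed_annotations=missed)


def _recall_count(detected: Sequence[Detection], annotated: Sequence[StepAnnotation]) -> int:
    """Number of annotations detected under the symmetric midpoint rule."""
    anns = validate_annotations(annotated)
    dets = sorted(detected, key=lambda d: (d.ic, d.fc))
    used: set[int] = set()
    count = 0
    for a in anns:
        # candidate detections containing this annotation's midpoint, not
        # yet used: a detection can only detect one annotated step, so
        # extra annotations inside the same detection stay undetected
        cands = [di for di, d in enumerate(dets)
                 if di not in used and _midpoint_inside(a.midpoint, d.ic, d.fc)]
        if cands:
            best = min(cands, key=lambda di: (abs(dets[di].midpoint - a.midpoint), dets[di].ic))
            used.add(best)
            count += 1
    return count


def precision_recall(
    detected: Sequence[Detection], annotated: Sequence[StepAnnotation]
) -> tuple[Optional[float], Optional[float]]:
    """(precision, recall); None where the denominator set is empty."""
    precision: Optional[float] = None
    recall: Optional[float] = None
    if len(detected) > 0:
        matching = match_detections(detected, annotated)
        precision = len(matching.pairs) / len(detected)
    if len(annotated) > 0:
        recall = _recall_count(detected, annotated) / len(annotated)
    return precision, recall


def timing_errors(
    matching: Matching, sampling_rate_hz: float = 100.0
) -> dict[str, np.ndarray]:
    """Per-correct-detection signed and absolute timing errors in ms."""
    ms = 1000.0 / sampling_rate_hz
    signed_start = np.array([(d.ic - a.ic) * ms for d, a in matching.pairs])
    signed_end = np.array([(d.fc - a.fc) * ms for d, a in matching.pairs])
    signed_dur = np.array([(d.duration - a.duration) * ms for d, a in matching.pairs])
    return {
        "delta_start_ms": np.abs(signed_start),
        "delta_end_ms": np.abs(signed_end),
        "delta_duration_ms": np.abs(signed_dur),
        "signed_start_ms": signed_start,
        "signed_end_ms": signed_end,
        "signed_duration_ms": signed_dur,
    }


def evaluate(
    detected: Sequence[Detection],
    annotated: Sequence[StepAnnotation],
    sampling_rate_hz: float = 100.0,
) -> EvalReport:
    """Full report: precision, recall and timing-error distributions."""
    precision, recall = precision_recall(detected, annotated)
    matching = match_detections(detected, annotated) if len(detected) else Matching()
    errors = timing_errors(matching, sampling_rate_hz)
    return EvalReport(
        precision=precision,
        recall=recall,
        n_detected=len(detected),
        n_annotated=len(annotated),
        n_correct=len(matching.pairs),
        **errors,
    )


def evaluate_cohort(
    per_trial: Sequence[tuple[Sequence[Detection], Sequence[StepAnnotation]]],
    sampling_rate_hz: float = 100.0,
) -> EvalReport:
    """Pooled report over trials: counts are summed, per-step errors concatenated.

    Precision and recall are computed from the pooled counts (equivalent
    to weighting each trial by its number of detections/annotations).
    """
    n_detected = n_annotated = n_correct = n_recalled = 0
    errors = {k: [] for k in ("delta_start_ms", "delta_end_ms", "delta_duration_ms",
                              "signed_start_ms", "signed_end_ms", "signed_duration_ms")}
    for detected, annotated in per_trial:
        n_detected += len(detected)
        n_annotated += len(annotated)
        if len(detected):
            matching = match_detections(detected, annotated)
            n_correct += len(matching.pairs)
            for k, v in timing_errors(matching, sampling_rate_hz).items():
                errors[k].append(v)
        if len(annotated):
            n_recalled += _recall_count(detected, annotated)
    concat = {k: (np.concatenate(v) if v else np.array([])) for k, v in errors.items()}
    return EvalReport(
        precision=(n_correct / n_detected) if n_detected else None,
        recall=(n_recalled / n_annotated) if n_annotated else None,
        n_detected=n_detected,
        n_annotated=n_annotated,
        n_correct=n_correct,
        **concat,
    )
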