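"""Detector evaluation: match detections to ground truth and compute
precision, recall, and false alarms per hour.

A detection matches an annotation when it overlaps the annotation by at
least half of the annotation's extent independently in time and in
frequency. Matching is one-to-one, greedy in descending detection score.
"""

from __future__ import annotations

from .types import Annotation, Detection, DetectionMetrics, MatchResult


def overlap_fraction(det: Detection, ann: Annotation) -> tuple[float, float]:
    """Fraction of the annotation's time and frequency extent covered by
    the detection (annotation-referenced, not IoU)."""
    t_extent = ann.end_s - ann.start_s
    f_extent = ann.high_hz - ann.low_hz
    if t_extent <= 0 or f_extent <= 0:
        raise ValueError("zero-extent annotation")
    t_inter = max(0.0, min(det.end_s, ann.end_s) - max(det.start_s, ann.start_s))
    f_inter = max(0.0, min(det.high_hz, ann.high_hz) - max(det.low_hz, ann.low_hz))
    return t_inter / t_extent, f_inter / f_extent


def match_detections(
    detections: list[Detection],
    annotations: list[Annotation] | object,
    min_overlap: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending detection score.

    A pair is eligible iff both the time and the frequency overlap fraction
    reach ``min_overlap``. Among eligible annotations the one with the
    largest combined overlap is taken; each detection and annotation is used
    at most once.
    """
    anns = list(annotations)
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].score, detections[i].start_s),
    )
    unmatched_ann = set(range(len(anns)))
    pairs: list[tuple[Detection, Annotation]] = []
    matched_det = set()
    for i in order:
        det = detections[i]
        best_j, best_ov = None, -1.0
        for j in unmatched_ann:
            tf, ff = overlap_fraction(det, anns[j])
            if tf >= min_overlap and ff >= min_overlap and tf + ff > best_ov:
                best_j, best_ov = j, tf + ff
        if best_j is not None:
            unmatched_ann.discard(best_j)
            matched_det.add(i)
            pairs.append((det, anns[best_j]))
    fps = [d for i, d in enumerate(detections) if i not in matched_det]
    fns = [anns[j] for j in sorted(unmatched_ann)]
    return MatchResult(true_positives=pairs, false_positives=fps, false_negatives=fns)


def detector_metrics(match: MatchResult, recording_hours: float) -> DetectionMetrics:
    """Precision, recall, and false-alarm rate (false positives per hour).

    Precision is undefined (flagged, reported 0) with no detections; recall
    is undefined with no annotations.
    """
    if recording_hours <= 0:
        raise ValueError("recording_hours must be positive")
    n_det = match.tp + match.fp
    n_ann = match.tp + match.fn
    precision_defined = n_det > 0
    recall_defined = n_ann > 0
    precision = match.tp / n_det if precision_defined else 0.0
    recall = match.tp / n_ann if recall_defined else 0.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        false_alarm_rate=match.fp / recording_hours,
        recording_hours=recording_hours,
        n_detections=n_det,
        n_annotations=n_ann,
        precision_defined=precision_defined,
        recall_defined=recall_defined,
    )
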