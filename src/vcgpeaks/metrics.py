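"""Tolerance-matched beat-detection scoring and heart-rate statistics.

Detections and annotations are paired one-to-one when their timing differs
by at most 75 ms (inclusive, compared in seconds — the tolerance derives
from the maximum ~150 ms duration of a QRS complex). Recall, precision and
F1 are reported as percentages. Heart-rate summaries (average and standard
deviation of instantaneous HR, RMSSD) are computed from RR intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detect import DetectedPeaks
from .records import BeatAnnotations

TOLERANCE_MS = 75.0


@dataclass
class MatchResult:
    """One-to-one pairing of detections with annotations."""

    pairs: list                  # (annotation_index, detection_index) sample pairs
    false_negatives: np.ndarray  # unmatched annotation samples
    false_positives: np.ndarray  # unmatched detection samples
    tolerance_ms: float = TOLERANCE_MS

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return int(self.false_negatives.size)

    @property
    def fp(self) -> int:
        return int(self.false_positives.size)


@dataclass
class MetricsReport:
    tp: int
    fn: int
    fp: int
    recall: float | None
    precision: float | None
    f1: float | None
    aggregation: str = "single"
    f1_mean: float | None = None   # macro only: mean of per-record F1

    @property
    def undefined(self) -> bool:
        return self.recall is None and self.precision is None


@dataclass
class HRVSummary:
    avg_hr: float | None    # beats/min
    sd_hr: float | None     # beats/min
    rmssd: float | None     # ms
    n_beats: int = 0


def restrict_to_annotated_span(detections: DetectedPeaks,
                               annotations: BeatAnnotations, fs: float,
                               tolerance_ms: float = TOLERANCE_MS
                               ) -> DetectedPeaks:
    """Drop detections outside [first annotation - tol, last annotation + tol].

    Records often leave their first/last cardiac cycles unannotated; those
    cycles are excluded from scoring entirely.
    """
    if len(annotations) == 0:
        raise ValueError("annotations must be non-empty")
    tol = tolerance_ms / 1000.0 * fs
    lo = annotations.sample_indices[0] - tol
    hi = annotations.sample_indices[-1] + tol
    keep = (detections.sample_indices >= lo) & (detections.sample_indices <= hi)
    return DetectedPeaks(
        sample_indices=detections.sample_indices[keep],
        peak_probability=np.asarray(detections.peak_probability)[keep],
        support_count=np.asarray(detections.support_count)[keep],
        sampling_rate=detections.sampling_rate,
    )


def match_peaks(detections, annotations, fs: float,
                tolerance_ms: float = TOLERANCE_MS) -> MatchResult:
    """Greedy one-to-one matching in increasing order of |time difference|.

    Candidate pairs differ by at most ``tolerance_ms`` (inclusive, in
    seconds). Ties in distance are broken toward the earlier annotation.
    """
    det = np.asarray(getattr(detections, "sample_indices", detections),
                     dtype=np.int64)
    ann = np.asarray(getattr(annotations, "sample_indices", annotations),
                     dtype=np.int64)
    tol_s = tolerance_ms / 1000.0
    cands = []
    for i, a in enumerate(ann):
        lo = np.searchsorted(det, a - tol_s * fs - 1)
        hi = np.searchsorted(det, a + tol_s * fs + 1, side="right")
        for j in range(lo, hi):
            dt = abs(int(det[j]) - int(a)) / fs
            if dt <= tol_s + 1e-12:
                cands.append((dt, i, j))
    cands.sort(key=lambda t: (t[0], t[1]))
    used_a, used_d, pairs = set(), set(), []
    for dt, i, j in cands:
        if i in used_a or j in used_d:
            continue
        used_a.add(i)
        used_d.add(j)
        pairs.append((int(ann[i]), int(det[j])))
    pairs.sort()
    fn = np.array([a for i, a in enumerate(ann) if i not in used_a],
                  dtype=np.int64)
    fp = np.array([d for j, d in enumerate(det) if j not in used_d],
                  dtype=np.int64)
    return MatchResult(pairs=pairs, false_negatives=fn, false_positives=fp,
                       tolerance_ms=tolerance_ms)


def compute_metrics(match) -> MetricsReport:
    """Recall/precision/F1 (%) from TP/FN/FP counts.

    Accepts a MatchResult or an (tp, fn, fp) triple. A ratio with a zero
    denominator is reported as None (undefined) rather than 0 or 100.
    """
    if isinstance(match, MatchResult):
        tp, fn, fp = match.tp, match.fn, match.fp
    else:
        tp, fn, fp = match
    return _metrics_from_counts(tp, fn, fp)


def _metrics_from_counts(tp, fn, fp, aggregation="single"):
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    f1 = None
    if recall is not None and precision is not None and recall + precision > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(tp=tp, fn=fn, fp=fp, recall=recall,
                         precision=precision, f1=f1, aggregation=aggregation)


def aggregate(reports, mode: str = "pooled") -> MetricsReport:
    """Aggregate per-record reports.

    pooled: sum TP/FN/FP then apply the formulas. macro: unweighted mean of
    the per-record percentages (records with an undefined component are
    excluded from that component's mean, with a warning); the macro F1 is
    the harmonic mean of macro recall and macro precision, and the mean of
    per-record F1 values is exposed as ``f1_mean``.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")
    tp = sum(r.tp for r in reports)
    fn = sum(r.fn for r in reports)
    fp = sum(r.fp for r in reports)
    if mode == "pooled":
        return _metrics_from_counts(tp, fn, fp, aggregation="pooled")
    if mode != "macro":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    recalls = [r.recall for r in reports if r.recall is not None]
    precisions = [r.precision for r in reports if r.precision is not None]
    f1s = [r.f1 for r in reports if r.f1 is not None]
    if len(recalls) < len(reports) or len(precisions) < len(reports):
        warnings.warn("records with undefined metrics excluded from macro average")
    recall = float(np.mean(recalls)) if recalls else None
    precision = float(np.mean(precisions)) if precisions else None
    f1 = None
    if recall is not None and precision is not None and recall + precision > 0:
        f1 = 2 * precision * recall / (precision + recall)
    rep = MetricsReport(tp=tp, fn=fn, fp=fp, recall=recall,
                        precision=precision, f1=f1, aggregation="macro")
    rep.f1_mean = float(np.mean(f1s)) if f1s else None
    return rep


def hrv_summary(beats, fs: float) -> HRVSummary:
    """Heart-rate summaries from beat sample indices.

    RR_i = (beats[i+1]-beats[i]) / fs seconds; instantaneous HR_i = 60/RR_i.
    avg_hr and sd_hr (population standard deviation) need >= 2 beats;
    RMSSD = 1000 * sqrt(mean((RR_{i+1}-RR_i)^2)) ms needs >= 3 beats.
    Missing quantities are None.
    """
    beats = np.asarray(getattr(beats, "sample_indices", beats), dtype=np.float64)
    n = beats.size
    rr = np.diff(beats) / fs
    hr = 60.0 / rr if rr.size else np.empty(0)
    avg = float(hr.mean()) if n >= 2 else None
    sd = float(hr.std()) if n >= 2 else None
    rmssd = (float(1000.0 * np.sqrt(np.mean(np.diff(rr) ** 2)))
             if n >= 3 else None)
    return HRVSummary(avg_hr=avg, sd_hr=sd, rmssd=rmssd, n_beats=int(n))


def annotation_hrv_from_directory(directory, annotator="atr") -> HRVSummary:
    """Pooled ground-truth HRV over all WFDB records in ``directory``.

    Reads each record's header for sampling rate and length, loads the beat
    annotations, and pools RR intervals across records (intervals are never
    formed across record boundaries). With the 75 INCART records this
    reproduces the published ground-truth AVG-HR and RMSSD.
    """
    import os

    from .io import _parse_header, load_annotations

    names = sorted(f[:-4] for f in os.listdir(directory)
                   if f.endswith(".hea"))
    if not names:
        raise FileNotFoundError(
            f"no WFDB records (.hea) found under {directory!r}")
    beat_lists, fs_list = [], []
    for name in names:
        _, fs, n_samples, _ = _parse_header(
            os.path.join(directory, f"{name}.hea"))
        ann = load_annotations(
            os.path.join(directory, f"{name}.{annotator}"), n_samples or 2**62)
        beat_lists.append(ann.sample_indices)
        fs_list.append(fs)
    return pooled_hrv(beat_lists, fs_list)


def pooled_hrv(beat_lists, fs_list) -> HRVSummary:
    """HRV pooled across records: RR intervals are formed within each
    record (never across record boundaries) and the statistics computed
    over the concatenated interval lists."""
    rr_all, drr_all = [], []
    n_tot = 0
    for beats, fs in zip(beat_lists, fs_list):
        beats = np.asarray(getattr(beats, "sample_indices", beats),
                           dtype=np.float64)
        n_tot += beats.size
        rr = np.diff(beats) / fs
        rr_all.append(rr)
        drr_all.append(np.diff(rr))
    rr = np.concatenate(rr_all) if rr_all else np.empty(0)
    drr = np.concatenate(drr_all) if drr_all else np.empty(0)
    hr = 60.0 / rr if rr.size else np.empty(0)
    return HRVSummary(
        avg_hr=float(hr.mean()) if hr.size else None,
        sd_hr=float(hr.std()) if hr.size else None,
        rmssd=float(1000.0 * np.sqrt(np.mean(drr ** 2))) if drr.size else None,
        n_beats=n_tot,
    )
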