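"""Overlap-averaged inference and consensus R-peak extraction.

A record is cut into half-overlapping windows; per-window probability
predictions are averaged per sample into a record-level probability trace.
Candidate samples above the 50% threshold hill-climb to their local
maximum; a maximum is retained as an R-peak only when at least five
candidates converge to it (the consensus rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SegmentationModel
from .records import VCGRecord
from .windows import make_inference_set

PROB_THRESHOLD = 0.5
MIN_SUPPORT = 5


@dataclass
class ProbabilityTrace:
    """Per-sample R-peak probability with window coverage counts."""

    values: np.ndarray
    coverage: np.ndarray
    sampling_rate: float | None = None


@dataclass
class DetectedPeaks:
    """Final peak locations with their probability and consensus support."""

    sample_indices: np.ndarray
    peak_probability: np.ndarray
    support_count: np.ndarray
    sampling_rate: float | None = None

    def __len__(self):
        return int(self.sample_indices.size)


def average_overlaps(window_predictions, starts, n_samples: int,
                     sampling_rate=None) -> ProbabilityTrace:
    """Per-sample mean of all window predictions covering each sample.

    Samples covered by no window get value 0 and coverage 0.
    """
    total = np.zeros(n_samples)
    cover = np.zeros(n_samples, dtype=np.int64)
    for pred, s in zip(window_predictions, starts):
        pred = np.asarray(pred)
        total[s: s + pred.size] += pred
        cover[s: s + pred.size] += 1
    values = np.divide(total, cover, out=np.zeros(n_samples),
                       where=cover > 0)
    return ProbabilityTrace(values=values, coverage=cover,
                            sampling_rate=sampling_rate)


def _hill_climb(values: np.ndarray, start: int) -> int:
    """Steepest ascent to a local maximum.

    From sample s, step to the strictly greater neighbor; when both
    neighbors are greater, to the greater of the two (ties toward the
    left). A plateau maximum is represented by its leftmost sample.
    """
    n = values.size
    s = start
    while True:
        left = values[s - 1] if s > 0 else -np.inf
        right = values[s + 1] if s < n - 1 else -np.inf
        here = values[s]
        if left > here and right > here:
            s = s - 1 if left >= right else s + 1  # tie toward the left
        elif left > here:
            s -= 1
        elif right > here:
            s += 1
        elif left == here and s > 0:
            s -= 1  # walk a plateau to its leftmost sample
        else:
            return s


def extract_peaks(trace: ProbabilityTrace, threshold: float = PROB_THRESHOLD,
                  min_support: int = MIN_SUPPORT) -> DetectedPeaks:
    """Threshold / local-maximum / consensus peak extraction.

    1. candidates = samples with probability strictly above ``threshold``;
    2. each candidate hill-climbs to its local maximum;
    3. a maximum with at least ``min_support`` converging candidates
       becomes one detected peak at the maximum's index.
    """
    values = np.asarray(trace.values)
    candidates = np.flatnonzero(values > threshold)
    groups: dict[int, int] = {}
    for c in candidates:
        m = _hill_climb(values, int(c))
        groups[m] = groups.get(m, 0) + 1
    kept = sorted(m for m, n in groups.items() if n >= min_support)
    return DetectedPeaks(
        sample_indices=np.array(kept, dtype=np.int64),
        peak_probability=values[kept] if kept else np.empty(0),
        support_count=np.array([groups[m] for m in kept], dtype=np.int64),
        sampling_rate=trace.sampling_rate,
    )


def predict_trace(model: SegmentationModel, vcg: VCGRecord,
                  batch_size: int = 64) -> ProbabilityTrace:
    """Half-overlap inference over a whole record."""
    segs = make_inference_set(vcg, window_length=model.config.input_length)
    preds = []
    for i in range(0, len(segs), batch_size):
        preds.append(model.predict(segs.data[i: i + batch_size]))
    preds = np.concatenate(preds) if preds else np.empty((0, segs.window_length))
    return average_overlaps(list(preds), segs.starts, vcg.n_samples,
                            sampling_rate=vcg.sampling_rate)


def detect(model: SegmentationModel, vcg: VCGRecord,
           threshold: float = PROB_THRESHOLD,
           min_support: int = MIN_SUPPORT) -> DetectedPeaks:
    """End-to-end detection on one vectorcardiogram record."""
    trace = predict_trace(model, vcg)
    return extract_peaks(trace, threshold=threshold, min_support=min_support)
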