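"""Fixed-length windowing of records and 5-sample R-peak label masks.

Training uses non-overlapping windows (stride = window length); inference
uses half-overlapping windows (stride = length / 2) so beats near window
borders are seen by two windows and their predictions averaged. Ragged
record tails that do not fill a whole window are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kors import normalize
from .records import BeatAnnotations, VCGRecord

WINDOW_LENGTH = 2048  # ~4 s at 500 Hz
MASK_HALF_WIDTH = 2   # peaks labeled as 5-sample runs


@dataclass
class SegmentSet:
    """Windows cut from one record, optionally with binary label masks."""

    window_length: int
    stride: int
    starts: np.ndarray                    # (n_windows,)
    data: np.ndarray                      # (n_windows, window_length, C)
    masks: np.ndarray | None = None       # (n_windows, window_length) binary

    def __len__(self) -> int:
        return int(self.starts.size)


def window_starts(n_samples: int, length: int, stride: int) -> np.ndarray:
    """Start indices 0, stride, 2*stride, ... with the window fully inside
    the record; empty when the record is shorter than one window."""
    if length < 1 or stride < 1:
        raise ValueError("length and stride must be >= 1")
    if n_samples < length:
        return np.empty(0, dtype=np.int64)
    last = n_samples - length
    return np.arange(0, last + 1, stride, dtype=np.int64)


def build_label_mask(n: int, peaks) -> np.ndarray:
    """Binary mask of length ``n`` with a 5-sample run centered on each peak
    (clipped at the borders; overlapping runs merge by union)."""
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= n):
        raise ValueError("peak index out of range")
    mask = np.zeros(n, dtype=np.float64)
    for p in peaks:
        mask[max(0, p - MASK_HALF_WIDTH): p + MASK_HALF_WIDTH + 1] = 1.0
    return mask


def _cut(vectors, starts, length):
    if starts.size == 0:
        return np.empty((0, length, vectors.shape[1]))
    wins = np.stack([vectors[s: s + length] for s in starts])
    return np.stack([normalize(w) for w in wins])


def make_training_set(vcg: VCGRecord, ann: BeatAnnotations,
                      window_length: int = WINDOW_LENGTH) -> SegmentSet:
    """Non-overlapping normalized windows with per-window label masks.

    Annotated peaks are re-indexed to window coordinates; a 5-sample run is
    truncated at the window edge rather than spilled into the neighbor.
    """
    starts = window_starts(vcg.n_samples, window_length, window_length)
    if starts.size == 0:
        warnings.warn(
            f"record {vcg.record_id!r} shorter than one window; empty set")
    data = _cut(vcg.vectors, starts, window_length)
    masks = np.zeros((starts.size, window_length))
    idx = ann.sample_indices
    for i, s in enumerate(starts):
        inside = idx[(idx >= s) & (idx < s + window_length)] - s
        masks[i] = build_label_mask(window_length, inside)
    return SegmentSet(window_length=window_length, stride=window_length,
                      starts=starts, data=data, masks=masks)


def make_inference_set(vcg: VCGRecord,
                       window_length: int = WINDOW_LENGTH) -> SegmentSet:
    """Half-overlapping normalized windows (stride = length / 2), no masks."""
    if vcg.n_samples < window_length:
        raise ValueError(
            f"record {vcg.record_id!r} has {vcg.n_samples} samples, "
            f"shorter than one {window_length}-sample window")
    stride = window_length // 2
    starts = window_starts(vcg.n_samples, window_length, stride)
    data = _cut(vcg.vectors, starts, window_length)
    return SegmentSet(window_length=window_length, stride=stride,
                      starts=starts, data=data, masks=None)
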