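"""Kors regression vectorcardiogram reconstruction and signal normalization.

The Kors regression transformation maps the eight independent ECG leads
(I, II, V1-V6) to the three orthogonal vectorcardiographic axes (X, Y, Z)
by a fixed linear map V = E M, where E holds one row of eight lead values
per sample and M is the published 8x3 regression coefficient matrix. The
augmented limb leads (III, aVR, aVL, aVF) are linear combinations of I and
II and are deliberately refused rather than silently dropped.
"""

from __future__ import annotations

import warnings

import numpy as np

from .records import STANDARD_8_LEADS, ECGRecord, VCGRecord

#: Kors regression coefficients; rows (I, II, V1..V6), columns (X, Y, Z).
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, 0.11],
        [-0.07, 0.93, -0.23],
        [-0.13, 0.06, -0.43],
        [0.05, -0.02, -0.06],
        [-0.01, -0.05, -0.14],
        [0.14, 0.06, -0.20],
        [0.06, -0.17, -0.11],
        [0.54, 0.13, 0.31],
    ]
)


def kors_transform(record: ECGRecord) -> VCGRecord:
    """Project an 8-lead ECG onto the vectorcardiographic X, Y, Z axes.

    The record must carry exactly the leads I, II, V1-V6 in that order;
    any other lead set (including a full 12-lead record) is rejected so the
    caller selects leads explicitly.
    """
    if record.lead_names != STANDARD_8_LEADS:
        expected = list(STANDARD_8_LEADS)
        got = list(record.lead_names)
        for pos, want in enumerate(expected):
            if pos >= len(got) or got[pos] != want:
                offending = got[pos] if pos < len(got) else "<missing>"
                raise ValueError(
                    f"kors_transform requires leads {expected} in order; "
                    f"position {pos} holds {offending!r} instead of {want!r}"
                )
        raise ValueError(f"kors_transform requires exactly 8 leads, got {len(got)}")
    vectors = record.signal @ KORS_MATRIX
    return VCGRecord(record_id=record.record_id,
                     sampling_rate=record.sampling_rate,
                     vectors=vectors)


def normalize(segment: np.ndarray) -> np.ndarray:
    """Min-max scale each channel of ``segment`` to [-1, 1] independently.

    A constant channel has no scale and maps to all zeros (warned once per
    call).
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim == 1:
        seg = seg[:, None]
        squeeze = True
    else:
        squeeze = False
    lo = seg.min(axis=0)
    hi = seg.max(axis=0)
    span = hi - lo
    const = span == 0
    if np.any(const):
        warnings.warn("constant channel(s) mapped to zeros during normalization")
    span = np.where(const, 1.0, span)
    out = 2.0 * (seg - lo) / span - 1.0
    out[:, const] = 0.0
    return out[:, 0] if squeeze else out
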