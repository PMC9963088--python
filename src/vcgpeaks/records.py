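"""Core in-memory containers for multi-lead ECG and vectorcardiogram data.

Conventions
-----------
* Signals are stored as ``(n_samples, n_channels)`` float arrays in millivolts.
* Annotation sample indices are 0-based and map directly onto WFDB sample
  numbers.
* Lead names follow the conventional 12-lead naming; the eight independent
  leads used throughout the package are I, II and V1-V6 (III, aVR, aVL and
  aVF are linear combinations of I and II and carry no extra information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default lead order expected by the vectorcardiogram transform.
STANDARD_8_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ECGRecord:
    """A multi-lead sampled ECG.

    Parameters
    ----------
    record_id : str
        Identifier of the record (WFDB record name for on-disk records).
    sampling_rate : float
        Sampling frequency in Hz. Must be positive.
    lead_names : tuple of str
        Ordered, unique lead names; one per signal column.
    signal : ndarray of shape (n_samples, n_leads)
        Sampled voltages in millivolts.
    """

    record_id: str
    sampling_rate: float
    lead_names: tuple
    signal: np.ndarray

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_samples, n_leads)")
        self.lead_names = tuple(self.lead_names)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[0] < 1:
            raise ValueError("record must contain at least one sample")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.lead_names)} lead names were given"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    def select_leads(self, leads) -> "ECGRecord":
        """Return a copy restricted to ``leads``, columns in that order."""
        leads = tuple(leads)
        missing = [name for name in leads if name not in self.lead_names]
        if missing:
            raise KeyError(f"lead not found in record: {missing[0]!r}")
        cols = [self.lead_names.index(name) for name in leads]
        return ECGRecord(
            record_id=self.record_id,
            sampling_rate=self.sampling_rate,
            lead_names=leads,
            signal=self.signal[:, cols].copy(),
        )


@dataclass
class BeatAnnotations:
    """Ground-truth R-peak locations for one record.

    ``sample_indices`` is strictly increasing; indices are 0-based samples at
    the sampling rate of the associated record.
    """

    record_id: str
    sample_indices: np.ndarray
    reference_lead: str = "II"

    def __post_init__(self):
        idx = np.asarray(self.sample_indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("sample_indices must be 1-D")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("sample_indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("sample_indices must be non-negative")
        self.sample_indices = idx

    def __len__(self) -> int:
        return int(self.sample_indices.size)


@dataclass
class VCGRecord:
    """A 3-axis (X, Y, Z) vectorcardiogram."""

    record_id: str
    sampling_rate: float
    vectors: np.ndarray

    AXES = ("X", "Y", "Z")

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n_samples, 3)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]
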