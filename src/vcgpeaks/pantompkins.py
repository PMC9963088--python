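"""Classical Pan-Tompkins single-lead R-peak detector.

The canonical 1985 recipe: band-pass filtering (5-15 Hz), five-point
derivative, squaring, 150 ms moving-window integration, then adaptive
dual signal/noise thresholds with a 200 ms refractory period, a 360 ms
T-wave slope discrimination check, and search-back at 1.66 times the
running RR estimate when a beat appears missed. Detected peaks are
snapped to the dominant local extremum of the band-passed signal.

This is a faithful re-implementation of the published algorithm, not a
clone of any particular open-source variant; constants live in
:class:`PTConfig`. The band-pass uses a zero-phase Butterworth filter so
detections align with the raw signal without delay compensation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

from .detect import DetectedPeaks


@dataclass
class PTConfig:
    band_low: float = 5.0            # Hz
    band_high: float = 15.0          # Hz
    integration_ms: float = 150.0    # moving-window integration width
    refractory_ms: float = 200.0
    twave_ms: float = 360.0          # T-wave discrimination window
    blend: float = 0.125             # running signal/noise estimate blend
    threshold_coeff: float = 0.25    # T = noise + coeff * (signal - noise)
    searchback_factor: float = 1.66  # of the running RR average


def _preprocess(x, fs, config):
    nyq = fs / 2.0
    b, a = butter(2, [config.band_low / nyq, config.band_high / nyq],
                  btype="band")
    bp = filtfilt(b, a, x)
    # five-point derivative: (2x[n] + x[n-1] - x[n-3] - 2x[n-4]) / 8
    h = np.array([2, 1, 0, -1, -2]) / 8.0
    deriv = lfilter(h, 1.0, bp)
    sq = deriv ** 2
    width = max(1, int(round(config.integration_ms / 1000.0 * fs)))
    mwi = lfilter(np.ones(width) / width, 1.0, sq)
    return bp, mwi, width


def _local_peaks(x):
    """Indices of strict local maxima (plateau: first sample)."""
    peaks = []
    rising = False
    for i in range(1, x.size):
        if x[i] > x[i - 1]:
            rising = True
        elif x[i] < x[i - 1] and rising:
            peaks.append(i - 1)
            rising = False
    return np.array(peaks, dtype=np.int64)


def pt_detect(lead_signal, fs: float, config: PTConfig | None = None
              ) -> DetectedPeaks:
    """Detect R-peaks in a single ECG lead.

    Requires ``fs >= 100`` Hz and at least 2 s of signal (the adaptive
    thresholds need an initialization span).
    """
    config = config or PTConfig()
    x = np.asarray(lead_signal, dtype=np.float64)
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    bp, mwi, width = _preprocess(x, fs, config)
    peaks = _local_peaks(mwi)
    if peaks.size == 0:
        return DetectedPeaks(np.empty(0, np.int64), np.empty(0),
                             np.empty(0, np.int64), sampling_rate=fs)

    refractory = config.refractory_ms / 1000.0 * fs
    twave_win = config.twave_ms / 1000.0 * fs
    blend = config.blend

    # threshold initialization from the first 2 s
    init = mwi[: int(2 * fs)]
    spki = float(init.max()) * 0.25
    npki = float(init.mean()) * 0.5
    qrs: list[int] = []
    noise_peaks: list[int] = []
    rr_avg = fs  # running RR estimate, start at 60 bpm equivalent
    last_qrs = -np.inf

    def slope_at(i):
        lo = max(0, i - width // 2)
        return np.max(np.abs(np.diff(mwi[lo: i + 1]))) if i > lo else 0.0

    i = 0
    while i < peaks.size:
        p = int(peaks[i])
        level = mwi[p]
        threshold = npki + config.threshold_coeff * (spki - npki)
        is_qrs = False
        if p - last_qrs > refractory and level > threshold:
            is_qrs = True
            # T-wave discrimination: close to the previous beat with a
            # shallower upslope -> treat as T wave
            if qrs and p - last_qrs < twave_win:
                if slope_at(p) < 0.5 * slope_at(int(last_qrs)):
                    is_qrs = False
        if is_qrs:
            spki = blend * level + (1 - blend) * spki
            if qrs:
                rr = p - last_qrs
                rr_avg = 0.875 * rr_avg + 0.125 * rr
            qrs.append(p)
            last_qrs = p
        elif p - last_qrs > refractory:
            npki = blend * level + (1 - blend) * npki
            noise_peaks.append(p)
            # search-back: no beat for 1.66x the running RR -> take the
            # largest candidate above half threshold in the gap
            if qrs and p - last_qrs > config.searchback_factor * rr_avg:
                gap = [int(q) for q in peaks
                       if last_qrs + refractory < q <= p
                       and mwi[int(q)] > 0.5 * threshold]
                if gap:
                    best = max(gap, key=lambda q: mwi[q])
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    rr_avg = 0.875 * rr_avg + 0.125 * (best - last_qrs)
                    qrs.append(best)
                    qrs.sort()
                    last_qrs = max(last_qrs, best)
        i += 1

    # snap each detection to the dominant extremum of the band-passed
    # signal within the integration-window span behind the MWI peak
    snapped = []
    for p in qrs:
        lo = max(0, p - width)
        hi = min(x.size, p + 1)
        seg = bp[lo:hi]
        snapped.append(lo + int(np.argmax(np.abs(seg))))
    snapped = sorted(set(snapped))
    # enforce the refractory period on the snapped indices
    final = []
    for s in snapped:
        if final and s - final[-1] < refractory:
            if abs(bp[s]) > abs(bp[final[-1]]):
                final[-1] = s
            continue
        final.append(s)
    idx = np.array(final, dtype=np.int64)
    return DetectedPeaks(sample_indices=idx,
                         peak_probability=np.abs(bp[idx]) if idx.size else np.empty(0),
                         support_count=np.zeros(idx.size, dtype=np.int64),
                         sampling_rate=fs)
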