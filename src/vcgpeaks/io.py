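"""Reading and writing WFDB-format ECG records and beat annotations.

Implements the subset of the PhysioNet WFDB family needed here:

* headers (``.hea``), signal files in formats 16 (16-bit little-endian) and
  212 (paired 12-bit samples), honoring per-signal gain and baseline when
  converting to millivolts;
* MIT-format annotation files (``.atr`` / ``.qrs``), reading the full byte
  stream (including SKIP/NUM/SUB/CHN/AUX pseudo-annotations) and keeping
  beat-class annotations only.

Also provides band-limited resampling of (record, annotations) pairs and the
1-D k-means collapse used to reduce interval-style QRS annotations (every
sample inside the QRS marked) to one R-peak location per complex.
"""

from __future__ import annotations

import os
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .records import STANDARD_8_LEADS, BeatAnnotations, ECGRecord

# MIT annotation type codes that denote beats (QRS complexes).
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38})
_NORMAL = 1
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class WFDBFormatError(ValueError):
    """Raised when a header, signal or annotation stream cannot be parsed."""


# ---------------------------------------------------------------------------
# headers and signals
# ---------------------------------------------------------------------------

def _parse_header(hea_path):
    with open(hea_path) as fh:
        lines = [
            ln.strip() for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise WFDBFormatError(f"empty header: {hea_path}")
    top = lines[0].split()
    record_name = top[0].split("/")[0]
    n_sig = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    n_samples = int(top[3]) if len(top) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(
            dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                 units=units, description=desc)
        )
    return record_name, fs, n_samples, signals


def _decode_212(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_trip = len(b) // 3
    b = b[: n_trip * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_trip, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out


def load_record(path, leads=None) -> ECGRecord:
    """Load a WFDB record from ``path`` (with or without ``.hea`` suffix).

    Parameters
    ----------
    path : str or Path
        Path to the record (header file, extension optional).
    leads : sequence of str, optional
        Lead names to keep, in the requested order. By default, if all of
        I, II, V1-V6 are present they are selected in that order; otherwise
        the stored order is kept.
    """
    path = str(path)
    if path.endswith(".hea"):
        path = path[:-4]
    hea_path = path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    record_name, fs, n_samples, signals = _parse_header(hea_path)
    rec_dir = os.path.dirname(os.path.abspath(hea_path))

    # All signals of one record are assumed multiplexed in one .dat file
    # (true for every database handled here).
    dat_path = os.path.join(rec_dir, signals[0]["file"])
    fmt = signals[0]["fmt"]
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    n_sig = len(signals)
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        flat = _decode_212(raw)
    else:
        raise WFDBFormatError(f"unsupported signal format {fmt}")
    n_frames = len(flat) // n_sig
    if n_samples:
        n_frames = min(n_frames, n_samples)
    adc = flat[: n_frames * n_sig].reshape(n_frames, n_sig)

    gains = np.array([s["gain"] for s in signals])
    baselines = np.array([s["baseline"] for s in signals])
    mv = (adc - baselines) / gains

    names = []
    for s in signals:
        nm = s["description"].strip()
        # Normalize common spellings ("i", "MLII", "v1", ...)
        up = nm.upper().replace("LEAD", "").strip()
        names.append(up if up else nm)
    record = ECGRecord(record_id=record_name, sampling_rate=fs,
                       lead_names=_dedupe(names), signal=mv)
    if leads is None and all(l in record.lead_names for l in STANDARD_8_LEADS):
        leads = STANDARD_8_LEADS
    if leads is not None:
        record = record.select_leads(leads)
    return record


def _dedupe(names):
    seen, out = {}, []
    for nm in names:
        if nm in seen:
            seen[nm] += 1
            out.append(f"{nm}_{seen[nm]}")
        else:
            seen[nm] = 0
            out.append(nm)
    return tuple(out)


def write_record(record: ECGRecord, directory, gain: float = 1000.0) -> str:
    """Write ``record`` as a format-16 WFDB record; returns the header path.

    Quantization is 1/gain mV per ADC unit (default 1 uV).
    """
    os.makedirs(directory, exist_ok=True)
    name = record.record_id
    adc = np.clip(np.rint(record.signal * gain), -32768, 32767).astype("<i2")
    dat_name = f"{name}.dat"
    with open(os.path.join(directory, dat_name), "wb") as fh:
        fh.write(adc.reshape(-1).tobytes())
    checksums = (adc.astype(np.int64).sum(axis=0) & 0xFFFF).astype(np.int64)
    checksums[checksums > 32767] -= 65536
    fs = record.sampling_rate
    fs_str = f"{fs:g}"
    lines = [f"{name} {record.n_leads} {fs_str} {record.n_samples}"]
    for j, lead in enumerate(record.lead_names):
        first = int(adc[0, j])
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {int(checksums[j])} 0 {lead}"
        )
    hea_path = os.path.join(directory, f"{name}.hea")
    with open(hea_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hea_path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotation_stream(path):
    """Decode a MIT-format annotation file into (sample_index, code) pairs."""
    with open(path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    out = []
    t = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code, interval = w >> 10, w & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP and interval == 0:
            if i + 2 >= len(words):
                raise WFDBFormatError("truncated SKIP in annotation stream")
            skip = (int(words[i + 1]) << 16) | int(words[i + 2])
            if skip >= 1 << 31:
                skip -= 1 << 32
            t += skip
            i += 3
            continue
        if code == _AUX:
            i += 1 + (interval + 1) // 2
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code > _SKIP:
            raise WFDBFormatError(f"bad annotation code {code}")
        t += interval
        out.append((t, code))
        i += 1
    return out


def load_annotations(path, n_samples, record_id=None,
                     reference_lead="II") -> BeatAnnotations:
    """Load beat annotations: beat-class marks only, sorted, de-duplicated,
    clipped to ``[0, n_samples)``."""
    pairs = read_annotation_stream(path)
    beats = sorted({t for t, code in pairs if code in BEAT_CODES})
    beats = [t for t in beats if 0 <= t < n_samples]
    if record_id is None:
        record_id = os.path.splitext(os.path.basename(str(path)))[0]
    return BeatAnnotations(record_id=record_id,
                           sample_indices=np.array(beats, dtype=np.int64),
                           reference_lead=reference_lead)


def write_annotations(path, sample_indices, code: int = _NORMAL) -> None:
    """Write sample indices as a MIT-format annotation file (one beat code
    per index)."""
    idx = np.asarray(sample_indices, dtype=np.int64)
    if idx.size and np.any(np.diff(idx) <= 0):
        raise ValueError("annotation indices must be strictly increasing")
    words = []
    prev = 0
    for t in idx:
        delta = int(t - prev)
        if delta > 1023:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = t
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(path)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_record(record: ECGRecord, annotations, target_rate: float):
    """Band-limited (polyphase) resampling of a record and its annotations.

    Output length is ``round(n_samples * target_rate / sampling_rate)``;
    each annotation index maps through the same ratio (rounded, clipped).
    Returns ``(record, annotations)``; inputs are returned unchanged when
    ``target_rate`` equals the record's rate.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    fs = record.sampling_rate
    if target_rate == fs:
        return record, annotations
    ratio = Fraction(target_rate / fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    new_n = int(round(record.n_samples * target_rate / fs))
    sig = resample_poly(record.signal, up, down, axis=0)
    if sig.shape[0] < new_n:
        sig = np.pad(sig, ((0, new_n - sig.shape[0]), (0, 0)))
    sig = sig[:new_n]
    out_rec = ECGRecord(record_id=record.record_id, sampling_rate=target_rate,
                        lead_names=record.lead_names, signal=sig)
    out_ann = annotations
    if annotations is not None:
        idx = np.rint(annotations.sample_indices * target_rate / fs)
        idx = np.clip(idx, 0, new_n - 1).astype(np.int64)
        idx = np.unique(idx)
        out_ann = BeatAnnotations(record_id=annotations.record_id,
                                  sample_indices=idx,
                                  reference_lead=annotations.reference_lead)
    return out_rec, out_ann


# ---------------------------------------------------------------------------
# interval-annotation collapse
# ---------------------------------------------------------------------------

def collapse_interval_annotations(marked_indices, k: int):
    """Collapse interval-style QRS marks to ``k`` R-peak locations.

    Runs deterministic 1-D k-means on the marked sample indices: centroids
    initialized at k evenly spaced quantiles, Lloyd iterations to convergence
    (centroid movement < 1e-6, cap 100 iterations). Returns the k centroids
    rounded to the nearest integer (halves away from zero), sorted.
    """
    x = np.sort(np.asarray(marked_indices, dtype=np.float64))
    if x.size == 0:
        raise ValueError("marked_indices must be non-empty")
    if not 1 <= k <= x.size:
        raise ValueError(f"k={k} must be in [1, {x.size}]")
    q = (np.arange(k) + 0.5) / k
    centroids = np.quantile(x, q)
    for _ in range(100):
        # nearest-centroid assignment; centroids stay sorted in 1-D Lloyd
        d = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(d, axis=1)
        new = centroids.copy()
        for j in range(k):
            members = x[assign == j]
            if members.size:
                new[j] = members.mean()
        if np.max(np.abs(new - centroids)) < 1e-6:
            centroids = new
            break
        centroids = new
    # round half away from zero
    rounded = np.sign(centroids) * np.floor(np.abs(centroids) + 0.5)
    return np.sort(rounded.astype(np.int64))
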