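"""Overlap averaging and consensus peak extraction against brute oracles."""

import numpy as np
import pytest

from vcgpeaks.detect import (DetectedPeaks, ProbabilityTrace,
                             average_overlaps, detect, extract_peaks,
                             predict_trace)


from tests_oracles import brute_force_peaks


def test_all_zero_trace_has_no_peaks():
    trace = ProbabilityTrace(np.zeros(100), np.ones(100, dtype=int))
    assert len(extract_peaks(trace)) == 0


def test_triangular_bump_single_peak():
    values = np.zeros(101)
    bump = [0.2, 0.55, 0.7, 0.85, 0.95, 0.85, 0.7, 0.55, 0.2]
    values[46:55] = bump
    peaks = extract_peaks(ProbabilityTrace(values, np.ones(101, dtype=int)))
    assert peaks.sample_indices.tolist() == [50]
    assert peaks.support_count.tolist() == [7]  # 7 samples above 0.5
    assert peaks.peak_probability[0] == pytest.approx(0.95)


def test_bump_with_three_candidates_is_rejected():
    values = np.zeros(50)
    values[20:23] = [0.6, 0.9, 0.6]
    peaks = extract_peaks(ProbabilityTrace(values, np.ones(50, dtype=int)))
    assert len(peaks) == 0


@pytest.mark.parametrize("seed", range(30))
def test_matches_brute_force_oracle_on_random_traces(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(16, 512))
    # mixture of smooth bumps and raw noise exercises plateaus and ties
    values = rng.random(n) * rng.choice([0.4, 1.0])
    values = np.round(values, 2)  # induce plateau ties
    got = extract_peaks(
        ProbabilityTrace(values, np.ones(n, dtype=int))).sample_indices
    assert got.tolist() == brute_force_peaks(values)


def test_threshold_monotonicity(rng):
    values = np.round(rng.random(256), 2)
    trace = ProbabilityTrace(values, np.ones(256, dtype=int))
    n_peaks = [len(extract_peaks(trace, threshold=th))
               for th in (0.3, 0.5, 0.7, 0.9)]
    assert n_peaks == sorted(n_peaks, reverse=True)


def test_retained_peaks_strictly_increasing(rng):
    values = np.round(rng.random(400), 2)
    peaks = extract_peaks(ProbabilityTrace(values, np.ones(400, dtype=int)))
    assert np.all(np.diff(peaks.sample_indices) > 0)


# ---------------------------------------------------------------------------
# overlap averaging
# ---------------------------------------------------------------------------

def test_average_identical_full_overlap():
    w = np.linspace(0, 1, 8)
    trace = average_overlaps([w, w], [0, 0], 8)
    assert np.allclose(trace.values, w)
    assert np.all(trace.coverage == 2)


def test_average_hand_example():
    trace = average_overlaps([np.ones(4), np.zeros(4)], [0, 2], 6)
    assert trace.values.tolist() == [1.0, 1.0, 0.5, 0.5, 0.0, 0.0]
    assert trace.coverage.tolist() == [1, 1, 2, 2, 1, 1]


def test_average_constant_windows():
    trace = average_overlaps([np.full(4, 0.7)] * 3, [0, 2, 4], 8)
    assert np.allclose(trace.values[:8][trace.coverage[:8] > 0], 0.7)


def test_uncovered_samples_are_zero_with_zero_coverage():
    trace = average_overlaps([np.ones(4)], [2], 10)
    assert trace.coverage[:2].tolist() == [0, 0]
    assert trace.values[6:].tolist() == [0.0] * 4


def test_average_matches_per_sample_recomputation(rng):
    n, L = 500, 64
    starts = list(range(0, n - L + 1, 32))
    preds = [rng.random(L) for _ in starts]
    trace = average_overlaps(preds, starts, n)
    for s in rng.integers(0, n, size=40):
        covering = [p[s - st] for p, st in zip(preds, starts)
                    if st <= s < st + L]
        expected = np.mean(covering) if covering else 0.0
        assert trace.values[s] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# end-to-end composition
# ---------------------------------------------------------------------------

class _ZeroModel:
    """Stub emitting zero probability everywhere."""

    class config:
        input_length = 2048
        in_channels = 3

    def predict(self, windows):
        return np.zeros((len(windows), 2048))


def test_flat_line_record_yields_no_detections():
    from vcgpeaks.records import VCGRecord
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant channels normalize to 0
        vcg = VCGRecord("flat", 500.0, np.zeros((4096, 3)))
        peaks = detect(_ZeroModel(), vcg)
    assert len(peaks) == 0


def test_single_window_record_matches_extract_peaks(clean_vcg):
    from vcgpeaks.model import build_model
    from vcgpeaks.records import VCGRecord
    from vcgpeaks.windows import make_inference_set
    vcg, _ = clean_vcg
    one = VCGRecord("one", 500.0, vcg.vectors[:2048])
    model = build_model(seed=2)
    whole = detect(model, one)
    segs = make_inference_set(one)
    pred = model.predict(segs.data)[0]
    direct = extract_peaks(
        ProbabilityTrace(pred, np.ones(2048, dtype=int)))
    assert whole.sample_indices.tolist() == direct.sample_indices.tolist()
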