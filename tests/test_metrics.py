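"""Tolerance matching vs an exhaustive oracle, metric formulas, HRV."""

import itertools

import numpy as np
import pytest

from vcgpeaks.detect import DetectedPeaks
from vcgpeaks.metrics import (MatchResult, aggregate, compute_metrics,
                              hrv_summary, match_peaks, pooled_hrv,
                              restrict_to_annotated_span)
from vcgpeaks.records import BeatAnnotations


def _det(indices, fs=500.0):
    idx = np.asarray(indices, dtype=np.int64)
    return DetectedPeaks(idx, np.ones(idx.size), np.full(idx.size, 5),
                         sampling_rate=fs)


from tests_oracles import optimal_pair_count


def test_match_inside_tolerance():
    m = match_peaks(_det([1037]), BeatAnnotations("r", [1000]), 500.0)
    assert (m.tp, m.fn, m.fp) == (1, 0, 0)  # 74 ms apart


def test_match_outside_tolerance():
    m = match_peaks(_det([1038]), BeatAnnotations("r", [1000]), 500.0)
    assert (m.tp, m.fn, m.fp) == (0, 1, 1)  # 76 ms apart


def test_match_exactly_at_tolerance_inclusive():
    # 75 ms at 640 Hz = 48 samples exactly
    m = match_peaks(_det([1048], fs=640.0), BeatAnnotations("r", [1000]), 640.0)
    assert (m.tp, m.fn, m.fp) == (1, 0, 0)


def test_detection_near_two_annotations_matches_nearest():
    # 60 ms from 1000, 140 ms from 1100: only the first qualifies
    m = match_peaks(_det([1030]), BeatAnnotations("r", [1000, 1100]), 500.0)
    assert m.pairs == [(1000, 1030)]
    assert m.false_negatives.tolist() == [1100]


def test_equidistant_tie_prefers_earlier_annotation():
    m = match_peaks(_det([1030]), BeatAnnotations("r", [1000, 1060]), 500.0)
    assert m.pairs == [(1000, 1030)]
    assert m.false_negatives.tolist() == [1060]


@pytest.mark.parametrize("seed", range(25))
def test_pair_count_equals_exhaustive_optimum(seed):
    rng = np.random.default_rng(seed)
    fs = 500.0
    n_ann = int(rng.integers(1, 8))
    n_det = int(rng.integers(0, 8))
    ann = np.unique(rng.integers(0, 2000, n_ann))
    det = np.unique(rng.integers(0, 2000, n_det))
    m = match_peaks(_det(det), BeatAnnotations("r", ann), fs)
    assert m.tp == optimal_pair_count(det, ann, fs)
    assert m.tp + m.fn == ann.size
    assert m.tp + m.fp == det.size


def test_shifted_detections_all_miss(clean_vcg):
    _, ann = clean_vcg
    fs = 500.0
    shift = int(0.075 * fs) + 1
    m = match_peaks(_det(ann.sample_indices + shift), ann, fs)
    # every pairing between neighbors is also out of range (1 s beat spacing)
    assert m.tp == 0
    rep = compute_metrics(m)
    assert rep.recall == 0.0


@pytest.mark.parametrize("tp,fn,fp,recall,precision", [
    (175_631, 276, 16, 99.84, 99.99),
    (3946, 27, 0, None, 100.00),  # recall left unasserted: see note
])
def test_metric_formulas_printed_values(tp, fn, fp, recall, precision):
    rep = compute_metrics((tp, fn, fp))
    if recall is not None:
        assert round(rep.recall, 2) == recall
    assert round(rep.precision, 2) == precision


def test_perfect_match_scores_100():
    rep = compute_metrics((10, 0, 0))
    assert (rep.recall, rep.precision, rep.f1) == (100.0, 100.0, 100.0)


def test_undefined_metrics_flagged():
    rep = compute_metrics((0, 0, 0))
    assert rep.undefined
    rep2 = compute_metrics((0, 5, 0))  # no detections at all
    assert rep2.precision is None and rep2.recall == 0.0


def test_f1_between_recall_and_precision(rng):
    for _ in range(20):
        tp = int(rng.integers(1, 100))
        fn = int(rng.integers(0, 50))
        fp = int(rng.integers(0, 50))
        rep = compute_metrics((tp, fn, fp))
        assert min(rep.recall, rep.precision) - 1e-9 <= rep.f1
        assert rep.f1 <= max(rep.recall, rep.precision) + 1e-9


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_identical_reports_identity():
    rep = compute_metrics((90, 10, 5))
    for mode in ("pooled", "macro"):
        agg = aggregate([rep, rep], mode)
        assert agg.recall == pytest.approx(rep.recall)
        assert agg.precision == pytest.approx(rep.precision)


def test_macro_vs_pooled_hand_arithmetic():
    r1 = compute_metrics((10, 0, 0))    # recall 100, 10 beats
    r2 = compute_metrics((45, 45, 0))   # recall 50, 90 beats
    macro = aggregate([r1, r2], "macro")
    pooled = aggregate([r1, r2], "pooled")
    assert macro.recall == pytest.approx(75.0)
    assert pooled.recall == pytest.approx(55.0)


def test_macro_equal_beat_counts():
    r1 = compute_metrics((10, 0, 0))
    r2 = compute_metrics((5, 5, 0))
    agg = aggregate([r1, r2], "macro")
    assert agg.recall == pytest.approx(75.0)
    pooled = aggregate([r1, r2], "pooled")
    assert pooled.recall == pytest.approx(100.0 * 15 / 20)


def test_single_report_unchanged_in_both_modes():
    rep = compute_metrics((7, 1, 2))
    for mode in ("pooled", "macro"):
        agg = aggregate([rep], mode)
        assert agg.recall == pytest.approx(rep.recall)
        assert agg.f1 == pytest.approx(rep.f1)


def test_aggregate_empty_raises():
    with pytest.raises(ValueError):
        aggregate([], "pooled")


def test_macro_excludes_undefined_with_warning():
    good = compute_metrics((10, 0, 0))
    bad = compute_metrics((0, 5, 0))  # precision undefined
    with pytest.warns(UserWarning, match="undefined"):
        agg = aggregate([good, bad], "macro")
    assert agg.precision == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# span restriction
# ---------------------------------------------------------------------------

def test_restrict_drops_outside_span():
    ann = BeatAnnotations("r", [1000, 2000])
    det = _det([900, 1000, 2000, 2100])  # 200 ms early / late
    out = restrict_to_annotated_span(det, ann, 500.0)
    assert out.sample_indices.tolist() == [1000, 2000]


def test_restrict_keeps_inside_and_identity():
    ann = BeatAnnotations("r", [1000, 2000])
    det = _det([1000, 1500, 2030])
    out = restrict_to_annotated_span(det, ann, 500.0)
    assert out.sample_indices.tolist() == det.sample_indices.tolist()


def test_restrict_empty_annotations_raises():
    with pytest.raises(ValueError):
        restrict_to_annotated_span(_det([1]), BeatAnnotations("r", []), 500.0)


# ---------------------------------------------------------------------------
# heart rate / HRV
# ---------------------------------------------------------------------------

def test_constant_rhythm_hrv():
    beats = np.arange(10) * 500  # one beat per second at 500 Hz
    s = hrv_summary(beats, 500.0)
    assert s.avg_hr == pytest.approx(60.0)
    assert s.sd_hr == pytest.approx(0.0)
    assert s.rmssd == pytest.approx(0.0)


def test_alternating_rr_rmssd_closed_form():
    # RR alternates 0.8 s / 1.0 s -> every successive difference is 0.2 s
    rr = np.tile([0.8, 1.0], 10)
    beats = np.round(np.concatenate([[0], np.cumsum(rr)]) * 500).astype(int)
    s = hrv_summary(beats, 500.0)
    assert s.rmssd == pytest.approx(200.0)
    assert s.avg_hr == pytest.approx(np.mean(60.0 / rr))


def test_two_beats_only_rmssd_undefined():
    s = hrv_summary([0, 500], 500.0)
    assert s.avg_hr == pytest.approx(60.0)
    assert s.rmssd is None


def test_pooled_hrv_never_crosses_record_boundaries():
    # two records with constant but different rates: pooled RMSSD must be 0
    # within records; only pooling of interval lists, not concatenation of
    # beats, achieves that
    b1 = np.arange(5) * 500          # 1.0 s intervals
    b2 = np.arange(5) * 400          # 0.8 s intervals
    s = pooled_hrv([b1, b2], [500.0, 500.0])
    assert s.rmssd == pytest.approx(0.0)
    hrs = [60.0, 75.0]
    assert s.avg_hr == pytest.approx(np.mean(np.repeat(hrs, 4)))
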