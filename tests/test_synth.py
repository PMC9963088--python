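"""Synthetic generator: rhythm, determinism, noise calibration, VCG link."""

import numpy as np
import pytest

from vcgpeaks.kors import kors_transform
from vcgpeaks.records import ECGRecord
from vcgpeaks.synth import (DEFAULT_LEAD_PROJECTION, NoiseConfig, PRESETS,
                            SynthConfig, generate, generate_dataset,
                            inject_noise)


def test_metronome_rhythm_beats_at_half_second_grid():
    rec, ann = generate(SynthConfig(duration=10.0, mean_hr=60.0, rr_sd=0.0,
                                    seed=0))
    assert len(ann) == 10
    assert np.array_equal(ann.sample_indices, (np.arange(10) + 0.5) * 500)


def test_same_seed_bit_identical():
    a, _ = generate(SynthConfig(seed=42, rr_sd=0.05,
                                noise=NoiseConfig(broadband_sigma=0.02)))
    b, _ = generate(SynthConfig(seed=42, rr_sd=0.05,
                                noise=NoiseConfig(broadband_sigma=0.02)))
    assert np.array_equal(a.signal, b.signal)


def test_different_seeds_differ():
    a, _ = generate(SynthConfig(seed=1, rr_sd=0.05))
    b, _ = generate(SynthConfig(seed=2, rr_sd=0.05))
    assert not np.array_equal(a.signal, b.signal)


def test_annotations_inside_record_and_count_conserved():
    rec, ann = generate(SynthConfig(duration=30.0, rr_sd=0.08,
                                    ectopic_rate=0.15, seed=9))
    assert np.all(ann.sample_indices >= 0)
    assert np.all(ann.sample_indices < rec.n_samples)
    assert np.all(np.diff(ann.sample_indices) > 0)
    # beat count ~ duration * hr / 60 with premature-beat excess
    assert 25 <= len(ann) <= 45


def test_rmssd_matches_iid_gaussian_identity():
    """For i.i.d. Gaussian RR jitter, successive differences have variance
    2*sigma^2, so RMSSD ~= sigma*sqrt(2)."""
    sigma = 0.05
    rec, ann = generate(SynthConfig(duration=2200.0, mean_hr=60.0,
                                    rr_sd=sigma, seed=5))
    assert len(ann) >= 2000
    rr = np.diff(ann.sample_indices) / 500.0
    rmssd = 1000.0 * np.sqrt(np.mean(np.diff(rr) ** 2))
    assert rmssd == pytest.approx(sigma * np.sqrt(2) * 1000.0, rel=0.05)


def test_kors_recovers_dipole_on_clean_record():
    rec, ann = generate(SynthConfig(duration=10.0, seed=3))
    vcg = kors_transform(rec)
    # default lead projection is the Kors pseudo-inverse: X axis of the
    # transform correlates with the dipole X (dominant R deflection)
    x = vcg.vectors[:, 0]
    assert x[ann.sample_indices].mean() > 5 * np.abs(x).mean()
    proj = DEFAULT_LEAD_PROJECTION
    from vcgpeaks.kors import KORS_MATRIX
    assert np.allclose(proj.T @ KORS_MATRIX, np.eye(3), atol=1e-12)


def test_annotation_at_local_extremum_of_vcg():
    rec, ann = generate(SynthConfig(duration=10.0, rr_sd=0.03, seed=13))
    vcg = kors_transform(rec).vectors
    for p in ann.sample_indices:
        window = np.abs(vcg[p - 2: p + 3])
        center_is_max = [np.argmax(window[:, c]) in (1, 2, 3)
                         for c in range(3)]
        assert any(center_is_max)


def test_ectopic_beats_are_premature():
    rec, ann = generate(SynthConfig(duration=120.0, rr_sd=0.0,
                                    ectopic_rate=0.3, seed=21))
    rr = np.diff(ann.sample_indices) / 500.0
    assert rr.min() < 0.7  # premature couplings present
    assert rr.max() > 0.9  # normal intervals too


def test_pacemaker_spikes_present():
    clean, _ = generate(SynthConfig(duration=10.0, rr_sd=0.0, seed=4))
    paced, ann = generate(SynthConfig(duration=10.0, rr_sd=0.0, seed=4,
                                      pacemaker_spikes=True))
    diff = np.abs(paced.signal - clean.signal).max(axis=1)
    spikes = np.flatnonzero(diff > 0.5)
    assert len(spikes) == len(ann)
    # spikes precede the QRS
    assert np.all(ann.sample_indices - spikes > 0)


def test_zero_noise_is_identity(clean_record):
    rec, _ = clean_record
    out = inject_noise(rec, NoiseConfig(seed=1))
    assert np.array_equal(out.signal, rec.signal)


def test_powerline_noise_spectral_amplitude():
    fs, n = 500.0, 10_000
    rec = ECGRecord("quiet", fs, ("I",), np.zeros((n, 1)))
    amp = 0.08
    out = inject_noise(rec, NoiseConfig(powerline_amplitude=amp, seed=2))
    delta = out.signal[:, 0] - rec.signal[:, 0]
    spec = np.abs(np.fft.rfft(delta)) * 2 / n
    freqs = np.fft.rfftfreq(n, 1 / fs)
    assert freqs[np.argmax(spec)] == pytest.approx(50.0, abs=fs / n)
    assert spec.max() == pytest.approx(amp, rel=0.02)


def test_baseline_wander_mean_absolute_identity():
    # mean |a sin| = 2a/pi over whole cycles
    fs = 500.0
    n = int(fs * 60)  # many whole 0.33 Hz cycles
    rec = ECGRecord("quiet", fs, ("I", "II"), np.zeros((n, 2)))
    a = 0.2
    out = inject_noise(rec, NoiseConfig(baseline_amplitude=a, seed=3))
    mad = np.abs(out.signal - rec.signal).mean(axis=0)
    assert np.allclose(mad, 2 * a / np.pi, rtol=0.10)


def test_annotations_unchanged_by_noise():
    cfg = SynthConfig(duration=10.0, seed=8)
    _, ann_clean = generate(cfg)
    noisy_cfg = SynthConfig(duration=10.0, seed=8,
                            noise=NoiseConfig(baseline_amplitude=0.2,
                                              powerline_amplitude=0.05,
                                              broadband_sigma=0.05))
    _, ann_noisy = generate(noisy_cfg)
    assert np.array_equal(ann_clean.sample_indices, ann_noisy.sample_indices)


def test_presets_and_dataset_generation():
    assert set(PRESETS) == {"clean", "noisy", "ectopic", "paced"}
    ds = generate_dataset(3, seed=6)
    ids = [rec.record_id for rec, _ in ds]
    assert len(set(ids)) == 3
    for rec, ann in ds:
        assert rec.n_samples == 5000 and len(ann) > 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        generate(SynthConfig(duration=0.5, mean_hr=30.0))
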