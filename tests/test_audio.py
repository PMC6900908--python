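"""Stimulus synthesis: beat-frequency recovery, decibel arithmetic, mixing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sleepbeat import audio
from sleepbeat.audio import (MixSpec, StereoAudio, ToneSpec, calibrate_rms_level,
                             db_to_amplitude, generate_surrogate_asmr,
                             measure_beat_frequency, mix_combined,
                             synthesize_binaural)

DUR = 10.0  # seconds; envelope-spectrum resolution 0.1 Hz


def _beat(f_left, f_right, duration=DUR):
    return synthesize_binaural(
        ToneSpec(f_left, duration), ToneSpec(f_right, duration)
    )


@pytest.mark.parametrize(
    "f_left, f_right, expected",
    [(250.0, 256.0, 6.0), (250.0, 250.0, 0.0), (250.0, 253.0, 3.0)],
)
def test_envelope_peak_equals_tone_difference(f_left, f_right, expected):
    measured = measure_beat_frequency(_beat(f_left, f_right))
    assert measured == pytest.approx(expected, abs=1.0 / DUR)


@pytest.mark.parametrize("delta", [0.7, 5.0, 12.5, 29.0])
def test_beat_recovery_across_offsets(delta):
    """Any sub-30 Hz tone separation is recovered to within one frequency bin."""
    measured = measure_beat_frequency(_beat(250.0, 250.0 + delta))
    assert measured == pytest.approx(delta, abs=1.0 / DUR)


def test_binaural_channels_are_the_two_tones():
    bb = _beat(250.0, 256.0, duration=1.0)
    t = np.arange(bb.n_samples) / bb.sample_rate
    assert np.allclose(bb.left, np.sin(2 * np.pi * 250.0 * t))
    assert np.allclose(bb.right, np.sin(2 * np.pi * 256.0 * t))


def test_mismatched_components_rejected():
    with pytest.raises(ValueError):
        synthesize_binaural(ToneSpec(250, 1.0), ToneSpec(256, 2.0))
    with pytest.raises(ValueError):
        synthesize_binaural(ToneSpec(250, 1.0, 44100), ToneSpec(256, 1.0, 48000))
    with pytest.raises(ValueError):
        ToneSpec(frequency=30000.0, duration=1.0, sample_rate=44100.0)


@pytest.mark.parametrize(
    "delta_db, gain",
    [(0.0, 1.0), (-30.0, 0.031623), (-6.0206, 0.5000), (20.0, 10.0)],
)
def test_db_to_amplitude(delta_db, gain):
    assert db_to_amplitude(delta_db) == pytest.approx(gain, rel=1e-4)


def test_rms_calibration_definition_and_idempotence():
    tone = _beat(250.0, 250.0, duration=1.0)  # both channels identical sines
    cal = calibrate_rms_level(tone, 0.0, reference_rms=0.05)
    assert cal.rms() == pytest.approx(0.05, rel=1e-6)
    again = calibrate_rms_level(cal, 0.0, reference_rms=0.05)
    assert again.rms() == pytest.approx(cal.rms(), rel=1e-9)
    lo = calibrate_rms_level(tone, 30.0, reference_rms=0.001)
    hi = calibrate_rms_level(tone, 60.0, reference_rms=0.001)
    assert hi.rms() / lo.rms() == pytest.approx(10 ** (30 / 20), rel=1e-6)


def test_silent_audio_cannot_be_calibrated():
    silent = StereoAudio(np.zeros(100), np.zeros(100), 44100.0)
    with pytest.raises(ValueError, match="silent"):
        calibrate_rms_level(silent, 0.0)


@pytest.mark.parametrize(
    "condition, expected_ratio",
    [("CS1", 10 ** (15 / 20)), ("CS2", 10 ** (30 / 20)), ("CS3", 10 ** (40 / 20))],
)
def test_mix_preserves_decibel_ratio(condition, expected_ratio):
    """Measured bed/beat RMS ratio equals the labeled decibel difference
    within 1 %, including when headroom normalization kicks in."""
    bb = _beat(250.0, 256.0, duration=2.0)
    bed = generate_surrogate_asmr("rain", 2.0, seed=3)
    mix = mix_combined(bb, bed, MixSpec.from_condition(condition))
    assert mix.asmr_rms / mix.bb_rms == pytest.approx(expected_ratio, rel=0.01)
    peak = max(np.max(np.abs(mix.audio.left)), np.max(np.abs(mix.audio.right)))
    assert peak <= 0.99 + 1e-9


def test_sham_is_silent_and_levels_are_fixed():
    bb = _beat(250.0, 256.0, duration=1.0)
    mix = mix_combined(bb, None, MixSpec.from_condition("SHAM"))
    assert np.all(mix.audio.left == 0) and np.all(mix.audio.right == 0)
    with pytest.raises(ValueError, match="fixed"):
        MixSpec(condition_label="CS2", bb_level_db=40.0, asmr_level_db=60.0)
    with pytest.raises(ValueError):
        MixSpec(condition_label="CS9")


def test_surrogate_determinism_and_shape():
    a = generate_surrogate_asmr("waves", 10.0, seed=11)
    b = generate_surrogate_asmr("waves", 10.0, seed=11)
    assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)
    assert a.n_samples == 441_000
    c = generate_surrogate_asmr("waves", 10.0, seed=12)
    assert not np.array_equal(a.left, c.left)
    with pytest.raises(ValueError, match="unknown"):
        generate_surrogate_asmr("thunder", 1.0)


def test_rain_surrogate_spectral_slope():
    """Log-log PSD slope of the rain bed is ~ -10 dB/decade (pink noise)."""
    from scipy import signal

    bed = generate_surrogate_asmr("rain", 10.0, seed=5)
    f, pxx = signal.welch(bed.left, fs=44100, nperseg=2**14)
    mask = (f >= 100) & (f <= 8000)
    slope = np.polyfit(np.log10(f[mask]), 10 * np.log10(pxx[mask]), 1)[0]
    assert slope == pytest.approx(-10.0, abs=2.0)


def test_wav_round_trip(tmp_path):
    mix = mix_combined(
        _beat(250, 256, duration=1.0),
        generate_surrogate_asmr("river", 1.0, seed=1),
        MixSpec.from_condition("CS2"),
    )
    path = tmp_path / "cs2.wav"
    audio.write_wav(path, mix.audio)
    back = audio.read_wav(path)
    assert back.sample_rate == mix.audio.sample_rate
    assert np.allclose(back.left, mix.audio.left, atol=1e-6)


@given(st.floats(min_value=-60, max_value=60))
def test_db_gain_inverts(delta_db):
    gain = db_to_amplitude(delta_db)
    assert 20 * np.log10(gain) == pytest.approx(delta_db, abs=1e-9)
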