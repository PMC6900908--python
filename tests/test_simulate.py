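"""Synthetic-EEG generator: determinism, parameter recovery, spectral sanity."""

import numpy as np
import pytest

from sleepbeat import io as sio
from sleepbeat import spectral
from sleepbeat.montage import default_montage
from sleepbeat.simulate import (BackgroundSpec, Cohort, EegRecording,
                                EntrainmentEffect, EpochSpec, effect_cs2_like,
                                effect_null, simulate_cohort, simulate_subject)
from sleepbeat.stats import paired_t

SHORT = EpochSpec(baseline_s=32.0, stimulation_s=32.0)
MIDLINE = default_montage().subset(("Fz", "Cz", "Pz"))
FS = 250.0


def _theta_change(rec):
    base = spectral.band_power_table(rec, "baseline")
    stim = spectral.band_power_table(rec, "stimulation")
    diff = spectral.power_change(stim, base)
    return float(diff["theta"].mean())


def test_same_seed_is_bit_identical():
    a = simulate_subject(effect_cs2_like(), SHORT, seed=42, montage=MIDLINE, sample_rate=FS)
    b = simulate_subject(effect_cs2_like(), SHORT, seed=42, montage=MIDLINE, sample_rate=FS)
    assert np.array_equal(a.data, b.data)
    c = simulate_subject(effect_cs2_like(), SHORT, seed=43, montage=MIDLINE, sample_rate=FS)
    assert not np.array_equal(a.data, c.data)


def test_invalid_epochs_rejected():
    data = np.zeros((3, 100))
    with pytest.raises(ValueError, match="outside"):
        EegRecording(data, 100.0, ("Fz", "Cz", "Pz"), epochs={"baseline": (0.0, 2.0)})
    with pytest.raises(ValueError, match="overlap"):
        EegRecording(data, 100.0, ("Fz", "Cz", "Pz"),
                     epochs={"baseline": (0.0, 0.6), "stimulation": (0.5, 1.0)})
    with pytest.raises(ValueError, match="not in montage"):
        simulate_subject(EntrainmentEffect(affected_regions=("Thalamus",)), SHORT)


def test_null_effect_has_no_systematic_theta_change():
    """With zero injected amplitude the mean theta change across many
    simulated subjects is statistically indistinguishable from zero."""
    changes = [
        _theta_change(simulate_subject(effect_null(), SHORT, seed=s,
                                       montage=MIDLINE, sample_rate=FS))
        for s in range(100)
    ]
    res = paired_t(np.asarray(changes))
    assert res.p_value > 0.05


def test_theta_change_monotone_in_amplitude():
    """Recovered theta change increases strictly with the injected amplitude
    (common background noise across levels isolates the injection)."""
    means = []
    for amp in (0.5, 1.0, 2.0, 4.0):
        eff = EntrainmentEffect(amplitude_mean=amp, between_subject_sd=0.0)
        vals = [
            _theta_change(simulate_subject(eff, SHORT, seed=s,
                                           montage=MIDLINE, sample_rate=FS))
            for s in range(20)
        ]
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_injection_is_region_specific():
    """Midline-only injection: only midline channels are modified at all,
    midline theta rises significantly, and the occipital mean change is
    small relative to the midline one."""
    eff = EntrainmentEffect(amplitude_mean=2.0, between_subject_sd=0.3)
    rec_eff = simulate_subject(eff, SHORT, seed=99, sample_rate=FS)
    rec_null = simulate_subject(effect_null(), SHORT, seed=99, sample_rate=FS)
    touched = np.where(np.abs(rec_eff.data - rec_null.data).max(axis=1) > 1e-12)[0]
    midline_idx = {rec_eff.channels.index(c) for c in ("Fz", "Cz", "Pz")}
    assert set(touched) == midline_idx

    mid, occ = [], []
    for s in range(40):
        rec = simulate_subject(eff, SHORT, seed=s, sample_rate=FS)
        base = spectral.band_power_table(rec, "baseline")
        stim = spectral.band_power_table(rec, "stimulation")
        diff = spectral.region_power_table(spectral.power_change(stim, base))
        mid.append(diff.loc["Midline", "theta"])
        occ.append(diff.loc["Occipital", "theta"])
    assert paired_t(np.asarray(mid)).p_value < 1e-4
    assert abs(np.mean(occ)) < 0.3 * np.mean(mid)


def test_background_spectral_slope_matches_chi():
    """Log-log PSD slope of the pure background is within 0.3 of -chi."""
    bg = BackgroundSpec(chi=1.0, alpha_amplitude_uv=0.0)
    rec = simulate_subject(effect_null(), EpochSpec(120.0, 8.0), seed=7,
                           montage=MIDLINE, sample_rate=FS, background=bg)
    f, pxx = spectral.welch_psd(rec.data[0], FS)
    mask = (f >= 1.0) & (f <= 40.0)
    slope = np.polyfit(np.log10(f[mask]), np.log10(pxx[mask]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.3)


def test_alpha_suppression_lowers_stimulation_alpha():
    eff = EntrainmentEffect(amplitude_mean=0.0, between_subject_sd=0.0,
                            alpha_suppression=0.5)
    drops = []
    for s in range(10):
        rec = simulate_subject(eff, SHORT, seed=s, montage=MIDLINE, sample_rate=FS)
        base = spectral.band_power_table(rec, "baseline")
        stim = spectral.band_power_table(rec, "stimulation")
        drops.append(float((stim["alpha"] - base["alpha"]).mean()))
    assert np.mean(drops) < 0


def test_cohort_structure_and_determinism():
    conds = [("SHAM", effect_null()), ("BB", effect_cs2_like()),
             ("AT", effect_null()), ("CS", effect_cs2_like())]
    cohort = simulate_cohort(3, conds, timing=EpochSpec(8.0, 8.0), seed=5,
                             montage=MIDLINE, sample_rate=FS)
    assert cohort.n == 3 and set(cohort.conditions) == {"SHAM", "BB", "AT", "CS"}
    assert all(len(recs) == 4 for recs in cohort.subjects)
    cohort2 = simulate_cohort(3, conds, timing=EpochSpec(8.0, 8.0), seed=5,
                              montage=MIDLINE, sample_rate=FS)
    assert np.array_equal(cohort.subjects[2]["CS"].data, cohort2.subjects[2]["CS"].data)
    with pytest.raises(ValueError):
        simulate_cohort(1, conds)


def test_recording_round_trip(tmp_path):
    rec = simulate_subject(effect_cs2_like(), EpochSpec(8.0, 8.0), seed=9,
                           montage=MIDLINE, sample_rate=FS)
    sio.save_recording(rec, tmp_path / "sub01_CS")
    back = sio.load_recording(tmp_path / "sub01_CS")
    assert back.channels == rec.channels
    assert back.epochs == rec.epochs
    assert np.allclose(back.data, rec.data, atol=1e-3)  # 4-decimal text format
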