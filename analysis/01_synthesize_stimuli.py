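"""Build the auditory stimuli and verify their design contracts.

Synthesizes the 6 Hz binaural beat (250/256 Hz), the five surrogate
nature-sound beds, and the three combined stimuli (CS1/CS2/CS3 at
45:60 / 30:60 / 20:60 dB), then measures what matters: the envelope-spectrum
beat peak, each mix's bed-to-beat RMS ratio, and each bed's spectral slope.

Writes: results/stimulus_metrics.csv (measurements) and WAV files under
scratch/stimuli/ (audio is bulky; everything quantitative is in the CSV).
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from sleepbeat import audio

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "stimuli"
DURATION = 60.0
SEED = 7


def spectral_slope(bed: audio.StereoAudio) -> float:
    f, pxx = signal.welch(bed.left, fs=bed.sample_rate, nperseg=2**14)
    mask = (f >= 100) & (f <= 8000)
    return float(np.polyfit(np.log10(f[mask]), 10 * np.log10(pxx[mask]), 1)[0])


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []

    bb = audio.synthesize_binaural(
        audio.ToneSpec(250.0, DURATION), audio.ToneSpec(256.0, DURATION)
    )
    beat = audio.measure_beat_frequency(bb)
    audio.write_wav(SCRATCH / "binaural_250_256.wav", audio.calibrate_rms_level(bb, 60.0))
    rows.append({"stimulus": "BB", "measure": "envelope_peak_hz", "value": beat})
    print(f"binaural beat: envelope peak {beat:.2f} Hz (design 6.0)")

    for kind in sorted(audio.ASMR_KINDS):
        bed = audio.generate_surrogate_asmr(kind, DURATION, seed=SEED)
        slope = spectral_slope(bed)
        audio.write_wav(SCRATCH / f"bed_{kind}.wav", bed)
        rows.append({"stimulus": f"bed_{kind}", "measure": "psd_slope_db_per_decade",
                     "value": slope})
        print(f"bed {kind:10s}: PSD slope {slope:6.1f} dB/decade")

    bed = audio.generate_surrogate_asmr("rain", DURATION, seed=SEED)
    for cond in ("CS1", "CS2", "CS3"):
        mix = audio.mix_combined(bb, bed, audio.MixSpec.from_condition(cond))
        ratio_db = 20 * np.log10(mix.asmr_rms / mix.bb_rms)
        audio.write_wav(SCRATCH / f"{cond.lower()}_rain.wav", mix.audio)
        rows.append({"stimulus": cond, "measure": "bed_minus_beat_db", "value": ratio_db})
        rows.append({"stimulus": cond, "measure": "headroom_gain", "value": mix.headroom_gain})
        print(f"{cond}: bed-beat level difference {ratio_db:5.2f} dB "
              f"(design {60 - audio.CONDITION_LEVELS[cond][0]:g}), "
              f"headroom gain {mix.headroom_gain:.3f}")

    pd.DataFrame(rows).to_csv(RESULTS / "stimulus_metrics.csv", index=False,
                              float_format="%.6g")
    print(f"\nwrote {RESULTS / 'stimulus_metrics.csv'} and WAVs under {SCRATCH}")


if __name__ == "__main__":
    main()
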