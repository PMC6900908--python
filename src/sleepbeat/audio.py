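"""Auditory stimulus synthesis: binaural-beat tones, surrogate nature sounds,
and decibel-ratio mixes.

A binaural beat is produced by playing two pure tones of slightly different
frequency, one to each ear; the perceived beat rate equals the frequency
difference.  The sleep-induction stimulus pairs a 250 Hz left-ear carrier with
a 256 Hz right-ear tone (6 Hz beat, the centre of the theta band) and mixes it
with a nature-sound bed at fixed decibel ratios.

Printed sound-pressure levels (45/30/20 dB against a 60 dB bed) cannot be
realized in a digital file; they are interpreted as *relative* levels on a
dBFS-anchored scale that preserves every printed difference.  ``REFERENCE_RMS``
is the RMS corresponding to 0 dB, chosen so a 60 dB track sits at RMS 0.2 with
headroom to spare.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "ToneSpec", "MixSpec", "StereoAudio", "MixResult",
    "db_to_amplitude", "synthesize_binaural", "calibrate_rms_level",
    "generate_surrogate_asmr", "mix_combined", "measure_beat_frequency",
    "write_wav", "read_wav",
    "REFERENCE_RMS", "CONDITION_LEVELS", "ASMR_KINDS",
]

#: RMS amplitude assigned to 0 dB on the relative level scale.
REFERENCE_RMS = 2.0e-4

#: (binaural-beat level, nature-sound level) in relative dB per condition.
CONDITION_LEVELS: dict[str, tuple[float | None, float | None]] = {
    "CS1": (45.0, 60.0),
    "CS2": (30.0, 60.0),
    "CS3": (20.0, 60.0),
    "BB_only": (60.0, None),
    "AT_only": (None, 60.0),
    "SHAM": (None, None),
}


def db_to_amplitude(delta_db: float) -> float:
    """Amplitude gain for a level difference in dB: ``10**(delta_db/20)``."""
    if not np.isfinite(delta_db):
        raise ValueError("delta_db must be finite")
    return float(10.0 ** (delta_db / 20.0))


@dataclass(frozen=True)
class ToneSpec:
    """A pure sinusoid: frequency (Hz), duration (s), sample rate (Hz), phase (rad)."""

    frequency: float
    duration: float
    sample_rate: float = 44100.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.frequency < self.sample_rate / 2:
            raise ValueError(
                f"frequency {self.frequency} Hz must lie in (0, Nyquist={self.sample_rate / 2} Hz)"
            )

    def render(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        t = np.arange(n) / self.sample_rate
        return np.sin(2 * np.pi * self.frequency * t + self.phase)


@dataclass(frozen=True)
class StereoAudio:
    """Two-channel waveform with sample rate; samples nominally within [-1, 1]."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left/right channel lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def rms(self) -> float:
        """Whole-file RMS averaged across the two channels."""
        rl = float(np.sqrt(np.mean(self.left**2)))
        rr = float(np.sqrt(np.mean(self.right**2)))
        return 0.5 * (rl + rr)

    def mono(self) -> np.ndarray:
        return 0.5 * (self.left + self.right)

    def scaled(self, gain: float) -> "StereoAudio":
        return replace(self, left=self.left * gain, right=self.right * gain)


@dataclass(frozen=True)
class MixSpec:
    """Levels (relative dB) for the beat and the nature-sound bed of one condition."""

    condition_label: str
    bb_level_db: float | None = None
    asmr_level_db: float | None = None

    def __post_init__(self) -> None:
        if self.condition_label not in CONDITION_LEVELS:
            raise ValueError(f"unknown condition {self.condition_label!r}")
        fixed = CONDITION_LEVELS[self.condition_label]
        got = (self.bb_level_db, self.asmr_level_db)
        if got != (None, None) and got != fixed:
            raise ValueError(
                f"{self.condition_label} levels are fixed at {fixed}, got {got}"
            )
        object.__setattr__(self, "bb_level_db", fixed[0])
        object.__setattr__(self, "asmr_level_db", fixed[1])

    @classmethod
    def from_condition(cls, label: str) -> "MixSpec":
        return cls(condition_label=label)


@dataclass(frozen=True)
class MixResult:
    """A mixed stimulus plus the level bookkeeping needed to audit it."""

    audio: StereoAudio
    bb_rms: float
    asmr_rms: float
    headroom_gain: float = 1.0


def synthesize_binaural(carrier: ToneSpec, offset: ToneSpec) -> StereoAudio:
    """Carrier tone to the left ear, offset tone to the right ear.

    The beat (envelope-modulation) frequency of the mono sum equals
    ``|offset.frequency - carrier.frequency|``.
    """
    if carrier.sample_rate != offset.sample_rate:
        raise ValueError("carrier and offset sample rates differ")
    if carrier.duration != offset.duration:
        raise ValueError("carrier and offset durations differ")
    return StereoAudio(
        left=carrier.render(), right=offset.render(), sample_rate=carrier.sample_rate
    )


def calibrate_rms_level(
    audio: StereoAudio, target_db: float, reference_rms: float = REFERENCE_RMS
) -> StereoAudio:
    """Scale ``audio`` so its channel-averaged RMS is ``reference_rms * 10**(target_db/20)``."""
    if reference_rms <= 0:
        raise ValueError("reference_rms must be positive")
    current = audio.rms()
    if current == 0:
        raise ValueError("cannot calibrate silent audio")
    target = reference_rms * db_to_amplitude(target_db)
    return audio.scaled(target / current)


# kind -> (power-spectral slope chi in S(f) ~ 1/f^chi, AM rate Hz, AM depth,
#          high-pass edge Hz).  Kinds differ only in these documented values.
ASMR_KINDS: dict[str, tuple[float, float, float, float]] = {
    "rain": (1.0, 0.0, 0.0, 200.0),
    "waves": (1.2, 0.12, 0.8, 80.0),
    "waterfall": (0.8, 0.0, 0.1, 100.0),
    "forest": (1.4, 0.5, 0.4, 300.0),
    "river": (1.1, 0.25, 0.25, 120.0),
}


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, chi: float, f_floor: float
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^chi above ``f_floor`` (flat below)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    hi = f > f_floor
    shape[hi] = (f[hi] / f_floor) ** (-chi / 2.0)
    shape[0] = 0.0  # no DC
    return np.fft.irfft(spec * shape, n=n)


def generate_surrogate_asmr(
    kind: str, duration: float, sample_rate: float = 44100.0, seed: int = 0
) -> StereoAudio:
    """Seeded broadband noise standing in for one of the five nature-sound beds.

    Each kind is filtered noise with a documented spectral tilt and optional
    slow amplitude modulation (``ASMR_KINDS``); output is deterministic in
    ``(kind, duration, sample_rate, seed)`` and normalized to RMS 0.1.
    """
    if kind not in ASMR_KINDS:
        raise ValueError(f"unknown surrogate kind {kind!r}; choose from {sorted(ASMR_KINDS)}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    chi, am_rate, am_depth, f_floor = ASMR_KINDS[kind]
    n = int(round(duration * sample_rate))
    kind_tag = zlib.crc32(kind.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([kind_tag, seed]))
    channels = []
    t = np.arange(n) / sample_rate
    for _ in range(2):
        x = _shaped_noise(rng, n, sample_rate, chi, f_floor)
        if am_rate > 0 and am_depth > 0:
            x = x * (1.0 + am_depth * np.sin(2 * np.pi * am_rate * t))
        x = x / np.sqrt(np.mean(x**2)) * 0.1
        channels.append(x)
    return StereoAudio(left=channels[0], right=channels[1], sample_rate=sample_rate)


def _match_length(x: StereoAudio, n: int) -> StereoAudio:
    """Trim or loop ``x`` to exactly ``n`` samples."""
    if x.n_samples == n:
        return x
    reps = int(np.ceil(n / x.n_samples))
    return replace(
        x,
        left=np.tile(x.left, reps)[:n],
        right=np.tile(x.right, reps)[:n],
    )


def mix_combined(
    bb: StereoAudio | None,
    asmr: StereoAudio | None,
    spec: MixSpec,
    reference_rms: float = REFERENCE_RMS,
    headroom: float = 0.99,
) -> MixResult:
    """Combine beat and nature-sound bed at the condition's relative levels.

    Components are independently RMS-calibrated, the bed is trimmed/looped to
    the beat's length, and the sum is jointly rescaled (ratio-preserving) if it
    would exceed ``headroom`` in absolute value; the applied gain is recorded.
    """
    bb_db, asmr_db = spec.bb_level_db, spec.asmr_level_db
    if bb_db is not None and bb is None:
        raise ValueError(f"{spec.condition_label} needs a binaural-beat component")
    if asmr_db is not None and asmr is None:
        raise ValueError(f"{spec.condition_label} needs a nature-sound component")

    parts: list[StereoAudio] = []
    bb_rms = asmr_rms = 0.0
    fs = None
    if bb_db is not None:
        cal = calibrate_rms_level(bb, bb_db, reference_rms)
        bb_rms = cal.rms()
        parts.append(cal)
        fs = cal.sample_rate
    if asmr_db is not None:
        if fs is not None and asmr.sample_rate != fs:
            raise ValueError("sample-rate mismatch between components")
        cal = calibrate_rms_level(asmr, asmr_db, reference_rms)
        asmr_rms = cal.rms()
        if parts:
            cal = _match_length(cal, parts[0].n_samples)
        parts.append(cal)
        fs = cal.sample_rate

    if not parts:  # SHAM: one second of silence unless a template length is given
        n = bb.n_samples if bb is not None else int(44100)
        fs = bb.sample_rate if bb is not None else 44100.0
        silent = StereoAudio(np.zeros(n), np.zeros(n), fs)
        return MixResult(audio=silent, bb_rms=0.0, asmr_rms=0.0)

    left = sum(p.left for p in parts)
    right = sum(p.right for p in parts)
    out = StereoAudio(left=left, right=right, sample_rate=fs)
    gain = 1.0
    peak = max(np.max(np.abs(left), initial=0.0), np.max(np.abs(right), initial=0.0))
    if peak > headroom:
        gain = headroom / peak
        out = out.scaled(gain)
        bb_rms *= gain
        asmr_rms *= gain
    return MixResult(audio=out, bb_rms=bb_rms, asmr_rms=asmr_rms, headroom_gain=gain)


def measure_beat_frequency(audio: StereoAudio, f_min: float = 0.5) -> float:
    """Beat rate of a stimulus: peak of the mono-sum envelope spectrum above ``f_min``.

    The envelope is the magnitude of the analytic (Hilbert) signal of the mono
    sum; its periodogram peaks at the beat frequency.  Resolution is one
    frequency bin, ``1/duration`` Hz.  Returns 0.0 for an unmodulated envelope
    (no spectral line above ``f_min`` rising above the noise floor).
    """
    mono = audio.mono()
    env = np.abs(signal.hilbert(mono))
    env = env - np.mean(env)
    f, pxx = signal.periodogram(env, fs=audio.sample_rate)
    mask = f >= f_min
    if not np.any(mask) or np.max(pxx[mask]) <= 0:
        return 0.0
    # A flat envelope leaves only broadband numerical noise: require the peak
    # to dominate the envelope variance rather than be an arbitrary noise bin.
    total = np.sum(pxx[mask])
    peak_i = np.argmax(pxx[mask])
    if pxx[mask][peak_i] < 0.5 * total:
        return 0.0
    return float(f[mask][peak_i])


def write_wav(path, audio: StereoAudio) -> None:
    """Write a stereo float32 RIFF/WAV file."""
    data = np.stack([audio.left, audio.right], axis=1).astype(np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wavfile.write(path, int(audio.sample_rate), data)


def read_wav(path) -> StereoAudio:
    fs, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a stereo WAV file")
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return StereoAudio(left=np.asarray(data[:, 0], float),
                       right=np.asarray(data[:, 1], float),
                       sample_rate=float(fs))
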