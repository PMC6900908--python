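"""Synthetic EEG cohorts with the statistical structure the analysis assumes.

Each channel is 1/f^chi background noise plus an alpha-band oscillation; during
the stimulation epoch a target-frequency sinusoid (default 6 Hz) is added to
the channels of the affected regions, with an amplitude drawn once per subject
from a log-normal distribution.  That single per-subject draw reproduces the
paired-design correlation structure: within a subject, baseline and
stimulation epochs share the background statistics and differ by the injected
oscillation.  A configurable fraction of the amplitude persists into the
post-stimulus rest epoch so that pre-vs-post resting analyses have something
to recover.  No volume-conduction model is applied — the downstream analysis
consumes channel band powers only.

Units are microvolts; all randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so cohorts are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, default_montage

__all__ = [
    "EpochSpec", "BackgroundSpec", "EntrainmentEffect", "EegRecording", "Cohort",
    "simulate_subject", "simulate_cohort",
    "effect_null", "effect_cs2_like", "effect_strong_midline",
    "session1_effects", "session2_effects",
    "log_sd_for_standardized_effect",
    "SESSION1_TIMING", "SESSION2_TIMING",
]


@dataclass(frozen=True)
class EpochSpec:
    """Durations (s) of the baseline rest, stimulation, and post rest epochs."""

    baseline_s: float = 120.0
    stimulation_s: float = 180.0
    post_s: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.stimulation_s <= 0 or self.post_s < 0:
            raise ValueError("epoch durations must be positive (post may be 0)")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stimulation_s + self.post_s

    def intervals(self) -> dict[str, tuple[float, float]]:
        b, s, p = self.baseline_s, self.stimulation_s, self.post_s
        out = {"baseline": (0.0, b), "stimulation": (b, b + s)}
        if p > 0:
            out["post"] = (b + s, b + s + p)
        return out


#: Study timings: 2 min baseline + 3 min stimulation (session 1);
#: 2 min rest + 10 min stimulation + 2 min rest (session 2).
SESSION1_TIMING = EpochSpec(baseline_s=120.0, stimulation_s=180.0, post_s=0.0)
SESSION2_TIMING = EpochSpec(baseline_s=120.0, stimulation_s=600.0, post_s=120.0)


@dataclass(frozen=True)
class BackgroundSpec:
    """Ongoing-EEG model: 1/f^chi noise (RMS in uV) plus an alpha oscillation."""

    chi: float = 1.0
    noise_rms_uv: float = 10.0
    alpha_freq_hz: float = 10.0
    alpha_amplitude_uv: float = 5.0
    f_floor_hz: float = 0.5  # spectrum flat below this corner


def log_sd_for_standardized_effect(d: float) -> float:
    """Log-scale SD of the amplitude draw so the injected *power* change
    (proportional to amplitude squared, hence itself log-normal) has
    mean/SD = ``d`` between subjects.  Estimation noise in finite epochs
    lowers the realized effect slightly below this design value.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    return float(np.sqrt(np.log1p(1.0 / d**2) / 4.0))


@dataclass(frozen=True)
class EntrainmentEffect:
    """Stimulus-locked oscillation injected during stimulation.

    amplitude_mean is the *median* (uV) of the per-subject log-normal amplitude
    draw; between_subject_sd is the SD of its natural log.  alpha_suppression
    scales the background alpha oscillation down by that fraction during
    stimulation.  post_fraction is the fraction of the subject's amplitude
    persisting through the post-stimulus rest epoch.
    """

    target_frequency: float = 6.0
    affected_regions: tuple[str, ...] = ("Midline",)
    amplitude_mean: float = 2.0
    between_subject_sd: float = 0.45
    alpha_suppression: float = 0.0
    post_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be >= 0")
        if not 0.0 <= self.alpha_suppression <= 1.0:
            raise ValueError("alpha_suppression must be in [0, 1]")


def effect_null() -> EntrainmentEffect:
    """No injected oscillation (sham-like condition)."""
    return EntrainmentEffect(amplitude_mean=0.0, between_subject_sd=0.0)


def effect_cs2_like(d: float = 0.9) -> EntrainmentEffect:
    """Midline 6 Hz injection calibrated to a paired standardized effect ~= d.

    The default d = 0.9 mirrors the strongest theta entrainment the combined
    stimulus produced at the 30:60 ratio.
    """
    return EntrainmentEffect(
        amplitude_mean=2.0,
        between_subject_sd=log_sd_for_standardized_effect(d),
        alpha_suppression=0.3,
    )


def effect_strong_midline() -> EntrainmentEffect:
    """Deliberately suprathreshold midline injection for recovery demonstrations."""
    return EntrainmentEffect(
        amplitude_mean=3.0, between_subject_sd=0.2, alpha_suppression=0.3,
        post_fraction=1.0,
    )


def session1_effects() -> list[tuple[str, "EntrainmentEffect"]]:
    """Ground truth for session-1 cohorts: all three decibel ratios entrain
    midline theta, the 30:60 mix (CS2) most strongly.  Amplitudes and
    between-subject spreads are set so the whole-cohort standardized theta
    effects sit near the published values (~0.6 / 0.9 / 0.8); the short
    3-minute exposure produced no reliable alpha change, so none is injected.
    """
    return [
        ("CS1", EntrainmentEffect(amplitude_mean=1.4,
                                  between_subject_sd=log_sd_for_standardized_effect(0.63),
                                  alpha_suppression=0.0)),
        ("CS2", EntrainmentEffect(amplitude_mean=2.2,
                                  between_subject_sd=log_sd_for_standardized_effect(0.89),
                                  alpha_suppression=0.0)),
        ("CS3", EntrainmentEffect(amplitude_mean=1.2,
                                  between_subject_sd=log_sd_for_standardized_effect(0.84),
                                  alpha_suppression=0.0)),
    ]


def session2_effects() -> list[tuple[str, "EntrainmentEffect"]]:
    """Ground truth for session-2 cohorts: sham silent; beat-only and
    nature-sound-only entrain theta moderately; the combined stimulus
    entrains midline theta most strongly.  The 10-minute exposure suppressed
    alpha under every active stimulus, so all three inject a fractional
    alpha reduction."""
    return [
        ("SHAM", effect_null()),
        ("BB", EntrainmentEffect(amplitude_mean=1.6,
                                 between_subject_sd=log_sd_for_standardized_effect(0.67),
                                 alpha_suppression=0.25)),
        ("AT", EntrainmentEffect(amplitude_mean=1.2,
                                 between_subject_sd=log_sd_for_standardized_effect(0.54),
                                 alpha_suppression=0.35)),
        ("CS", EntrainmentEffect(amplitude_mean=2.4,
                                 between_subject_sd=log_sd_for_standardized_effect(0.9),
                                 alpha_suppression=0.35)),
    ]


@dataclass(frozen=True)
class EegRecording:
    """channels x samples matrix (uV) with montage labels and epoch markers."""

    data: np.ndarray
    sample_rate: float
    channels: tuple[str, ...]
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching channel labels")
        dur = self.data.shape[1] / self.sample_rate
        spans = sorted(self.epochs.values())
        for (a, b) in spans:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"epoch ({a}, {b}) outside record of {dur:.1f} s")
        for (_, b), (a2, _) in zip(spans, spans[1:]):
            if a2 < b - 1e-9:
                raise ValueError("epoch intervals overlap")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def epoch_data(self, label: str) -> np.ndarray:
        a, b = self.epochs[label]
        i0, i1 = int(round(a * self.sample_rate)), int(round(b * self.sample_rate))
        return self.data[:, i0:i1]


@dataclass(frozen=True)
class Cohort:
    """Per-subject sets of condition recordings plus the seed that made them."""

    subjects: tuple[dict[str, EegRecording], ...]
    conditions: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("a cohort needs n >= 2 subjects")
        for i, recs in enumerate(self.subjects):
            missing = [c for c in self.conditions if c not in recs]
            if missing:
                raise ValueError(f"subject {i} missing conditions {missing}")

    @property
    def n(self) -> int:
        return len(self.subjects)


def _background(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    spec: BackgroundSpec,
) -> np.ndarray:
    """1/f^chi noise for all channels at once (FFT-shaped white noise)."""
    white = rng.standard_normal((n_channels, n_samples))
    fft = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(f)
    hi = f > spec.f_floor_hz
    shape[hi] = (f[hi] / spec.f_floor_hz) ** (-spec.chi / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(fft * shape[None, :], n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms * spec.noise_rms_uv


def simulate_subject(
    effect: EntrainmentEffect,
    timing: EpochSpec = SESSION1_TIMING,
    seed: int | np.random.SeedSequence = 0,
    montage: Montage | None = None,
    sample_rate: float = 500.0,
    background: BackgroundSpec = BackgroundSpec(),
    amplitude_scale: float | None = None,
) -> EegRecording:
    """One subject's recording for one condition.

    Reproducible from ``seed``; the per-subject entrainment amplitude is a
    single log-normal draw applied to every affected-region channel.  When
    ``amplitude_scale`` is given (cohort simulation with a shared subject
    responsiveness), the amplitude is ``amplitude_mean * amplitude_scale``
    instead of a fresh draw.
    """
    montage = montage or default_montage()
    bad = [r for r in effect.affected_regions if r not in montage.regions]
    if bad:
        raise ValueError(f"affected regions not in montage: {bad}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n_ch = montage.n_channels
    n = int(round(timing.total_s * sample_rate))
    t = np.arange(n) / sample_rate
    intervals = timing.intervals()
    stim_a, stim_b = intervals["stimulation"]
    in_stim = (t >= stim_a) & (t < stim_b)

    data = _background(rng, n_ch, n, sample_rate, background)

    # alpha oscillation with per-channel random phase; optionally suppressed
    # during stimulation (drowsiness / entrainment side effect)
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    alpha = background.alpha_amplitude_uv * np.sin(
        2 * np.pi * background.alpha_freq_hz * t[None, :] + phases[:, None]
    )
    env = np.ones(n)
    if effect.alpha_suppression > 0:
        env[in_stim] = 1.0 - effect.alpha_suppression
        if "post" in intervals:
            a, b = intervals["post"]
            env[(t >= a) & (t < b)] = 1.0 - effect.alpha_suppression * effect.post_fraction
    data += alpha * env[None, :]

    if effect.amplitude_mean > 0:
        if amplitude_scale is not None:
            amp = effect.amplitude_mean * amplitude_scale
        else:
            amp = float(
                np.exp(rng.normal(np.log(effect.amplitude_mean), effect.between_subject_sd))
            )
        gain = np.zeros(n)
        gain[in_stim] = amp
        if "post" in intervals:
            a, b = intervals["post"]
            gain[(t >= a) & (t < b)] = amp * effect.post_fraction
        wave = gain * np.sin(2 * np.pi * effect.target_frequency * t + rng.uniform(0, 2 * np.pi))
        idx = sorted({i for r in effect.affected_regions for i in montage.region_indices(r)})
        data[idx, :] += wave[None, :]

    return EegRecording(
        data=data, sample_rate=sample_rate, channels=montage.channels,
        epochs=intervals,
    )


def simulate_cohort(
    n: int,
    conditions: list[tuple[str, EntrainmentEffect]],
    timing: EpochSpec = SESSION1_TIMING,
    seed: int = 0,
    montage: Montage | None = None,
    sample_rate: float = 500.0,
    background: BackgroundSpec = BackgroundSpec(),
    shared_subject_effect: bool = True,
) -> Cohort:
    """Simulate ``n`` subjects, each recorded under every condition.

    Per-subject-per-condition seeds are spawned deterministically from the
    master seed, so any sub-cohort is reproducible without regenerating the
    rest.  Conditions are generated independently (no carry-over between
    sub-sessions), matching the washout assumption of the paired analysis.

    With ``shared_subject_effect`` (the default) a single standard-normal
    responsiveness draw per subject sets the entrainment amplitude under
    every condition (scaled by each condition's between-subject SD).  Each
    condition's marginal amplitude distribution is unchanged, but a strongly
    responding subject responds strongly everywhere — the repeated-measures
    correlation that makes one condition win within subjects.  Set it False
    for condition-independent draws.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    labels = [lab for lab, _ in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n)
    subjects = []
    for i in range(n):
        cond_seeds = subject_seeds[i].spawn(len(conditions) + 1)
        scale_z = float(np.random.default_rng(cond_seeds[-1]).standard_normal())
        recs = {}
        for (lab, eff), cs in zip(conditions, cond_seeds):
            scale = (
                float(np.exp(scale_z * eff.between_subject_sd))
                if shared_subject_effect else None
            )
            recs[lab] = simulate_subject(
                eff, timing=timing, seed=cs, montage=montage,
                sample_rate=sample_rate, background=background,
                amplitude_scale=scale,
            )
        subjects.append(recs)
    return Cohort(subjects=tuple(subjects), conditions=tuple(labels), seed=seed)
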