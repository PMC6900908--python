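# Methods

## Stimulus synthesis

The binaural stimulus is two phase-locked sinusoids: a 250 Hz carrier on the
left channel and a 256 Hz tone on the right, rendered at 44.1 kHz into float32
WAV. The beat rate is verified, not assumed: the mono sum's amplitude
envelope (magnitude of the analytic signal) is periodogram-analysed and the
peak above 0.5 Hz reported, with one-bin (1/duration Hz) resolution. A flat
envelope (identical tones) is reported as 0 Hz by requiring the peak bin to
carry at least half of the envelope variance, which separates a genuine
spectral line from broadband numerical noise.

**Level scale.** The design levels (beat at 45/30/20 dB against a 60 dB bed)
are sound-pressure levels, which have no absolute meaning in a digital file.
They are realized as *relative* levels on a dBFS-anchored scale that
preserves every printed difference: level L dB maps to RMS
`REFERENCE_RMS · 10^(L/20)` with `REFERENCE_RMS = 2·10⁻⁴` (so a 60 dB track
sits at RMS 0.2, leaving headroom). Level is whole-file RMS averaged across
the two channels. If a mix would exceed |0.99| the two components are scaled
jointly and the gain recorded — the ratio, which is what the design fixes, is
untouched.

**Surrogate nature sounds.** The five beds (rain, waves, waterfall, forest,
river) are seeded filtered noise, not downloaded audio: broadband Gaussian
noise spectrally shaped to 1/f^χ above a kind-specific corner, with optional
slow amplitude modulation. The kinds differ only in the documented
(χ, AM rate, AM depth, high-pass corner) tuple — e.g. rain is plain pink
noise (−10 dB/decade), waves add 0.12 Hz deep modulation. Which bed a
subject hears was arbitrary in the original design, so nothing downstream
depends on the kind. Output is bit-reproducible from (kind, seed).

## Synthetic EEG cohorts

Each channel is the sum of

* **1/f^χ background** (default χ = 1, flat below 0.5 Hz), FFT-shaped white
  noise normalized to 10 µV RMS per channel, independent across channels;
* an **alpha oscillation** (10 Hz, 5 µV amplitude, random phase per channel),
  optionally suppressed by a fractional `alpha_suppression` during
  stimulation (and, scaled by `post_fraction`, during the post rest);
* during stimulation, the **entrainment effect**: a sinusoid at the target
  frequency (default 6 Hz) added to every channel of the affected regions
  (default: midline Fz/Cz/Pz), with a per-subject amplitude drawn once from
  a log-normal distribution (median `amplitude_mean` µV, log-SD
  `between_subject_sd`). A fraction `post_fraction` (default 0.7) of that
  amplitude persists through the post-stimulus rest, so pre-vs-post resting
  analyses have a recoverable signal.

Units are µV throughout; powers are reported in µV² (linear scale; the
original report's power units are unstated, so only standardized quantities
are comparable).

**Calibration to a standardized effect.** The injected theta-power change is
proportional to amplitude², hence itself log-normal; choosing the log-SD as
`sqrt(ln(1 + 1/d²)/4)` makes the between-subject mean/SD of the injected
power equal a design effect size d. The CS2-like preset targets d = 0.9,
echoing the strongest reported whole-cohort theta effect. Because the
injected change is strictly positive within every subject, realized test
power exceeds the normal-theory power at the same d — a property of the
log-normal effect model, not an analysis artefact.

**Repeated-measures correlation.** In cohorts, one standard-normal
responsiveness draw per subject sets the amplitude under every condition
(scaled by each condition's log-SD). Marginal distributions per condition are
unchanged, but a responsive subject is responsive everywhere — which is what
lets the strongest condition win the per-subject 6 Hz peak vote in (nearly)
all subjects, as observed in the original cohort. Condition-independent
draws are available via `shared_subject_effect=False`.

**Session presets.** `session1_effects()` gives the three mixing ratios
midline injections with amplitudes 1.4/2.2/1.2 µV and spreads targeting
d ≈ 0.63/0.89/0.84 and no alpha change (3-minute exposures); `session2_effects()`
gives sham (nothing), beat-only (1.6 µV, d ≈ 0.67, 25 % alpha suppression),
bed-only (1.2 µV, d ≈ 0.54, 35 %), and combined (2.4 µV, d ≈ 0.9, 35 %)
(10-minute exposures suppress alpha under every active stimulus).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: ocular/muscle artifacts, volume conduction
(channels are independent, so scalp topographies are idealized), the
condition-specific *regional* profiles beyond the midline injection
(temporal effects of the beat-heavy mix, frontal effects of the bed), sleep
staging and drowsiness drift, and re-referencing (data are generated as if
already referenced). The analysis consumes channel band powers only, which
is why these simplifications are tolerable.

## Preprocessing

Recordings are decimated from 500 to 250 Hz by polyphase resampling (the
anti-alias low-pass is part of the polyphase filter; only integer ratios are
accepted), band-passed 0.5–50 Hz, and notch-filtered 58–62 Hz. Both filters
are windowed-sinc (Hamming) FIRs; the band-pass is designed for a 0.5 Hz
transition at the low edge (1651 taps at 250 Hz), the notch for a 2 Hz
transition (≥ 20 dB at 60 Hz, < 1 dB at 50/70 Hz). Since a linear-phase FIR
delayed by (N−1)/2 samples has exactly zero phase, filters are applied in a
single pass by FFT convolution on reflection-padded signals rather than
forward–backward: the designed magnitude response is preserved (no squaring)
and a 6 Hz sine shows zero cross-correlation lag through the chain. With the
50 Hz upper band edge, notch-vs-bandpass ordering is immaterial; the notch
runs last and is skipped when 60 Hz exceeds Nyquist.

## Spectral analysis

Welch PSDs use 4 s Hann windows with 50 % overlap (0.25 Hz bins at 250 Hz —
fine enough to resolve the 6 Hz bin and the 0.5 Hz band edge); signals must
cover at least two windows. Band powers integrate the PSD over half-open
bands [low, high), so the five bands partition 0.5–50 Hz exactly and sum to
the total. Regional power is the arithmetic mean of member channels; the
midline channels belong both to their lobe region and to the midline region.
The entrainment peak is the midline-averaged PSD at the bin nearest 6 Hz as
a stimulation/baseline ratio (1 = no entrainment); the original report does
not define its normalization, and a ratio makes the null case scale-free.
The alpha laterality index uses L = {Fp1, F7, F3}, R = {Fp2, F8, F4} — the
lateralized members of the prefrontal + frontal regions, midline excluded.

## Statistics

Two-sided tests throughout. Paired *t* on per-subject differences with
df = n−1; an all-zero difference vector returns t = 0, p = 1 (no evidence)
while a constant non-zero vector raises, since its statistic is undefined.
Cohen's d for paired designs is |mean|/SD of the differences, identically
|t|/√n. One-way ANOVA treats conditions as independent groups by default —
with k groups of 15 this reproduces the published df layouts (2, 42) and
(3, 56) despite the repeated-measures design — and a subject-blocked
repeated-measures variant is available behind `repeated=True`. The
channel × stimulation two-way ANOVA is the balanced fixed-effects
decomposition with subjects as within-cell replicates: effect dfs 18/1/18
and error df 19·2·(n−1) = 532 at n = 15 (the original error stratum is
unstated). η²ₚ = SS_effect/(SS_effect+SS_error) = F·df₁/(F·df₁+df₂).
Bonferroni families: 3 (session-1 pairwise post hocs), 6 (session-2
pairwise), 19 (per-channel topography), and the table width (5 bands /
7 regions / 8 mood factors) for the descriptive tables; raw and adjusted
p-values are always emitted side by side.

**Published-table audit.** For every published row (mean ± SD, t, p at
n = 15) the checker computes the interval of t statistics compatible with
two-decimal rounding of mean and SD and flags rows whose printed t falls
outside it; where a numeric p is printed it cross-checks p against the
printed t. Three of 91 rows fail: two (session-2 band table, BB/delta;
session-2 mood table, SHAM/happy) are printed-t typos — their printed p
matches the *recomputed* t — and one (session-2 band table, SHAM/gamma) has
a rounded mean (0.00) that cannot produce its printed t = −0.092 even though
t and p agree. One quoted Cohen's d (frontal bed-vs-combined contrast,
t = −3.704, printed d = 0.887) deviates from |t|/√15 = 0.956 by far more
than rounding; the package reports the formula value and flags the mismatch
rather than fitting the outlier.

## Mood scoring

The 32-item mood scale maps four descriptor ratings (0–4) to each of eight
factors (anger, tension, depression, vigor, fatigue, confusion, happy,
calmness), scored as plain sums (0–16). The true item→factor assignment is
in unavailable supplementary material, so the mapping is an explicit input
with a documented block default (items 1–4 → anger, …, 29–32 → calmness);
all scoring arithmetic is mapping-agnostic. The response simulator draws a
per-subject factor delta from the published per-condition mean ± SD and
distributes the rounded change across the factor's items within rating
bounds, so extreme draws saturate at the scale limits instead of escaping
them.

## Pipeline and selection rule

Session 1 emits the band-change, regional-theta, ANOVA + post hoc, and mood
tables, plus per-subject midline 6 Hz peak ratios. The selection rule —
condition winning the most per-subject peaks, mean calmness change breaking
ties, indeterminate when both tie — is a codified reconstruction of the
original informal choice ("best per-subject 6 Hz peak plus psychological
stability") and is labeled as such in the report output. Session 2 adds the
two-way ANOVA, per-channel pre/post-rest paired tests (Bonferroni over 19),
and the alpha laterality table. Identical seeds and configuration yield
byte-identical CSV output.

## Problem sizes

The study timings are 120 s baseline + 180 s stimulation (session 1) and
120/600/120 s (session 2) at 500 Hz, 19 channels, n = 15. Tests and the
analysis drivers run the same code on scaled epochs chosen as the smallest
sizes at which the 4 s Welch windows and the statistics remain well-posed:
32 s epochs on the three midline channels at 250 Hz for the 500-cohort power
calibration, 40/60/40 s with the full montage at 500 Hz for the 15-subject
recovery cohort, and 60/90 s (session 1) and 40/60/40 s (session 2) in the
drivers. Statistical calibrations use 10 000 null samples (type-I error),
500 two-way ANOVA replicates (null uniformity), and 200–500 simulated
cohorts (power).

## Known limitations

* The published absolute power values (e.g. 0.18 ± 0.20) have unstated
  units and spatial aggregation; only standardized effects and internal
  consistency are comparable, and the whole-head band table aggregates by
  the all-channel mean as a documented choice.
* EDF files can be read (via mne) but not written; the native on-disk format
  is a TSV matrix with a JSON sidecar.
* No artifact rejection, ICA, or bad-channel handling is implemented — the
  original analysis reports none, and the generator produces none.
* Human-subject outcomes (specific power changes, mood deltas) are not
  reproducible without the undeposited raw data; the pipeline demonstrates
  *recovery of known synthetic ground truth* and *internal consistency of
  the published statistics*, which is the strongest claim the available
  inputs support.
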