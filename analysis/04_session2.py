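"""Session-2 replication on a synthetic cohort: the selected mix vs controls.

Simulates 15 subjects under sham, beat-only, nature-sound-only, and the
combined stimulus, with the combined condition carrying the strongest
midline 6 Hz injection (partially persisting into the post-rest epoch) and
every active stimulus suppressing alpha.  Runs
the full session-2 battery: band/region change tables, the channel x
stimulation two-way ANOVA, per-channel pre/post tests with Bonferroni
correction over the 19 electrodes, the alpha laterality index, and mood
deltas.

Epochs are scaled to 40/60/40 s (the study used 120/600/120 s).
Writes results/session2/ (CSV tables + report.md).
"""

from pathlib import Path

from sleepbeat.pipeline import SessionConfig, run_session2
from sleepbeat.simulate import EpochSpec, session2_effects, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results" / "session2"
SEED = 7
TIMING = EpochSpec(baseline_s=40.0, stimulation_s=60.0, post_s=40.0)


def main() -> None:
    cohort = simulate_cohort(15, session2_effects(), timing=TIMING, seed=SEED)
    res = run_session2(cohort, SessionConfig.session2(
        timing=TIMING, seed=SEED, out_dir=str(RESULTS)))

    mid = res.region_theta_stats.query("region == 'Midline'")[
        ["condition", "mean", "statistic", "p_raw", "effect_size"]]
    print("midline theta change per condition:")
    print(mid.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    for cond in ("SHAM", "BB", "AT", "CS"):
        sig = res.channel_prepost.query(
            "condition == @cond and p_adj < 0.05")["channel"].tolist()
        print(f"{cond}: Bonferroni-significant pre/post electrodes: {sig or 'none'}")

    print("\ntwo-way ANOVA (channel x stimulation), stimulation effect:")
    stim = res.twoway_anova.query("source == 'stimulation'")[
        ["condition", "statistic", "df", "p_raw", "effect_size"]]
    print(stim.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    print("\nalpha laterality (pre vs post):")
    print(res.laterality[["condition", "li_pre_mean", "li_post_mean", "p_raw"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\ntables under {RESULTS}")


if __name__ == "__main__":
    main()
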