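"""Session-1 replication on a synthetic cohort: find the optimal mixing ratio.

Simulates 15 subjects under the three combined stimuli, with the 30:60
condition (CS2) carrying the strongest midline 6 Hz entrainment — the ground
truth the original session-1 data suggested — then runs the full analysis:
whole-head band-power changes, regional theta changes, across-condition
ANOVA with post hocs, mood-score deltas, and the per-subject midline 6 Hz
peak vote that selects the ratio for session 2.

Epoch durations are scaled to 60 s baseline / 90 s stimulation (the study
used 120/180 s) to keep the driver quick; the analysis is unchanged.

Writes results/session1/ (CSV tables + report.md).
"""

from pathlib import Path

from sleepbeat.pipeline import SessionConfig, run_session1
from sleepbeat.simulate import EpochSpec, session1_effects, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results" / "session1"
SEED = 7
TIMING = EpochSpec(baseline_s=60.0, stimulation_s=90.0)


def main() -> None:
    cohort = simulate_cohort(15, session1_effects(), timing=TIMING, seed=SEED)
    res = run_session1(cohort, SessionConfig.session1(
        timing=TIMING, seed=SEED, out_dir=str(RESULTS)))

    print(f"selected ratio: {res.selected} "
          f"(votes {res.votes.to_dict()}, indeterminate={res.indeterminate})")
    theta = res.band_stats.query("band == 'theta'")[
        ["condition", "mean", "sd", "statistic", "p_raw", "effect_size"]]
    print("\nwhole-head theta change per condition:")
    print(theta.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    mid = res.region_theta_stats.query("region == 'Midline'")[
        ["condition", "mean", "statistic", "p_raw", "effect_size"]]
    print("\nmidline theta change per condition:")
    print(mid.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\ntables under {RESULTS}")


if __name__ == "__main__":
    main()
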