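"""Two-session study orchestration on cohorts of recordings.

Session 1 compares three combined stimuli (CS1/CS2/CS3, decibel ratios
45:60 / 30:60 / 20:60) and selects the ratio whose midline 6 Hz entrainment
peak wins in the most subjects (calmness change breaking ties) — a codified
reconstruction of the original per-subject selection, and labeled as such in
the output.  Session 2 compares the selected stimulus against sham,
beat-only, and nature-sound-only conditions, adding per-channel pre/post
topography statistics, the channel x stimulation two-way ANOVA, and the alpha
laterality index.

Every emitted statistics row carries (statistic, df, raw p, Bonferroni-adjusted
p, effect size); nothing is silently dropped.  Given identical seeds and
configuration the output tables are byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import brums as brums_mod
from .montage import Montage, default_montage
from .preprocess import preprocess_chain
from .simulate import Cohort, EegRecording, EpochSpec, SESSION1_TIMING, SESSION2_TIMING
from .spectral import (BANDS, alpha_laterality, band_power_table, peak_at_6hz,
                       power_change, region_power_table)
from .stats import (StatResult, bonferroni, one_way_anova, paired_t,
                    two_way_anova)

__all__ = ["SessionConfig", "Session1Result", "Session2Result",
           "run_session1", "run_session2"]

SESSION1_CONDITIONS = ("CS1", "CS2", "CS3")
SESSION2_CONDITIONS = ("SHAM", "BB", "AT", "CS")


@dataclass(frozen=True)
class SessionConfig:
    """Which session to run, with timing, preprocessing, and output choices."""

    session: int = 1
    conditions: tuple[str, ...] = SESSION1_CONDITIONS
    timing: EpochSpec = SESSION1_TIMING
    target_fs: float = 250.0
    apply_preprocessing: bool = True
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def session1(cls, **kw) -> "SessionConfig":
        kw.setdefault("timing", SESSION1_TIMING)
        return cls(session=1, conditions=SESSION1_CONDITIONS, **kw)

    @classmethod
    def session2(cls, **kw) -> "SessionConfig":
        kw.setdefault("timing", SESSION2_TIMING)
        return cls(session=2, conditions=SESSION2_CONDITIONS, **kw)


def _stat_row(label_cols: dict, res: StatResult, p_adj: float) -> dict:
    row = dict(label_cols)
    row.update({
        "statistic": res.statistic, "df": "/".join(str(d) for d in res.df),
        "p_raw": res.p_value, "p_adj": p_adj,
        "effect_size": res.effect_size, "effect_size_name": res.effect_size_name,
    })
    return row


def _prepare(rec: EegRecording, config: SessionConfig) -> EegRecording:
    if config.apply_preprocessing:
        return preprocess_chain(rec, target_fs=config.target_fs)
    return rec


def _per_subject_tables(
    cohort: Cohort, config: SessionConfig, montage: Montage,
) -> list[dict[str, dict[str, pd.DataFrame]]]:
    """For each subject and condition: channel x band tables per epoch."""
    out = []
    for recs in cohort.subjects:
        subj = {}
        for cond in cohort.conditions:
            rec = _prepare(recs[cond], config)
            epochs = {"baseline": band_power_table(rec, "baseline"),
                      "stimulation": band_power_table(rec, "stimulation")}
            if "post" in rec.epochs:
                epochs["post"] = band_power_table(rec, "post")
            subj[cond] = epochs
        out.append(subj)
    return out


def _band_change_stats(tables, conditions, n_bands_family: int) -> pd.DataFrame:
    """Whole-head band-power change (stimulation - baseline), per condition."""
    rows = []
    for cond in conditions:
        diffs = {band: [] for band in BANDS}
        for subj in tables:
            ch = power_change(subj[cond]["stimulation"], subj[cond]["baseline"])
            head_mean = ch.mean(axis=0)  # average over all channels
            for band in BANDS:
                diffs[band].append(head_mean[band])
        for band in BANDS:
            d = np.array(diffs[band])
            res = paired_t(d)
            rows.append(_stat_row(
                {"condition": cond, "band": band, "mean": d.mean(), "sd": d.std(ddof=1)},
                res, float(bonferroni(res.p_value, n_bands_family)[0]),
            ))
    return pd.DataFrame(rows)


def _region_theta_changes(tables, conditions, montage) -> dict[str, dict[str, np.ndarray]]:
    """Per condition and region: the n-vector of subject theta changes."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for cond in conditions:
        per_region: dict[str, list[float]] = {r: [] for r in montage.regions}
        for subj in tables:
            ch = power_change(subj[cond]["stimulation"], subj[cond]["baseline"])
            reg = region_power_table(ch, montage)
            for r in montage.regions:
                per_region[r].append(float(reg.loc[r, "theta"]))
        out[cond] = {r: np.array(v) for r, v in per_region.items()}
    return out


def _region_theta_stats(changes, conditions, montage) -> pd.DataFrame:
    rows = []
    n_regions = len(montage.regions)
    for cond in conditions:
        for r in montage.regions:
            d = changes[cond][r]
            res = paired_t(d)
            rows.append(_stat_row(
                {"condition": cond, "region": r, "mean": d.mean(), "sd": d.std(ddof=1)},
                res, float(bonferroni(res.p_value, n_regions)[0]),
            ))
    return pd.DataFrame(rows)


def _region_anova_and_posthoc(changes, conditions, montage) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-condition one-way ANOVA per region, plus pairwise paired t post hocs."""
    pairs = list(itertools.combinations(conditions, 2))
    anova_rows, post_rows = [], []
    for r in montage.regions:
        groups = [changes[c][r] for c in conditions]
        res = one_way_anova(groups)
        anova_rows.append(_stat_row({"region": r}, res, res.p_value))
        for a, b in pairs:
            pres = paired_t(changes[a][r] - changes[b][r])
            post_rows.append(_stat_row(
                {"region": r, "contrast": f"{a} vs {b}"},
                pres, float(bonferroni(pres.p_value, len(pairs))[0]),
            ))
    return pd.DataFrame(anova_rows), pd.DataFrame(post_rows)


def _brums_stats(scores: pd.DataFrame, conditions) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition factor-change stats plus the per-subject delta table."""
    deltas = []
    for (subj, cond), grp in scores.groupby(["subject", "condition"], sort=False):
        pre = grp[grp.timepoint == "pre"].iloc[0]
        post = grp[grp.timepoint == "post"].iloc[0]
        row = {"subject": subj, "condition": cond}
        row.update({f: int(post[f] - pre[f]) for f in brums_mod.FACTORS})
        deltas.append(row)
    delta_df = pd.DataFrame(deltas)
    rows = []
    for cond in conditions:
        sub = delta_df[delta_df.condition == cond]
        for f in brums_mod.FACTORS:
            d = sub[f].to_numpy(float)
            res = paired_t(d)
            rows.append(_stat_row(
                {"condition": cond, "factor": f, "mean": d.mean(), "sd": d.std(ddof=1)},
                res, float(bonferroni(res.p_value, len(brums_mod.FACTORS))[0]),
            ))
    return pd.DataFrame(rows), delta_df


def _entrainment_peaks(cohort: Cohort, config: SessionConfig, montage: Montage) -> pd.DataFrame:
    rows = []
    for i, recs in enumerate(cohort.subjects):
        row = {"subject": f"sub{i + 1:02d}"}
        for cond in cohort.conditions:
            rec = _prepare(recs[cond], config)
            row[cond] = peak_at_6hz(rec, montage=montage)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def _select_condition(
    peaks: pd.DataFrame, brums_deltas: pd.DataFrame, conditions,
    rel_tol: float = 1e-9,
) -> tuple[str | None, pd.Series, bool]:
    """Condition winning the most per-subject 6 Hz peaks; calmness breaks ties."""
    votes = pd.Series(0, index=list(conditions))
    for _, row in peaks.iterrows():
        vals = row[list(conditions)].astype(float)
        best = vals.max()
        winners = vals[vals >= best * (1 - rel_tol)] if best > 0 else vals
        if len(winners) == 1:
            votes[winners.index[0]] += 1
    top = votes.max()
    leaders = votes[votes == top].index.tolist()
    if len(leaders) == 1:
        return leaders[0], votes, False
    calm = brums_deltas.groupby("condition")["calmness"].mean()
    calm = calm.reindex(leaders)
    if calm.notna().all() and calm.nunique() > 1:
        return calm.idxmax(), votes, False
    return None, votes, True


@dataclass(frozen=True)
class Session1Result:
    band_stats: pd.DataFrame
    region_theta_stats: pd.DataFrame
    region_anova: pd.DataFrame
    region_posthoc: pd.DataFrame
    brums_stats: pd.DataFrame
    brums_deltas: pd.DataFrame
    peaks: pd.DataFrame
    selected: str | None
    votes: pd.Series
    indeterminate: bool

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "band_stats": self.band_stats,
            "region_theta_stats": self.region_theta_stats,
            "region_anova": self.region_anova,
            "region_posthoc": self.region_posthoc,
            "brums_stats": self.brums_stats,
            "brums_deltas": self.brums_deltas,
            "peaks": self.peaks.reset_index(),
        }


@dataclass(frozen=True)
class Session2Result:
    band_stats: pd.DataFrame
    region_theta_stats: pd.DataFrame
    region_anova: pd.DataFrame
    region_posthoc: pd.DataFrame
    twoway_anova: pd.DataFrame
    channel_prepost: pd.DataFrame
    laterality: pd.DataFrame
    brums_stats: pd.DataFrame
    brums_deltas: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "band_stats": self.band_stats,
            "region_theta_stats": self.region_theta_stats,
            "region_anova": self.region_anova,
            "region_posthoc": self.region_posthoc,
            "twoway_anova": self.twoway_anova,
            "channel_prepost": self.channel_prepost,
            "laterality": self.laterality,
            "brums_stats": self.brums_stats,
            "brums_deltas": self.brums_deltas,
        }


def _write_tables(result, out_dir: str, header_note: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables().items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    lines = [header_note, ""]
    for name, df in result.tables().items():
        lines.append(f"## {name}\n")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))


def run_session1(
    cohort: Cohort,
    config: SessionConfig | None = None,
    responses: pd.DataFrame | None = None,
    montage: Montage | None = None,
) -> Session1Result:
    """Session-1 analysis: band/region change tables, mood deltas, and the
    combined-ratio selection (6 Hz midline peak vote, calmness tie-break).
    """
    config = config or SessionConfig.session1()
    montage = montage or default_montage()
    missing = [c for c in SESSION1_CONDITIONS if c not in cohort.conditions]
    if missing:
        raise ValueError(f"cohort missing session-1 conditions {missing}")
    if responses is None:
        responses = brums_mod.simulate_responses(
            {c: brums_mod.shifts_like_study(1)[c] for c in SESSION1_CONDITIONS},
            n=cohort.n, seed=config.seed,
        )
    tables = _per_subject_tables(cohort, config, montage)
    band_stats = _band_change_stats(tables, SESSION1_CONDITIONS, len(BANDS))
    changes = _region_theta_changes(tables, SESSION1_CONDITIONS, montage)
    region_stats = _region_theta_stats(changes, SESSION1_CONDITIONS, montage)
    anova, posthoc = _region_anova_and_posthoc(changes, SESSION1_CONDITIONS, montage)
    scores = brums_mod.score_sheet(responses)
    brums_stats, brums_deltas = _brums_stats(scores, SESSION1_CONDITIONS)
    peaks = _entrainment_peaks(cohort, config, montage)
    selected, votes, indet = _select_condition(peaks, brums_deltas, SESSION1_CONDITIONS)
    result = Session1Result(
        band_stats=band_stats, region_theta_stats=region_stats,
        region_anova=anova, region_posthoc=posthoc,
        brums_stats=brums_stats, brums_deltas=brums_deltas,
        peaks=peaks, selected=selected, votes=votes, indeterminate=indet,
    )
    if config.out_dir:
        note = (f"# Session 1 report\n\nSelected condition: {selected} "
                f"(reconstructed rule: per-subject midline 6 Hz peak vote, "
                f"calmness tie-break; indeterminate={indet})")
        _write_tables(result, config.out_dir, note)
    return result


def run_session2(
    cohort: Cohort,
    config: SessionConfig | None = None,
    responses: pd.DataFrame | None = None,
    montage: Montage | None = None,
) -> Session2Result:
    """Session-2 analysis: band/region tables, channel x stimulation two-way
    ANOVA, per-channel pre/post tests (Bonferroni over 19 channels), alpha
    laterality, and mood deltas.
    """
    config = config or SessionConfig.session2()
    montage = montage or default_montage()
    missing = [c for c in SESSION2_CONDITIONS if c not in cohort.conditions]
    if missing:
        raise ValueError(f"cohort missing session-2 conditions {missing}")
    if responses is None:
        responses = brums_mod.simulate_responses(
            {c: brums_mod.shifts_like_study(2)[c] for c in SESSION2_CONDITIONS},
            n=cohort.n, seed=config.seed,
        )
    tables = _per_subject_tables(cohort, config, montage)
    band_stats = _band_change_stats(tables, SESSION2_CONDITIONS, len(BANDS))
    changes = _region_theta_changes(tables, SESSION2_CONDITIONS, montage)
    region_stats = _region_theta_stats(changes, SESSION2_CONDITIONS, montage)
    anova, posthoc = _region_anova_and_posthoc(changes, SESSION2_CONDITIONS, montage)

    # Pre-vs-post resting topography: theta per channel, both phases
    n_ch = montage.n_channels
    twoway_rows, prepost_rows = [], []
    for cond in SESSION2_CONDITIONS:
        pre = np.stack([subj[cond]["baseline"]["theta"].to_numpy() for subj in tables], axis=1)
        post = np.stack([subj[cond]["post"]["theta"].to_numpy() for subj in tables], axis=1)
        cells = np.stack([pre, post], axis=1)  # channels x phase x subjects
        for source, res in two_way_anova(cells).items():
            twoway_rows.append(_stat_row({"condition": cond, "source": source},
                                         res, res.p_value))
        for ci, ch in enumerate(montage.channels):
            res = paired_t(post[ci] - pre[ci])
            prepost_rows.append(_stat_row(
                {"condition": cond, "channel": ch,
                 "mean": float((post[ci] - pre[ci]).mean())},
                res, float(bonferroni(res.p_value, n_ch)[0]),
            ))

    # Alpha laterality index, pre vs post rest
    li_rows = []
    for cond in SESSION2_CONDITIONS:
        li_pre = np.array([alpha_laterality(subj[cond]["baseline"]) for subj in tables])
        li_post = np.array([alpha_laterality(subj[cond]["post"]) for subj in tables])
        res = paired_t(li_post - li_pre)
        li_rows.append(_stat_row(
            {"condition": cond, "li_pre_mean": li_pre.mean(), "li_post_mean": li_post.mean()},
            res, res.p_value,
        ))

    scores = brums_mod.score_sheet(responses)
    brums_stats, brums_deltas = _brums_stats(scores, SESSION2_CONDITIONS)
    result = Session2Result(
        band_stats=band_stats, region_theta_stats=region_stats,
        region_anova=anova, region_posthoc=posthoc,
        twoway_anova=pd.DataFrame(twoway_rows),
        channel_prepost=pd.DataFrame(prepost_rows),
        laterality=pd.DataFrame(li_rows),
        brums_stats=brums_stats, brums_deltas=brums_deltas,
    )
    if config.out_dir:
        _write_tables(result, config.out_dir, "# Session 2 report")
    return result
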