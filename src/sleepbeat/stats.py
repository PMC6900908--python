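"""Statistical battery: paired t, paired Cohen's d, one- and two-way ANOVA,
partial eta squared, Bonferroni correction, and summary-table consistency
checks.

Conventions: two-sided tests throughout; Cohen's d for a paired design is the
magnitude of the mean within-subject difference over its SD, which equals
|t|/sqrt(n) exactly; partial eta squared is SS_effect/(SS_effect + SS_error),
recoverable from the F statistic as F*df1/(F*df1 + df2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult", "DegenerateSampleError",
    "paired_t", "cohens_d_paired", "one_way_anova", "partial_eta_squared",
    "two_way_anova", "bonferroni",
    "t_from_summary", "t_interval_from_rounded", "check_summary_consistency",
]


class DegenerateSampleError(ValueError):
    """Raised when a test statistic is undefined (zero variance, empty group)."""


@dataclass(frozen=True)
class StatResult:
    """Test statistic with df, two-sided p, and an effect size."""

    statistic: float
    df: tuple[int, ...]
    p_value: float
    effect_size: float
    effect_size_name: str
    correction: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _diffs(differences) -> np.ndarray:
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-D sample of n >= 2 differences")
    return d


def paired_t(differences) -> StatResult:
    """Paired t-test on per-subject differences.

    t = mean(d) / (sd(d)/sqrt(n)) with df = n-1 and a two-sided Student p.
    An all-zero sample carries no evidence and returns t = 0, p = 1; a
    constant nonzero sample has an undefined statistic and raises.
    """
    d = _diffs(differences)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult(0.0, (n - 1,), 1.0, 0.0, "cohens_d")
        raise DegenerateSampleError("zero variance with nonzero mean: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), df=n - 1))
    return StatResult(t, (n - 1,), p, abs(t) / np.sqrt(n), "cohens_d")


def paired_t_batch(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over the last axis: (t, two-sided p) per row.

    Same arithmetic as :func:`paired_t`; used by the calibration simulations.
    """
    d = np.asarray(diffs, float)
    n = d.shape[-1]
    sd = d.std(axis=-1, ddof=1)
    t = d.mean(axis=-1) / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    return t, p


def cohens_d_paired(differences) -> float:
    """|mean(d)| / sd(d); identically |t|/sqrt(n) for the paired t-test."""
    d = _diffs(differences)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0
        raise DegenerateSampleError("zero variance with nonzero mean: d undefined")
    return float(abs(d.mean()) / sd)


def partial_eta_squared(f_value: float, df1: int, df2: int) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2), in [0, 1)."""
    if f_value < 0:
        raise ValueError("F must be non-negative")
    return float(f_value * df1 / (f_value * df1 + df2))


def one_way_anova(groups, repeated: bool = False) -> StatResult:
    """One-way ANOVA across condition groups, with partial eta squared.

    By default conditions are treated as independent groups — with k groups of
    15 subjects this yields df = (k-1, 15k-k), the published layout — even
    though the design is repeated measures.  ``repeated=True`` instead fits
    the within-subject (subject-blocked) decomposition, assuming the i-th
    value of every group belongs to subject i.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise DegenerateSampleError("need >= 2 groups with >= 2 values each")
    if repeated:
        if len({g.size for g in gs}) != 1:
            raise ValueError("repeated-measures ANOVA needs equal group sizes")
        data = np.column_stack(gs)  # subjects x conditions
        n, k = data.shape
        grand = data.mean()
        ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((data - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        df1, df2 = k - 1, (k - 1) * (n - 1)
    else:
        all_vals = np.concatenate(gs)
        grand = all_vals.mean()
        ss_cond = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
        ss_err = sum(np.sum((g - g.mean()) ** 2) for g in gs)
        df1 = len(gs) - 1
        df2 = all_vals.size - len(gs)
    if ss_err == 0:
        if ss_cond == 0:
            return StatResult(0.0, (df1, df2), 1.0, 0.0, "partial_eta_sq")
        raise DegenerateSampleError("zero within-group variance: F undefined")
    f = float((ss_cond / df1) / (ss_err / df2))
    p = float(sps.f.sf(f, df1, df2))
    eta = float(ss_cond / (ss_cond + ss_err))
    return StatResult(f, (df1, df2), p, eta, "partial_eta_sq")


def two_way_anova(data: np.ndarray) -> dict[str, StatResult]:
    """Balanced two-factor fixed-effects ANOVA with replication.

    ``data`` has shape (levels_A, levels_B, n_replicates) — here 19 channels x
    2 stimulation phases x subjects, giving effect dfs (18, 1, 18).  Subjects
    are treated as replicates within cells; the error stratum is the pooled
    within-cell variance with df a*b*(n-1).
    """
    x = np.asarray(data, float)
    if x.ndim != 3:
        raise ValueError("data must be (levels_A, levels_B, n_replicates)")
    a, b, n = x.shape
    if n < 2:
        raise ValueError("need >= 2 replicates per cell")
    grand = x.mean()
    mean_a = x.mean(axis=(1, 2))
    mean_b = x.mean(axis=(0, 2))
    mean_ab = x.mean(axis=2)
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_err = np.sum((x - mean_ab[:, :, None]) ** 2)
    df_err = a * b * (n - 1)
    if ss_err == 0:
        raise DegenerateSampleError("zero within-cell variance: F undefined")
    ms_err = ss_err / df_err

    def result(ss: float, df1: int) -> StatResult:
        f = float((ss / df1) / ms_err)
        return StatResult(
            f, (df1, df_err), float(sps.f.sf(f, df1, df_err)),
            float(ss / (ss + ss_err)), "partial_eta_sq",
        )

    return {
        "channel": result(ss_a, a - 1),
        "stimulation": result(ss_b, b - 1),
        "interaction": result(ss_ab, (a - 1) * (b - 1)),
    }


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.atleast_1d(np.asarray(p_values, float))
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# Consistency of published summary tables (mean +/- SD vs printed t)

def t_from_summary(mean: float, sd: float, n: int) -> float:
    """t statistic implied by a reported mean and SD of paired differences."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return mean / (sd / np.sqrt(n))


def t_interval_from_rounded(mean: float, sd: float, n: int,
                            decimals: int = 2) -> tuple[float, float]:
    """Range of t statistics consistent with a mean and SD printed at
    ``decimals`` places: extremes of m/(s/sqrt(n)) over the rounding boxes.
    """
    half = 0.5 * 10.0 ** (-decimals)
    ts = [
        t_from_summary(m, max(s, 1e-12), n)
        for m in (mean - half, mean + half)
        for s in (sd - half, sd + half)
    ]
    return min(ts), max(ts)


def check_summary_consistency(table: pd.DataFrame, n: int = 15,
                              decimals: int = 2) -> pd.DataFrame:
    """Audit published rows of (mean, sd, t[, p]) against their own rounding.

    Adds: the recomputed point t, the t interval implied by rounding of mean
    and SD, ``consistent`` (printed t inside that interval), and — where a
    numeric printed p exists — ``p_of_printed_t`` and ``t_p_coherent``
    (printed p agrees with the printed t at printed precision).  A row that is
    inconsistent *and* incoherent points at a typo in the printed t itself.
    """
    out = table.copy()
    lo, hi, point = [], [], []
    for _, row in out.iterrows():
        a, b = t_interval_from_rounded(row["mean"], row["sd"], n, decimals)
        lo.append(a)
        hi.append(b)
        point.append(t_from_summary(row["mean"], max(row["sd"], 1e-12), n))
    out["t_recomputed"] = point
    out["t_lo"], out["t_hi"] = lo, hi
    out["consistent"] = (out["t"] >= out["t_lo"] - 1e-12) & (out["t"] <= out["t_hi"] + 1e-12)
    if "p" in out.columns:
        p_of_t = 2 * sps.t.sf(np.abs(out["t"]), df=n - 1)
        out["p_of_printed_t"] = p_of_t
        with np.errstate(invalid="ignore"):
            out["t_p_coherent"] = np.abs(p_of_t - out["p"]) <= 0.0015
        out.loc[out["p"].isna(), "t_p_coherent"] = True  # "<0.001" rows: not checkable
    return out
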