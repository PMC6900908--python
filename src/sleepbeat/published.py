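"""Published group-level summary statistics of the study this pipeline
replicates (n = 15 subjects throughout).

Four summary tables report, per condition, the mean +/- SD of within-subject
changes (stimulation minus baseline band power, or post minus pre mood score)
together with the paired t statistic and p-value.  These printed numbers are
*inputs* to the consistency analysis: the raw recordings were never deposited,
so the strongest reproducible check is whether each printed t is compatible
with its own printed mean and SD under two-decimal rounding.

``PAIRED_CONTRASTS`` and ``ANOVA_EFFECTS`` collect the test statistics quoted
in the results prose, used to verify the effect-size arithmetic
(d = |t|/sqrt(n); eta_p^2 = F*df1/(F*df1 + df2)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_SUBJECTS = 15

_BANDS = ["delta", "theta", "alpha", "beta", "gamma"]
_FACTORS = ["anger", "tension", "depression", "vigor",
            "fatigue", "confusion", "happy", "calmness"]


def _table(rows: dict[str, list[tuple]], measures: list[str],
           measure_name: str) -> pd.DataFrame:
    recs = []
    for cond, entries in rows.items():
        for meas, (mean, sd, t, p) in zip(measures, entries):
            recs.append({
                "condition": cond, measure_name: meas,
                "mean": mean, "sd": sd, "t": t, "p": p,
            })
    return pd.DataFrame(recs)


# Session 1: whole-head band-power change (stimulation - baseline) per combined
# stimulus; columns (mean, sd, t, p); p = NaN where printed only as "<0.001".
SESSION1_BAND = _table({
    "CS1": [(-0.10, 1.06, -0.370, 0.716), (0.12, 0.19, 2.432, 0.029),
            (0.07, 0.41, 0.714, 0.486), (0.03, 0.07, 1.518, 0.151),
            (0.01, 0.05, 0.896, 0.385)],
    "CS2": [(0.08, 0.66, 0.472, 0.643), (0.18, 0.20, 3.461, 0.003),
            (0.22, 0.82, 1.025, 0.322), (0.06, 0.23, 1.024, 0.322),
            (0.01, 0.19, 0.192, 0.849)],
    "CS3": [(-0.08, 0.96, -0.332, 0.744), (0.13, 0.15, 3.266, 0.005),
            (-0.01, 0.46, -0.079, 0.937), (0.03, 0.12, 0.8555, 0.406),
            (0.02, 0.10, 0.972, 0.347)],
}, _BANDS, "band")

# Session 1: mood-factor score change (post - pre) per combined stimulus.
SESSION1_BRUMS = _table({
    "CS1": [(-1.93, 1.91, -3.925, 0.001), (-2.67, 3.18, -3.250, 0.005),
            (-1.60, 1.55, -4.000, 0.001), (-2.13, 3.27, -2.526, 0.024),
            (-1.80, 3.90, -1.789, 0.095), (-2.20, 1.86, -4.582, np.nan),
            (-0.27, 2.71, -0.380, 0.709), (-1.00, 1.65, -2.350, 0.033)],
    "CS2": [(-2.87, 2.53, -4.385, np.nan), (-3.00, 2.42, -4.800, np.nan),
            (-1.87, 1.51, -4.802, np.nan), (-2.27, 2.66, -3.302, 0.005),
            (-1.53, 3.87, -1.534, 0.147), (-2.33, 1.76, -5.136, np.nan),
            (1.33, 2.09, 2.467, 0.027), (0.33, 1.72, 0.751, 0.464)],
    "CS3": [(-2.73, 2.66, -3.982, 0.001), (-3.00, 2.54, -4.582, np.nan),
            (-2.07, 2.09, -3.836, 0.002), (-1.87, 3.31, -2.181, 0.046),
            (-1.33, 3.81, -1.355, 0.196), (-1.67, 2.41, -2.678, 0.018),
            (0.73, 2.60, 1.090, 0.293), (0.93, 1.75, 2.064, 0.058)],
}, _FACTORS, "factor")

# Session 2: whole-head band-power change per condition (10 min stimulation).
SESSION2_BAND = _table({
    "SHAM": [(-0.05, 1.62, -0.131, 0.897), (0.07, 0.97, 0.286, 0.778),
             (-0.59, 1.06, -2.143, 0.051), (-0.05, 0.20, -1.005, 0.331),
             (0.00, 0.29, -0.092, 0.927)],
    "BB": [(0.25, 0.80, 1.888, 0.254), (0.40, 0.59, 2.603, 0.020),
           (-0.96, 0.86, -4.340, np.nan), (-0.02, 0.32, -0.246, 0.808),
           (0.13, 0.29, 1.672, 0.116)],
    "AT": [(0.01, 2.01, 0.017, 0.986), (0.28, 0.51, 2.093, 0.055),
           (-1.32, 0.96, -5.347, np.nan), (0.04, 0.20, 0.756, 0.461),
           (0.08, 0.23, 1.308, 0.211)],
    "CS": [(0.32, 1.30, 0.943, 0.361), (0.48, 0.74, 2.516, 0.024),
           (-1.39, 1.19, -4.539, np.nan), (-0.09, 0.10, -3.432, 0.004),
           (-0.02, 0.21, -0.318, 0.754)],
}, _BANDS, "band")

# Session 2: mood-factor score change per condition.
SESSION2_BRUMS = _table({
    "SHAM": [(0.73, 1.49, 1.910, 0.077), (0.53, 1.41, 1.467, 0.164),
             (-0.47, 1.30, -1.388, 0.187), (-3.33, 3.48, -3.712, 0.002),
             (2.73, 2.55, 4.153, 0.001), (0.53, 1.60, 1.292, 0.217),
             (-2.53, 2.61, -3.450, 0.002), (-0.73, 2.25, -1.261, 0.228)],
    "BB": [(1.40, 2.06, 2.627, 0.020), (-1.53, 3.60, -1.648, 0.122),
           (-0.80, 2.91, -1.065, 0.305), (-4.20, 3.41, -4.776, np.nan),
           (1.47, 2.77, 2.047, 0.060), (-1.13, 2.45, -1.794, 0.094),
           (-1.87, 3.38, -2.140, 0.051), (-1.40, 2.44, -2.218, 0.044)],
    "AT": [(-1.07, 2.69, -1.538, 0.146), (-1.93, 2.94, -2.547, 0.023),
           (-1.33, 2.66, -1.938, 0.073), (-4.27, 3.06, -5.403, np.nan),
           (1.67, 3.27, 1.976, 0.068), (-1.13, 1.92, -2.283, 0.039),
           (-0.20, 2.68, -0.289, 0.777), (1.07, 1.75, 2.359, 0.033)],
    "CS": [(-1.87, 1.64, -4.403, 0.001), (-2.00, 1.96, -3.944, 0.001),
           (-0.80, 1.82, -1.701, 0.111), (-1.80, 3.17, -2.201, 0.045),
           (1.67, 2.85, 2.268, 0.040), (-1.00, 2.24, -1.732, 0.105),
           (0.07, 2.28, 0.113, 0.912), (1.87, 2.75, 2.630, 0.020)],
}, _FACTORS, "factor")

SUMMARY_TABLES: dict[str, pd.DataFrame] = {
    "session1_band": SESSION1_BAND,
    "session1_brums": SESSION1_BRUMS,
    "session2_band": SESSION2_BAND,
    "session2_brums": SESSION2_BRUMS,
}

# Paired contrasts quoted in the results prose: (label, t, printed Cohen's d).
# The frontal AT-vs-CS contrast's printed d departs from |t|/sqrt(15) by far
# more than rounding; the consistency analysis flags it rather than fits it.
PAIRED_CONTRASTS: list[tuple[str, float, float]] = [
    ("s1 temporal CS1 vs CS2", 3.982, 1.028),
    ("s1 temporal CS1 vs CS3", 2.699, 0.697),
    ("s1 prefrontal CS1 vs CS2", -3.577, 0.923),
    ("s1 prefrontal CS1 vs CS3", -4.046, 1.044),
    ("s1 midline CS1 vs CS3", 2.565, 0.662),
    ("s1 midline CS2 vs CS3", 3.430, 0.885),
    ("s2 frontal AT vs CS", -3.704, 0.887),
    ("s2 midline SHAM vs CS", -2.415, 0.623),
    ("s2 midline BB vs CS", -2.635, 0.680),
    ("s2 midline AT vs CS", -2.417, 0.624),
    ("s2 calmness SHAM vs AT", -3.108, 0.802),
    ("s2 calmness BB vs AT", -5.819, 1.502),
    ("s2 calmness SHAM vs CS", -2.963, 0.765),
    ("s2 calmness BB vs CS", -2.988, 0.771),
    ("s2 tension SHAM vs BB", 2.251, 0.581),
    ("s2 tension SHAM vs AT", 2.921, 0.754),
    ("s2 tension SHAM vs CS", 4.598, 1.187),
]

# One-way ANOVA effects quoted in the prose: (label, F, df1, df2, printed eta_p^2).
ANOVA_EFFECTS: list[tuple[str, float, int, int, float]] = [
    ("s1 prefrontal theta", 5.85, 2, 42, 0.217),
    ("s1 temporal theta", 3.29, 2, 42, 0.135),
    ("s1 midline theta", 3.42, 2, 42, 0.140),
    ("s1 calmness", 5.05, 2, 42, 0.193),
    ("s2 frontal theta", 5.70, 3, 56, 0.234),
    ("s2 temporal theta", 3.61, 3, 56, 0.162),
    ("s2 parietal theta", 3.66, 3, 56, 0.163),
    ("s2 midline theta", 3.31, 3, 56, 0.150),
    ("s2 anger", 8.50, 3, 56, 0.312),
    ("s2 tension", 3.12, 3, 56, 0.143),
    ("s2 happy", 2.87, 3, 56, 0.133),
    ("s2 calmness", 6.43, 3, 56, 0.256),
]
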