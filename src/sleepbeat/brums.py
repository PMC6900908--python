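"""Scoring of the 32-item Brunel Mood Scale (BRUMS-32).

Eight mood factors — anger, tension, depression, vigor, fatigue, confusion,
happy, calmness — each aggregate four descriptors rated 0 ("not at all") to 4
("extremely"), so factor scores range 0-16.  The true item-to-factor
assignment lives in unavailable supplementary material; scoring therefore
takes an explicit mapping, with a documented default that assigns items in
labeled blocks of four (items 1-4 anger, ..., 29-32 calmness).  The scoring
arithmetic is identical under any balanced mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS", "N_ITEMS", "default_item_map", "BrumsResponse",
    "score_brums", "delta_scores", "read_responses", "score_sheet",
    "load_item_map", "simulate_responses",
]

FACTORS: tuple[str, ...] = (
    "anger", "tension", "depression", "vigor",
    "fatigue", "confusion", "happy", "calmness",
)
N_ITEMS = 32
_ITEM_COLS = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]


def default_item_map() -> dict[int, str]:
    """Block assignment: items 4k+1..4k+4 -> FACTORS[k]."""
    return {i: FACTORS[(i - 1) // 4] for i in range(1, N_ITEMS + 1)}


def _validate_map(mapping: dict[int, str]) -> None:
    if sorted(mapping) != list(range(1, N_ITEMS + 1)):
        raise ValueError("mapping must assign exactly items 1..32")
    counts: dict[str, int] = {}
    for f in mapping.values():
        counts[f] = counts.get(f, 0) + 1
    if set(counts) != set(FACTORS) or any(c != 4 for c in counts.values()):
        raise ValueError(f"mapping must give each of the 8 factors exactly 4 items, got {counts}")


@dataclass(frozen=True)
class BrumsResponse:
    """One completed answer sheet: 32 Likert ratings plus identifying labels."""

    ratings: tuple[int, ...]
    subject: str = ""
    condition: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if len(self.ratings) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} ratings, got {len(self.ratings)}")
        bad = [r for r in self.ratings if r not in (0, 1, 2, 3, 4)]
        if bad:
            raise ValueError(f"ratings must be integers 0-4, got {sorted(set(bad))}")


def score_brums(resp: BrumsResponse, mapping: dict[int, str] | None = None) -> dict[str, int]:
    """Factor scores: sum of each factor's four item ratings (0-16)."""
    mapping = mapping or default_item_map()
    _validate_map(mapping)
    scores = {f: 0 for f in FACTORS}
    for item, rating in enumerate(resp.ratings, start=1):
        scores[mapping[item]] += rating
    return scores


def delta_scores(post: dict[str, int], pre: dict[str, int]) -> dict[str, int]:
    """Per-factor post minus pre change, each in [-16, 16]."""
    if set(post) != set(pre):
        raise ValueError("pre and post factor sets differ")
    return {f: post[f] - pre[f] for f in post}


def read_responses(path) -> pd.DataFrame:
    """Read an answer-sheet CSV (subject, condition, timepoint, item_01..item_32)."""
    df = pd.read_csv(path)
    missing = [c for c in ["subject", "condition", "timepoint", *_ITEM_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"response file missing columns {missing}")
    return df


def score_sheet(df: pd.DataFrame, mapping: dict[int, str] | None = None) -> pd.DataFrame:
    """Score every row of a response table; returns labels + 8 factor columns."""
    out = []
    for _, row in df.iterrows():
        resp = BrumsResponse(
            ratings=tuple(int(row[c]) for c in _ITEM_COLS),
            subject=str(row["subject"]), condition=str(row["condition"]),
            timepoint=str(row["timepoint"]),
        )
        rec = {"subject": resp.subject, "condition": resp.condition,
               "timepoint": resp.timepoint}
        rec.update(score_brums(resp, mapping))
        out.append(rec)
    return pd.DataFrame(out)


def load_item_map(path) -> dict[int, str]:
    """Load a two-column (item, factor) mapping file (CSV/TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if not {"item", "factor"} <= set(df.columns):
        raise ValueError("mapping file needs 'item' and 'factor' columns")
    mapping = {int(r.item): str(r.factor) for r in df.itertuples()}
    _validate_map(mapping)
    return mapping


@dataclass(frozen=True)
class MoodShift:
    """Per-factor mean/SD (score points) of the post-pre change one condition induces."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def simulate_responses(
    conditions: dict[str, MoodShift],
    n: int,
    seed: int = 0,
    baseline_p: float | None = None,
) -> pd.DataFrame:
    """Synthetic pre/post answer sheets whose factor deltas follow the given shifts.

    Pre ratings are binomial(4, p) per item (p = 0.35 for negative-mood factors,
    0.5 for vigor/happy/calmness by default); the target factor delta is drawn
    normal(mean, sd), rounded, and distributed over the factor's four items
    within the 0-4 rating bounds, so extreme draws saturate rather than escape
    the scale.  Returns a long table in the answer-sheet CSV layout.
    """
    rng = np.random.default_rng(seed)
    mapping = default_item_map()
    factor_items = {f: [i for i, g in mapping.items() if g == f] for f in FACTORS}
    rows = []
    for s in range(n):
        subject = f"sub{s + 1:02d}"
        for cond, shift in conditions.items():
            pre = np.zeros(N_ITEMS + 1, dtype=int)  # 1-based
            for f in FACTORS:
                if baseline_p is not None:
                    p = baseline_p
                else:
                    p = 0.5 if f in ("vigor", "happy", "calmness") else 0.35
                for i in factor_items[f]:
                    pre[i] = rng.binomial(4, p)
            post = pre.copy()
            for f in FACTORS:
                target = int(round(rng.normal(shift.mean.get(f, 0.0), shift.sd.get(f, 1.0))))
                step = 1 if target > 0 else -1
                moved = 0
                stuck = 0
                while moved != target and stuck < 4:
                    items = rng.permutation(factor_items[f])
                    progressed = False
                    for i in items:
                        if moved == target:
                            break
                        if 0 <= post[i] + step <= 4:
                            post[i] += step
                            moved += step
                            progressed = True
                    stuck = 0 if progressed else stuck + 1
                    if not progressed:
                        break
            for tp, vals in (("pre", pre), ("post", post)):
                rec = {"subject": subject, "condition": cond, "timepoint": tp}
                rec.update({f"item_{i:02d}": int(vals[i]) for i in range(1, N_ITEMS + 1)})
                rows.append(rec)
    return pd.DataFrame(rows)


def shifts_like_study(session: int) -> dict[str, MoodShift]:
    """Mood-shift presets mirroring the published per-condition factor deltas."""
    from . import published

    table = published.SESSION1_BRUMS if session == 1 else published.SESSION2_BRUMS
    out = {}
    for cond, grp in table.groupby("condition", sort=False):
        out[cond] = MoodShift(
            mean=dict(zip(grp["factor"], grp["mean"])),
            sd=dict(zip(grp["factor"], grp["sd"])),
        )
    return out
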