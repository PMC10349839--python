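"""Behavioral preprocessing and signal-detection sensitivity.

Trials are rows of a tidy table with columns ``participant_id, group,
condition, trial_type, response, rt_ms`` (a ``correct`` column is derived:
response equals trial type).  "Same" responses on same trials are hits;
"same" responses on different trials are false alarms.

Sensitivity uses the loglinear-corrected d':

    d' = Phi^-1((hits + 0.5) / (hits + misses + 1))
       - Phi^-1((false_alarms + 0.5) / (false_alarms + correct_rejections + 1))

which is finite for any counts, including perfect performance.

RT preprocessing excludes, per participant, trials with RT more than 3 SD
*above* that participant's grand mean (one-sided trim).  The quintile
analysis sorts each participant x condition cell's trials from fastest to
slowest separately per trial type and forms five bins -- bin 1 holds the
fastest 20% of same trials plus the fastest 20% of different trials, and
so on -- then computes d' and mean RT within each bin.  When a trial
type's count is not divisible by five, the earlier (faster) bins receive
the extra trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "condition",
    "trial_type",
    "response",
    "rt_ms",
)
N_BINS = 5
RT_TRIM_SD = 3.0


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    group: str  # expert | novice
    condition: str  # full | central | peripheral
    trial_type: str  # same | different
    response: str  # same | different
    rt_ms: float

    @property
    def correct(self) -> bool:
        return self.response == self.trial_type


def trials_frame(trials) -> pd.DataFrame:
    """Normalize records/DataFrame to the tidy layout and derive ``correct``."""
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame([t.__dict__ for t in trials])
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    df["correct"] = df["response"] == df["trial_type"]
    return df


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_trials(cls, trials) -> "ConfusionCounts":
        df = trials_frame(trials)
        same = df["trial_type"] == "same"
        said_same = df["response"] == "same"
        return cls(
            hits=int((same & said_same).sum()),
            misses=int((same & ~said_same).sum()),
            false_alarms=int((~same & said_same).sum()),
            correct_rejections=int((~same & ~said_same).sum()),
        )


def dprime(c: ConfusionCounts) -> float:
    """Loglinear-corrected sensitivity; always finite."""
    n_same = c.hits + c.misses
    n_diff = c.false_alarms + c.correct_rejections
    if n_same < 1 or n_diff < 1:
        raise ValueError("need at least one same trial and one different trial")
    hit_rate = (c.hits + 0.5) / (n_same + 1)
    fa_rate = (c.false_alarms + 0.5) / (n_diff + 1)
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def criterion(c: ConfusionCounts) -> float:
    """Response bias c = -(Z(hit rate)+Z(fa rate))/2, with the same loglinear
    correction.  Exposed as a utility; not part of the core analyses."""
    hit_rate = (c.hits + 0.5) / (c.hits + c.misses + 1)
    fa_rate = (c.false_alarms + 0.5) / (c.false_alarms + c.correct_rejections + 1)
    return float(-(norm.ppf(hit_rate) + norm.ppf(fa_rate)) / 2.0)


def trim_rt(
    trials, n_sd: float = RT_TRIM_SD
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """One-sided per-participant RT trim.

    Returns (kept, excluded, excluded_fraction).  The cut-off is each
    participant's grand mean + ``n_sd`` * SD over all of their trials;
    only trials strictly above it are excluded, so slow outliers go but
    fast ones stay.  Zero-variance participants lose nothing.
    """
    df = trials_frame(trials)
    counts = df.groupby("participant_id")["rt_ms"].size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"participants with fewer than 2 trials: {bad}")
    stats = df.groupby("participant_id")["rt_ms"].agg(["mean", "std"])
    cut = (stats["mean"] + n_sd * stats["std"]).reindex(df["participant_id"]).to_numpy()
    keep = df["rt_ms"].to_numpy() <= cut
    kept = df[keep].reset_index(drop=True)
    excluded = df[~keep].reset_index(drop=True)
    frac = float(len(excluded) / len(df)) if len(df) else 0.0
    return kept, excluded, frac


def _bin_sizes(n: int, n_bins: int = N_BINS) -> list[int]:
    """As-equal-as-possible partition of n ranks; earlier bins get extras."""
    base, rem = divmod(n, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def quintile_bins(trials, n_bins: int = N_BINS) -> pd.DataFrame:
    """RT-quintile sensitivity for one participant x condition cell.

    Input: that cell's (trimmed) trials, both correct and incorrect.
    Within each trial type, trials are stable-sorted by (rt, original
    order) and partitioned into ``n_bins`` rank bins; bin b pools its same
    and different trials into a confusion matrix.  Returns one row per bin:
    ``bin`` (1-based), ``mean_rt_ms``, ``dprime``, per-type counts.
    """
    df = trials_frame(trials).reset_index(drop=True)
    if df["participant_id"].nunique() > 1 or df["condition"].nunique() > 1:
        raise ValueError("quintile_bins expects one participant x condition cell")
    for tt in ("same", "different"):
        n = int((df["trial_type"] == tt).sum())
        if n < n_bins:
            pid = df["participant_id"].iloc[0] if len(df) else "?"
            cond = df["condition"].iloc[0] if len(df) else "?"
            raise ValueError(
                f"cell (participant={pid}, condition={cond}) has only {n} "
                f"{tt!r} trials; need at least {n_bins}"
            )
    df["_bin"] = 0
    for tt in ("same", "different"):
        sub = df[df["trial_type"] == tt]
        order = sub.sort_values("rt_ms", kind="stable").index  # ties: input order
        sizes = _bin_sizes(len(order), n_bins)
        start = 0
        for b, size in enumerate(sizes, start=1):
            df.loc[order[start : start + size], "_bin"] = b
            start += size
    rows = []
    for b in range(1, n_bins + 1):
        sub = df[df["_bin"] == b]
        counts = ConfusionCounts.from_trials(sub)
        rows.append(
            dict(
                participant_id=df["participant_id"].iloc[0],
                condition=df["condition"].iloc[0],
                bin=b,
                mean_rt_ms=float(sub["rt_ms"].mean()),
                dprime=dprime(counts),
                n_same=counts.hits + counts.misses,
                n_different=counts.false_alarms + counts.correct_rejections,
            )
        )
    return pd.DataFrame(rows)


def sensitivity_table(
    trials, per_bin: bool = False, n_bins: int = N_BINS
) -> pd.DataFrame:
    """Per participant x condition d' and mean correct RT (optionally x bin).

    Input should already be RT-trimmed.  d' uses all trials of the cell;
    mean RT uses correct trials only.  Cells empty of a trial type are kept
    as flagged rows (``flag='empty_cell'``, NaN statistics) rather than
    silently dropped.
    """
    df = trials_frame(trials)
    rows = []
    for (pid, grp, cond), sub in df.groupby(
        ["participant_id", "group", "condition"], sort=True
    ):
        base = dict(participant_id=pid, group=grp, condition=cond)
        counts = ConfusionCounts.from_trials(sub)
        if counts.hits + counts.misses == 0 or (
            counts.false_alarms + counts.correct_rejections == 0
        ):
            rows.append(dict(**base, dprime=np.nan, mean_rt_correct_ms=np.nan,
                             flag="empty_cell"))
            continue
        correct_rts = sub.loc[sub["correct"], "rt_ms"]
        base_row = dict(
            **base,
            dprime=dprime(counts),
            mean_rt_correct_ms=float(correct_rts.mean()) if len(correct_rts) else np.nan,
            flag="",
        )
        if not per_bin:
            rows.append(base_row)
        else:
            bins = quintile_bins(sub, n_bins=n_bins)
            for r in bins.itertuples(index=False):
                rows.append(
                    dict(
                        **base,
                        bin=r.bin,
                        dprime=r.dprime,
                        mean_rt_ms=r.mean_rt_ms,
                        flag="",
                    )
                )
    return pd.DataFrame(rows)
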