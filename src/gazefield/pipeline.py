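"""End-to-end analysis stages tying the modules into one pipeline.

Each stage is a pure function of (inputs, config, seed).  The flow mirrors
the experiment's analysis: detect oculomotor events in the study-phase
gaze traces, attribute fixations to bird ROIs, summarize looking-time
proportions and their 100-ms time course, then trim RTs, compute d' per
participant x condition (and per RT-quintile bin), and run the split-plot
ANOVAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import EventParams, detect_events
from .roi import (
    DEFAULT_N_WINDOWS,
    DEFAULT_WINDOW_MS,
    ROI_LABELS,
    proportion_looking,
    time_course,
)
from .sdt import sensitivity_table, trim_rt
from .simulate import SimulatedCohort
from .stats import AnovaResult, mixed_anova


def participant_looking(
    cohort: SimulatedCohort,
    participant_id: str,
    params: EventParams | None = None,
) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """Pooled ROI looking-time proportions for one participant's study
    phase, plus the on-bird-time-weighted window time course.

    Returns (proportions indexed by ROI label, time-course proportions
    array (n_windows, 5), per-window on-bird ms).
    """
    params = params or EventParams()
    dur = {label: 0.0 for label in ROI_LABELS}
    tc_acc = np.zeros((DEFAULT_N_WINDOWS, len(ROI_LABELS)))
    for trial, trace in cohort.iter_study_traces(participant_id):
        m = cohort.roimaps[trial.study_image_id]
        _, fixations = detect_events(trace.samples, params, cohort.cfg)
        summary = proportion_looking(fixations, m)
        if summary.total_on_bird_ms > 0:
            for label in ROI_LABELS:
                dur[label] += summary.proportions[label] * summary.total_on_bird_ms
        tc = time_course(fixations, m, DEFAULT_WINDOW_MS, DEFAULT_N_WINDOWS)
        filled = np.where(np.isnan(tc.values), 0.0, tc.values)
        tc_acc += filled * tc.on_bird_ms[:, None]
    total = sum(dur.values())
    props = pd.Series(
        {k: (dur[k] / total if total > 0 else np.nan) for k in ROI_LABELS}
    )
    on_bird = tc_acc.sum(axis=1)
    tc_props = np.full_like(tc_acc, np.nan)
    ok = on_bird > 0
    tc_props[ok] = tc_acc[ok] / on_bird[ok, None]
    return props, tc_props, on_bird


def cohort_looking(
    cohort: SimulatedCohort, params: EventParams | None = None
) -> pd.DataFrame:
    """Tidy per-participant ROI proportions (one row per participant x ROI)."""
    rows = []
    for row in cohort.participants.itertuples(index=False):
        props, _, _ = participant_looking(cohort, row.participant_id, params)
        for label in ROI_LABELS:
            rows.append(
                dict(
                    participant_id=row.participant_id,
                    group=row.group,
                    roi=label,
                    proportion=props[label],
                )
            )
    return pd.DataFrame(rows)


def behavior_analysis(
    trials: pd.DataFrame, rt_trim_sd: float = 3.0, n_bins: int = 5
) -> dict:
    """Trim RTs, build the d'/RT tables and run the group x condition and
    group x condition x bin ANOVAs.  Returns a dict of tidy tables and
    :class:`AnovaResult` objects."""
    kept, excluded, frac = trim_rt(trials, n_sd=rt_trim_sd)
    dtable = sensitivity_table(kept)
    btable = sensitivity_table(kept, per_bin=True, n_bins=n_bins)
    anova_d = mixed_anova(
        dtable, dv="dprime", between="group", within="condition",
        subject="participant_id",
    )
    anova_rt = mixed_anova(
        dtable.dropna(subset=["mean_rt_correct_ms"]),
        dv="mean_rt_correct_ms", between="group", within="condition",
        subject="participant_id",
    )
    anova_bins = mixed_anova(
        btable, dv="dprime", between="group", within=["condition", "bin"],
        subject="participant_id",
    )
    return dict(
        trials_kept=kept,
        trials_excluded=excluded,
        excluded_fraction=frac,
        dprime_table=dtable,
        bin_table=btable,
        anova_dprime=anova_d,
        anova_rt=anova_rt,
        anova_bins=anova_bins,
    )


def roi_anova(looking: pd.DataFrame) -> AnovaResult:
    """2 x 5 mixed ANOVA (group x ROI) on the looking-time proportions."""
    return mixed_anova(
        looking, dv="proportion", between="group", within="roi",
        subject="participant_id",
    )
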