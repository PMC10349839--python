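"""Signal-detection sensitivity and the RT-quintile distribution analysis.

Simulates a small expert/novice cohort, trims slow outliers (3 SD above
each participant's grand mean), computes loglinear-corrected d' per
participant x viewing condition, and splits each cell into five RT bins.
"""

from gazefield.sdt import sensitivity_table, trim_rt
from gazefield.simulate import simulate_cohort

cohort = simulate_cohort(n_experts=3, n_novices=3, master_seed=12)
kept, excluded, frac = trim_rt(cohort.trial_records)
print(f"RT trimming excluded {len(excluded)} of {len(cohort.trial_records)} trials "
      f"({frac:.2%})")

table = sensitivity_table(kept)
print("\nmean d' by group and viewing condition:")
print(table.groupby(["group", "condition"])["dprime"].mean().round(2).unstack())

bins = sensitivity_table(kept, per_bin=True)
print("\nmean d' by group, condition and RT-quintile bin:")
summary = bins.groupby(["group", "condition", "bin"])["dprime"].mean().round(2)
print(summary.unstack("bin"))
# Experts hold their sensitivity in the peripheral view while novices fall
# toward chance there: the wider perceptual field lets the expert observer
# keep accruing evidence from features away from fixation.
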