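"""Inferential statistics: Welch's t from summaries, power, split-plot ANOVA.

Reproduces the two desk-scale computations (Welch's t-test from printed
group summaries; the minimal detectable effect size of the design) and runs
the 2 x 3 mixed ANOVA with generalized eta squared on a simulated cohort's
d' table.
"""

from gazefield import SummaryGroup, min_detectable_d, welch_t
from gazefield.pipeline import behavior_analysis
from gazefield.simulate import simulate_cohort
from gazefield.stats import generalized_eta_sq

res = welch_t(SummaryGroup(1.86, 0.14, 14), SummaryGroup(0.87, 0.09, 15))
print(f"Welch's t from group summaries: t({res.df:.2f}) = {res.t:.2f}, p = {res.p:.2g}")

d = min_detectable_d(n_per_group=15, alpha=0.05, power=0.80)
print(f"minimal detectable Cohen's d (n=15/group, alpha=.05, power=.80): {d:.2f}")

cohort = simulate_cohort(n_experts=6, n_novices=6, master_seed=8)
analysis = behavior_analysis(cohort.trial_records)
anova = analysis["anova_dprime"]
print("\n2 x 3 mixed ANOVA on d' (group x viewing condition):")
print(anova)
ges = generalized_eta_sq(anova, "group")
print(f"\ngeneralized eta^2 for the group effect: {ges:.2f}")
# The between-subjects group effect is tested against subjects-within-group,
# the within-subject condition effect against condition x subjects; eta^2_G
# relates each effect's SS to all subject-variance and error strata.
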