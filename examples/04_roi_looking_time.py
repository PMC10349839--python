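"""ROI looking-time proportions and their 100-ms time course.

Runs the study-phase analysis for two simulated participants: detect
fixations, attribute them to the five bird ROIs, compute each participant's
overall proportions and windowed time course, and correlate the two
participants' head-ROI trajectories.
"""

import numpy as np

from gazefield.pipeline import participant_looking
from gazefield.roi import ROI_LABELS, TimeCourse, timecourse_correlation
from gazefield.simulate import simulate_cohort

cohort = simulate_cohort(n_experts=2, n_novices=2, master_seed=4)
pids = list(cohort.participants["participant_id"][:2])

courses = {}
for pid in pids:
    props, tc_values, on_bird = participant_looking(cohort, pid)
    courses[pid] = TimeCourse(window_ms=100, values=tc_values, on_bird_ms=on_bird)
    shares = ", ".join(f"{l} {props[l]:.1%}" for l in ROI_LABELS)
    print(f"{pid}: {shares}")

ramp = courses[pids[0]].on_bird_ms[:5] / courses[pids[0]].on_bird_ms.max()
print("\non-bird coverage over the first five 100-ms windows:",
      np.round(ramp, 2))
# Every trial starts on the off-bird trigger dot, so early windows have
# little on-bird time; coverage ramps up as gaze lands on the bird.

r = timecourse_correlation(courses[pids[0]], courses[pids[1]], "head")
print(f"\nhead-ROI time-course correlation between {pids[0]} and {pids[1]}: r = {r:.3f}")
# The simulator draws every fixation target from the same stationary
# distribution, so each head trajectory is flat at ~44% plus window noise
# and the cross-observer correlation is weak.  Human viewing has strong
# shared temporal structure (an initial head bias that relaxes over the
# trial), which is what drives high cross-group correlations in real data;
# the stationary generator deliberately trades that structure for an exact,
# recoverable overall ROI distribution.
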