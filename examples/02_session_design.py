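"""Stimulus catalog and randomized session structure.

Builds the 288-image catalog (warbler/finch/sparrow/woodpecker species x 12
exemplars) and one seeded 144-trial session, then verifies its counting
structure: 48 trials per viewing condition, each 24 same + 24 different,
with no image shown twice.
"""

from collections import Counter

from gazefield import build_catalog, generate_session

catalog = build_catalog()
print(f"catalog: {len(catalog.species)} species, {catalog.n_images} experimental "
      f"images, {len(catalog.practice_image_ids)} practice-only images")

plan = generate_session(catalog, seed=2024, participant_id="demo")
plan.validate()

cells = Counter((t.condition, t.trial_type) for t in plan.trials)
print(f"session: {len(plan.trials)} experimental + {len(plan.practice)} practice trials")
for (cond, tt), n in sorted(cells.items()):
    print(f"  {cond:>10} / {tt:<9} {n} trials")

used = {t.study_image_id for t in plan.trials} | {t.test_image_id for t in plan.trials}
print(f"distinct images used: {len(used)} (the full catalog, none repeated)")

triggers = Counter(t.trigger_position for t in plan.trials)
print("trigger positions:", dict(sorted(triggers.items())))
# Each trial's obligatory fixation dot appears on a uniformly random side,
# so the first fixation is always off the bird when it appears.
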