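"""Stimulus catalog and randomized session plans for the same/different task.

The catalog holds four bird families (warbler and finch with 8 species each,
sparrow and woodpecker with 4 each), every species represented by 12
exemplar images: 288 experimental images in total.  A session consists of
144 experimental trials -- 48 per viewing condition (full, central,
peripheral), each split into 24 *same* trials (two exemplars of one
species) and 24 *different* trials (one exemplar each of two species from
the same family) -- plus 6 practice trials.  No image is shown twice in a
session, which makes the image budget exactly tight: 144 trials x 2 images
consume all 288 experimental images, so practice trials draw from a small
practice-only reserve (12 images by default) that is never used in the
experimental phase.

Image exhaustion works out because each species contributes 3 same trials
(6 exemplars) and 6 different-trial slots (6 exemplars).  Within a family
the different-trial pairing is a round-robin schedule, so every species is
paired evenly with its family members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

DEFAULT_FAMILIES: dict[str, int] = {
    "warbler": 8,
    "finch": 8,
    "sparrow": 4,
    "woodpecker": 4,
}
EXEMPLARS_PER_SPECIES = 12
TRIAL_TYPES = ("same", "different")
TRIGGER_POSITIONS = ("left", "right", "above", "below")
STUDY_DURATION_MS = 3000
N_PRACTICE_TRIALS = 6


class InfeasibleDesignError(ValueError):
    """Raised when a catalog cannot satisfy the session's counting constraints."""


@dataclass(frozen=True)
class StimulusCatalog:
    """families: family -> list of species names; exemplars: species -> image ids.

    ``practice_species`` is a disjoint reserve (pseudo-family "practice")
    used only for practice trials.
    """

    families: dict[str, list[str]]
    exemplars: dict[str, list[str]]
    practice_species: dict[str, list[str]]

    @property
    def species(self) -> list[str]:
        return [s for specs in self.families.values() for s in specs]

    @property
    def image_ids(self) -> list[str]:
        return [img for s in self.species for img in self.exemplars[s]]

    @property
    def practice_image_ids(self) -> list[str]:
        return [img for imgs in self.practice_species.values() for img in imgs]

    @property
    def n_images(self) -> int:
        return len(self.image_ids)


def build_catalog(
    families: Mapping[str, int] = DEFAULT_FAMILIES,
    exemplars_per_species: int = EXEMPLARS_PER_SPECIES,
    practice_reserve: int = 12,
) -> StimulusCatalog:
    """Build a catalog of synthetic image identifiers with the given structure.

    ``practice_reserve`` extra images (default 12, organised as 4 practice
    species x 3 exemplars) are flagged non-experimental so the 6 practice
    trials never reuse experimental images.
    """
    if not families:
        raise ValueError("families must be non-empty")
    if any(n <= 0 for n in families.values()) or exemplars_per_species <= 0:
        raise ValueError("species and exemplar counts must be positive")
    fam_species: dict[str, list[str]] = {}
    seen: set[str] = set()
    for fam, n_species in families.items():
        names = [f"{fam}{i:02d}" for i in range(1, n_species + 1)]
        for s in names:
            if s in seen:
                raise ValueError(f"duplicate species name {s!r}")
            seen.add(s)
        fam_species[fam] = names
    exemplars = {
        s: [f"{s}_ex{j:02d}" for j in range(1, exemplars_per_species + 1)]
        for names in fam_species.values()
        for s in names
    }
    if practice_reserve % 3 != 0 or practice_reserve < 0:
        raise ValueError("practice_reserve must be a non-negative multiple of 3")
    n_prac_species = practice_reserve // 3
    practice = {
        f"practice{i:02d}": [f"practice{i:02d}_ex{j:02d}" for j in range(1, 4)]
        for i in range(1, n_prac_species + 1)
    }
    return StimulusCatalog(
        families=fam_species, exemplars=exemplars, practice_species=practice
    )


@dataclass(frozen=True)
class TrialSpec:
    index: int
    trial_type: str  # same | different
    condition: str  # full | central | peripheral
    study_image_id: str
    test_image_id: str
    trigger_position: str  # left | right | above | below
    study_duration_ms: int = STUDY_DURATION_MS

    def __post_init__(self) -> None:
        if self.study_image_id == self.test_image_id:
            raise ValueError("study and test images must differ")


@dataclass(frozen=True)
class SessionPlan:
    participant_id: str
    trials: tuple[TrialSpec, ...]
    practice: tuple[TrialSpec, ...]
    seed: int

    def validate(self) -> None:
        """Assert the session's counting invariants; raises AssertionError."""
        from collections import Counter

        assert len(self.trials) == 144, len(self.trials)
        combos = Counter((t.condition, t.trial_type) for t in self.trials)
        for cond in ("full", "central", "peripheral"):
            for tt in TRIAL_TYPES:
                assert combos[(cond, tt)] == 24, (cond, tt, combos[(cond, tt)])
        used = [t.study_image_id for t in self.trials + self.practice]
        used += [t.test_image_id for t in self.trials + self.practice]
        assert len(used) == len(set(used)), "an image id is repeated in the session"


def _round_robin_rounds(species: Sequence[str]) -> list[list[tuple[str, str]]]:
    """Circle-method round robin: for an even number k of species, k-1 rounds
    of perfect matchings covering every pair exactly once."""
    s = list(species)
    k = len(s)
    assert k % 2 == 0
    rounds = []
    rotating = s[1:]
    for _ in range(k - 1):
        order = [s[0]] + rotating
        rounds.append([(order[i], order[k - 1 - i]) for i in range(k // 2)])
        rotating = rotating[-1:] + rotating[:-1]
    return rounds


def generate_session(
    catalog: StimulusCatalog,
    seed: int,
    participant_id: str = "p01",
) -> SessionPlan:
    """Generate one randomized 144-trial session (plus 6 practice trials).

    The same seed always yields the identical plan.  Trigger positions are
    drawn uniformly from left/right/above/below.  Raises
    :class:`InfeasibleDesignError` naming the violated constraint when the
    catalog cannot support the design.
    """
    rng = np.random.default_rng(seed)
    e = len(next(iter(catalog.exemplars.values()), []))
    if any(len(v) != e for v in catalog.exemplars.values()):
        raise InfeasibleDesignError("all species must have equal exemplar counts")
    if e < 4 or e % 4 != 0:
        raise InfeasibleDesignError(
            "exemplars per species must be a positive multiple of 4 "
            "(2*same_trials + different_slots = exemplars)"
        )
    n_same_per_species = e // 4
    n_diff_slots = e - 2 * n_same_per_species  # = e/2 per species
    for fam, specs in catalog.families.items():
        if len(specs) < 2 or len(specs) % 2 != 0:
            raise InfeasibleDesignError(
                f"family {fam!r} needs an even number (>=2) of species for "
                "round-robin different-trial pairing"
            )

    # --- exemplar budgets: shuffle each species' images, reserve 2 per same
    # trial and 1 per different slot.
    same_pool: dict[str, list[str]] = {}
    diff_pool: dict[str, list[str]] = {}
    for s in catalog.species:
        imgs = list(catalog.exemplars[s])
        rng.shuffle(imgs)
        same_pool[s] = imgs[: 2 * n_same_per_species]
        diff_pool[s] = imgs[2 * n_same_per_species :]

    # --- same trials: n_same_per_species exemplar pairs per species.
    same_pairs: list[tuple[str, str]] = []
    for s in catalog.species:
        pool = same_pool[s]
        for i in range(n_same_per_species):
            same_pairs.append((pool[2 * i], pool[2 * i + 1]))

    # --- different trials: round-robin species pairs within family, each
    # species used in exactly n_diff_slots pairings.
    diff_pairs: list[tuple[str, str]] = []
    for fam, specs in catalog.families.items():
        rounds = _round_robin_rounds(specs)
        if n_diff_slots > len(rounds):
            # reuse rounds cyclically (pairs repeat, images never do)
            rounds = [rounds[i % len(rounds)] for i in range(n_diff_slots)]
        else:
            rounds = rounds[:n_diff_slots]
        for rnd in rounds:
            for a, b in rnd:
                diff_pairs.append((diff_pool[a].pop(), diff_pool[b].pop()))

    n_conditions = 3
    if len(same_pairs) % n_conditions or len(diff_pairs) % n_conditions:
        raise InfeasibleDesignError(
            "same/different trial counts must divide evenly across the three "
            f"viewing conditions (got {len(same_pairs)} same, {len(diff_pairs)} different)"
        )

    trials: list[dict] = []
    for trial_type, pairs in (("same", same_pairs), ("different", diff_pairs)):
        pairs = list(pairs)
        rng.shuffle(pairs)
        per_cond = len(pairs) // n_conditions
        for ci, cond in enumerate(("full", "central", "peripheral")):
            for study, test in pairs[ci * per_cond : (ci + 1) * per_cond]:
                if rng.random() < 0.5:  # either exemplar may serve as study
                    study, test = test, study
                trials.append(
                    dict(
                        trial_type=trial_type,
                        condition=cond,
                        study_image_id=study,
                        test_image_id=test,
                    )
                )
    order = rng.permutation(len(trials))
    triggers = rng.choice(TRIGGER_POSITIONS, size=len(trials))
    trial_specs = tuple(
        TrialSpec(index=i, trigger_position=str(triggers[i]), **trials[j])
        for i, j in enumerate(order)
    )

    practice_specs = _practice_trials(catalog, rng)
    plan = SessionPlan(
        participant_id=participant_id,
        trials=trial_specs,
        practice=practice_specs,
        seed=int(seed),
    )
    return plan


def _practice_trials(catalog: StimulusCatalog, rng: np.random.Generator):
    """6 practice trials (3 same + 3 different) from the practice reserve of
    4 species x 3 exemplars; uses each reserve image at most once."""
    specs = list(catalog.practice_species)
    if len(specs) < 4 or any(len(catalog.practice_species[s]) < 3 for s in specs):
        return tuple()  # no/insufficient reserve: session has no practice block
    a, b, c, d = specs[:4]
    ex = {s: list(catalog.practice_species[s]) for s in specs}
    for imgs in ex.values():
        rng.shuffle(imgs)
    raw = [
        ("same", ex[a][0], ex[a][1]),
        ("same", ex[b][0], ex[b][1]),
        ("same", ex[c][0], ex[c][1]),
        ("different", ex[d][0], ex[a][2]),
        ("different", ex[d][1], ex[b][2]),
        ("different", ex[d][2], ex[c][2]),
    ]
    order = rng.permutation(len(raw))
    conds = rng.choice(("full", "central", "peripheral"), size=len(raw))
    triggers = rng.choice(TRIGGER_POSITIONS, size=len(raw))
    return tuple(
        TrialSpec(
            index=i,
            trial_type=raw[j][0],
            condition=str(conds[i]),
            study_image_id=raw[j][1],
            test_image_id=raw[j][2],
            trigger_position=str(triggers[i]),
        )
        for i, j in enumerate(order)
    )


def session_to_frame(plan: SessionPlan):
    """Tidy one-row-per-trial DataFrame (experimental trials only)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                participant_id=plan.participant_id,
                index=t.index,
                trial_type=t.trial_type,
                condition=t.condition,
                study_image_id=t.study_image_id,
                test_image_id=t.test_image_id,
                trigger_position=t.trigger_position,
            )
            for t in plan.trials
        ]
    )
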