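"""Synthetic perceptual-field observer: gaze traces and same/different
responses with the statistical structure the analysis pipeline assumes.

The observer model embodies the perceptual-field hypothesis directly.  An
observer has a Gaussian sensitivity profile over retinal eccentricity,
``gain(e) = exp(-e^2 / (2 sigma_field^2))``: information at eccentricity
``e`` (degrees) from the current fixation is weighted by this gain.  Each
stimulus carries a set of diagnostic features (one per ROI, at the ROI
centroid, with weights summing to 1).  During a fixation of duration
``dt`` at gaze position g the observer accrues evidence

    dI = info_rate_per_s * dt * sum_f  w_f * gain(e_f) * gate(e_f)

where the gate implements the viewing condition: full view passes
everything, central view passes only features within the aperture radius
(2.905 deg, the 95-px radius under the horizontal calibration), peripheral
view passes only features beyond it.  By construction
dI(full) = dI(central) + dI(peripheral) for identical fixations.

A response is issued when cumulative information reaches
``evidence_bound`` (reaction time = crossing time + motor delay) or at the
response timeout.  Accuracy follows equal-variance signal detection with
effective sensitivity ``d_eff = d_max * (1 - exp(-I))`` and an unbiased
criterion, so the probability of a correct response is Phi(d_eff / 2);
lapses respond uniformly at random.

Experts differ from novices in a wider field (sigma_field 3.0 vs 1.5 deg)
and higher asymptotic sensitivity (d_max 3.5 vs 2.0).  These are free
parameters of the simulator, not estimates from human data; the defaults
are chosen to reproduce the qualitative group x condition x speed
structure the analysis is designed to detect.

Gaze traces alternate fixations (targets drawn from ``roi_attraction``,
jittered uniformly within the ROI polygon; durations lognormal) and 20-60
ms saccades with raised-cosine position profiles, sampled at 1000 Hz.
Every trace starts on the trigger dot, off the bird.  All randomness flows
from a single master seed through documented ``numpy`` SeedSequence
spawn keys (participant index, trial index, phase), so any trial's trace
can be regenerated bit-identically on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .design import SessionPlan, StimulusCatalog, TrialSpec, build_catalog, generate_session
from .geometry import DisplayConfig, STIMULUS_FRAME_PX, px_to_deg
from .roi import ROI_LABELS, ROIMap

#: empirical mean looking-time shares used as fixation-target probabilities
DEFAULT_ROI_ATTRACTION: dict[str, float] = {
    "head": 0.4428,
    "wings": 0.2324,
    "body": 0.1705,
    "tail": 0.0779,
    "feet": 0.0765,
}

#: aperture radius expressed in degrees via the horizontal calibration
APERTURE_RADIUS_DEG = 2.905

SAMPLE_RATE_HZ = 1000
TRIGGER_MARGIN_PX = 40  # trigger dot sits this far outside the stimulus frame
MIN_SACCADE_PX = 25  # minimal inter-fixation jump, keeps saccades detectable


def _phi(x: float) -> float:
    """Standard normal CDF (scalar)."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _phi_vec(x):
    from scipy.special import ndtr

    return ndtr(x)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated observer."""

    sigma_field_deg: float
    d_max: float
    info_rate_per_s: float = 4.5
    evidence_bound: float = 1.5
    motor_delay_ms: float = 300.0
    lapse_rate: float = 0.02
    fixation_duration_lognormal: tuple[float, float] = (math.log(230.0), 0.35)
    roi_attraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROI_ATTRACTION)
    )
    response_timeout_ms: float = 2000.0
    field_profile: str = "gaussian"  # or "exponential"

    def __post_init__(self) -> None:
        if self.sigma_field_deg <= 0 or self.d_max <= 0:
            raise ValueError("sigma_field_deg and d_max must be positive")
        if self.info_rate_per_s <= 0 or self.evidence_bound <= 0:
            raise ValueError("info_rate_per_s and evidence_bound must be positive")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must be in [0, 1)")
        total = sum(self.roi_attraction.values())
        # the published shares sum to 100.01% as printed; allow rounding slack
        if set(self.roi_attraction) != set(ROI_LABELS) or abs(total - 1.0) > 1e-2:
            raise ValueError("roi_attraction must cover the five ROIs and sum to 1")
        if self.field_profile not in ("gaussian", "exponential"):
            raise ValueError("field_profile must be 'gaussian' or 'exponential'")

    @classmethod
    def expert(cls, **overrides) -> "ObserverParams":
        return cls(sigma_field_deg=3.0, d_max=3.5, **overrides)

    @classmethod
    def novice(cls, **overrides) -> "ObserverParams":
        return cls(sigma_field_deg=1.5, d_max=2.0, **overrides)

    def gain(self, ecc_deg):
        e = np.asarray(ecc_deg, float)
        if self.field_profile == "gaussian":
            return np.exp(-(e**2) / (2.0 * self.sigma_field_deg**2))
        return np.exp(-e / self.sigma_field_deg)


@dataclass(frozen=True)
class FeatureLayout:
    """Diagnostic features of one stimulus: (roi_label, screen position,
    weight >= 0); weights sum to 1."""

    features: tuple[tuple[str, tuple[float, float], float], ...]

    def __post_init__(self) -> None:
        w = sum(f[2] for f in self.features)
        if abs(w - 1.0) > 1e-9 or any(f[2] < 0 for f in self.features):
            raise ValueError("feature weights must be non-negative and sum to 1")

    @property
    def positions(self) -> np.ndarray:
        return np.array([f[1] for f in self.features], float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([f[2] for f in self.features], float)

    @classmethod
    def from_roi_map(
        cls, m: ROIMap, weights: dict[str, float] | None = None
    ) -> "FeatureLayout":
        """One feature per ROI at its centroid; default weights follow the
        head-dominant empirical looking-time shares."""
        weights = weights or DEFAULT_ROI_ATTRACTION
        total = sum(weights[l] for l in ROI_LABELS)
        ox, oy = m.frame_origin_xy
        feats = []
        for label in ROI_LABELS:
            cen = m.shape(label).centroid
            feats.append((label, (cen.x + ox, cen.y + oy), weights[label] / total))
        return cls(features=tuple(feats))


# --- synthetic stimulus geometry -------------------------------------------

_SYNTHETIC_ROIS: dict[str, list[tuple[float, float]]] = {
    # a left-facing bird silhouette, blocked out as disjoint rectangles
    # inside the 450x450 frame
    "head": [(60, 60), (160, 60), (160, 150), (60, 150)],
    "wings": [(180, 120), (330, 120), (330, 220), (180, 220)],
    "body": [(150, 230), (320, 230), (320, 320), (150, 320)],
    "tail": [(340, 150), (420, 150), (420, 260), (340, 260)],
    "feet": [(180, 330), (300, 330), (300, 390), (180, 390)],
}


def synthetic_roi_map(
    image_id: str, cfg: DisplayConfig | None = None
) -> ROIMap:
    """Synthetic stand-in for a hand-drawn ROI map: five disjoint rectangles
    in the 450x450 frame, centered on screen."""
    cfg = cfg or DisplayConfig.default()
    ox = (cfg.screen_width_px - STIMULUS_FRAME_PX) // 2
    oy = (cfg.screen_height_px - STIMULUS_FRAME_PX) // 2
    return ROIMap(
        image_id=image_id,
        polygons={k: list(v) for k, v in _SYNTHETIC_ROIS.items()},
        frame_origin_xy=(ox, oy),
    )


def trigger_xy(position: str, cfg: DisplayConfig) -> tuple[float, float]:
    """Screen position of the obligatory fixation dot: just outside the
    stimulus frame on the given side."""
    cx, cy = cfg.screen_width_px / 2.0, cfg.screen_height_px / 2.0
    off = STIMULUS_FRAME_PX / 2.0 + TRIGGER_MARGIN_PX
    return {
        "left": (cx - off, cy),
        "right": (cx + off, cy),
        "above": (cx, cy - off),
        "below": (cx, cy + off),
    }[position]


# --- gaze generation --------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthFixation:
    label: str  # ROI label or "trigger"
    x_px: float
    y_px: float
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class SimulatedTrace:
    """A 1000-Hz gaze trace plus its generative ground truth."""

    samples: pd.DataFrame  # t_ms, x_px, y_px, valid
    fixations: list[GroundTruthFixation]


def _sample_point_in_roi(
    m: ROIMap, label: str, rng: np.random.Generator
) -> tuple[float, float]:
    poly = m.shape(label)
    if poly.area <= 0:
        raise ValueError(f"degenerate polygon for {label!r}")
    minx, miny, maxx, maxy = poly.bounds
    ox, oy = m.frame_origin_xy
    for _ in range(1000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            return (x + ox, y + oy)
    raise ValueError(f"could not sample a point inside polygon {label!r}")


def _fixation_sequence(
    duration_ms: float,
    obs: ObserverParams,
    m: ROIMap,
    trigger: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[list[GroundTruthFixation], list[tuple[float, float, float]]]:
    """Alternating fixation/saccade plan covering [0, duration_ms).

    Returns (fixations, saccades) where each saccade is
    (onset_ms, duration_ms, ...) implied by consecutive fixation positions.
    Fixation targets are drawn from roi_attraction and jittered within the
    ROI polygon; consecutive targets are at least MIN_SACCADE_PX apart so
    every saccade clears the velocity threshold.
    """
    labels = list(ROI_LABELS)
    probs = np.array([obs.roi_attraction[l] for l in labels])
    probs = probs / probs.sum()
    mu, sd = obs.fixation_duration_lognormal
    fixations: list[GroundTruthFixation] = []
    sacc_plan: list[tuple[float, float]] = []  # (onset, duration)
    t = 0.0
    pos = trigger
    label = "trigger"
    while t < duration_ms:
        dur = float(np.clip(rng.lognormal(mu, sd), 60.0, 1200.0))
        offset = min(t + dur, duration_ms)
        fixations.append(
            GroundTruthFixation(label=label, x_px=pos[0], y_px=pos[1],
                                onset_ms=t, offset_ms=offset)
        )
        t = t + dur
        if t >= duration_ms:
            break
        # plan the next fixation target and the connecting saccade; the ROI
        # label is drawn once (keeping the label marginal exactly at
        # roi_attraction) and only the within-ROI point is resampled until
        # the jump is large enough to register as a saccade
        label = str(rng.choice(labels, p=probs))
        for _ in range(100):
            nxt = _sample_point_in_roi(m, label, rng)
            amp_px = math.hypot(nxt[0] - pos[0], nxt[1] - pos[1])
            if amp_px >= MIN_SACCADE_PX:
                break
        amp_deg = px_to_deg(amp_px, "horizontal", DisplayConfig.default())
        sacc_dur = float(np.clip(21.0 + 2.2 * amp_deg, 20.0, 60.0))
        if t + sacc_dur >= duration_ms:
            sacc_plan.append((t, duration_ms - t))
            break
        sacc_plan.append((t, sacc_dur))
        t += sacc_dur
        pos = nxt
    return fixations, sacc_plan


def _materialize_samples(
    duration_ms: float,
    fixations: Sequence[GroundTruthFixation],
    rng: np.random.Generator | None = None,
    noise_sd_px: float = 0.0,
) -> pd.DataFrame:
    """Render a fixation/saccade plan into 1-ms gaze samples with
    raised-cosine saccade trajectories."""
    n = int(round(duration_ms))
    t = np.arange(n, dtype=float)
    x = np.empty(n)
    y = np.empty(n)
    # fill fixation spans; saccade spans interpolate between neighbours
    for i, f in enumerate(fixations):
        i0 = int(round(f.onset_ms))
        i1 = min(int(round(f.offset_ms)), n)
        x[i0:i1] = f.x_px
        y[i0:i1] = f.y_px
        if i + 1 < len(fixations):
            j0 = i1
            j1 = min(int(round(fixations[i + 1].onset_ms)), n)
            if j1 > j0:
                phase = (np.arange(j1 - j0) + 1) / (j1 - j0 + 1)
                s = (1 - np.cos(np.pi * phase)) / 2.0  # raised cosine 0->1
                x[j0:j1] = f.x_px + s * (fixations[i + 1].x_px - f.x_px)
                y[j0:j1] = f.y_px + s * (fixations[i + 1].y_px - f.y_px)
        else:
            # trailing (truncated) saccade: hold the last fixation position
            if i1 < n:
                x[i1:] = f.x_px
                y[i1:] = f.y_px
    if noise_sd_px > 0 and rng is not None:
        x = x + rng.normal(0, noise_sd_px, n)
        y = y + rng.normal(0, noise_sd_px, n)
    return pd.DataFrame(
        dict(t_ms=t.astype(int), x_px=x, y_px=y, valid=np.ones(n, bool))
    )


def simulate_gaze_trace(
    trial: TrialSpec,
    obs: ObserverParams,
    m: ROIMap,
    seed,
    duration_ms: float | None = None,
    cfg: DisplayConfig | None = None,
    noise_sd_px: float = 0.0,
) -> SimulatedTrace:
    """Generate a study-phase gaze trace for one trial.

    The trace starts on the trigger dot (off the bird), then alternates
    ROI-directed fixations and short saccades for the study duration.
    ``seed`` may be an int or a ``numpy`` SeedSequence.
    """
    cfg = cfg or DisplayConfig.default()
    rng = np.random.default_rng(seed)
    duration = float(duration_ms if duration_ms is not None else trial.study_duration_ms)
    trig = trigger_xy(trial.trigger_position, cfg)
    fixations, _ = _fixation_sequence(duration, obs, m, trig, rng)
    samples = _materialize_samples(duration, fixations, rng, noise_sd_px)
    return SimulatedTrace(samples=samples, fixations=fixations)


# --- response model ---------------------------------------------------------


def fixation_eccentricities(
    fixation_xy: tuple[float, float], layout: FeatureLayout, cfg: DisplayConfig
) -> np.ndarray:
    """Eccentricity (deg) of every feature from a gaze position, using the
    horizontal calibration for both axes (field anisotropy ignored)."""
    pos = layout.positions
    d_px = np.hypot(pos[:, 0] - fixation_xy[0], pos[:, 1] - fixation_xy[1])
    return px_to_deg(d_px, "horizontal", cfg)


def condition_gate(ecc_deg: np.ndarray, condition: str, r_deg: float = APERTURE_RADIUS_DEG):
    """Indicator gate of the viewing condition.  central passes e <= r,
    peripheral passes e > r, full passes everything; central + peripheral
    partition full exactly."""
    e = np.asarray(ecc_deg, float)
    if condition == "full":
        return np.ones_like(e)
    if condition == "central":
        return (e <= r_deg).astype(float)
    if condition == "peripheral":
        return (e > r_deg).astype(float)
    raise ValueError(f"unknown condition {condition!r}")


def information_rate(
    fixation_xy: tuple[float, float],
    obs: ObserverParams,
    layout: FeatureLayout,
    condition: str,
    cfg: DisplayConfig,
    r_deg: float = APERTURE_RADIUS_DEG,
) -> float:
    """Instantaneous information accrual rate (1/s) at a gaze position."""
    ecc = fixation_eccentricities(fixation_xy, layout, cfg)
    g = obs.gain(ecc) * condition_gate(ecc, condition, r_deg)
    return float(obs.info_rate_per_s * np.sum(layout.weights * g))


@dataclass(frozen=True)
class ResponseOutcome:
    response: str  # same | different
    rt_ms: float
    information: float  # cumulative I at decision time
    d_eff: float
    lapsed: bool


def simulate_response(
    trial_type: str,
    obs: ObserverParams,
    layout: FeatureLayout,
    fixations: Sequence[GroundTruthFixation],
    condition: str,
    rng: np.random.Generator,
    cfg: DisplayConfig | None = None,
    r_deg: float = APERTURE_RADIUS_DEG,
) -> ResponseOutcome:
    """Accumulate gated evidence over the test-phase fixations and emit a
    same/different response.

    The bound crossing is solved exactly within the crossing fixation
    (information grows linearly during a fixation); saccade time accrues
    no information.  At timeout the response is issued with whatever
    information was gathered.
    """
    cfg = cfg or DisplayConfig.default()
    I = 0.0
    decision_t = None
    for f in fixations:
        rate = information_rate((f.x_px, f.y_px), obs, layout, condition, cfg, r_deg)
        dt_s = f.duration_ms / 1000.0
        if rate > 0 and I + rate * dt_s >= obs.evidence_bound:
            decision_t = f.onset_ms + 1000.0 * (obs.evidence_bound - I) / rate
            I = obs.evidence_bound
            break
        I += rate * dt_s
    if decision_t is None:
        decision_t = fixations[-1].offset_ms if fixations else obs.response_timeout_ms
        decision_t = min(decision_t, obs.response_timeout_ms)
    rt_ms = decision_t + obs.motor_delay_ms

    d_eff = obs.d_max * (1.0 - math.exp(-I))
    lapsed = bool(rng.random() < obs.lapse_rate)
    if lapsed:
        response = "same" if rng.random() < 0.5 else "different"
    else:
        p_correct = _phi(d_eff / 2.0)
        correct = rng.random() < p_correct
        if trial_type == "same":
            response = "same" if correct else "different"
        else:
            response = "different" if correct else "same"
    return ResponseOutcome(
        response=response, rt_ms=rt_ms, information=I, d_eff=d_eff, lapsed=lapsed
    )


# --- cohort -----------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """A full synthetic experiment: session plans, trial records, ground
    truth, and deterministic access to every gaze trace."""

    master_seed: int
    participants: pd.DataFrame  # participant_id, group, sigma_field_deg, d_max
    session_plans: dict[str, SessionPlan]
    trial_records: pd.DataFrame  # tidy behavioral table
    roimaps: dict[str, ROIMap]
    observers: dict[str, ObserverParams]
    cfg: DisplayConfig
    catalog: StimulusCatalog
    evidence_records: dict[str, list[dict]]  # per participant, per trial

    def _pidx(self, participant_id: str) -> int:
        return list(self.participants["participant_id"]).index(participant_id)

    def trace_seed(self, participant_id: str, trial_index: int, phase: str):
        phase_code = {"study": 0, "test": 1}[phase]
        return np.random.SeedSequence(
            entropy=self.master_seed,
            spawn_key=(self._pidx(participant_id), trial_index, phase_code),
        )

    def study_trace(self, participant_id: str, trial_index: int) -> SimulatedTrace:
        """Regenerate the study-phase gaze trace of one trial (bit-identical
        for a fixed master seed)."""
        plan = self.session_plans[participant_id]
        trial = plan.trials[trial_index]
        obs = self.observers[participant_id]
        m = self.roimaps[trial.study_image_id]
        return simulate_gaze_trace(
            trial, obs, m, self.trace_seed(participant_id, trial_index, "study"),
            cfg=self.cfg,
        )

    def iter_study_traces(self, participant_id: str):
        plan = self.session_plans[participant_id]
        for trial in plan.trials:
            yield trial, self.study_trace(participant_id, trial.index)


def _jittered(
    base: ObserverParams, jitter_sd: float, rng: np.random.Generator
) -> ObserverParams:
    """Lognormal multiplicative jitter on the two expertise parameters."""
    return replace(
        base,
        sigma_field_deg=base.sigma_field_deg * rng.lognormal(0.0, jitter_sd),
        d_max=base.d_max * rng.lognormal(0.0, jitter_sd),
    )


def simulate_cohort(
    n_experts: int = 15,
    n_novices: int = 15,
    master_seed: int = 0,
    param_jitter_sd: float = 0.15,
    catalog: StimulusCatalog | None = None,
    cfg: DisplayConfig | None = None,
    simulate_test_phase: bool = True,
    expert_params: ObserverParams | None = None,
    novice_params: ObserverParams | None = None,
) -> SimulatedCohort:
    """Simulate a full expert/novice cohort with 144-trial sessions.

    Per-participant observer parameters are drawn around the group defaults
    with lognormal jitter.  Trial responses (the behavioral table) come
    from the evidence-accumulation model on simulated test-phase fixation
    sequences; study-phase gaze traces are regenerated on demand from the
    seed-splitting scheme rather than stored.
    """
    if n_experts < 2 or n_novices < 2:
        raise ValueError("need at least 2 participants per group")
    cfg = cfg or DisplayConfig.default()
    catalog = catalog or build_catalog()
    expert_params = expert_params or ObserverParams.expert()
    novice_params = novice_params or ObserverParams.novice()

    root = np.random.SeedSequence(entropy=master_seed, spawn_key=(2**16,))
    rng_master = np.random.default_rng(root)

    roimaps = {img: synthetic_roi_map(img, cfg) for img in catalog.image_ids}
    roimaps.update(
        {img: synthetic_roi_map(img, cfg) for img in catalog.practice_image_ids}
    )
    layouts = {img: FeatureLayout.from_roi_map(m) for img, m in roimaps.items()}

    part_rows = []
    observers: dict[str, ObserverParams] = {}
    plans: dict[str, SessionPlan] = {}
    trial_rows = []
    evidence: dict[str, list[dict]] = {}
    roster = [("expert", i, expert_params) for i in range(n_experts)] + [
        ("novice", i, novice_params) for i in range(n_novices)
    ]
    for p_idx, (group, i, base) in enumerate(roster):
        pid = f"{group[0]}{i + 1:02d}"
        obs = _jittered(base, param_jitter_sd, rng_master)
        observers[pid] = obs
        session_seed = int(rng_master.integers(0, 2**31 - 1))
        plan = generate_session(catalog, seed=session_seed, participant_id=pid)
        plans[pid] = plan
        part_rows.append(
            dict(
                participant_id=pid,
                group=group,
                sigma_field_deg=obs.sigma_field_deg,
                d_max=obs.d_max,
                session_seed=session_seed,
            )
        )
        evidence[pid] = []
        if not simulate_test_phase:
            continue
        for trial in plan.trials:
            seed = np.random.SeedSequence(
                entropy=master_seed, spawn_key=(p_idx, trial.index, 1)
            )
            rng = np.random.default_rng(seed)
            m = roimaps[trial.test_image_id]
            trig = trigger_xy(trial.trigger_position, cfg)
            fixations, _ = _fixation_sequence(
                obs.response_timeout_ms, obs, m, trig, rng
            )
            layout = layouts[trial.test_image_id]
            outcome = simulate_response(
                trial.trial_type, obs, layout, fixations, trial.condition, rng, cfg
            )
            trial_rows.append(
                dict(
                    participant_id=pid,
                    group=group,
                    condition=trial.condition,
                    trial_type=trial.trial_type,
                    response=outcome.response,
                    rt_ms=outcome.rt_ms,
                    trial_index=trial.index,
                )
            )
            evidence[pid].append(
                dict(
                    trial_index=trial.index,
                    condition=trial.condition,
                    trial_type=trial.trial_type,
                    correct=outcome.response == trial.trial_type,
                    rt_ms=outcome.rt_ms,
                    durations_s=np.array([f.duration_ms for f in fixations]) / 1000.0,
                    ecc_deg=np.array(
                        [
                            fixation_eccentricities((f.x_px, f.y_px), layout, cfg)
                            for f in fixations
                        ]
                    ),
                    weights=layout.weights,
                )
            )

    return SimulatedCohort(
        master_seed=int(master_seed),
        participants=pd.DataFrame(part_rows),
        session_plans=plans,
        trial_records=pd.DataFrame(trial_rows),
        roimaps=roimaps,
        observers=observers,
        cfg=cfg,
        catalog=catalog,
        evidence_records=evidence,
    )


# --- parameter recovery -----------------------------------------------------


def _flatten_records(records: list[dict], template: ObserverParams):
    """Precompute the sigma-independent parts of the likelihood: for every
    fixation of every trial, its gated eccentricities/weights and the
    effective exposure time (clipped at the observed decision time).

    Because accrual rates are non-negative, capping the running total at
    the bound is equivalent to capping the final sum, so the per-trial
    information reduces to min(bound, sum_i rate_i * dt_i)."""
    ecc_rows, w_rows, dt_rows, trial_of = [], [], [], []
    correct = []
    for ti, rec in enumerate(records):
        t_avail = max(rec["rt_ms"] - template.motor_delay_ms, 0.0) / 1000.0
        used = 0.0
        for k, dur in enumerate(rec["durations_s"]):
            dt = min(dur, t_avail - used)
            used += dur
            if dt <= 0:
                break
            gate = condition_gate(rec["ecc_deg"][k], rec["condition"])
            ecc_rows.append(rec["ecc_deg"][k])
            w_rows.append(rec["weights"] * gate)
            dt_rows.append(dt)
            trial_of.append(ti)
        correct.append(bool(rec["correct"]))
    return (
        np.asarray(ecc_rows),
        np.asarray(w_rows),
        np.asarray(dt_rows),
        np.asarray(trial_of),
        np.asarray(correct),
    )


def _loglik_sigma(
    sigma: float, records: list[dict], template: ObserverParams
) -> float:
    """Log-likelihood of observed correctness given a candidate field width,
    re-accumulating evidence along each trial's fixation sequence."""
    flat = _flatten_records(records, template)
    return float(_loglik_sigma_flat(sigma, flat, len(records), template))


def _loglik_sigma_flat(sigma, flat, n_trials, template: ObserverParams):
    ecc, w, dt, trial_of, correct = flat
    obs = replace(template, sigma_field_deg=float(sigma))
    rates = obs.info_rate_per_s * (obs.gain(ecc) * w).sum(axis=1)
    I = np.zeros(n_trials)
    np.add.at(I, trial_of, rates * dt)
    I = np.minimum(I, obs.evidence_bound)
    d_eff = obs.d_max * (1.0 - np.exp(-I))
    p_correct = (1 - obs.lapse_rate) * _phi_vec(d_eff / 2.0) + obs.lapse_rate / 2.0
    p = np.where(correct, p_correct, 1.0 - p_correct)
    return np.log(np.maximum(p, 1e-12)).sum()


def fit_sigma_field(
    records: list[dict],
    template: ObserverParams,
    grid: Sequence[float] | None = None,
) -> float:
    """Grid-search maximum-likelihood estimate of the perceptual-field width
    from one participant's evidence records (as stored by
    :func:`simulate_cohort`)."""
    if grid is None:
        grid = np.geomspace(0.5, 10.0, 25)
    flat = _flatten_records(records, template)
    lls = [_loglik_sigma_flat(s, flat, len(records), template) for s in grid]
    return float(grid[int(np.argmax(lls))])


def sigma_recovery_ordering(
    n_replicates: int = 20,
    n_per_group: int = 3,
    seed: int = 0,
    catalog: StimulusCatalog | None = None,
) -> float:
    """Fraction of replicate cohorts in which the fitted group-mean field
    width preserves the generative ordering (expert > novice)."""
    catalog = catalog or build_catalog()
    template = ObserverParams(sigma_field_deg=1.0, d_max=2.5)  # neutral template
    hits = 0
    for r in range(n_replicates):
        cohort = simulate_cohort(
            n_experts=n_per_group,
            n_novices=n_per_group,
            master_seed=seed + 7919 * r + 1,
            catalog=catalog,
        )
        est = {}
        for row in cohort.participants.itertuples(index=False):
            fit = fit_sigma_field(cohort.evidence_records[row.participant_id], template)
            est.setdefault(row.group, []).append(fit)
        if np.mean(est["expert"]) > np.mean(est["novice"]):
            hits += 1
    return hits / n_replicates
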