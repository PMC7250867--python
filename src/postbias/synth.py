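"""Synthetic two-stage perceptual decision sessions and sensor-space epochs.

Emulates the random-dot-motion task in which confidence is manipulated
independently of accuracy ("positive evidence" manipulation): dots move
coherently in *both* directions, the incorrect-direction coherence is fixed
per condition (5% low-PE, 15% high-PE) and the correct-direction coherence
is staircased to a target accuracy, so that high-PE stimuli raise
confidence at matched performance.  Each trial has an initial decision with
confidence rating, a post-decision evidence sample (weak or strong, always
in the true direction), and a final decision — the substrate for
post-decisional drift-diffusion regression and neural decision-variable
decoding, here with known ground truth for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .ddm import _simulate_wiener_trials
from .neural import EpochSet

LPE_INCORRECT = 0.05   # fixed incorrect-direction coherence, low positive evidence
HPE_INCORRECT = 0.15   # fixed incorrect-direction coherence, high positive evidence
STRONG_MULTIPLIER = 1.3  # strong post-decision evidence = 1.3 x weak

CONFIDENCE_SCALE = np.linspace(0.5, 1.0, 7)  # 7-point rating between 50% and 100%


# ---------------------------------------------------------------------------
# Stimulus arithmetic and scoring rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusCoherences:
    """Coherence levels (proportions of coherently moving dots) of the design.

    Pre-decision: per PE condition, a fixed incorrect-direction coherence
    and a staircased correct-direction coherence.  Post-decision: the
    incorrect coherence is the mean of the two staircased incorrect values;
    weak correct coherence is the mean of the two staircased correct
    values; strong = weak x 1.3.
    """

    lpe_correct: float
    lpe_incorrect: float
    hpe_correct: float
    hpe_incorrect: float
    post_incorrect: float
    post_weak_correct: float
    post_strong_correct: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"coherence {name}={val} outside [0, 1]")
        for c, i in (
            (self.lpe_correct, self.lpe_incorrect),
            (self.hpe_correct, self.hpe_incorrect),
            (self.post_weak_correct, self.post_incorrect),
            (self.post_strong_correct, self.post_incorrect),
        ):
            if c + i > 1.0 + 1e-9:
                raise ValueError(f"correct+incorrect coherence {c}+{i} exceeds 1")


def make_stimulus_set(
    lpe_correct: float,
    hpe_correct: float,
    lpe_incorrect: float = LPE_INCORRECT,
    hpe_incorrect: float = HPE_INCORRECT,
) -> StimulusCoherences:
    """Derive the full coherence set from the two staircased values."""
    for name, v in (("lpe_correct", lpe_correct), ("hpe_correct", hpe_correct)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    post_incorrect = (lpe_incorrect + hpe_incorrect) / 2.0
    post_weak = (lpe_correct + hpe_correct) / 2.0
    post_strong = post_weak * STRONG_MULTIPLIER
    return StimulusCoherences(
        lpe_correct=lpe_correct,
        lpe_incorrect=lpe_incorrect,
        hpe_correct=hpe_correct,
        hpe_incorrect=hpe_incorrect,
        post_incorrect=post_incorrect,
        post_weak_correct=post_weak,
        post_strong_correct=post_strong,
    )


def score_qsr(correct, confidence):
    """Quadratic scoring rule: ``100 * [1 - (correct - confidence)^2]``.

    A proper scoring rule: expected points are maximised by reporting
    confidence equal to the subjective probability of being correct.
    """
    confidence = np.asarray(confidence, dtype=float)
    if np.any(confidence < 0.0) or np.any(confidence > 1.0):
        raise ValueError("confidence must lie in [0, 1]")
    correct = np.asarray(correct, dtype=float)
    pts = 100.0 * (1.0 - (correct - confidence) ** 2)
    return float(pts) if pts.ndim == 0 else pts


# ---------------------------------------------------------------------------
# Observer and staircase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverSpec:
    """Generative observer: psychometric function, diffusion stages,
    confidence model, and the post-decisional ground-truth coefficients.

    The psychometric function is logistic over net coherence
    (correct minus incorrect): P(correct) = expit(slope * (dc - threshold)).
    Pre- and post-decision stages are diffusions whose drift is chosen so
    that, from an unbiased start, the diffusion's accuracy equals the
    psychometric function at the presented net coherence
    (v = slope * (dc - threshold) / boundary, since P = expit(v * a) at
    z = 1/2, s = 1).

    Confidence is a logistic function of the accumulated pre-decision
    evidence (terminal bound sign plus decision speed) with an additive
    positive-evidence offset, mapped into [0.5, 1].

    ``z_*``/``v_*`` are the ground-truth dependencies of the post-decision
    starting point (logit scale) and drift on scaled confidence, initial
    decision (+1 correct / -1 error) and their interaction.
    """

    slope: float = 18.0
    threshold: float = 0.0
    # pre-decision diffusion
    pre_boundary: float = 1.6
    pre_t0: float = 0.35
    # confidence model
    conf_intercept: float = -1.0
    conf_evidence: float = 0.8
    conf_speed: float = 0.5
    pe_offset: float = 0.6
    conf_noise: float = 0.9
    # post-decision diffusion
    post_boundary: float = 1.6
    post_t0: float = 0.35
    z_confidence: float = 0.0
    z_decision: float = 0.25
    z_interaction: float = 0.15
    v_confidence: float = 0.0
    v_decision: float = 0.4
    v_interaction: float = 0.45

    def __post_init__(self):
        if not (self.slope > 0):
            raise ValueError("psychometric slope must be positive")
        for name in ("z_confidence", "z_decision", "z_interaction",
                     "v_confidence", "v_decision", "v_interaction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"generative coefficient {name} must be finite")

    def p_correct(self, net_coherence) -> np.ndarray:
        return expit(self.slope * (np.asarray(net_coherence, float) - self.threshold))

    def drift(self, net_coherence, boundary) -> np.ndarray:
        return self.slope * (np.asarray(net_coherence, float) - self.threshold) / boundary


@dataclass
class StaircaseState:
    """Trajectory of a weighted up/down calibration staircase."""

    target_accuracy: float
    current_coherence: float
    history: list = field(default_factory=list)  # (coherence, correct) pairs
    step_up: float = 0.01
    step_down: float = 0.0
    converged: bool = True

    @property
    def tail_accuracy(self) -> float:
        n_tail = max(len(self.history) // 5, 1)
        return float(np.mean([c for _, c in self.history[-n_tail:]]))


def run_staircase(
    observer: ObserverSpec,
    target_accuracy: float,
    n_trials: int,
    seed: int,
    incorrect_coherence: float = LPE_INCORRECT,
    initial_coherence: float | None = None,
    step_up: float = 0.01,
) -> StaircaseState:
    """Calibrate the correct-direction coherence to a target accuracy.

    A transformed weighted up/down rule: after an error the coherence rises
    by ``step_up``; after a correct response it falls by
    ``step_up * (1 - p) / p`` where p is the target, so the expected drift
    of the staircase vanishes exactly at the target accuracy.  Flags
    non-convergence when the observer cannot reach the target anywhere in
    the achievable coherence range, or when the staircase spends much of
    its tail pinned to a range limit.
    """
    if not (0.5 < target_accuracy < 1.0):
        raise ValueError("target_accuracy must lie in (0.5, 1)")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    step_down = step_up * (1.0 - target_accuracy) / target_accuracy
    c_max = 1.0 - incorrect_coherence
    if initial_coherence is None:
        # start at a fixed net evidence so both PE conditions approach the
        # equilibrium symmetrically
        initial_coherence = incorrect_coherence + 0.10
    state = StaircaseState(
        target_accuracy=target_accuracy,
        current_coherence=min(initial_coherence, c_max),
        step_up=step_up,
        step_down=step_down,
    )
    c = state.current_coherence
    pinned = 0
    for _ in range(n_trials):
        p = float(observer.p_correct(c - incorrect_coherence))
        correct = bool(rng.random() < p)
        state.history.append((c, int(correct)))
        c = c - step_down if correct else c + step_up
        if c >= c_max or c <= 0.0:
            pinned += 1
        c = min(max(c, 0.0), c_max)
    state.current_coherence = c
    p_top = float(observer.p_correct(c_max - incorrect_coherence))
    p_bottom = float(observer.p_correct(-incorrect_coherence))
    if p_top < target_accuracy or p_bottom > target_accuracy or pinned > n_trials // 5:
        state.converged = False
    return state


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Design of one simulated session (defaults mirror the behavioural
    studies: 2x2 factorial, 90 trials per cell, staircase target 71%)."""

    n_trials_per_cell: int = 90
    target_accuracy: float = 0.71
    calibration_trials: int = 90  # staircase length per PE condition
    confidence_format: str = "rating"  # "rating" (7-point) or "binary" (MEG)
    step_up: float = 0.02

    def __post_init__(self):
        if self.n_trials_per_cell <= 0 or self.calibration_trials <= 0:
            raise ValueError("trial counts must be positive")
        if self.confidence_format not in ("rating", "binary"):
            raise ValueError("confidence_format must be 'rating' or 'binary'")


def _confidence(observer, correct_sign, rt_decision, is_hpe, rng):
    latent = (
        observer.conf_intercept
        + observer.conf_evidence * correct_sign
        - observer.conf_speed * np.log(np.maximum(rt_decision, 1e-3))
        + observer.pe_offset * is_hpe
        + observer.conf_noise * rng.standard_normal(len(correct_sign))
    )
    return 0.5 + 0.5 * expit(latent)


def _snap_to_scale(conf):
    idx = np.argmin(np.abs(conf[:, None] - CONFIDENCE_SCALE[None, :]), axis=1)
    return CONFIDENCE_SCALE[idx]


def simulate_session(
    config: SessionConfig,
    observer: ObserverSpec,
    seed: int,
    subject_id: str = "s00",
    coherences: StimulusCoherences | None = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate one subject's session as a balanced 2x2 factorial table.

    Stages: (1) staircase calibration of the two correct-direction
    coherences (unless ``coherences`` is supplied); (2) initial decisions
    and RTs from the pre-decision diffusion; (3) confidence from the
    accumulated-evidence model with the positive-evidence offset;
    (4) final decisions from the post-decision diffusion whose starting
    point and drift depend on confidence, initial decision and their
    interaction per the observer's ground-truth coefficients.
    """
    rng = np.random.default_rng(seed)

    if coherences is None:
        stair_lpe = run_staircase(
            observer, config.target_accuracy, config.calibration_trials,
            seed=int(rng.integers(2**31)), incorrect_coherence=LPE_INCORRECT,
            step_up=config.step_up,
        )
        stair_hpe = run_staircase(
            observer, config.target_accuracy, config.calibration_trials,
            seed=int(rng.integers(2**31)), incorrect_coherence=HPE_INCORRECT,
            step_up=config.step_up,
        )
        coherences = make_stimulus_set(stair_lpe.current_coherence, stair_hpe.current_coherence)

    cells = [(pe, ps) for pe in ("LPE", "HPE") for ps in ("weak", "strong")]
    n = config.n_trials_per_cell * len(cells)
    pe_cond = np.repeat([c[0] for c in cells], config.n_trials_per_cell)
    post_strength = np.repeat([c[1] for c in cells], config.n_trials_per_cell)
    order = rng.permutation(n)
    pe_cond, post_strength = pe_cond[order], post_strength[order]
    direction = rng.choice(["left", "right"], n)

    is_hpe = (pe_cond == "HPE").astype(float)
    net_pre = np.where(
        is_hpe == 1.0,
        coherences.hpe_correct - coherences.hpe_incorrect,
        coherences.lpe_correct - coherences.lpe_incorrect,
    )

    # initial stage: accuracy-coded diffusion (upper bound = correct)
    v_pre = observer.drift(net_pre, observer.pre_boundary)
    init_correct, init_rt = _simulate_wiener_trials(
        v_pre, np.full(n, observer.pre_boundary), np.full(n, 0.5),
        np.full(n, observer.pre_t0), dt, rng,
    )
    initial_choice = np.where(
        init_correct == 1, direction, np.where(direction == "left", "right", "left")
    )

    corr_sign = 2.0 * init_correct - 1.0
    conf_raw = _confidence(observer, corr_sign, init_rt - observer.pre_t0, is_hpe, rng)
    initial_confidence = _snap_to_scale(conf_raw)
    conf_signed = 4.0 * initial_confidence - 3.0

    # post-decision stage
    net_post = np.where(
        post_strength == "strong",
        coherences.post_strong_correct - coherences.post_incorrect,
        coherences.post_weak_correct - coherences.post_incorrect,
    )
    v_post = (
        observer.drift(net_post, observer.post_boundary)
        + observer.v_confidence * conf_signed
        + observer.v_decision * corr_sign
        + observer.v_interaction * conf_signed * corr_sign
    )
    zeta = (
        observer.z_confidence * conf_signed
        + observer.z_decision * corr_sign
        + observer.z_interaction * conf_signed * corr_sign
    )
    final_correct, final_rt = _simulate_wiener_trials(
        v_post, np.full(n, observer.post_boundary), expit(zeta),
        np.full(n, observer.post_t0), dt, rng,
    )
    final_choice = np.where(
        final_correct == 1, direction, np.where(direction == "left", "right", "left")
    )
    fcorr_sign = 2.0 * final_correct - 1.0
    final_conf = _snap_to_scale(
        _confidence(observer, fcorr_sign, final_rt - observer.post_t0, is_hpe, rng)
    )

    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "pe_condition": pe_cond,
            "post_strength": post_strength,
            "direction": direction,
            "initial_choice": initial_choice,
            "initial_correct": init_correct,
            "initial_confidence": initial_confidence,
            "initial_rt": init_rt,
            "final_choice": final_choice,
            "final_correct": final_correct,
            "final_confidence": final_conf,
            "final_rt": final_rt,
            "change_of_mind": (final_choice != initial_choice).astype(int),
        }
    )
    if config.confidence_format == "binary":
        med = float(np.median(table["initial_confidence"]))
        table["confidence_binary"] = np.where(
            table["initial_confidence"] > med, "high", "low"
        )
    return table


def simulate_study(
    config: SessionConfig,
    observer: ObserverSpec,
    n_subjects: int,
    seed: int,
    observer_jitter: float = 0.0,
) -> pd.DataFrame:
    """Simulate several subjects; optional Gaussian jitter on the
    ground-truth post-decision coefficients across subjects."""
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(n_subjects)
    rng = np.random.default_rng(ss.spawn(1)[0])
    tables = []
    for i in range(n_subjects):
        obs = observer
        if observer_jitter > 0:
            obs = replace(
                observer,
                **{
                    k: getattr(observer, k) + observer_jitter * rng.standard_normal()
                    for k in ("z_decision", "z_interaction", "v_decision", "v_interaction")
                },
            )
        tables.append(
            simulate_session(config, obs, int(subj_seeds[i]) % 2**31, subject_id=f"s{i:02d}")
        )
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Sensor-space epoch simulation
# ---------------------------------------------------------------------------


@dataclass
class EpochGroundTruth:
    """Forward model for synthetic sensor epochs, plus (after generation)
    the per-trial injected decision-variable trajectories.

    One fixed spatial pattern (unit norm over channels) carries a signed
    amplitude: during the pre-decision window the amplitude ramps up with
    the sign of the initial choice (+ right / - left); during the
    post-decision window it evolves linearly with a per-trial intercept
    (signed by the initial choice — a continuation of the initial
    decision) and slope (signed by the presented motion direction), where
    the unsigned slope depends on the condition:
    slope = slope0 + slope_decision*dec + slope_confidence*conf
            + slope_interaction*dec*conf  (dec, conf coded +/-1).
    Noise is Gaussian with exponential spatial correlation across channels.
    """

    n_channels: int = 273
    n_samples: int = 821
    sampling_rate: float = 100.0
    t_start_ms: float = -200.0
    pre_onset_ms: float = 0.0
    post_onset_ms: float = 4000.0
    window_ms: float = 850.0
    pre_amplitude: float = 1.0
    intercept0: float = 0.3
    intercept_confidence: float = 0.15
    slope0: float = 1.0          # amplitude units per second
    slope_decision: float = 0.25
    slope_confidence: float = 0.0
    slope_interaction: float = 0.35
    slope_jitter: float = 0.1    # sd of trial-level slope heterogeneity
    noise_scale: float = 0.5
    spatial_corr_length: float = 10.0  # channels
    pattern: np.ndarray | None = None
    # filled in by simulate_epochs:
    trial_intercepts: np.ndarray | None = None
    trial_slopes: np.ndarray | None = None
    trial_slopes_signed: np.ndarray | None = None

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.pattern is not None:
            p = np.asarray(self.pattern, float)
            if p.shape != (self.n_channels,):
                raise ValueError("pattern length must equal n_channels")
            nrm = np.linalg.norm(p)
            if nrm <= 0:
                raise ValueError("pattern must be non-zero")
            self.pattern = p / nrm


def _choice_conf_codes(trials: pd.DataFrame):
    s_choice = np.where(trials["initial_choice"].to_numpy() == "right", 1.0, -1.0)
    s_dir = np.where(trials["direction"].to_numpy() == "right", 1.0, -1.0)
    dec = np.where(trials["initial_correct"].to_numpy().astype(int) == 1, 1.0, -1.0)
    if "confidence_binary" in trials.columns:
        conf = np.where(trials["confidence_binary"].to_numpy() == "high", 1.0, -1.0)
    else:
        med = float(np.median(trials["initial_confidence"]))
        conf = np.where(trials["initial_confidence"].to_numpy() > med, 1.0, -1.0)
    return s_choice, s_dir, dec, conf


def simulate_epochs(
    trials: pd.DataFrame, truth: EpochGroundTruth, seed: int
) -> tuple[EpochSet, EpochGroundTruth]:
    """Generate sensor-space epochs for the given trials.

    Returns the epochs (float32, trials x channels x samples) and the
    ground truth with per-trial injected intercepts/slopes filled in.
    """
    required = {"initial_choice", "direction", "initial_correct"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials table missing columns: {required - set(trials.columns)}")
    n = len(trials)
    rng = np.random.default_rng(seed)

    pattern = truth.pattern
    if pattern is None:
        pattern = rng.standard_normal(truth.n_channels)
        pattern /= np.linalg.norm(pattern)
        truth.pattern = pattern

    times = truth.t_start_ms + 1000.0 / truth.sampling_rate * np.arange(truth.n_samples)
    s_choice, s_dir, dec, conf = _choice_conf_codes(trials)

    intercepts = truth.intercept0 + truth.intercept_confidence * conf
    slopes = (
        truth.slope0
        + truth.slope_decision * dec
        + truth.slope_confidence * conf
        + truth.slope_interaction * dec * conf
        + truth.slope_jitter * rng.standard_normal(n)
    )
    truth.trial_intercepts = intercepts
    truth.trial_slopes = slopes
    truth.trial_slopes_signed = s_dir * slopes

    pre = (times >= truth.pre_onset_ms) & (times <= truth.pre_onset_ms + truth.window_ms)
    post = (times >= truth.post_onset_ms) & (times <= truth.post_onset_ms + truth.window_ms)
    t_pre = (times[pre] - truth.pre_onset_ms) / 1000.0
    t_post = (times[post] - truth.post_onset_ms) / 1000.0

    amp = np.zeros((n, truth.n_samples))
    ramp = t_pre / max(t_pre[-1], 1e-9)
    amp[:, pre] = s_choice[:, None] * truth.pre_amplitude * ramp[None, :]
    amp[:, post] = (
        s_choice[:, None] * intercepts[:, None]
        + s_dir[:, None] * slopes[:, None] * t_post[None, :]
    )

    # spatially correlated Gaussian noise, white in time
    idx = np.arange(truth.n_channels)
    cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / truth.spatial_corr_length)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(truth.n_channels))
    data = np.empty((n, truth.n_channels, truth.n_samples), dtype=np.float32)
    for i in range(n):
        noise = truth.noise_scale * (L @ rng.standard_normal((truth.n_channels, truth.n_samples)))
        data[i] = (noise + pattern[:, None] * amp[i][None, :]).astype(np.float32)

    labels = pd.DataFrame(
        {
            "initial_choice": trials["initial_choice"].to_numpy(),
            "direction": trials["direction"].to_numpy(),
            "initial_correct": trials["initial_correct"].to_numpy().astype(int),
            "confidence_class": np.where(conf > 0, "high", "low"),
            "change_of_mind": trials["change_of_mind"].to_numpy().astype(int)
            if "change_of_mind" in trials.columns
            else np.zeros(n, dtype=int),
        }
    )
    epochs = EpochSet(
        data=data,
        sampling_rate=truth.sampling_rate,
        times=times,
        labels=labels,
        channels=[f"MEG{i:04d}" for i in range(truth.n_channels)],
        alignment="trial_onset",
    )
    return epochs, truth
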