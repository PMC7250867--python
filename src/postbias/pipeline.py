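"""End-to-end orchestration: simulate -> ddm-fit -> decode -> stats.

A single validated configuration drives all stages; one global seed is
expanded into per-stage seeds through named SeedSequence spawn keys, so
stages are individually reproducible and never share streams.  Each run
emits a RunReport with per-stage provenance and the headline tables (DIC
ladder, fixed effects, mediation paths, cluster p values).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import io as pbio
from . import neural, stats
from .ddm import FitConfig, build_model, dic, fit_hierarchical
from .synth import (
    EpochGroundTruth,
    ObserverSpec,
    SessionConfig,
    simulate_epochs,
    simulate_study,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_STAGE_ORDER = ("simulate", "ddm", "decode", "stats")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ObserverCfg(_Strict):
    slope: float = 18.0
    threshold: float = 0.0
    pre_boundary: float = 1.6
    pre_t0: float = 0.35
    conf_intercept: float = -1.0
    conf_evidence: float = 0.8
    conf_speed: float = 0.5
    pe_offset: float = 0.6
    conf_noise: float = 0.9
    post_boundary: float = 1.6
    post_t0: float = 0.35
    z_confidence: float = 0.0
    z_decision: float = 0.25
    z_interaction: float = 0.15
    v_confidence: float = 0.0
    v_decision: float = 0.4
    v_interaction: float = 0.45


class SessionCfg(_Strict):
    n_trials_per_cell: int = 40
    target_accuracy: float = 0.71
    calibration_trials: int = 90
    confidence_format: str = "rating"
    step_up: float = 0.02


class DdmCfg(_Strict):
    models: list[int] = [1, 4, 7, 10]
    n_samples: int = 1600
    n_burn: int = 700
    thinning: int = 1
    chains: int = 2
    outlier_probability: float = 0.05
    min_rt: float = 0.200


class DecodeCfg(_Strict):
    n_channels: int = 32
    n_epoch_samples: int = 251
    t_start_ms: float = -200.0
    pre_onset_ms: float = 0.0
    post_onset_ms: float = 1200.0
    window_ms: float = 850.0
    feature_window_ms: float = 100.0
    step_ms: float = 25.0
    noise_scale: float = 0.5
    spatial_corr_length: float = 4.0
    max_trials_per_subject: int = 120
    tg_folds: int = 3
    tg_reps: int = 3
    sensor_subset: int = 16
    sensor_reps: int = 200
    save_epochs: bool = False


class StatsCfg(_Strict):
    n_perm: int = 300
    n_boot: int = 1000
    cluster_alpha: float = 0.05


class PipelineConfig(_Strict):
    """Schema-validated configuration of a full synthetic run.

    Unknown keys are rejected at load time.  The defaults are the bundled
    small configuration: 6 subjects x 160 trials with reduced MCMC,
    decoding grid and permutation counts.
    """

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    n_subjects: int = 6
    observer_jitter: float = 0.05
    run_ddm: bool = True
    run_decode: bool = True
    run_stats: bool = True
    observer: ObserverCfg = ObserverCfg()
    session: SessionCfg = SessionCfg()
    ddm: DdmCfg = DdmCfg()
    decode: DecodeCfg = DecodeCfg()
    stats: StatsCfg = StatsCfg()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline configuration."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError("configuration must be a mapping")
    cfg = PipelineConfig(**payload)
    if cfg.schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {cfg.schema_version}")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global, spawn_key=(k,))
    where k is the stage's fixed position in the pipeline order."""
    k = _STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunReport:
    """Provenance and headline results of one pipeline run."""

    config: dict
    stages: list = field(default_factory=list)
    headline: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name, seed, duration, **info):
        self.stages.append(
            {"stage": name, "seed": seed, "duration_s": round(duration, 3), **info}
        )

    def _payload(self, with_timing: bool) -> dict:
        stages = [
            {k: v for k, v in s.items() if with_timing or k != "duration_s"}
            for s in self.stages
        ]
        return {
            "config": self.config,
            "stages": stages,
            "headline": self.headline,
            "warnings": self.warnings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self._payload(with_timing=True), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def checksum(self) -> str:
        """SHA-256 of the canonical report payload, excluding wall-clock
        timings — identical config + seed must give identical checksums."""
        text = json.dumps(self._payload(with_timing=False), sort_keys=True, default=_jsonify)
        return hashlib.sha256(text.encode()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path, report: RunReport) -> pd.DataFrame:
    seed = stage_seed(cfg.seed, "simulate")
    observer = ObserverSpec(**cfg.observer.model_dump())
    session = SessionConfig(**cfg.session.model_dump())
    trials = simulate_study(
        session, observer, cfg.n_subjects, seed, observer_jitter=cfg.observer_jitter
    )
    pbio.write_trials(trials, out / "trials.csv")
    return trials, seed


def _stage_ddm(cfg: PipelineConfig, trials: pd.DataFrame, out: Path, report: RunReport):
    seed = stage_seed(cfg.seed, "ddm")
    fit_cfg = FitConfig(
        n_samples=cfg.ddm.n_samples,
        n_burn=cfg.ddm.n_burn,
        thinning=cfg.ddm.thinning,
        chains=cfg.ddm.chains,
        seed=seed,
        outlier_probability=cfg.ddm.outlier_probability,
        min_rt=cfg.ddm.min_rt,
    )
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    ladder = {}
    effects = {}
    for mid in cfg.ddm.models:
        spec = build_model(mid)
        result = fit_hierarchical(trials, spec, fit_cfg)
        pbio.write_fit(result, fit_dir / f"model_{mid:02d}.h5")
        ladder[str(mid)] = round(dic(result), 2)
        if not result.converged:
            report.warnings.append(f"ddm model {mid}: convergence flagged (rhat)")
        if mid == max(cfg.ddm.models):
            effects = {
                name: round(result.posterior_mean(name), 4)
                for name in result.draws
                if name.startswith(("z_", "v_", "a_")) and "_s" not in name[2:]
            }
    best = min(ladder, key=ladder.get)
    return {"dic": ladder, "best_model": int(best), "top_model_effects": effects}, seed


def _stage_decode(cfg: PipelineConfig, trials: pd.DataFrame, out: Path, report: RunReport):
    seed = stage_seed(cfg.seed, "decode")
    d = cfg.decode
    ss = np.random.SeedSequence(seed)
    subj_ids = sorted(trials["subject_id"].unique())
    subj_seeds = ss.generate_state(len(subj_ids))
    summaries = []
    contrasts = []
    for i, sid in enumerate(subj_ids):
        sub = trials[trials["subject_id"] == sid].reset_index(drop=True)
        sub = sub.iloc[: d.max_trials_per_subject]
        truth = EpochGroundTruth(
            n_channels=d.n_channels,
            n_samples=d.n_epoch_samples,
            t_start_ms=d.t_start_ms,
            pre_onset_ms=d.pre_onset_ms,
            post_onset_ms=d.post_onset_ms,
            window_ms=d.window_ms,
            noise_scale=d.noise_scale,
            spatial_corr_length=d.spatial_corr_length,
        )
        epochs, truth = simulate_epochs(sub, truth, int(subj_seeds[i]) % 2**31)
        if d.save_epochs:
            pbio.write_epochs(epochs, out / f"epochs_{sid}.h5")
        pre = neural.sliding_features(
            epochs, d.feature_window_ms, d.step_ms,
            tmin_ms=d.pre_onset_ms, tmax_ms=d.pre_onset_ms + d.window_ms,
        )
        post = neural.sliding_features(
            epochs, d.feature_window_ms, d.step_ms,
            tmin_ms=d.post_onset_ms, tmax_ms=d.post_onset_ms + d.window_ms,
        )
        ens = neural.train_decoders(pre, epochs.labels["initial_choice"], scheme="loo")
        dv = neural.decode_dv(ens, post)
        trend = neural.dv_trend(dv)
        unsigned = neural.unsign(trend, epochs.labels["direction"])
        conf = np.where(epochs.labels["confidence_class"] == "high", 1.0, -1.0)
        dec = np.where(epochs.labels["initial_correct"] == 1, 1.0, -1.0)
        summaries.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "decision": dec,
                    "confidence": conf,
                    "slope": unsigned["slope"],
                    "intercept": unsigned["intercept"],
                    "final_rt": sub["final_rt"],
                    "final_correct": sub["final_correct"],
                    "final_confidence": sub["final_confidence"],
                }
            )
        )
        cells = np.char.add(
            np.where(conf > 0, "high_", "low_"),
            np.where(epochs.labels["change_of_mind"] == 1, "com", "stay"),
        )
        conf_strata = np.where(conf > 0, "high", "low")
        try:
            tg = neural.temporal_generalization(
                pre, post, epochs.labels["initial_choice"], cells,
                folds=d.tg_folds, reps=d.tg_reps, seed=int(subj_seeds[i]) % 2**31,
            )
        except ValueError:
            # change-of-mind cells can hold fewer trials than folds at this
            # session length; fall back to choice x confidence strata
            try:
                tg = neural.temporal_generalization(
                    pre, post, epochs.labels["initial_choice"], cells,
                    folds=d.tg_folds, reps=d.tg_reps, seed=int(subj_seeds[i]) % 2**31,
                    stratify_cells=conf_strata,
                )
                report.warnings.append(f"decode {sid}: TG folds stratified by confidence only")
            except ValueError as e:
                report.warnings.append(f"decode {sid}: temporal generalization skipped ({e})")
                tg = None
        if tg is not None:
            contrast = stats.confidence_contrast(tg.by_cell)
            if np.isfinite(contrast).all():
                contrasts.append(contrast)
            else:
                report.warnings.append(
                    f"decode {sid}: contrast undefined (single-class condition cell)"
                )
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "dv_summaries.csv", index=False)
    return summary, contrasts, seed


def _stage_stats(cfg: PipelineConfig, trials, summary, contrasts, out: Path, report: RunReport):
    seed = stage_seed(cfg.seed, "stats")
    headline = {}
    eff = stats.slope_effects(summary, outcome="slope")
    headline["slope_effects"] = eff.table.round(5).to_dict(orient="records")
    rt_val = stats.hier_regress(
        summary["final_rt"],
        summary[["slope", "intercept"]],
        summary["subject_id"],
        family="linear",
    )
    headline["rt_validation"] = rt_val.table.round(5).to_dict(orient="records")

    med = stats.mediation(
        predictor=np.where(trials["pe_condition"] == "HPE", 2.0, 1.0),
        mediator=trials["initial_confidence"],
        outcome=trials["change_of_mind"],
        subjects=trials["subject_id"],
        covariates=pd.DataFrame(
            {
                "accuracy": trials["initial_correct"].astype(float),
                "rt": trials["initial_rt"],
                "pes": np.where(trials["post_strength"] == "strong", 1.0, -1.0),
                "acc_x_pes": trials["initial_correct"].astype(float)
                * np.where(trials["post_strength"] == "strong", 1.0, -1.0),
            }
        ),
        n_boot=cfg.stats.n_boot,
        seed=seed,
    )
    headline["mediation"] = med.paths.round(5).to_dict(orient="records")
    med.paths.to_csv(out / "mediation.csv", index=False)

    if len(contrasts) >= 5:
        ct = stats.cluster_permutation(
            np.stack(contrasts), n_perm=cfg.stats.n_perm,
            cluster_alpha=cfg.stats.cluster_alpha, seed=seed,
        )
        headline["clusters"] = ct.clusters.round(5).to_dict(orient="records")
        ct.clusters.to_csv(out / "clusters.csv", index=False)
    else:
        report.warnings.append(
            f"cluster permutation skipped: only {len(contrasts)} usable subjects (need 5)"
        )
    eff.table.to_csv(out / "slope_effects.csv", index=False)
    return headline, seed


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Run all enabled stages in order, writing artifacts under ``out_dir``.

    Any stage failure aborts with the stage name and cause; artifacts from
    completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.model_dump())
    trials = summary = None
    contrasts = []

    t0 = time.perf_counter()
    try:
        trials, seed = _stage_simulate(config, out, report)
    except Exception as e:  # noqa: BLE001 - converted to a stage failure
        raise StageFailure("simulate", e) from e
    report.add_stage(
        "simulate", seed, time.perf_counter() - t0,
        n_trials=len(trials), n_subjects=config.n_subjects,
    )
    logger.info("simulate: %d trials", len(trials))

    if config.run_ddm:
        t0 = time.perf_counter()
        try:
            ddm_head, seed = _stage_ddm(config, trials, out, report)
        except Exception as e:
            raise StageFailure("ddm", e) from e
        report.add_stage("ddm", seed, time.perf_counter() - t0, models=config.ddm.models)
        report.headline.update(ddm_head)
        logger.info("ddm: DIC ladder %s", ddm_head["dic"])

    if config.run_decode:
        t0 = time.perf_counter()
        try:
            summary, contrasts, seed = _stage_decode(config, trials, out, report)
        except Exception as e:
            raise StageFailure("decode", e) from e
        report.add_stage(
            "decode", seed, time.perf_counter() - t0, n_tg_subjects=len(contrasts)
        )
        logger.info("decode: %d trial summaries", len(summary))

    if config.run_stats and summary is not None:
        t0 = time.perf_counter()
        try:
            stats_head, seed = _stage_stats(config, trials, summary, contrasts, out, report)
        except Exception as e:
            raise StageFailure("stats", e) from e
        report.add_stage("stats", seed, time.perf_counter() - t0)
        report.headline.update(stats_head)

    report.to_json(out / "report.json")
    return report
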