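"""End-to-end pipeline: simulate -> score -> assess -> analyze -> report.

Stages are individually re-runnable from their persisted CSV inputs; a run
log records the seed, package version, and every subject/trial exclusion
with its reason (non-responder, excessive movement, outlier, missing cell).
Exclusion screens mirror common practice in this paradigm:

* non-responder - fewer than 10% of scored trials show any SCR;
* excessive movement - more than 10% of trials artifact-flagged;
* outlier (optional, off by default) - |z| above a threshold (classically 6)
  on the early CS+ vs CS- difference score.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InsufficientDataError
from .learning import assess_cohort
from .scoring import ScoringConfig, cohort_cell_magnitudes, reduce_ratings, score_session
from .stats import (
    CELLS_2X2, batch_estimate_at, batch_simple_regression,
    build_difference_scores, fit_condition_ancova, fit_rm_ancova,
    hierarchical_regression,
)
from .synthetic import (
    AmplitudeEffectModel, Cohort, DEFAULT_INSTRUMENTS, KernelParams,
    RatingModel, batch_extinction_cell_magnitudes, default_effect_model,
    null_moderation_model, simulate_cohort,
)
from .task_design import DesignConfig


@dataclass
class AnalysisConfig:
    drop_non_learners: bool = False
    covariate: str = "iu"  # iu | stai | pswq
    outlier_z: float | None = None  # e.g. 6.0 in paper-faithful mode
    non_responder_max_zero_prop: float = 0.90
    movement_max_artifact_prop: float = 0.10

    def validate(self):
        if self.covariate not in ("iu", "stai", "pswq"):
            raise ValueError(f"unknown covariate {self.covariate!r}")


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 38
    out_dir: str = "fearext_out"
    fs: float = 50.0
    tonic_level_uS: float = 2.0
    drift_sd_uS: float = 0.02
    noise_sd_uS: float = 0.01
    artifact_rate: float = 26 / 1904
    artifact_magnitude_uS: float = 1.0
    shared_sequence: bool = False
    design: DesignConfig = field(default_factory=DesignConfig)
    kernel: KernelParams = field(default_factory=KernelParams)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    rating_model: RatingModel = field(default_factory=RatingModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # amplitude model is rebuilt from magnitude targets unless overridden
    effect_model: AmplitudeEffectModel | None = None

    def resolved_effect_model(self) -> AmplitudeEffectModel:
        return self.effect_model or default_effect_model()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("design", DesignConfig), ("kernel", KernelParams),
                         ("scoring", ScoringConfig),
                         ("rating_model", RatingModel),
                         ("analysis", AnalysisConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = {
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in kwargs[key].items()}
                kwargs[key] = sub(**sub_kwargs)
        if isinstance(kwargs.get("effect_model"), dict):
            kwargs["effect_model"] = AmplitudeEffectModel(**kwargs["effect_model"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    cohort: Cohort
    scored: pd.DataFrame
    magnitudes: pd.DataFrame
    rating_cells: pd.DataFrame
    learning: pd.DataFrame
    scr_extinction: object
    scr_acquisition: object
    rating_extinction: object
    rating_acquisition: object
    regressions: dict
    exclusions: pd.DataFrame
    log: list[str]
    tables: dict = field(default_factory=dict)


def _zero_proportions(scored: pd.DataFrame) -> dict:
    out = {}
    for phase, grp in scored.groupby("phase"):
        out[phase] = float(grp["is_zero"].mean())
    return out


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full simulate/score/assess/analyze pipeline.

    Deterministic under ``config.seed``.  When ``write`` is true all tables
    and the run log are persisted as CSV/text under ``config.out_dir``.
    """
    config.analysis.validate()
    config.design.validate()
    log: list[str] = [f"run: fearext {__version__} seed={config.seed} "
                      f"n_subjects={config.n_subjects}"]

    # --- simulate -----------------------------------------------------
    model = config.resolved_effect_model()
    cohort = simulate_cohort(
        n_subjects=config.n_subjects, seed=config.seed, design=config.design,
        model=model, kernel=config.kernel, rating_model=config.rating_model,
        fs=config.fs, tonic_level=config.tonic_level_uS,
        drift_sd=config.drift_sd_uS, noise_sd=config.noise_sd_uS,
        artifact_rate=config.artifact_rate,
        artifact_magnitude=config.artifact_magnitude_uS,
        shared_sequence=config.shared_sequence)
    log.append(f"simulate: {config.n_subjects} subjects, fs={config.fs} Hz, "
               f"{len(cohort.events)} trials total")

    # --- score --------------------------------------------------------
    scored = pd.concat(
        [score_session(cohort.recordings[sid],
                       cohort.events[cohort.events.subject_id == sid],
                       config.scoring)
         for sid in sorted(cohort.recordings)], ignore_index=True)
    zp = _zero_proportions(scored)
    log.append("score: zero-response proportions " +
               ", ".join(f"{k}={v:.1%}" for k, v in sorted(zp.items())))
    n_art = int(scored["artifact"].sum())
    log.append(f"score: {n_art} trial(s) artifact-flagged and discarded")

    # --- reduce -------------------------------------------------------
    magnitudes, dropped_cells = cohort_cell_magnitudes(scored)
    exclusions = []
    for sid in dropped_cells:
        exclusions.append({"subject_id": sid, "reason": "missing_cell"})
        log.append(f"exclude: subject {sid} (missing cell)")
    rating_cells = reduce_ratings(cohort.ratings)

    # --- assess learning ---------------------------------------------
    learning = assess_cohort(scored, cohort.ratings)
    n_nl = int((learning["learner_status"] == "non_learner").sum())
    log.append(f"assess: {n_nl} non-learner(s) "
               f"({'dropped' if config.analysis.drop_non_learners else 'retained'})")

    # --- SCR exclusion screens ---------------------------------------
    keep = set(magnitudes["subject_id"])
    for sid, grp in scored.groupby("subject_id"):
        zero_prop = float(grp["is_zero"].mean())
        art_prop = float(grp["artifact"].mean())
        if zero_prop > config.analysis.non_responder_max_zero_prop and sid in keep:
            keep.discard(sid)
            exclusions.append({"subject_id": sid, "reason": "non_responder"})
            log.append(f"exclude: subject {sid} (non-responder, "
                       f"{zero_prop:.0%} zero trials)")
        if art_prop > config.analysis.movement_max_artifact_prop and sid in keep:
            keep.discard(sid)
            exclusions.append({"subject_id": sid, "reason": "excessive_movement"})
            log.append(f"exclude: subject {sid} (excessive movement, "
                       f"{art_prop:.0%} artifact trials)")
    if config.analysis.outlier_z is not None:
        sub = magnitudes[magnitudes["subject_id"].isin(keep)]
        early_diff = (sub["csplus_early"] - sub["csminus_early"]).to_numpy()
        z = (early_diff - early_diff.mean()) / early_diff.std(ddof=1)
        for sid, zi in zip(sub["subject_id"], z):
            if abs(zi) > config.analysis.outlier_z:
                keep.discard(sid)
                exclusions.append({"subject_id": sid, "reason": "outlier"})
                log.append(f"exclude: subject {sid} (outlier, z={zi:+.1f} on "
                           "early CS+ vs CS- difference)")
    if config.analysis.drop_non_learners:
        for sid in learning.loc[learning.learner_status == "non_learner",
                                "subject_id"]:
            if sid in keep:
                keep.discard(sid)
                exclusions.append({"subject_id": sid, "reason": "non_learner"})
                log.append(f"exclude: subject {sid} (non-learner)")

    quest = cohort.questionnaires.set_index("subject_id")
    covariate = config.analysis.covariate

    # --- SCR analyses -------------------------------------------------
    scr_cells = magnitudes[magnitudes["subject_id"].isin(keep)].reset_index(drop=True)
    cov_scr = quest.loc[scr_cells["subject_id"], covariate].to_numpy(dtype=float)
    log.append(f"analyze: SCR n={len(scr_cells)} "
               f"(of {config.n_subjects}), covariate={covariate}")
    scr_ext = fit_rm_ancova(scr_cells, cov_scr)
    scr_acq = fit_condition_ancova(scr_cells, cov_scr)

    # --- rating analyses ---------------------------------------------
    cov_rate = quest.loc[rating_cells["subject_id"], covariate].to_numpy(dtype=float)
    log.append(f"analyze: ratings n={len(rating_cells)}")
    rate_ext = fit_rm_ancova(rating_cells, cov_rate)
    rate_acq = fit_condition_ancova(rating_cells, cov_rate)

    # --- hierarchical regressions ------------------------------------
    diffs = build_difference_scores(scr_cells)
    regressions = {}
    reg_frames = []
    step1 = quest.loc[scr_cells["subject_id"], ["stai", "pswq"]].reset_index(drop=True)
    step2 = quest.loc[scr_cells["subject_id"], ["iu"]].reset_index(drop=True)
    for name in diffs.columns:
        if name == "subject_id":
            continue
        res = hierarchical_regression(diffs[name].to_numpy(), [step1, step2])
        regressions[name] = res
        summary = res.summary()
        summary.insert(0, "outcome", name)
        reg_frames.append(summary)
    log.append(f"analyze: hierarchical regressions on "
               f"{len(regressions)} difference scores")

    tables = {
        "events": cohort.events,
        "questionnaires": cohort.questionnaires,
        "scored_trials": scored,
        "magnitudes": magnitudes,
        "rating_cells": rating_cells,
        "learning": learning,
        "scr_extinction_effects": scr_ext.effects,
        "scr_extinction_emm": scr_ext.emm,
        "scr_extinction_contrasts": scr_ext.contrasts,
        "scr_acquisition_effects": scr_acq.effects,
        "rating_extinction_effects": rate_ext.effects,
        "rating_extinction_emm": rate_ext.emm,
        "rating_extinction_contrasts": rate_ext.contrasts,
        "rating_acquisition_effects": rate_acq.effects,
        "hierarchical_regressions": (pd.concat(reg_frames, ignore_index=True)
                                     if reg_frames else pd.DataFrame()),
        "exclusions": pd.DataFrame(exclusions,
                                   columns=["subject_id", "reason"]),
    }

    result = PipelineResult(
        cohort=cohort, scored=scored, magnitudes=magnitudes,
        rating_cells=rating_cells, learning=learning,
        scr_extinction=scr_ext, scr_acquisition=scr_acq,
        rating_extinction=rate_ext, rating_acquisition=rate_acq,
        regressions=regressions, exclusions=tables["exclusions"],
        log=log, tables=tables)

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        (out / "run.log").write_text("\n".join(log) + "\n")
    return result


# ---------------------------------------------------------------------------
# calibration study: type-I error and moderation-pattern recovery

def _wilson_ci(k: int, n: int, level: float = 0.95):
    from scipy.stats import norm
    if n == 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (center - half, center + half)


def pattern_recovery_flags(mags: np.ndarray, z: np.ndarray,
                           alpha: float = 0.05) -> dict:
    """Per-replicate checks of the qualitative moderation pattern.

    ``mags``: (reps, n, 4) scored cell magnitudes ordered as CELLS_2X2;
    ``z``: (reps, n) moderator.  Directional claims are checked on the sign
    of the simple-slope estimate; "null" claims require the contrast not to
    reach significance at ``alpha``.  Pattern:

    * low IU (-1 SD): early CS+ > CS-, late difference null;
    * high IU (+1 SD): early difference null, late CS+ > CS-,
      and CS- early > CS- late.
    """
    pe, me, pl, ml = (mags[..., i] for i in range(4))
    sd = z.std(axis=1, ddof=1)
    d_early = batch_simple_regression(pe - me, z)
    d_late = batch_simple_regression(pl - ml, z)
    d_cm_time = batch_simple_regression(me - ml, z)
    e_lo = batch_estimate_at(d_early, -sd)
    e_hi = batch_estimate_at(d_early, sd)
    l_lo = batch_estimate_at(d_late, -sd)
    l_hi = batch_estimate_at(d_late, sd)
    cm_hi = batch_estimate_at(d_cm_time, sd)
    checks = {
        "low_iu_early_csplus_gt_csminus": e_lo[0] > 0,
        "low_iu_late_null": l_lo[3] > alpha,
        "high_iu_early_null": e_hi[3] > alpha,
        "high_iu_late_csplus_gt_csminus": l_hi[0] > 0,
        "high_iu_csminus_early_gt_late": cm_hi[0] > 0,
    }
    checks["full_pattern"] = np.logical_and.reduce(list(checks.values()))
    return checks


def run_calibration_study(n_replicates: int, n_subjects: int = 34,
                          model: AmplitudeEffectModel | None = None,
                          seed=0, alpha: float = 0.05,
                          null_model: bool = False) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the moderated ANCOVA.

    Simulates replicate cohorts at the scored-cell level (the same
    per-trial amplitude model the waveform generator injects; rendering and
    peak detection are validated separately by the scorer-recovery tests),
    fits the contrast regressions, and aggregates rejection and
    pattern-recovery rates with Wilson confidence intervals.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = model or (null_moderation_model() if null_model
                      else default_effect_model())
    rng = np.random.default_rng(seed)
    mags, z = batch_extinction_cell_magnitudes(n_replicates, n_subjects,
                                               model, rng=rng)
    pe, me, pl, ml = (mags[..., i] for i in range(4))
    X = (pe - me) - (pl - ml)
    reject = batch_simple_regression(X, z)["p1"] < alpha
    checks = pattern_recovery_flags(mags, z, alpha)

    rows = []
    def add(metric, flags):
        k = int(np.sum(flags))
        lo, hi = (_wilson_ci(k, n_replicates) if n_replicates > 1
                  else (float("nan"), float("nan")))
        rows.append({"metric": metric, "rate": k / n_replicates,
                     "ci_low": lo, "ci_high": hi,
                     "n_replicates": n_replicates, "n_subjects": n_subjects})

    add("reject_condition_x_time_x_iu", reject)
    for name, flags in checks.items():
        add(name, flags)
    return pd.DataFrame(rows)
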