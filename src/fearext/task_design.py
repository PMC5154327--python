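"""Conditioning-task structure: trial sequences, counterbalancing, timings.

The task has two analyzed phases presented as separate blocks: acquisition
(12 CS+ / 12 CS-, the CS+ paired with an aversive 90 dB scream on every
trial) and extinction (16 CS+ / 16 CS-, both unpaired).  An optional partial
reacquisition phase (16 CS+ of which 4 unpaired, 14 CS-) can be generated
but is never analyzed.  Trial orders are pseudo-randomized so that the same
condition never occurs more than ``max_run_length`` times in a row, and cue
color (blue/yellow) is counterbalanced across subjects.

Each trial unfolds as: CS square (1.5 s; on CS+ acquisition trials the
scream starts 0.5 s after CS onset and lasts 1 s), a jittered blank screen
(3.0-6.45 s), a 4 s uneasiness rating scale, and a second jittered blank
(1.0-2.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConstraintInfeasibleError

PHASES = ("acquisition", "extinction", "reacquisition")
CONDITIONS = ("csplus", "csminus")
CUE_COLORS = ("blue", "yellow")

#: columns of the events table, one row per trial
EVENT_COLUMNS = [
    "subject_id",
    "phase",
    "trial_index",
    "condition",
    "us_present",
    "cue_color",
    "cs_onset_s",
    "rating_onset_s",
]


@dataclass
class DesignConfig:
    """Trial counts, reinforcement and stimulus/response timings."""

    n_acquisition_csplus: int = 12
    n_acquisition_csminus: int = 12
    n_extinction_csplus: int = 16
    n_extinction_csminus: int = 16
    n_reacquisition_csplus: int = 16
    n_reacquisition_csplus_unpaired: int = 4
    n_reacquisition_csminus: int = 14
    include_reacquisition: bool = False
    reinforcement_rate_acquisition: float = 1.0
    max_run_length: int = 3
    cs_duration_s: float = 1.5
    us_onset_offset_s: float = 0.5
    us_duration_s: float = 1.0
    iti_blank_range_s: tuple[float, float] = (3.0, 6.45)
    rating_duration_s: float = 4.0
    post_rating_blank_range_s: tuple[float, float] = (1.0, 2.5)
    inter_phase_gap_s: float = 10.0

    def validate(self) -> None:
        counts = [
            self.n_acquisition_csplus,
            self.n_acquisition_csminus,
            self.n_extinction_csplus,
            self.n_extinction_csminus,
        ]
        if self.include_reacquisition:
            counts += [self.n_reacquisition_csplus, self.n_reacquisition_csminus]
        if any(c <= 0 for c in counts):
            raise ValueError("all trial counts must be > 0")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        if not 0.0 <= self.reinforcement_rate_acquisition <= 1.0:
            raise ValueError("reinforcement rate must be in [0, 1]")
        for lo, hi in (self.iti_blank_range_s, self.post_rating_blank_range_s):
            if lo > hi:
                raise ValueError("interval lower bound exceeds upper bound")
        if not 0 <= self.n_reacquisition_csplus_unpaired <= self.n_reacquisition_csplus:
            raise ValueError("unpaired reacquisition CS+ count out of range")

    def min_trial_duration_s(self) -> float:
        """Shortest possible CS-onset-to-CS-onset spacing."""
        return (
            self.cs_duration_s
            + self.iti_blank_range_s[0]
            + self.rating_duration_s
            + self.post_rating_blank_range_s[0]
        )

    def max_trial_duration_s(self) -> float:
        return (
            self.cs_duration_s
            + self.iti_blank_range_s[1]
            + self.rating_duration_s
            + self.post_rating_blank_range_s[1]
        )


@dataclass
class TrialSpec:
    """One conditioning trial."""

    phase: str
    index_in_phase: int
    condition: str
    us_present: bool
    cue_color: str = "blue"
    cs_onset_s: float = float("nan")
    rating_onset_s: float = float("nan")

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.us_present and self.condition != "csplus":
            raise ValueError("US on a CS- trial")
        if self.phase == "extinction" and self.us_present:
            raise ValueError("extinction trials are unreinforced")


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _max_run_length(labels) -> int:
    longest = run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        prev = lab
        longest = max(longest, run)
    return longest


def _pseudorandom_order(n_plus: int, n_minus: int, max_run: int,
                        rng: np.random.Generator, max_tries: int = 10_000):
    """Uniform draw over condition orders with bounded run length.

    Rejection-samples random permutations until the run-length constraint
    holds.  Raises :class:`ConstraintInfeasibleError` when provably or
    practically infeasible.
    """
    n_major, n_minor = max(n_plus, n_minus), min(n_plus, n_minus)
    if n_major > max_run * (n_minor + 1):
        raise ConstraintInfeasibleError(
            f"cannot order {n_plus} CS+ / {n_minus} CS- with runs <= {max_run}"
        )
    labels = np.array(["csplus"] * n_plus + ["csminus"] * n_minus)
    for _ in range(max_tries):
        order = rng.permutation(labels)
        if _max_run_length(order) <= max_run:
            return list(order)
    raise ConstraintInfeasibleError(
        f"no admissible order found in {max_tries} tries "
        f"({n_plus} CS+ / {n_minus} CS-, runs <= {max_run})"
    )


def generate_trial_sequence(config: DesignConfig, seed=None, rng=None,
                            csplus_color: str = "blue") -> list[TrialSpec]:
    """Generate the ordered trial list for one session (onsets unset).

    Reinforcement: every acquisition CS+ trial carries the US at rate 1.0;
    at lower rates the reinforced subset is an exact count, placed at random.
    Reacquisition (if enabled) pairs all but ``n_reacquisition_csplus_unpaired``
    CS+ trials.
    """
    config.validate()
    if csplus_color not in CUE_COLORS:
        raise ValueError(f"unknown cue color {csplus_color!r}")
    rng = _as_rng(seed, rng)
    csminus_color = CUE_COLORS[1 - CUE_COLORS.index(csplus_color)]

    trials: list[TrialSpec] = []

    def build_phase(phase, n_plus, n_minus, n_plus_reinforced):
        order = _pseudorandom_order(n_plus, n_minus, config.max_run_length, rng)
        plus_positions = [i for i, c in enumerate(order) if c == "csplus"]
        reinforced = set(
            rng.choice(plus_positions, size=n_plus_reinforced, replace=False)
        ) if n_plus_reinforced else set()
        for i, cond in enumerate(order):
            trials.append(TrialSpec(
                phase=phase,
                index_in_phase=i,
                condition=cond,
                us_present=(cond == "csplus" and i in reinforced),
                cue_color=csplus_color if cond == "csplus" else csminus_color,
            ))

    n_reinf = int(round(config.reinforcement_rate_acquisition
                        * config.n_acquisition_csplus))
    build_phase("acquisition", config.n_acquisition_csplus,
                config.n_acquisition_csminus, n_reinf)
    build_phase("extinction", config.n_extinction_csplus,
                config.n_extinction_csminus, 0)
    if config.include_reacquisition:
        build_phase(
            "reacquisition", config.n_reacquisition_csplus,
            config.n_reacquisition_csminus,
            config.n_reacquisition_csplus - config.n_reacquisition_csplus_unpaired,
        )
    return trials


def assign_counterbalance(n_subjects: int, seed=None, rng=None) -> list[str]:
    """CS+ cue color per subject, balanced across the cohort.

    For even ``n_subjects`` exactly half receive blue as CS+; for odd n the
    counts differ by one.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _as_rng(seed, rng)
    half = n_subjects // 2
    colors = ["blue"] * half + ["yellow"] * half
    if n_subjects % 2:
        colors.append(str(rng.choice(CUE_COLORS)))
    return [str(c) for c in rng.permutation(colors)]


def schedule_timings(sequence: list[TrialSpec], config: DesignConfig,
                     seed=None, rng=None) -> list[TrialSpec]:
    """Fill CS and rating-scale onsets by walking the session timeline.

    Jittered blank durations are drawn uniformly from the configured ranges;
    phases are separated by ``inter_phase_gap_s``.  Returns new TrialSpec
    objects; the input is not modified.
    """
    config.validate()
    rng = _as_rng(seed, rng)
    out: list[TrialSpec] = []
    cursor = 0.0
    prev_phase = None
    for trial in sequence:
        if prev_phase is not None and trial.phase != prev_phase:
            cursor += config.inter_phase_gap_s
        prev_phase = trial.phase
        cs_onset = cursor
        blank = rng.uniform(*config.iti_blank_range_s)
        rating_onset = cs_onset + config.cs_duration_s + blank
        post = rng.uniform(*config.post_rating_blank_range_s)
        cursor = rating_onset + config.rating_duration_s + post
        out.append(replace(trial, cs_onset_s=cs_onset, rating_onset_s=rating_onset))
    return out


def trials_to_frame(trials: list[TrialSpec], subject_id=None) -> pd.DataFrame:
    """Events table (one row per trial) from a list of TrialSpec."""
    rows = [{
        "subject_id": subject_id,
        "phase": t.phase,
        "trial_index": t.index_in_phase,
        "condition": t.condition,
        "us_present": t.us_present,
        "cue_color": t.cue_color,
        "cs_onset_s": t.cs_onset_s,
        "rating_onset_s": t.rating_onset_s,
    } for t in trials]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_trials(events: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            phase=r.phase, index_in_phase=int(r.trial_index),
            condition=r.condition, us_present=bool(r.us_present),
            cue_color=r.cue_color, cs_onset_s=float(r.cs_onset_s),
            rating_onset_s=float(r.rating_onset_s),
        )
        for r in events.itertuples(index=False)
    ]


def generate_session(config: DesignConfig, seed=None, rng=None,
                     csplus_color: str = "blue") -> list[TrialSpec]:
    """Convenience: pseudo-randomized sequence with timings filled."""
    rng = _as_rng(seed, rng)
    return schedule_timings(
        generate_trial_sequence(config, rng=rng, csplus_color=csplus_color),
        config, rng=rng,
    )
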