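"""Conditioned-response scores at extinction onset and learner status.

Because acquisition used a 100% reinforcement schedule (CS+ and US are
confounded there), learning is assessed at the start of extinction: the
conditioned response (CR) score is the mean of the first two CS+ trials
minus the mean of the first two CS- trials, computed separately for SCR
magnitude (sqrt scale) and uneasiness ratings.  A positive score indexes a
conditioned response; a subject is a non-learner only when NEITHER measure
is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .scoring import usable_trials

LEARNER = "learner"
NON_LEARNER = "non_learner"


@dataclass
class CrScore:
    subject_id: object
    measure: str  # "scr_magnitude" or "rating"
    value: float


def _first_two_means(values_plus, values_minus, measure, subject_id):
    if len(values_plus) < 2 or len(values_minus) < 2:
        raise InsufficientDataError(
            f"subject {subject_id}: fewer than 2 usable extinction trials per "
            f"condition for {measure}")
    return float(np.mean(values_plus[:2]) - np.mean(values_minus[:2]))


def conditioned_response_score(trials: pd.DataFrame, measure: str,
                               use_post_exclusion: bool = True) -> CrScore:
    """CR score for ONE subject from extinction trials.

    ``trials`` is a scored-trials frame (``measure='scr_magnitude'``, using
    ``amplitude_sqrt``) or a ratings frame (``measure='rating'``).  For SCR,
    the first-of-phase exclusion and artifact rejection apply before the
    "first two" trials are selected (set ``use_post_exclusion=False`` to
    take the first two as presented).
    """
    ext = trials[trials["phase"] == "extinction"].sort_values("trial_index")
    sid = trials["subject_id"].iloc[0] if len(trials) else None
    if measure == "scr_magnitude":
        if use_post_exclusion:
            ext = usable_trials(ext)
        col = "amplitude_sqrt"
    elif measure == "rating":
        col = "rating"
    else:
        raise ValueError(f"unknown measure {measure!r}")
    plus = ext.loc[ext["condition"] == "csplus", col].to_numpy(dtype=float)
    minus = ext.loc[ext["condition"] == "csminus", col].to_numpy(dtype=float)
    return CrScore(sid, measure, _first_two_means(plus, minus, measure, sid))


def classify_learner(cr_scr: CrScore | None, cr_rating: CrScore | None) -> str:
    """Non-learner iff no positive differential response on EITHER measure.

    A missing measure defers to the other; both missing is an error.
    A score of exactly 0 counts as no differential response.
    """
    scores = [c.value for c in (cr_scr, cr_rating) if c is not None]
    if not scores:
        raise InsufficientDataError("both CR scores missing")
    return LEARNER if any(v > 0 for v in scores) else NON_LEARNER


def assess_cohort(scored: pd.DataFrame, ratings: pd.DataFrame | None = None,
                  use_post_exclusion: bool = True) -> pd.DataFrame:
    """CR scores and learner status for every subject.

    Returns columns subject_id, cr_scr, cr_rating, learner_status; a NaN CR
    means that measure was unavailable for the subject.
    """
    sids = sorted(set(scored["subject_id"]))
    rows = []
    for sid in sids:
        cr_s = cr_r = None
        try:
            cr_s = conditioned_response_score(
                scored[scored["subject_id"] == sid], "scr_magnitude",
                use_post_exclusion)
        except InsufficientDataError:
            pass
        if ratings is not None and sid in set(ratings["subject_id"]):
            try:
                cr_r = conditioned_response_score(
                    ratings[ratings["subject_id"] == sid], "rating")
            except InsufficientDataError:
                pass
        rows.append({
            "subject_id": sid,
            "cr_scr": cr_s.value if cr_s else float("nan"),
            "cr_rating": cr_r.value if cr_r else float("nan"),
            "learner_status": classify_learner(cr_s, cr_r),
        })
    return pd.DataFrame(rows)
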