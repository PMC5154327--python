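"""Trough-to-peak scoring of event-related skin conductance responses.

Scoring rules implemented here:

* a response is scored only when the trough-to-peak rise exceeds
  0.03 microSiemens;
* amplitude is the difference between the response onset (trough) and the
  maximum deflection before the signal flattens out or decreases;
* a response counts toward a trial when its onset falls within 0-7 s after
  CS onset (the peak itself may fall later);
* trials with no discernible response are scored zero;
* the first trial of each experimental phase is excluded from averages
  (the start-of-session response is unusually large);
* amplitudes are square-root transformed to reduce skew;
* trials with motion artifacts - transients visible in BOTH the
  electrodermal and the pulse/interbeat channel - are discarded;
* condition magnitudes average the sqrt-transformed values *including*
  zero-response trials; extinction is split into early/late halves (first
  8 vs last 8 trials per condition).

The scorer is sampling-rate agnostic: smoothing is defined by a cutoff
frequency and thresholds by physical units (uS, uS/s, seconds).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as ssig

from .errors import MissingCellError
from .synthetic import PhysioRecording, cell_of_trial

SCORED_COLUMNS = [
    "subject_id", "phase", "trial_index", "condition", "cell",
    "amplitude_uS", "amplitude_sqrt", "onset_latency_s",
    "is_zero", "artifact", "excluded_first_trial",
]


@dataclass
class ScoringConfig:
    """Thresholds and windows of the trough-to-peak scorer."""

    min_amplitude_uS: float = 0.03
    onset_window_s: tuple[float, float] = (0.0, 7.0)
    smoothing_cutoff_hz: float = 2.0
    rise_threshold_uS_per_s: float = 0.01
    peak_flatten_eps_uS_per_s: float = 0.001
    flatten_sustain_s: float = 0.2
    peak_search_limit_s: float = 10.0
    artifact_z_threshold: float = 8.0
    artifact_highpass_hz: float = 5.0
    artifact_scale_floor_uS: float = 0.005
    pick: str = "first"  # or "largest": which qualifying SCR to keep

    def validate(self) -> None:
        if self.min_amplitude_uS <= 0:
            raise ValueError("min_amplitude_uS must be > 0")
        lo, hi = self.onset_window_s
        if lo >= hi:
            raise ValueError("onset window lower bound must be < upper bound")
        if self.peak_search_limit_s <= 0:
            raise ValueError("peak_search_limit_s must be > 0")
        if self.pick not in ("first", "largest"):
            raise ValueError("pick must be 'first' or 'largest'")


def sqrt_transform(amplitude_uS):
    """Square-root transform of SCR amplitude; 0 maps to 0."""
    amp = np.asarray(amplitude_uS, dtype=float)
    if np.any(amp < 0):
        raise ValueError("SCR amplitude cannot be negative")
    out = np.sqrt(amp)
    return float(out) if out.ndim == 0 else out


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass; identity above Nyquist."""
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return np.asarray(x, dtype=float)
    b, a = ssig.butter(2, cutoff_hz / (fs / 2))
    return ssig.filtfilt(b, a, x)


def _candidate_responses(s: np.ndarray, fs: float, config: ScoringConfig,
                         lo: int, hi: int, cap: int):
    """Trough-to-peak candidates whose onset index lies in [lo, hi).

    ``s`` is the smoothed signal; the peak search runs to ``cap``.
    Yields (onset_idx, peak_idx, amplitude).
    """
    d = np.gradient(s, 1.0 / fs)
    rising = d > config.rise_threshold_uS_per_s
    sustain = max(1, int(round(config.flatten_sustain_s * fs)))
    i = lo
    while i < hi:
        if not rising[i] or (i > 0 and rising[i - 1]):
            i += 1
            continue
        # onset: walk back (at most 1 s) to the local minimum before the rise
        onset = i
        back_limit = max(0, i - int(round(1.0 * fs)))
        while onset > back_limit and s[onset - 1] <= s[onset]:
            onset -= 1
        # peak: advance until decrease or sustained flattening, capped
        j = i
        stop = min(cap, len(s) - 1)
        flat = 0
        while j < stop:
            if d[j] < 0:
                break
            flat = flat + 1 if d[j] <= config.peak_flatten_eps_uS_per_s else 0
            if flat >= sustain:
                break
            j += 1
        peak = onset + int(np.argmax(s[onset:j + 1]))
        amp = float(s[peak] - s[onset])
        if amp > 0:
            yield onset, peak, amp
        i = max(i + 1, j)


def detect_scr(recording_or_eda, cs_onset_s: float,
               config: ScoringConfig | None = None, fs: float | None = None,
               search_end_s: float | None = None):
    """Score one trial: returns ``(amplitude_uS, onset_latency_s)``.

    ``amplitude_uS`` is 0.0 (with latency NaN) when no candidate rise with
    onset inside the 0-7 s post-CS window reaches the 0.03 uS threshold.
    ``search_end_s`` bounds the peak search (typically the next CS onset).
    """
    config = config or ScoringConfig()
    config.validate()
    if isinstance(recording_or_eda, PhysioRecording):
        eda, fs = recording_or_eda.eda, recording_or_eda.sampling_rate_hz
    else:
        eda = np.asarray(recording_or_eda, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a raw array")
    s = lowpass(eda, fs, config.smoothing_cutoff_hz)
    return _detect_scr_smoothed(s, fs, cs_onset_s, config, search_end_s)


def _detect_scr_smoothed(s: np.ndarray, fs: float, cs_onset_s: float,
                         config: ScoringConfig,
                         search_end_s: float | None = None):
    win_lo = cs_onset_s + config.onset_window_s[0]
    win_hi = cs_onset_s + config.onset_window_s[1]
    if win_lo < 0 or win_hi > len(s) / fs:
        raise ValueError("scoring window outside the recording")
    lo = int(round(win_lo * fs))
    hi = min(int(round(win_hi * fs)), len(s) - 1)
    cap_t = win_lo + config.peak_search_limit_s
    if search_end_s is not None:
        cap_t = min(cap_t, search_end_s)
    cap = min(int(round(cap_t * fs)), len(s) - 1)
    best = None
    for onset, peak, amp in _candidate_responses(s, fs, config, lo, hi, cap):
        if amp < config.min_amplitude_uS:
            continue
        if config.pick == "first":
            best = (onset, peak, amp)
            break
        if best is None or amp > best[2]:
            best = (onset, peak, amp)
    if best is None:
        return 0.0, float("nan")
    onset, _, amp = best
    return amp, onset / fs - cs_onset_s


def flag_artifact(recording: PhysioRecording, window_s: tuple[float, float],
                  config: ScoringConfig | None = None) -> bool:
    """Motion-artifact flag for one trial window.

    Flags only when the robust z of the high-pass residual exceeds the
    threshold in BOTH the electrodermal and the pulse channel; with no pulse
    channel the conjunctive rule cannot fire and a warning is emitted.
    """
    config = config or ScoringConfig()
    if recording.pulse is None:
        warnings.warn("no pulse channel: artifact flagging disabled "
                      "(the rule requires distortions in both channels)")
        return False
    fs = recording.sampling_rate_hz
    lo = max(int(round(window_s[0] * fs)), 0)
    hi = min(int(round(window_s[1] * fs)), len(recording.eda))
    if hi <= lo:
        return False

    def max_robust_z(x, floor):
        resid = x - lowpass(x, fs, config.artifact_highpass_hz)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(1.4826 * mad, floor)
        return float(np.max(np.abs(resid[lo:hi])) / scale)

    z_eda = max_robust_z(recording.eda, config.artifact_scale_floor_uS)
    ptp = float(np.ptp(recording.pulse))
    z_pulse = max_robust_z(recording.pulse, max(1e-3 * ptp, 1e-9))
    return z_eda > config.artifact_z_threshold and z_pulse > config.artifact_z_threshold


def score_session(recording: PhysioRecording, events: pd.DataFrame,
                  config: ScoringConfig | None = None,
                  n_early: int = 8) -> pd.DataFrame:
    """Score every trial of one subject's session.

    Returns one row per trial with amplitude (uS and sqrt scale), onset
    latency, zero/artifact flags and the first-of-phase exclusion flag.
    """
    config = config or ScoringConfig()
    config.validate()
    events = events.sort_values("cs_onset_s").reset_index(drop=True)
    onsets = events["cs_onset_s"].to_numpy(dtype=float)
    fs = recording.sampling_rate_hz
    smoothed = lowpass(recording.eda, fs, config.smoothing_cutoff_hz)

    # artifact residuals and robust scales, computed once per session
    if recording.pulse is None:
        warnings.warn("no pulse channel: artifact flagging disabled "
                      "(the rule requires distortions in both channels)")
        resid = None
    else:
        def robust_z(x, floor):
            r = x - lowpass(x, fs, config.artifact_highpass_hz)
            mad = np.median(np.abs(r - np.median(r)))
            return np.abs(r) / max(1.4826 * mad, floor)
        ptp = float(np.ptp(recording.pulse))
        resid = (robust_z(recording.eda, config.artifact_scale_floor_uS),
                 robust_z(recording.pulse, max(1e-3 * ptp, 1e-9)))

    rank: dict = {}
    seen_phase: set = set()
    rows = []
    for i, ev in events.iterrows():
        key = (ev["phase"], ev["condition"])
        r = rank.get(key, 0)
        rank[key] = r + 1
        nxt = onsets[i + 1] if i + 1 < len(onsets) else None
        amp, lat = _detect_scr_smoothed(smoothed, fs, float(ev["cs_onset_s"]),
                                        config, search_end_s=nxt)
        first = ev["phase"] not in seen_phase
        seen_phase.add(ev["phase"])
        if resid is None:
            art = False
        else:
            lo = max(int(round(ev["cs_onset_s"] * fs)), 0)
            hi = min(int(round((ev["cs_onset_s"] + config.onset_window_s[1]) * fs)),
                     len(recording.eda))
            art = bool(
                np.max(resid[0][lo:hi]) > config.artifact_z_threshold
                and np.max(resid[1][lo:hi]) > config.artifact_z_threshold)
        rows.append({
            "subject_id": ev.get("subject_id"),
            "phase": ev["phase"], "trial_index": int(ev["trial_index"]),
            "condition": ev["condition"],
            "cell": cell_of_trial(ev["phase"], ev["condition"], r, n_early),
            "amplitude_uS": amp, "amplitude_sqrt": sqrt_transform(amp),
            "onset_latency_s": lat, "is_zero": amp == 0.0,
            "artifact": art, "excluded_first_trial": first,
        })
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def usable_trials(scored: pd.DataFrame) -> pd.DataFrame:
    """Trials that enter averages: not artifact, not first-of-phase."""
    return scored[~scored["artifact"] & ~scored["excluded_first_trial"]]


def compute_cell_magnitudes(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean sqrt magnitudes (zeros included) for ONE subject.

    The early/late split is by presentation order within condition (set when
    the session was scored); excluded and artifact trials are dropped from
    the averages but keep their presentation rank.  Raises
    :class:`MissingCellError` when a cell has no usable trial.
    """
    use = usable_trials(scored)
    rows = []
    for cell, grp in use.groupby("cell"):
        rows.append({"cell": cell,
                     "magnitude_sqrt_uS": float(grp["amplitude_sqrt"].mean()),
                     "n_trials": int(len(grp))})
    present = {r["cell"] for r in rows}
    expected = set(scored["cell"].unique())
    missing = expected - present
    if missing:
        sid = scored["subject_id"].iloc[0] if len(scored) else "?"
        raise MissingCellError(
            f"subject {sid}: no usable trials in cell(s) {sorted(missing)}")
    return pd.DataFrame(rows).sort_values("cell").reset_index(drop=True)


def cohort_cell_magnitudes(scored: pd.DataFrame, on_missing: str = "drop"):
    """Cell magnitudes per subject, wide format (one column per cell).

    Subjects with an empty cell are dropped (``on_missing='drop'``, with the
    dropped ids returned) or raise (``'raise'``).  Returns
    ``(wide_frame, dropped_ids)``.
    """
    frames, dropped = [], []
    for sid, grp in scored.groupby("subject_id"):
        try:
            mags = compute_cell_magnitudes(grp)
        except MissingCellError:
            if on_missing == "raise":
                raise
            dropped.append(sid)
            continue
        row = mags.set_index("cell")["magnitude_sqrt_uS"]
        row["subject_id"] = sid
        frames.append(row)
    wide = pd.DataFrame(frames).reset_index(drop=True)
    if len(wide):
        wide["subject_id"] = wide["subject_id"].astype(scored["subject_id"].dtype)
    return wide, dropped


def reduce_ratings(ratings: pd.DataFrame, n_early: int = 8) -> pd.DataFrame:
    """Per-subject mean rating for each design cell.

    No first-trial exclusion is applied (the exclusion rule concerns SCR
    only).  Extinction uses the same early/late split as the SCR cells.
    Raises :class:`MissingCellError` if a subject lacks a whole cell.
    """
    rows = []
    for sid, grp in ratings.groupby("subject_id"):
        grp = grp.sort_values(["phase", "trial_index"])
        rank: dict = {}
        cells: dict = {}
        for ev in grp.itertuples(index=False):
            key = (ev.phase, ev.condition)
            r = rank.get(key, 0)
            rank[key] = r + 1
            cell = cell_of_trial(ev.phase, ev.condition, r, n_early)
            cells.setdefault(cell, []).append(ev.rating)
        row = {c: float(np.mean(v)) for c, v in cells.items()}
        expected = {cell_of_trial(p, c, r, n_early)
                    for (p, c), n in rank.items() for r in range(n)}
        if expected - set(row):
            raise MissingCellError(
                f"subject {sid}: missing rating cell(s) {sorted(expected - set(row))}")
        row["subject_id"] = sid
        rows.append(row)
    return pd.DataFrame(rows)
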