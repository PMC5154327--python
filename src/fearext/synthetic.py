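"""Synthetic cohorts: questionnaires, electrodermal recordings, ratings.

The generator emulates the study conditions of a two-phase differential
conditioning experiment: 38 subjects, 24 acquisition trials (12 CS+/12 CS-,
100% reinforced) and 32 extinction trials (16/16, unreinforced), continuous
electrodermal activity built from event-locked skin-conductance-response
(SCR) kernels, an optional pulse channel used only to corroborate motion
artifacts, and per-trial 1-9 uneasiness ratings.

Amplitude model
---------------
Scored SCR data in this paradigm are sqrt-transformed *magnitudes*: condition
means over trials that include zero-response trials.  The generator is
therefore calibrated on that scale.  Each design cell has a target
sqrt-magnitude (defaults follow the published cell-mean structure) and an
intolerance-of-uncertainty (IU) moderation slope per SD of IU; both are
converted numerically into raw-microsiemens per-trial amplitude means such
that scoring the synthetic signals reproduces the targets.  Zero-response
trials occur with a per-phase probability calibrated so the *scored* zero
proportions match the published 33% (acquisition) / 53% (extinction) rates
after accounting for sub-threshold (<0.03 uS) draws.

Ground truth (injected amplitude, latency, artifact labels) is retained for
every trial so that scorer-recovery tests can regress detected against
injected values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .task_design import (
    DesignConfig, TrialSpec, assign_counterbalance, generate_session,
    trials_to_frame,
)

# ---------------------------------------------------------------------------
# design cells

ACQ_CELLS = ("acquisition_csplus", "acquisition_csminus")
EXT_CELLS = ("csplus_early", "csminus_early", "csplus_late", "csminus_late")
ALL_CELLS = ACQ_CELLS + EXT_CELLS

#: published cell-mean structure on the sqrt-magnitude scale (sqrt(uS))
TABLE_MAGNITUDE_MEANS = {
    "acquisition_csplus": 0.79,
    "acquisition_csminus": 0.32,
    "csplus_early": 0.32,
    "csminus_early": 0.29,
    "csplus_late": 0.29,
    "csminus_late": 0.22,
}

#: IU moderation of extinction magnitudes, sqrt(uS) per SD of IU.  The two
#: equality constraints of the moderation pattern (CS+ == CS- early at +1 SD,
#: CS+ == CS- late at -1 SD) combined with the grand cell means force
#: s(cs- early) - s(cs+ early) = 0.03 and s(cs+ late) - s(cs- late) = 0.07;
#: the remaining free magnitudes are fixed once at +0.03 / +0.035.
DEFAULT_MAGNITUDE_IU_SLOPES = {
    "acquisition_csplus": 0.0,
    "acquisition_csminus": 0.0,
    "csplus_early": 0.03,
    "csminus_early": 0.06,
    "csplus_late": 0.035,
    "csminus_late": -0.035,
}

#: proportions of trials scored as zero responses, per phase
SCORED_ZERO_RATES = {"acquisition": 0.33, "extinction": 0.53,
                     "reacquisition": 0.33}

#: published per-trial rating means (1-9 uneasiness scale)
TABLE_RATING_MEANS = {
    "acquisition_csplus": 6.14,
    "acquisition_csminus": 3.10,
    "csplus_early": 3.12,
    "csminus_early": 2.41,
    "csplus_late": 2.28,
    "csminus_late": 1.86,
}


def cell_of_trial(phase: str, condition: str, rank_in_condition: int,
                  n_early: int = 8) -> str:
    """Design cell of a trial given its presentation rank within condition."""
    if phase == "extinction":
        half = "early" if rank_in_condition < n_early else "late"
        return f"{condition}_{half}"
    return f"acquisition_{condition}"


# ---------------------------------------------------------------------------
# SCR kernel

@dataclass
class KernelParams:
    """Canonical bi-exponential SCR shape plus onset-latency distribution."""

    tau_rise: float = 0.75
    tau_decay: float = 2.5
    latency_mean_s: float = 1.5
    latency_sd_s: float = 0.3

    def validate(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.latency_sd_s < 0:
            raise ValueError("latency SD must be >= 0")

    @property
    def peak_time_s(self) -> float:
        """Analytic argmax of the bi-exponential difference."""
        tr, td = self.tau_rise, self.tau_decay
        return math.log(td / tr) * td * tr / (td - tr)

    @property
    def peak_value(self) -> float:
        tp = self.peak_time_s
        return math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)


def scr_kernel(t, params: KernelParams):
    """Unit-peak bi-exponential SCR kernel; zero for t < 0."""
    params.validate()
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = (np.exp(-tp / params.tau_decay)
                - np.exp(-tp / params.tau_rise)) / params.peak_value
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# questionnaires

@dataclass(frozen=True)
class Instrument:
    """A sum-scored questionnaire with a bounded range."""

    name: str
    mean: float
    sd: float
    minimum: float
    maximum: float


#: published cohort descriptives; truncation at the instruments' score ranges
DEFAULT_INSTRUMENTS = (
    Instrument("iu", 63.92, 19.56, 27.0, 135.0),
    Instrument("stai", 44.02, 9.33, 20.0, 80.0),
    Instrument("pswq", 51.60, 11.56, 16.0, 80.0),
)

#: inter-measure correlations are not published; 0.6 between all pairs is a
#: documented assumption consistent with "correlational consistency" among
#: the anxiety measures.
DEFAULT_QUESTIONNAIRE_CORRELATION = 0.6


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) whose [lo, hi]-truncated moments hit mean/sd."""

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sstats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def default_correlation_matrix(k: int, rho: float = DEFAULT_QUESTIONNAIRE_CORRELATION):
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


def sample_questionnaires(n: int, instruments=DEFAULT_INSTRUMENTS,
                          correlation=None, seed=None, rng=None) -> pd.DataFrame:
    """Correlated truncated-normal questionnaire panels for ``n`` subjects.

    Marginals are truncated normals whose post-truncation moments match each
    instrument's configured mean/SD (parent parameters solved numerically);
    the dependence structure is a Gaussian copula with the given correlation
    matrix.  Scores are rounded to integers, as questionnaire sums are.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    k = len(instruments)
    corr = (default_correlation_matrix(k) if correlation is None
            else np.asarray(correlation, dtype=float))
    if corr.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive semi-definite") from exc

    z = rng.standard_normal((n, k)) @ chol.T
    u = sstats.norm.cdf(z)
    cols = {}
    for j, inst in enumerate(instruments):
        mu, sigma = _truncnorm_parent(inst.mean, inst.sd, inst.minimum, inst.maximum)
        a, b = (inst.minimum - mu) / sigma, (inst.maximum - mu) / sigma
        x = sstats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sigma)
        cols[inst.name] = np.round(x).astype(int)
    out = pd.DataFrame(cols)
    out.insert(0, "subject_id", np.arange(n))
    return out


def iu_zscore(iu, instruments=DEFAULT_INSTRUMENTS):
    """Standardize IU against the configured population mean/SD (not the
    sample), so a subject's effect structure is invariant to cohort size."""
    inst = next(i for i in instruments if i.name == "iu")
    return (np.asarray(iu, dtype=float) - inst.mean) / inst.sd


# ---------------------------------------------------------------------------
# amplitude effect model and its calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _expect_gauss(func, mean, sd):
    """E[func(N(mean, sd))] by Gauss-Hermite quadrature (vector mean ok)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return func(mean)
    x = mean[..., None] + math.sqrt(2.0) * sd * _GH_NODES
    return (func(x) @ _GH_WEIGHTS) / math.sqrt(math.pi)


@dataclass
class AmplitudeEffectModel:
    """Per-cell raw SCR amplitude means (uS) with IU moderation.

    ``cell_means``/``iu_slopes`` are on the raw-amplitude scale at the
    average subject; ``zero_prob`` is the *injected* per-phase probability of
    a no-response trial.  ``magnitude_means``/``magnitude_iu_slopes`` record
    the sqrt-magnitude targets the raw values were calibrated against.
    """

    cell_means: dict[str, float]
    iu_slopes: dict[str, float]
    zero_prob: dict[str, float]
    amplitude_noise_sd: float = 0.10
    subject_sd: float = 0.12
    detection_threshold_uS: float = 0.03
    magnitude_means: dict[str, float] | None = None
    magnitude_iu_slopes: dict[str, float] | None = None

    def validate(self) -> None:
        if any(v < 0 for v in self.cell_means.values()):
            raise ValueError("cell means must be >= 0")
        if any(not 0 <= p <= 1 for p in self.zero_prob.values()):
            raise ValueError("zero probabilities must lie in [0, 1]")

    @classmethod
    def from_magnitude_targets(cls, magnitude_means=None, magnitude_iu_slopes=None,
                               scored_zero_rates=None, amplitude_noise_sd=0.10,
                               subject_sd=0.12, detection_threshold_uS=0.03):
        mags = dict(magnitude_means or TABLE_MAGNITUDE_MEANS)
        slopes = dict(magnitude_iu_slopes or DEFAULT_MAGNITUDE_IU_SLOPES)
        zero_rates = dict(scored_zero_rates or SCORED_ZERO_RATES)
        raw_means, raw_slopes, p_inj = _calibrate_raw_model(
            mags, slopes, zero_rates, amplitude_noise_sd, subject_sd,
            detection_threshold_uS)
        return cls(cell_means=raw_means, iu_slopes=raw_slopes, zero_prob=p_inj,
                   amplitude_noise_sd=amplitude_noise_sd, subject_sd=subject_sd,
                   detection_threshold_uS=detection_threshold_uS,
                   magnitude_means=mags, magnitude_iu_slopes=slopes)

    def subject_cell_mean(self, cell: str, z_iu: float, subject_offset: float = 0.0):
        """Raw nonzero-amplitude mean for one subject and cell (>= 0)."""
        return max(0.0, self.cell_means[cell]
                   + self.iu_slopes[cell] * z_iu + subject_offset)

    def expected_magnitude(self, cell: str, z_iu: float = 0.0) -> float:
        """Model-implied scored sqrt-magnitude (zeros included) for a cell."""
        phase = "acquisition" if cell.startswith("acquisition") else "extinction"
        u = self.cell_means[cell] + self.iu_slopes[cell] * z_iu
        g = _make_scored_sqrt_expectation(self.amplitude_noise_sd,
                                          self.detection_threshold_uS)
        val = _expect_gauss(lambda d: g(np.maximum(0.0, u + d)), 0.0,
                            self.subject_sd)
        return float((1.0 - self.zero_prob[phase]) * val)


def _make_scored_sqrt_expectation(noise_sd: float, threshold: float):
    """g(A) = E[sqrt(amp) * 1{amp >= threshold}], amp = max(0, N(A, sd)),
    i.e. the expected scored sqrt value of a nonzero-injected trial."""

    def g(A):
        def val(x):
            x = np.maximum(x, 0.0)
            return np.where(x >= threshold, np.sqrt(x), 0.0)
        return _expect_gauss(val, A, noise_sd)

    return g


def _make_subthreshold_prob(noise_sd: float, threshold: float):
    """q(A) = P(max(0, N(A, sd)) < threshold): a nonzero-injected trial that
    the scorer would still call a zero response."""

    def q(A):
        A = np.asarray(A, dtype=float)
        if noise_sd == 0:
            return (A < threshold).astype(float)
        return sstats.norm.cdf((threshold - A) / noise_sd)

    return q


def _calibrate_raw_model(magnitude_means, magnitude_iu_slopes, scored_zero_rates,
                         noise_sd, subject_sd, threshold):
    """Solve raw cell means/slopes and injected zero probabilities.

    For each cell the raw amplitude mean at z = -1, +1 is found by inverting
    M(u) = (1 - p_inj) * E_d[g(max(0, u + d))] against the magnitude target;
    the raw mean/slope are the midpoint/half-difference (the model is linear
    in z on the raw scale).  The injected zero probability is then adjusted
    so the scored zero proportion (injected zeros + sub-threshold draws)
    matches the published per-phase rate; means and probabilities are
    iterated to convergence.
    """
    g = _make_scored_sqrt_expectation(noise_sd, threshold)
    qfun = _make_subthreshold_prob(noise_sd, threshold)

    def pop_mag(u, p_inj):
        # population magnitude: subject offsets integrated out
        val = _expect_gauss(lambda d: g(np.maximum(0.0, u + d)), 0.0, subject_sd)
        return (1.0 - p_inj) * float(val)

    def invert(target, p_inj):
        if target <= 0:
            return 0.0
        hi = 5.0
        while pop_mag(hi, p_inj) < target:
            hi *= 2.0
            if hi > 1e4:
                raise RuntimeError("magnitude target not attainable")
        return optimize.brentq(lambda u: pop_mag(u, p_inj) - target, 0.0, hi,
                               xtol=1e-10)

    phase_of = {c: ("acquisition" if c.startswith("acquisition") else "extinction")
                for c in magnitude_means}
    p_inj = {ph: scored_zero_rates.get(ph, 0.33)
             for ph in set(phase_of.values()) | {"reacquisition"}}
    raw_means, raw_slopes = {}, {}
    for _ in range(4):
        for cell, m in magnitude_means.items():
            s = magnitude_iu_slopes.get(cell, 0.0)
            p = p_inj[phase_of[cell]]
            lo_u = invert(max(m - s, 0.0), p)
            hi_u = invert(m + s, p)
            raw_means[cell] = 0.5 * (lo_u + hi_u)
            raw_slopes[cell] = 0.5 * (hi_u - lo_u)
        # scored zero rate = p_inj + (1 - p_inj) * mean sub-threshold prob
        new_p = dict(p_inj)
        for ph in set(phase_of.values()):
            cells = [c for c in magnitude_means if phase_of[c] == ph]
            qs = [float(_expect_gauss(
                lambda d, c=c: qfun(np.maximum(0.0, raw_means[c] + d)),
                0.0, subject_sd)) for c in cells]
            qbar = float(np.mean(qs))
            target = scored_zero_rates.get(ph, 0.33)
            new_p[ph] = min(max((target - qbar) / (1.0 - qbar), 0.0), 1.0)
        if all(abs(new_p[ph] - p_inj[ph]) < 1e-6 for ph in new_p):
            p_inj = new_p
            break
        p_inj = new_p
    p_inj.setdefault("reacquisition", p_inj.get("acquisition", 0.33))
    return raw_means, raw_slopes, p_inj


@lru_cache(maxsize=1)
def default_effect_model() -> AmplitudeEffectModel:
    """Default moderated effect model calibrated to the published cell means."""
    return AmplitudeEffectModel.from_magnitude_targets()


@lru_cache(maxsize=1)
def null_moderation_model() -> AmplitudeEffectModel:
    """Same cell means but all IU slopes zero (for type-I error studies)."""
    return AmplitudeEffectModel.from_magnitude_targets(
        magnitude_iu_slopes={c: 0.0 for c in TABLE_MAGNITUDE_MEANS})


# ---------------------------------------------------------------------------
# per-trial ground truth and waveform rendering

TRUTH_COLUMNS = ["subject_id", "phase", "trial_index", "condition", "cell",
                 "true_amplitude_uS", "true_latency_s", "artifact"]


def draw_trial_truth(trials: list[TrialSpec], z_iu: float,
                     model: AmplitudeEffectModel, kernel: KernelParams,
                     rng: np.random.Generator, subject_id=None,
                     n_early: int = 8) -> pd.DataFrame:
    """Draw injected amplitude/latency for every trial of one subject.

    A single subject-level responsiveness offset (SD ``model.subject_sd``)
    shifts all cell means; per-trial amplitudes are zero with the phase's
    injected zero probability, otherwise truncated-normal around the
    subject's cell mean.  These draws do not depend on the sampling rate.
    """
    model.validate()
    kernel.validate()
    subj_offset = rng.normal(0.0, model.subject_sd) if model.subject_sd else 0.0
    rank = {}
    rows = []
    for t in trials:
        key = (t.phase, t.condition)
        r = rank.get(key, 0)
        rank[key] = r + 1
        cell = cell_of_trial(t.phase, t.condition, r, n_early)
        if cell in model.cell_means:
            mean = model.subject_cell_mean(cell, z_iu, subj_offset)
        else:  # reacquisition cells reuse the acquisition means
            mean = model.subject_cell_mean(
                f"acquisition_{t.condition}", z_iu, subj_offset)
        zero = rng.uniform() < model.zero_prob.get(t.phase, 0.0)
        amp = 0.0 if zero else max(0.0, rng.normal(mean, model.amplitude_noise_sd))
        lat = float(np.clip(rng.normal(kernel.latency_mean_s, kernel.latency_sd_s),
                            0.1, None))
        rows.append({
            "subject_id": subject_id, "phase": t.phase,
            "trial_index": t.index_in_phase, "condition": t.condition,
            "cell": cell, "true_amplitude_uS": amp, "true_latency_s": lat,
            "artifact": False,
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


@dataclass
class PhysioRecording:
    """Uniformly sampled physiological channels with synthetic ground truth."""

    sampling_rate_hz: float
    eda: np.ndarray
    pulse: np.ndarray | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        if self.pulse is not None and len(self.pulse) != len(self.eda):
            raise ValueError("eda and pulse must have equal length")

    @property
    def duration_s(self) -> float:
        return len(self.eda) / self.sampling_rate_hz

    def time(self) -> np.ndarray:
        return np.arange(len(self.eda)) / self.sampling_rate_hz


def render_recording(trials: list[TrialSpec], truth: pd.DataFrame,
                     kernel: KernelParams, fs: float, tonic_level: float,
                     drift_sd: float, noise_sd: float,
                     rng: np.random.Generator, pad_s: float = 15.0,
                     ) -> PhysioRecording:
    """Render EDA + pulse waveforms from scheduled trials and truth draws.

    EDA = tonic level + slow tonic drift (a Brownian walk of ``drift_sd``
    uS per sqrt-second, band-limited below ~0.05 Hz: tonic level changes
    over minutes, not within a scoring window) + sum of amplitude-scaled
    SCR kernels + white measurement noise.
    The pulse channel is a noisy ~70 bpm oscillation carrying no information
    except during injected artifacts.
    """
    if fs < 20:
        raise ValueError("sampling rate too low for the SCR kernel (need >= 20 Hz)")
    end = max(t.rating_onset_s for t in trials) + 4.0 + pad_s
    n = int(round(end * fs))
    tgrid = np.arange(n) / fs
    eda = np.full(n, float(tonic_level))
    if drift_sd > 0:
        from scipy import signal as ssig
        walk = np.cumsum(rng.normal(0.0, drift_sd / math.sqrt(fs), n))
        b, a = ssig.butter(2, 0.05 / (fs / 2))
        eda += ssig.filtfilt(b, a, walk)
    amps = truth["true_amplitude_uS"].to_numpy()
    lats = truth["true_latency_s"].to_numpy()
    support = int(round(25.0 * fs))  # kernel support; < 5e-5 of peak beyond
    for trial, amp, lat in zip(trials, amps, lats):
        if amp <= 0:
            continue
        i0 = int(round((trial.cs_onset_s + lat) * fs))
        i1 = min(i0 + support, n)
        if i0 >= n:
            continue
        tt = tgrid[i0:i1] - (trial.cs_onset_s + lat)
        eda[i0:i1] += amp * scr_kernel(tt, kernel)
    if noise_sd > 0:
        eda += rng.normal(0.0, noise_sd, n)
    eda = np.maximum(eda, 0.0)

    hr_hz = 70.0 / 60.0
    pulse = 0.5 * np.sin(2 * math.pi * hr_hz * tgrid
                         + 0.3 * np.sin(2 * math.pi * 0.08 * tgrid))
    pulse += rng.normal(0.0, 0.02, n)
    return PhysioRecording(sampling_rate_hz=fs, eda=eda, pulse=pulse,
                           truth=truth.copy())


def simulate_recording(trials: list[TrialSpec], z_iu: float,
                       model: AmplitudeEffectModel | None = None,
                       kernel: KernelParams | None = None,
                       fs: float = 50.0, tonic_level: float = 2.0,
                       drift_sd: float = 0.02, noise_sd: float = 0.01,
                       seed=None, subject_id=None) -> PhysioRecording:
    """Draw trial truth and render one subject's recording.

    Truth draws and waveform noise use separate child streams of ``seed``,
    so the injected amplitudes are identical across sampling rates.
    """
    model = model or default_effect_model()
    kernel = kernel or KernelParams()
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    truth_rng, render_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    truth = draw_trial_truth(trials, z_iu, model, kernel, truth_rng,
                             subject_id=subject_id)
    return render_recording(trials, truth, kernel, fs, tonic_level,
                            drift_sd, noise_sd, render_rng)


def inject_artifacts(recording: PhysioRecording, trial_indices,
                     trials: list[TrialSpec], magnitude: float = 1.0,
                     seed=None, rng=None, width_s: float = 0.1) -> PhysioRecording:
    """Add sharp motion transients to BOTH channels on the given trials.

    ``trial_indices`` are positional indices into ``trials``; the transient
    (a triangular bump of the given uS magnitude) lands at a random time in
    the trial's scoring window and the truth table gains artifact labels.
    Returns a new recording; the input is unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = sorted(set(int(i) for i in trial_indices))
    if any(i < 0 or i >= len(trials) for i in idx):
        raise ValueError("trial index out of range")
    eda = recording.eda.copy()
    pulse = None if recording.pulse is None else recording.pulse.copy()
    truth = recording.truth.copy() if recording.truth is not None else None
    fs = recording.sampling_rate_hz
    half = max(1, int(round(width_s / 2 * fs)))
    bump = magnitude * (1.0 - np.abs(np.arange(-half, half + 1)) / half)
    for i in idx:
        t0 = trials[i].cs_onset_s + rng.uniform(0.5, 6.0)
        c = int(round(t0 * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, len(eda))
        seg = bump[lo - (c - half): hi - (c - half)]
        eda[lo:hi] += seg
        if pulse is not None:
            pulse[lo:hi] += seg
        if truth is not None:
            truth.iloc[i, truth.columns.get_loc("artifact")] = True
    return PhysioRecording(sampling_rate_hz=fs, eda=eda, pulse=pulse, truth=truth)


# ---------------------------------------------------------------------------
# ratings

@dataclass
class RatingModel:
    """Latent-normal model for 1-9 uneasiness ratings.

    Per-trial latent value = calibrated cell mean + subject intercept
    + (subject conditioning-strength scale - 1) * cell deviation
    + IU slope * z(IU) + trial noise; observed rating = round + clamp to 1-9.
    Cell means are calibrated so the post-round/clamp expectation matches
    the configured target (identity when all noise terms are zero).
    """

    cell_means: dict[str, float] = field(
        default_factory=lambda: dict(TABLE_RATING_MEANS))
    iu_slopes: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in TABLE_RATING_MEANS})
    subject_sd: float = 0.8
    scale_sd: float = 0.6
    noise_sd: float = 1.0

    def latent_sd(self, cell: str) -> float:
        dev = self.cell_means[cell] - float(np.mean(list(self.cell_means.values())))
        return math.sqrt(self.subject_sd ** 2 + (self.scale_sd * dev) ** 2
                         + self.noise_sd ** 2)

    def calibrated_latent_means(self) -> dict[str, float]:
        return {c: _calibrate_rating_latent(m, self.latent_sd(c))
                for c, m in self.cell_means.items()}


def expected_observed_rating(latent_mean: float, latent_sd: float) -> float:
    """E[round+clamp(N(mu, sd))] on the 1..9 scale."""
    if latent_sd == 0:
        return float(np.clip(np.round(latent_mean), 1, 9))
    edges = np.arange(1.5, 9.0)  # 1.5 .. 8.5
    cdf = sstats.norm.cdf((edges - latent_mean) / latent_sd)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return float(np.sum(np.arange(1, 10) * probs))


def _calibrate_rating_latent(target: float, latent_sd: float) -> float:
    if latent_sd == 0:
        return target
    lo_val = expected_observed_rating(-20.0, latent_sd)
    hi_val = expected_observed_rating(30.0, latent_sd)
    if not lo_val < target < hi_val:
        return target  # outside the achievable range; pass through
    return optimize.brentq(
        lambda mu: expected_observed_rating(mu, latent_sd) - target, -20.0, 30.0,
        xtol=1e-9)


def simulate_ratings(trials: list[TrialSpec], z_iu: float,
                     rating_model: RatingModel | None = None,
                     seed=None, rng=None, subject_id=None,
                     n_early: int = 8) -> pd.DataFrame:
    """Per-trial integer uneasiness ratings for one subject."""
    rating_model = rating_model or RatingModel()
    rng = rng if rng is not None else np.random.default_rng(seed)
    latent = rating_model.calibrated_latent_means()
    grand = float(np.mean(list(latent.values())))
    b = rng.normal(0.0, rating_model.subject_sd) if rating_model.subject_sd else 0.0
    lam = rng.normal(1.0, rating_model.scale_sd) if rating_model.scale_sd else 1.0
    rank: dict = {}
    rows = []
    for t in trials:
        key = (t.phase, t.condition)
        r = rank.get(key, 0)
        rank[key] = r + 1
        cell = cell_of_trial(t.phase, t.condition, r, n_early)
        if cell not in latent:
            cell_mean = latent.get(f"acquisition_{t.condition}", grand)
        else:
            cell_mean = latent[cell]
        value = (cell_mean + b + (lam - 1.0) * (cell_mean - grand)
                 + rating_model.iu_slopes.get(cell, 0.0) * z_iu)
        if rating_model.noise_sd:
            value += rng.normal(0.0, rating_model.noise_sd)
        rows.append({
            "subject_id": subject_id, "phase": t.phase,
            "trial_index": t.index_in_phase, "condition": t.condition,
            "rating": int(np.clip(np.round(value), 1, 9)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class Cohort:
    """A full synthetic cohort with ground truth retained."""

    questionnaires: pd.DataFrame
    events: pd.DataFrame
    recordings: dict[int, PhysioRecording]
    ratings: pd.DataFrame
    truth: pd.DataFrame
    design: DesignConfig
    fs: float


def simulate_cohort(n_subjects: int = 38, seed=0,
                    design: DesignConfig | None = None,
                    model: AmplitudeEffectModel | None = None,
                    kernel: KernelParams | None = None,
                    rating_model: RatingModel | None = None,
                    instruments=DEFAULT_INSTRUMENTS, correlation=None,
                    fs: float = 50.0, tonic_level: float = 2.0,
                    drift_sd: float = 0.02, noise_sd: float = 0.01,
                    artifact_rate: float = 26 / 1904,
                    artifact_magnitude: float = 1.0,
                    shared_sequence: bool = False) -> Cohort:
    """Simulate a complete cohort.

    One master seed spawns per-subject child streams, so subject i's
    physiology, questionnaire panel and ratings are invariant to cohort
    size.  With ``shared_sequence`` every subject receives the trial order
    and timings of subject 0 (the alternative the task design leaves open).
    """
    design = design or DesignConfig()
    model = model or default_effect_model()
    kernel = kernel or KernelParams()
    rating_model = rating_model or RatingModel()

    master = np.random.SeedSequence(seed)
    cb_ss, *subject_ss = master.spawn(1 + n_subjects)
    colors = assign_counterbalance(n_subjects, rng=np.random.default_rng(cb_ss))

    events_frames, ratings_frames, truth_frames = [], [], []
    recordings: dict[int, PhysioRecording] = {}
    panels = []
    shared_trials = None
    for sid in range(n_subjects):
        seq_ss, quest_ss, phys_ss, rate_ss, art_ss = subject_ss[sid].spawn(5)
        panel = sample_questionnaires(1, instruments, correlation,
                                      rng=np.random.default_rng(quest_ss))
        panel["subject_id"] = sid
        panels.append(panel)
        z = float(iu_zscore(panel["iu"].iloc[0], instruments))

        if shared_sequence and shared_trials is not None:
            trials = [replace(t, cue_color=(
                colors[sid] if t.condition == "csplus"
                else ("yellow" if colors[sid] == "blue" else "blue")))
                for t in shared_trials]
        else:
            trials = generate_session(design, rng=np.random.default_rng(seq_ss),
                                      csplus_color=colors[sid])
            if shared_sequence and shared_trials is None:
                shared_trials = trials

        rec = simulate_recording(trials, z, model, kernel, fs=fs,
                                 tonic_level=tonic_level, drift_sd=drift_sd,
                                 noise_sd=noise_sd, seed=phys_ss, subject_id=sid)
        art_rng = np.random.default_rng(art_ss)
        if artifact_rate > 0:
            hit = np.nonzero(art_rng.uniform(size=len(trials)) < artifact_rate)[0]
            if hit.size:
                rec = inject_artifacts(rec, hit, trials,
                                       magnitude=artifact_magnitude, rng=art_rng)
        recordings[sid] = rec
        events_frames.append(trials_to_frame(trials, subject_id=sid))
        ratings_frames.append(simulate_ratings(
            trials, z, rating_model, rng=np.random.default_rng(rate_ss),
            subject_id=sid))
        truth_frames.append(rec.truth)

    return Cohort(
        questionnaires=pd.concat(panels, ignore_index=True),
        events=pd.concat(events_frames, ignore_index=True),
        recordings=recordings,
        ratings=pd.concat(ratings_frames, ignore_index=True),
        truth=pd.concat(truth_frames, ignore_index=True),
        design=design, fs=fs,
    )


# ---------------------------------------------------------------------------
# fast cell-level simulation (no waveform rendering) for calibration studies

def batch_extinction_cell_magnitudes(n_reps: int, n_subjects: int,
                                     model: AmplitudeEffectModel | None = None,
                                     seed=None, rng=None,
                                     n_trials_per_cell: int = 8):
    """Scored extinction cell magnitudes for many replicate cohorts at once.

    Draws the same per-trial amplitude model the waveform generator injects
    (zero inflation, truncated-normal amplitudes, detection threshold, sqrt,
    averaging) but skips rendering and peak detection, which the scorer
    recovery tests validate separately.  Returns ``(mags, z)`` where ``mags``
    has shape (n_reps, n_subjects, 4) ordered as
    (CS+ early, CS- early, CS+ late, CS- late) and ``z`` holds the IU
    z-scores used as the moderator.
    """
    model = model or default_effect_model()
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = EXT_CELLS
    z = rng.standard_normal((n_reps, n_subjects))
    d = rng.normal(0.0, model.subject_sd, (n_reps, n_subjects))
    means = np.stack([model.cell_means[c] + model.iu_slopes[c] * z + d
                      for c in cells], axis=-1)  # (reps, subj, 4)
    means = np.maximum(means, 0.0)
    shape = means.shape + (n_trials_per_cell,)
    amp = np.maximum(
        rng.normal(means[..., None], model.amplitude_noise_sd, shape), 0.0)
    nonzero = rng.uniform(size=shape) >= model.zero_prob["extinction"]
    scored = np.where(nonzero & (amp >= model.detection_threshold_uS),
                      np.sqrt(amp), 0.0)
    return scored.mean(axis=-1), z
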