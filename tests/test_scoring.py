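"""Trough-to-peak SCR detection, artifact rejection and reduction rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from fearext.errors import MissingCellError
from fearext.scoring import (
    ScoringConfig, compute_cell_magnitudes, detect_scr, flag_artifact,
    reduce_ratings, score_session, sqrt_transform, usable_trials,
)
from fearext.synthetic import (
    KernelParams, PhysioRecording, default_effect_model, draw_trial_truth,
    render_recording, scr_kernel,
)
from fearext.task_design import DesignConfig, generate_session, trials_to_frame


def make_recording(fs=50.0, duration=40.0, tonic=2.0, responses=(),
                   pulse=True, noise=0.0, rng=None):
    """Recording with kernels injected at (onset, amplitude) pairs."""
    t = np.arange(int(duration * fs)) / fs
    eda = np.full_like(t, tonic)
    k = KernelParams()
    for onset, amp in responses:
        eda = eda + amp * scr_kernel(t - onset, k)
    if noise and rng is not None:
        eda = eda + rng.normal(0, noise, len(t))
    p = 0.5 * np.sin(2 * np.pi * 1.17 * t) + 0.01 * np.sin(2 * np.pi * 0.2 * t)
    return PhysioRecording(fs, eda, p if pulse else None)


class TestDetect:
    def test_constant_signal_scores_zero(self):
        rec = make_recording(responses=())
        amp, lat = detect_scr(rec, 5.0)
        assert amp == 0.0 and np.isnan(lat)

    def test_rise_below_threshold_scores_zero(self):
        rec = make_recording(responses=[(7.0, 0.02)])
        amp, _ = detect_scr(rec, 5.0)
        assert amp == 0.0

    def test_injected_kernel_recovered_with_amplitude_and_latency(self):
        rec = make_recording(responses=[(7.0, 0.50)])
        amp, lat = detect_scr(rec, 5.0)
        assert abs(amp - 0.50) / 0.50 < 0.02
        assert abs(lat - 2.0) < 0.2

    def test_onset_outside_window_not_counted(self):
        # onset at 8 s after CS: outside the 0-7 s window
        rec = make_recording(responses=[(13.0, 0.50)])
        amp, _ = detect_scr(rec, 5.0)
        assert amp == 0.0

    def test_window_outside_recording_rejected(self):
        rec = make_recording(duration=10.0)
        with pytest.raises(ValueError, match="window"):
            detect_scr(rec, 8.0)

    def test_first_of_two_competing_responses_wins_by_default(self):
        rec = make_recording(responses=[(6.0, 0.2), (10.0, 0.6)])
        amp, lat = detect_scr(rec, 5.0)
        assert abs(amp - 0.2) < 0.02
        cfg = ScoringConfig(pick="largest")
        amp2, _ = detect_scr(rec, 5.0, cfg)
        # trough-to-peak on the decay tail of the first response slightly
        # underestimates the second; the larger response is still chosen
        assert amp2 > 0.5


class TestSqrtTransform:
    def test_arithmetic(self):
        assert sqrt_transform(0.0) == 0.0
        assert sqrt_transform(0.49) == pytest.approx(0.7)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform(-0.1)

    def test_reduces_skew_of_lognormal_amplitudes(self, rng):
        raw = rng.lognormal(mean=-1.0, sigma=0.8, size=5000)
        assert abs(sstats.skew(np.sqrt(raw))) < abs(sstats.skew(raw))


class TestArtifactFlag:
    def test_clean_trial_not_flagged(self):
        rec = make_recording(responses=[(7.0, 0.5)])
        assert not flag_artifact(rec, (5.0, 12.0))

    def test_transient_in_both_channels_flagged(self):
        rec = make_recording(responses=[(7.0, 0.5)])
        i = int(8.0 * rec.sampling_rate_hz)
        rec.eda[i:i + 3] += 1.0
        rec.pulse[i:i + 3] += 1.0
        assert flag_artifact(rec, (5.0, 12.0))

    def test_eda_only_transient_not_flagged(self):
        rec = make_recording(responses=[(7.0, 0.5)])
        i = int(8.0 * rec.sampling_rate_hz)
        rec.eda[i:i + 3] += 1.0
        assert not flag_artifact(rec, (5.0, 12.0))

    def test_missing_pulse_channel_warns_and_never_flags(self):
        rec = make_recording(pulse=False)
        i = int(8.0 * rec.sampling_rate_hz)
        rec.eda[i:i + 3] += 1.0
        with pytest.warns(UserWarning, match="pulse"):
            assert not flag_artifact(rec, (5.0, 12.0))

    def test_injected_artifacts_recovered_on_cohort(self, scored38, truth38):
        s = scored38.sort_values(
            ["subject_id", "phase", "trial_index"]).reset_index(drop=True)
        inj = truth38.artifact.to_numpy()
        det = s.artifact.to_numpy()
        assert inj.sum() >= 10  # ~1.4% of 2128 trials
        assert det[inj].mean() >= 0.9
        assert det[~inj].mean() < 0.01


class TestScoreSession:
    def test_first_trial_of_each_phase_excluded(self, design):
        trials = generate_session(design, seed=30)
        truth = draw_trial_truth(trials, 0.0, default_effect_model(),
                                 KernelParams(), np.random.default_rng(0))
        rec = render_recording(trials, truth, KernelParams(), 50.0, 2.0, 0.0,
                               0.0, np.random.default_rng(1))
        scored = score_session(rec, trials_to_frame(trials, 0))
        excl = scored[scored.excluded_first_trial]
        assert list(excl.phase) == ["acquisition", "extinction"]
        assert (excl.trial_index == 0).all()

    def test_flat_recording_scores_all_zero(self, design):
        trials = generate_session(design, seed=31)
        rec = PhysioRecording(50.0, np.full(int(50 * 700), 2.0))
        with pytest.warns(UserWarning):
            scored = score_session(rec, trials_to_frame(trials, 0))
        assert (scored.amplitude_uS == 0).all()
        assert scored.is_zero.all()

    def test_zero_proportions_match_published_rates(self, scored38):
        acq = scored38[scored38.phase == "acquisition"].is_zero.mean()
        ext = scored38[scored38.phase == "extinction"].is_zero.mean()
        assert abs(acq - 0.33) < 0.05
        assert abs(ext - 0.53) < 0.05

    def test_scorer_is_sampling_rate_invariant(self, design):
        trials = generate_session(design, seed=32)
        truth = draw_trial_truth(trials, 0.0, default_effect_model(),
                                 KernelParams(), np.random.default_rng(2))
        amps = {}
        for fs in (50.0, 250.0):
            rec = render_recording(trials, truth, KernelParams(), fs, 2.0,
                                   0.0, 0.0, np.random.default_rng(3))
            scored = score_session(rec, trials_to_frame(trials, 0))
            amps[fs] = scored.amplitude_uS.to_numpy()
        keep = truth.true_amplitude_uS.to_numpy() >= 0.05
        rel = np.abs(amps[50.0][keep] - amps[250.0][keep]) / amps[250.0][keep]
        assert rel.max() < 0.02

    def test_raising_threshold_never_raises_cell_magnitudes(self, design):
        trials = generate_session(design, seed=33)
        truth = draw_trial_truth(trials, 0.0, default_effect_model(),
                                 KernelParams(), np.random.default_rng(4))
        rec = render_recording(trials, truth, KernelParams(), 50.0, 2.0, 0.0,
                               0.005, np.random.default_rng(5))
        ev = trials_to_frame(trials, 0)
        lo = compute_cell_magnitudes(score_session(rec, ev, ScoringConfig()))
        hi = compute_cell_magnitudes(
            score_session(rec, ev, ScoringConfig(min_amplitude_uS=0.10)))
        merged = lo.merge(hi, on="cell", suffixes=("_lo", "_hi"))
        assert (merged.magnitude_sqrt_uS_hi
                <= merged.magnitude_sqrt_uS_lo + 1e-12).all()


class TestRecovery:
    def test_detected_amplitudes_track_injected_truth(self, design):
        det_all, inj_all = [], []
        model = default_effect_model()
        for s in range(4):
            trials = generate_session(design, seed=300 + s)
            truth = draw_trial_truth(trials, 0.0, model, KernelParams(),
                                     np.random.default_rng(400 + s))
            rec = render_recording(trials, truth, KernelParams(), 50.0, 2.0,
                                   0.0, 0.0, np.random.default_rng(500 + s))
            scored = score_session(rec, trials_to_frame(trials, s))
            inj = truth.true_amplitude_uS.to_numpy()
            keep = inj >= 0.03
            det_all.append(scored.amplitude_uS.to_numpy()[keep])
            inj_all.append(inj[keep])
        slope, intercept = np.polyfit(np.concatenate(inj_all),
                                      np.concatenate(det_all), 1)
        assert abs(slope - 1.0) < 0.02
        assert abs(intercept) < 0.01


def scored_frame(rows):
    base = dict(subject_id=0, phase="extinction", condition="csplus",
                artifact=False, excluded_first_trial=False, is_zero=False)
    recs = []
    for i, r in enumerate(rows):
        d = dict(base, trial_index=i, **r)
        d["amplitude_sqrt"] = np.sqrt(d.get("amplitude_uS", 0.0))
        recs.append(d)
    df = pd.DataFrame(recs)
    df["cell"] = "csplus_early"
    return df


class TestReduction:
    def test_magnitude_averages_sqrt_values_including_zeros(self):
        df = scored_frame([{"amplitude_uS": 0.64}, {"amplitude_uS": 0.0},
                           {"amplitude_uS": 0.0}, {"amplitude_uS": 0.0}])
        mags = compute_cell_magnitudes(df)
        assert mags.magnitude_sqrt_uS.iloc[0] == pytest.approx(0.2)
        assert mags.n_trials.iloc[0] == 4

    def test_all_artifact_cell_raises_missing_cell(self):
        df = scored_frame([{"amplitude_uS": 0.5, "artifact": True}] * 3)
        with pytest.raises(MissingCellError):
            compute_cell_magnitudes(df)

    def test_zero_inclusion_bounds_magnitude_by_nonzero_mean(self, scored38):
        use = usable_trials(scored38)
        for (sid, cell), grp in use.groupby(["subject_id", "cell"]):
            nonzero = grp.loc[~grp.is_zero, "amplitude_sqrt"]
            if len(nonzero):
                assert grp.amplitude_sqrt.mean() <= nonzero.mean() + 1e-12

    def test_extinction_split_is_first_eight_vs_last_eight(self, scored38):
        one = scored38[scored38.subject_id == 0]
        ext = one[one.phase == "extinction"].sort_values("trial_index")
        for cond in ("csplus", "csminus"):
            cells = ext[ext.condition == cond].cell.tolist()
            assert cells == [f"{cond}_early"] * 8 + [f"{cond}_late"] * 8

    def test_rating_reduction_arithmetic(self):
        ratings = pd.DataFrame({
            "subject_id": 0, "phase": "acquisition",
            "trial_index": range(4),
            "condition": ["csplus", "csplus", "csminus", "csminus"],
            "rating": [2, 4, 3, 3],
        })
        cells = reduce_ratings(ratings)
        assert cells.acquisition_csplus.iloc[0] == 3.0
        assert cells.acquisition_csminus.iloc[0] == 3.0

    def test_constant_ratings_give_constant_cells(self):
        ratings = pd.DataFrame({
            "subject_id": 0, "phase": "extinction", "trial_index": range(32),
            "condition": ["csplus", "csminus"] * 16, "rating": 3,
        })
        cells = reduce_ratings(ratings)
        for col in cells.columns:
            if col != "subject_id":
                assert (cells[col] == 3.0).all()
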