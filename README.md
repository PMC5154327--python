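# fearext

Simulation, skin-conductance-response (SCR) scoring, and moderated
repeated-measures analysis for differential fear conditioning/extinction
experiments.

## The problem

In a differential conditioning task, a neutral cue (the CS+, a colored
square) is paired with an aversive outcome (a 90 dB scream) while a second
cue (the CS−) is never paired; in a subsequent extinction phase both cues
are presented unreinforced. Phasic electrodermal responses and per-trial
uneasiness ratings index how quickly the learned threat response
extinguishes, and individual-difference measures — chiefly the Intolerance
of Uncertainty scale (IU), alongside trait anxiety (STAIX-2) and worry
(PSWQ) — may moderate that time course: high-IU individuals tend to
generalize threat to the safety cue early in extinction and keep responding
to the threat cue late in extinction.

This package provides, as tested and reusable components, everything such a
study's analysis needs:

- **task_design** — counterbalanced, pseudo-randomized trial schedules
  (24 acquisition trials 12 CS+/12 CS−, 100% reinforced; 32 extinction
  trials 16/16; optional partial reacquisition) with jittered timings;
- **synthetic** — a calibrated generator for cohorts of questionnaire
  panels, continuous electrodermal recordings built from event-locked
  bi-exponential SCR kernels with an IU-moderated amplitude structure and
  zero-response trials, a pulse channel, motion artifacts, and ordinal
  ratings — with ground truth retained for recovery testing;
- **scoring** — trough-to-peak SCR detection (0.03 µS threshold, 0–7 s
  onset window), conjunctive two-channel artifact rejection, first-trial
  exclusion, square-root transform, and condition × time magnitude cells;
- **learning** — conditioned-response scores at extinction onset
  (first 2 CS+ − first 2 CS− trials) and learner classification;
- **stats** — the Condition × Time × IU repeated-measures ANCOVA with a
  mean-centered continuous moderator, implemented through within-subject
  contrast scores, with partial η², estimated marginal means, simple-slopes
  contrasts at IU ± 1 SD, and hierarchical regressions with ΔR²;
- **pipeline / CLI** — a reproducible `simulate → score → assess →
  analyze → report` pipeline and Monte-Carlo calibration studies.

## The model in brief

Per subject, the four extinction cells (CS± × early/late, each the mean of
8 sqrt-transformed trial magnitudes including zeros) collapse to orthogonal
contrast scores G, C, T, X (grand mean, condition, time, interaction). Each
score is regressed on (1, IU_c) where IU_c is the mean-centered moderator;
the squared t of an intercept is the within-subject F, the squared t of a
slope the corresponding moderation F, each on (1, n − 2) df — algebraically
identical to the classical 2 × 2 RM-ANCOVA. Effect sizes are partial
η² = F/(F + df₂). Follow-up contrasts evaluate the fitted difference-score
regressions at IU mean ± 1 SD (simple slopes). Moderator specificity is
tested hierarchically: STAIX-2 and PSWQ in step 1, IU in step 2, with
ΔR² and its F-change test.

## Worked example

```bash
fearext run-all --subjects 38 --seed 5 --out-dir out/
```

prints the run log

```
run: fearext 0.1.0 seed=5 n_subjects=38
simulate: 38 subjects, fs=50.0 Hz, 2128 trials total
score: zero-response proportions acquisition=35.0%, extinction=52.2%
score: 23 trial(s) artifact-flagged and discarded
assess: 5 non-learner(s) (retained)
analyze: SCR n=38 (of 38), covariate=iu
analyze: ratings n=38
analyze: hierarchical regressions on 4 difference scores
```

and writes the analysis tables to `out/`. The SCR extinction ANCOVA
(`out/scr_extinction_effects.csv`) for this run is

```
               effect      F  df1  df2     p  partial_eta_sq
            condition 10.319    1   36 0.003           0.223
                 time 16.287    1   36 0.000           0.311
     condition_x_time  1.060    1   36 0.310           0.029
                   iu  4.046    1   36 0.052           0.101
       condition_x_iu  2.443    1   36 0.127           0.064
            time_x_iu  4.904    1   36 0.033           0.120
condition_x_time_x_iu 18.708    1   36 0.000           0.342
```

— larger responses to CS+ than CS− overall, extinction over time, and a
Condition × Time × IU interaction. The simple-slopes table
(`out/scr_extinction_contrasts.csv`) unpacks it:

```
iu_level                   contrast  estimate    se      t  df     p
    -1sd csplus_minus_csminus_early     0.089 0.041  2.161  36 0.037
    -1sd  csplus_minus_csminus_late    -0.033 0.029 -1.114  36 0.273
    +1sd csplus_minus_csminus_early    -0.015 0.041 -0.363  36 0.719
    +1sd  csplus_minus_csminus_late     0.181 0.029  6.203  36 0.000
    +1sd   csminus_early_minus_late     0.192 0.026  7.375  36 0.000
```

Low IU (−1 SD): threat/safety discrimination early that dissipates late —
ordinary extinction. High IU (+1 SD): no early discrimination (threat
generalization) but discrimination late, with a marked decline in CS−
responding from early to late — the compromised-safety-learning pattern the
generator's default effect structure encodes.

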