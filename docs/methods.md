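# Methods notes

## Task design

A session contains two analyzed phases presented as blocks: acquisition
(12 CS+ / 12 CS−, every CS+ reinforced by a 1 s aversive sound starting
0.5 s after CS onset) and extinction (16 / 16, unreinforced). An optional
partial-reacquisition block (16 CS+ of which 4 unpaired, 14 CS−) can be
generated but is never analyzed. Trials unfold as 1.5 s CS, 3.0–6.45 s
blank, 4 s uneasiness rating (1–9), 1.0–2.5 s blank; jitters are uniform
over their ranges. Blocks are separated by a 10 s gap (a plumbing choice;
the first trial of each phase is excluded from averages anyway).

Pseudo-randomization is not prescribed beyond its constraint (no more than
three consecutive presentations of the same condition), so the package
rejection-samples uniformly random permutations until the constraint holds,
capped at 10,000 attempts before raising a constraint-infeasible error;
this samples uniformly over admissible orders. Infeasible count/run-length
combinations (majority count > max-run × (minority + 1)) are rejected
analytically up front. Whether the order was fixed across participants or
drawn per participant is not documented for the original task; the
generator supports both (`shared_sequence`), defaulting to per-participant
draws. Cue color (blue/yellow) is counterbalanced exactly for even cohorts.

## Synthetic cohorts

The generator defines the study conditions the analyses are validated
under: 38 subjects, the trial structure above, and the following
data-generating layers. Ground truth (injected amplitude, latency,
artifact labels) is always retained.

**Questionnaires.** Truncated-normal marginals matching the published
descriptives — IU M = 63.92, SD = 19.56 (instrument range 27–135);
STAIX-2 M = 44.02, SD = 9.33 (20–80); PSWQ M = 51.60, SD = 11.56 (16–80) —
with parent parameters solved numerically so the *post-truncation* moments
hit the targets. Dependence is a Gaussian copula; inter-measure
correlations are not published, so all pairs default to 0.6 (an assumption,
configurable). The IU z-score entering the amplitude model is referenced to
the configured population mean/SD, not the sample, so a subject's data is
invariant to cohort size; each subject draws from a child stream of the
master seed for the same reason.

**SCR waveforms.** EDA = tonic level (2 µS) + slow tonic drift (a Brownian
walk of 0.02 µS/√s, band-limited below 0.05 Hz — tonic level wanders over
minutes but not within a 7 s scoring window) + event-locked responses +
white measurement noise (0.01 µS). Each response is a unit-peak
bi-exponential kernel h(t) ∝ e^(−t/τd) − e^(−t/τr) with τr = 0.75 s,
τd = 2.5 s (canonical phasic SCR morphology), onset latency N(1.5, 0.3²) s.
The default rendering rate is 50 Hz for desk-scale speed (the original
hardware digitized at 1000 Hz); the scorer is sampling-rate agnostic and
tests verify 50 vs 250 Hz agreement within 2%. The pulse channel is a noisy
~70 bpm oscillation that carries information only when a motion artifact (a
sharp 0.1 s transient added to BOTH channels) is injected; artifacts occur
at the published empirical rate (26/1904 ≈ 1.4% of trials) by default.

**Amplitude effect structure.** Published SCR tables report sqrt-transformed
*magnitudes* — condition means including zero-response trials — so the
model is calibrated on that scale. Targets at average IU are the published
cell means (acquisition CS+ 0.79, CS− 0.32; extinction CS+/CS− early
0.32/0.29, late 0.29/0.22 √µS). IU moderation slopes (√µS per SD of IU) for
extinction are derived from the qualitative moderation pattern: requiring
no CS+/CS− difference early at +1 SD and none late at −1 SD, the grand cell
means force s(CS−e) − s(CS+e) = 0.03 and s(CS+l) − s(CS−l) = 0.07; the two
remaining free values are fixed once at s(CS+e) = +0.03 and
s(CS+l) = +0.035, giving early threat-generalization (both cues elevated)
and a late CS− decline at high IU, and early discrimination with late
equality at low IU. Acquisition slopes are zero (no moderation was found
there).

Raw per-trial amplitudes are recovered from these targets numerically: for
each cell, the raw mean u solves
(1 − p_inj) · E[√amp · 1{amp ≥ 0.03}] = target, with amp = max(0, N(u + d,
0.10)) where d is a per-subject responsiveness offset (SD 0.12 µS) and the
expectation is Gauss–Hermite quadrature; means at z = ±1 give the raw
slope/intercept by midpoint/half-difference. The injected zero probability
p_inj is solved so that the *scored* zero proportion (injected zeros plus
sub-threshold draws) matches the published 33% (acquisition) / 53%
(extinction); calibration iterates the two solves to convergence. The
amplitude-noise and subject-dispersion values are assumptions (raw
amplitude distributions are not published); the truncated-normal noise
choice is likewise an assumption, noted here.

**Ratings.** A latent-normal model: calibrated cell mean + subject
intercept (SD 0.8) + (conditioning-strength scale λ − 1) × cell deviation
(λ ~ N(1, 0.6), so subjects differ in how strongly condition separates
their ratings, mimicking the large published between-subject SDs) + trial
noise (SD 1.0), rounded and clamped to 1–9. Latent cell means are
calibrated numerically so the post-round/clamp expectation equals the
published per-trial target (identity when all noise is zero; targets
outside the achievable 1–9 expectation range pass through unchanged, which
implements the clamp floor). Rating IU slopes default to zero (no rating
moderation was found).

**What the generator does not emulate.** Within-phase habituation beyond
the early/late structure; respiratory/cardiac physiology (the pulse channel
is a prop for the artifact rule); separate CS- and US-omission responses
(a single amplitude per trial — the 500 ms CS–US interval makes them
inseparable in this design anyway); spontaneous non-specific SCRs;
questionnaire item structure. Passing tests therefore demonstrate that the
*pipeline* recovers known structure of this form, not that real
electrodermal data satisfies the model.

## SCR scoring

Trough-to-peak scoring with explicit operationalizations of the manual
rules:

- smoothing: zero-phase 2nd-order Butterworth low-pass at 2 Hz (phasic SCR
  content lies well below; attenuation of a kernel-shaped response < 1%);
- candidate onsets: first sample of a rising run (derivative >
  0.01 µS/s) whose preceding local minimum (searched at most 1 s back) is
  the trough; the onset must fall within 0–7 s after CS onset;
- peak: advance until the derivative turns negative or stays ≤ 0.001 µS/s
  for 0.2 s ("flattening out"), capped at onset + 10 s or the next CS
  onset, whichever is earlier — the cap resolves window overlap at short
  inter-trial intervals, which the source procedure leaves unspecified;
- amplitude = smoothed signal at peak − at trough; responses < 0.03 µS are
  scored zero; when several responses qualify, the *first* in-window onset
  wins (stimulus-locked reading; `pick="largest"` is available);
- artifacts: a trial is discarded only when the robust z (MAD-scaled, with
  a 0.005 µS physical floor) of the > 5 Hz residual exceeds 8 in BOTH the
  EDA and the pulse channel inside the trial window; without a pulse
  channel the conjunctive rule cannot fire and a warning is emitted rather
  than flagging on EDA alone;
- the first trial of each phase is excluded from averages; sqrt transform;
  extinction cells are the first 8 vs last 8 trials per condition by
  presentation order, with excluded/artifact trials dropped from the
  average but keeping their rank. An empty cell raises a missing-cell
  error and drops the subject with a log entry.

Ratings are averaged per cell with no first-trial exclusion (that rule is
documented only for SCR), using the same early/late split so one Time
factor applies to both measures.

## Learning assessment

CR score = mean(first 2 CS+ extinction trials) − mean(first 2 CS−), per
measure; for SCR the first-of-phase exclusion and artifact rejection apply
before "first two" are selected (configurable to first-two-as-presented —
the source is ambiguous). A subject is a non-learner only if neither score
is positive; exactly zero counts as no differential response (ties are
measure-zero for continuous SCR). Non-learners are retained by default
with a flag, matching the original analysis; a switch drops them.

## Statistics

The contrast-score route (G/C/T/X regressed on the centered moderator) was
chosen over omnibus mixed-model machinery because it is transparent,
exactly equivalent for 2 × 2 designs (the published df₂ = n − 2 confirms
this parameterization), and directly oracle-testable against brute-force
least squares. Sums-of-squares type is moot for single-df,
single-covariate regressions. p-values are two-sided; follow-up contrasts
are uncorrected, as in the source analyses. The ±1 SD evaluation points use
the analyzed subsample's covariate SD, recomputed per measure. A constant
covariate degrades gracefully to one-sample t-tests on the contrast scores
(df n − 1) with moderation terms reported as F = 0.

Two published effect-size cells (Condition × Time on ratings, 0.13;
Condition × Time × IU on SCR, 0.12) do not equal F/(F + df₂) from their
printed F values while the other reported cells do; the package reports
F/(F + df₂) throughout and makes no claim about those two cells. Printed
step-1 coefficient signs in the published hierarchical-regression table are
internally inconsistent (e.g. a positive B with negative β), so
coefficient-level values are validated against a normal-equations oracle
rather than against that table.

## Pipeline and calibration studies

Exclusion screens mirror the published taxonomy: non-responder (> 90%
zero-scored trials), excessive movement (> 10% artifact trials), optional
|z| > 6 outlier screen on the early CS+ − CS− difference (off by default in
simulation, available for paper-faithful runs), and missing cells. Every
exclusion is logged with subject and reason; runs are byte-reproducible
under a seed.

`run_calibration_study` simulates replicate cohorts at the scored-cell
level — the same per-trial amplitude model the waveform generator injects
(zero inflation, truncated-normal amplitudes, detection threshold, sqrt,
8-trial averaging), skipping rendering and peak detection, which the
scorer-recovery tests validate separately. This keeps 2,000-replicate
type-I studies and 500-replicate pattern studies at n = 34 in seconds.
The fast path uses 8 trials per cell (ignoring the first-of-phase
exclusion's 7-trial cell, a negligible difference for operating
characteristics). "Pattern recovery" is operationalized a priori as:
directional claims (early CS+ > CS− at −1 SD; late CS+ > CS− and CS−
early > late at +1 SD) require a positive point estimate; "null" claims
(late at −1 SD, early at +1 SD) require the contrast not to reach
significance at α = 0.05 — matching the verbal description of the
moderation figure.

Problem sizes used by the acceptance script: 10,000 schedules for the
run-length constant; 8 noiseless sessions (~255 supra-threshold trials)
for recovery; three independent 38-subject cohorts (pooled) for
zero-response proportions and magnitudes, tightening Monte-Carlo error
while keeping each cohort at the study's size; 4,000 null replicates for
type-I error; 500 replicates for pattern recovery.

## Known limitations

- Between-subject dispersion of SCR magnitudes is smaller than the
  published cell SDs (the subject offset is kept moderate so that
  calibrated zero-rates and magnitudes stay unbiased); contrast-level
  inference, which subject main effects cancel, is unaffected.
- Trough-to-peak amplitudes on overlapping responses are slightly
  underestimated when a response rides a predecessor's decay tail (~1%
  at the default timings; visible as a recovery slope of ~1.01).
- The zero-phase smoothing filter spreads response onsets backwards by a
  fraction of a second, so detected latencies sit ~0.2 s before the
  injected kernel onset; amplitude is unaffected.
- Cohort-level F statistics cannot be compared to the published ones
  (the original raw data are unavailable); validation rests on analytic
  identities, design constants, recovery of injected structure, and
  operating characteristics.
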