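# Methods

`loomlab` simulates a wheel-of-fortune gambling session together with the
electrodermal activity (EDA) it evokes, reduces the continuous conductance
signal to trial-wise summaries, and estimates how those summaries scale with
the money at stake.  This note documents the generative model, the signal
reduction, the estimators, the numerical choices, and what the simulations
do and do not establish.

## Task model

A session has 76 trials: 19 wins, 19 losses, 10 near-wins, 10 near-losses
and 18 fillers, in a fully shuffled order (one seeded permutation per
session; no ordering constraints are imposed).  The wheel is modelled as
four 90° segments — gain and loss opposite each other, separated by two null
segments.  Segment sizes are a package choice: equal quadrants make "near
the centre of the null segment" well defined for fillers.  Stop angles are
drawn per condition:

* win/loss — uniform in the interior of the segment (offset from both
  boundaries > 1.8°);
* near-win / near-loss — inside a null segment, within (0°, 1.8°] of the
  win/loss boundary, uniform (only the bound is constrained by the design;
  uniform is the maximum-entropy completion), side chosen at random;
* filler — at least 20° from any boundary.

Bets sit on a 9-level grid (10–90 pence, anchored at 50 p); wins pay
+10 × bet, losses −10 × bet; near outcomes and fillers pay nothing, with
near outcomes carrying a counterfactual magnitude of 10 × bet.  Feedback
sounds map win → applause, loss → boo, any null outcome → thud.

Each trial runs choice → spin → outcome → luck rating → intertrial interval
(ITI).  Choice and rating phases are self-paced: latencies are log-normal
with means 2.91 s / 2.44 s and SDs 2.0 s / 1.75 s (typical empirical values for self-paced betting and rating),
floored at 0.2 s.  The spin (anticipation) interval is uniform on
5.3–6.9 s; the outcome phase is 1 s followed by a 1 s numeric display; the
ITI is exactly 10 s.  The session opens with a 300 s rest recording.  The
analysis windows are anchored to the choice and outcome onsets only; the
numeric display simply extends the outcome phase in the timeline.

## Behavioral agents

**Betting agent.**  bet₁ = anchor; betₜ₊₁ = nearest-grid clip of
betₜ + shift(outcomeₜ) + ε, with shift −5.77 p after wins, +3.40 p after
losses, 0 after null outcomes, and ε ~ N(0, 9 p).  The shift means and the noise SD
(set between the two empirical adjustment SDs, 8.69/9.76 p) are the
reference values the generator is designed to emulate.  Note a structural property verified by an
independent re-simulation of the same walk: grid rounding and clipping at
10/90 p shrink the *observed* mean post-outcome changes toward zero
(post-win ≈ −4.5 p rather than −5.77 p at these defaults), because bets
spend time at the grid boundary where downward moves are truncated.  The
generative shifts are therefore not exactly recoverable as observed change
scores; the agent is tested against the independent walk oracle instead.

**Luck ratings.**  rating = clip₁..₉ round(5 + slope × magnitude + ε),
ε ~ N(0, 1.5).  Slope magnitudes default to the reference coefficients (2.56e-3,
2.29e-3, 1.34e-3, 1.21e-3 rating units per pence).  The reference
coefficient *signs* for losses and near-losses contradict their described
directions (larger losses "unluckier", near-losses raise luck), so the sign
coding is an explicit switch: the default, `sign_convention="prose"`,
follows the described directions (win +, loss −, near-win −, near-loss +);
`"printed"` applies the printed signs verbatim.  Rounding and the 1–9 clip
slightly attenuate recovered luck slopes at extreme magnitudes; this is a
property of the scale, not of the estimator.

## Conductance model

The trace is built in log10 space and exponentiated:

    EDA(t) [µS] = 10^( tonic_i + drift(t) + noise(t) + Σ_e A_e · k(t − t_e − L) )

* tonic_i ~ N(0.3, 0.15) log10 µS per participant (≈ 2 µS typical level);
* drift is a slow sinusoid (period 120 s, amplitude 0.05 log units, random
  phase) — the low-frequency wander that motivates per-trial baselining;
* noise is white measurement noise, SD 0.005 log units per sample;
* k is a unit-peak bi-exponential SCR kernel
  k(τ) ∝ e^(−τ/4.0) − e^(−τ/0.75) (rise 0.75 s, decay 4.0 s, event-to-
  response latency L = 1.0 s — typical electrodermal values), and
  overlapping responses superpose additively in log space.

Event amplitudes realize the analysis-space linear model directly:

    A_choice  = 0.10 + b_i + g_i · β_sel · bet + ε
    A_outcome = 0.15 + b_i + g_i · β_cond · magnitude + ε

with participant intercept b_i ~ N(0, 0.05), participant gain
g_i ~ LogNormal(−σ²/2, σ = 0.8) (mean 1) shared across phases, and trial
noise ε ~ N(0, 0.08 log units); amplitudes are floored at 0 (the phase
intercepts keep flooring rare, < 3 % of events).  Slope defaults are the
reference fixed effects the generator emulates: β_sel = 6.30e-4 per pence of bet, and
2.625e-5 / 8.35e-5 / 6.34e-5 / 7.23e-5 per pence of (counterfactual)
magnitude for win / loss / near-win / near-loss.  The trial noise SD 0.08
was chosen so the fitted slope standard errors land on the reference scale
(back-solving SE ≈ σ/(σₓ√n) from the reference SEs gives σ ≈ 0.06–0.14);
the gain σ = 0.8 reflects the order-of-magnitude spread of individual
electrodermal responsiveness and is what couples selection- and
outcome-related slopes across participants.

**Summary calibration.**  The analyzed summary is a max of 2-s bin means,
which attenuates a unit-peak SCR by the factor κ = max bin-mean of the
kernel over bins 2–4 (κ ≈ 0.83 at the default shape; closed form in
`kernel_bin_means`).  By default the synthesizer scales the kernel by 1/κ so
that an isolated event's summary equals its nominal amplitude — making the
generative slopes the estimand of the downstream fit, rather than κ-scaled
copies of it.  Setting `calibrate_summary=False` gives the raw unit-peak
kernel.

**Summary-level shortcut.**  `simulate_trial_records` draws
selection/outcome summaries directly from the same linear model (no trace,
no flooring).  Replicate studies (parameter recovery, test calibration) use
this route; it is exactly the model the estimator assumes, so it isolates
estimator properties from signal-processing effects.

## Signal reduction

Raw traces are decimated to 100 Hz (polyphase FIR, DC preserved exactly),
log10-transformed with a 1e-3 µS floor (well below physiological range),
and summarized per trial and phase as

    summary = max_{k ∈ {2,3,4}} ( mean EDA in [onset + 2(k−1), onset + 2k) ) − baseline

where baseline is the mean over the last 2 s of the trial's preceding ITI
(the first trial uses the tail of the pre-task rest).  Choices made where
the design is silent: the summary is the *signed* maximum (deflections of
interest are rises, and the signed form keeps the linear model
interpretable); the baseline statistic is the mean; bins are half-open.
Trials whose windows are not fully recorded are flagged missing, not
dropped silently.  Participants whose outcome summaries vary by less than
1e-4 log units SD across trials are screened out as nonresponders (an
operationalization of "no phasic changes").

Because the baseline subtraction cancels any multiplicative rescaling of
the raw trace (log shift), every summary is scale-invariant — verified
exactly in the tests, along with bit-level agreement with a brute-force
reimplementation of the binning.

## Estimation and tests

The core estimator is the random-intercept model
`summary ~ magnitude + (1 | participant)` fitted by REML (statsmodels
`MixedLM`), one fit per condition, with magnitudes in pence (no centering).
`MagnitudeSlopeModel.fit()` returns the fixed slope with SE, t, and a
two-sided p on a t reference with within-participant residual df
(n_obs − n_participants − 1; the REML backend does not expose a
Satterthwaite approximation, and the df choice is flagged in the output).
A fit with degenerate between-participant variance falls back to pooled
OLS, flagged.  Per-participant OLS slopes are always computed; they feed:

* the paired t test of slope asymmetries (loss vs win, near-loss vs
  near-win), df = n − 1, restricted to participants with both slopes
  defined;
* Pearson correlations between the selection-slope and outcome-slope
  profiles;
* the Williams test (Steiger's modification) for two dependent
  correlations sharing the selection slope:
  t = (r12 − r13)·√[(n−1)(1+r23) / (2·((n−1)/(n−3))·|R| + r̄²(1−r23)³)],
  df = n − 3, with |R| the determinant of the 3×3 correlation matrix and
  r̄ = (r12+r13)/2.  Non-positive-semidefinite correlation triples are
  rejected with the offending determinant named.

No multiple-testing correction is applied anywhere.

## Simulation studies and their scope

`recovery_study` (500 replicate 50-participant cohorts, summary route)
measures bias, RMSE, CI coverage and contrast rejection rates against the
generative slopes.  At defaults all five slopes recover with relative bias
within a few percent (the Monte-Carlo SE of the 500-replicate mean is
itself ≈ 2 % for the shallow win slope, which bounds how sharply bias can
be resolved at this study size).  CI coverage for the slopes runs *below*
nominal: the generator has participant-varying slopes (the gain factor)
while the fitted model has a random intercept only, so the fixed-effect SE
understates between-cohort variance.  This mirrors the analysis model's own
simplification and is reported, not hidden.

`williams_type1_study` and `paired_test_type1_study` (5,000 Monte-Carlo
replicates each, vectorized) verify empirical size ≈ 0.05 under the
respective nulls (equal population correlations; equal win/loss slopes).

What passing these studies does **not** show: the trace route inherits two
small systematic effects absent from the summary route — (i) the choice-SCR
decay tail overlaps the outcome analysis window, and since outcome
magnitude is exactly 10 × bet, this adds a positive component to the
outcome slopes (order +7e-6 per pence at defaults); (ii) the previous
trial's outcome SCR elevates the next trial's ITI baseline slightly.  Both
leave the loss > win and near-loss > near-win orderings intact (verified
directly), but absolute slope recovery through the full signal path is only
approximate.  The generator also omits habituation across trials,
respiration and motion artifacts, and nonstationary electrode drift beyond
the sinusoid; real recordings are less well behaved than anything simulated
here.

## Problem sizes

Default study sizes — 50 participants, 76 trials, 100 Hz analysis rate,
500 recovery replicates, 5,000 calibration replicates — are the package's
standard operating points; unit tests use smaller cohorts and shorter
sessions where only structure is being checked.
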