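# Methods

This note documents the models, conventions and numerical choices behind
`paincode`, and what the synthetic-data experiments do and do not show.

## Time base and binning

All spike times are seconds relative to stimulus (laser) onset.  Bins are
half-open `[t, t + Δ)`, so a spike exactly at onset belongs to the first
post-stimulus bin; this convention is applied uniformly to PSTHs (Δ =
200 ms over a ±5 s window: 25 baseline + 25 post bins) and to decoding
features (Δ = 100 ms over [0, 5) s: 50 bins).  Trials in which the paw was
withdrawn before 5 s still contribute the full post-stimulus window: the
stimulus ends at withdrawal, the recording does not.

## Baseline normalization

The z-scored PSTH divides by the SD of the baseline firing rate.  Two
readings of "baseline SD" are possible and both are implemented
(`baseline_sd_mode`): the default takes mean and SD across the 25 baseline
bins of the *trial-averaged* rate, which makes the baseline bins of `Z`
have sample mean 0 and SD 1 by construction; the alternative pools the SD
across per-trial baseline rates.  The default was chosen because `Z` is a
property of the trial-averaged PSTH, and it gives the threshold criteria a
fixed false-positive geometry independent of trial count.

When one stimulus class of a mixed session is z-scored, the baseline
statistics come from **all** trials of the session (`baseline_from=
"session"`), not from the class subset.  Pre-stimulus activity does not
depend on the upcoming stimulus, so the pooled estimate is strictly less
noisy — and, more importantly, giving both classes one shared normalizer
prevents two artifacts we measured with class-specific normalizers: the
paired HS-vs-LS test becomes anti-conservative (a noisy class-level SD
shifts every trial of that class coherently), and independent
multiplicative noise on the two axes of the tuning fit dilutes slopes
toward 1, erasing the regime difference.

Units with zero baseline variability are flagged degenerate, get NaN
z-scores, and are never classified responsive.

## Responsiveness criteria

Criterion 1 counts post-stimulus bins with `|Z| ≥ 2.33` (two-sided,
z ≈ 99th percentile); criterion 2, evaluated only if criterion 1 produced
at least two bins, counts bins whose lower bound `Z − Z_SEM` exceeds 1.645
(one-sided 95%).  Both need ≥2 bins.  `Z_SEM(bin)` is the standard error
of the per-trial rate in that bin across trials, divided by the baseline
SD — the dimensionally consistent reading of the definition, isolated in
`compute_z_sem` so the alternative is a one-line change.  For a
stationary Poisson unit the conjunction flags well under 5% of units
(measured ≈1–2% across 1000 simulated units); note that under the default
normalization `Z_SEM ≈ 1` for a stationary unit, because numerator and
denominator are both √T-scaled estimates of the same variability.

The two-bin absolute-value criterion is *not* monotone under uniform
positive shifts for purely inhibitory response profiles (a bin at
Z = −2.4 can leave criterion 1 before an excitatory bin enters); the
monotonicity property is therefore stated and tested for excitatory
evidence, which is the population of interest.

## Intensity-coding test

Responsive units are tested for HS > LS with a paired t-test on per-trial
peak responses (max over post-stimulus 200 ms bins of the trial's
z-scored rate).  With LS and HS acquired in separate passes there is no
natural pairing; trials are paired by recording order (`pairing="index"`),
which keeps the null calibrated (measured flag rate ≈4% at α = 0.05).
Rank pairing (sorting each condition) is available but measured badly
anti-conservative under the null (~27%), because order-statistic
differences are strongly correlated; it should only be used as a
descriptive device.

## Decoding

Features at evaluation bin `b` are the concatenated per-unit counts of
bins 1..b (dimension `b·C`).  The classifier is an SVM with polynomial
kernel; degree 3 with unit independent term (`coef0 = 1`) is the default
— the kernel degree is a free choice, config-exposed, with a linear
fallback.  Features are standardized per dimension with statistics fit on
the training folds only.  "80/20 split" and "5-fold cross-validation" are
reconciled as stratified 5-fold CV (each fold is a 20% test set); fold
membership is reshuffled each Monte-Carlo repeat, and accuracies are
reported as mean ± SEM over repeats.  The summary statistic of a session
is the maximum of the cumulative accuracy curve.  No class reweighting is
applied, so imbalanced classes push the permutation chance level slightly
above 50%.  Chance is estimated by permuting trial labels and re-running
the identical CV procedure; on balanced synthetic sessions the measured
chance level is 49–51%.  Sessions with fewer than 5 simultaneously
recorded units are excluded from cohort aggregation.

## Tuning fits

Peak pairs take the maximum z over the 25 post-stimulus bins per
condition, keeping units with `hs_peak > ls_peak`.  The line is fit by
IRLS with Tukey's bisquare (tuning constant 4.685, the standard
95%-efficiency value), intercept included.  R² of a robust fit is
ambiguous; it is reported as the squared correlation between fitted and
observed HS peaks.  Slopes are compared as independent estimates with
`df = n₁ + n₂ − 4`.  Note that peak-selection noise attenuates
session-derived slopes slightly toward 1 relative to the generating
amplitude ratio; the direction of the regime difference is preserved and
is what the tests assert.

## Up-down 50% threshold

The staircase runs over the calibrated filament set (0.45–15.10 g,
roughly log-spaced, start 2.55 g): withdrawal steps down, no response
steps up, and estimation uses the classical form
`threshold = 10^(x_f + k·δ)/10⁴` g, with `x_f` the log-unit value of the
final filament and `δ` the mean log step.  The pattern factor `k` is
derived at run time as the maximum-likelihood location of a
cumulative-normal response curve with scale `δ` fitted to the whole
sequence — the model whose tabulated approximations the classical method
uses — so every valid sequence (any pattern containing a reversal) has a
defined estimate; monotone runs that pin at an end of the set clamp to
that filament.  The ML estimator is verified against a brute-force grid
search and is monotone: converting a no-response to a response never
raises the threshold.

## Synthetic-data generator

Spike trains are inhomogeneous Poisson: rate `b` before onset and
`b + g·A_s·k(t)` after, with baseline `b` log-normal across units (median
2 Hz, log-SD 0.4), `k(t)` a normalized transient (linear rise over 0.5 s,
exponential decay τ = 1.5 s, peak 1) so evoked responses land inside the
5 s analysis window, `A_s` the class amplitude in Hz, and `g` a per-trial
log-normal gain shared across units (SD 0.15, chosen so that mixed
LS-vs-HS decoding operates in the 60–75% regime the analysis assumes
rather than saturating or collapsing to chance).  The regimes differ only
in amplitudes: pre_cfa (NS, LS, HS) = (0, 7.6, 10) Hz and post_cfa =
(0, 9.3, 10) Hz — the flattened regime compresses the LS amplitude toward
HS (response saturation), with ratios chosen to land generated tuning
slopes near the steep (≈1.3) and flattened (≈1.1) fits.  80% of units are
responsive by default.  Withdrawal latencies are shifted gammas with
means 1.5 s (HS) and 3.0 s (LS), matching the observed ordering and
typical withdrawal times; NS withdraws on 3% of trials.  Trials carry
~60 s inter-trial intervals as metadata.

Place-aversion cohorts draw the paired-chamber baseline from
N(300 s, 156 s) clipped to [0, 600]; 156 s puts ≈20% of animals outside
the 100–500 s inclusion band, matching the stated exclusion rate.  Test
occupancy subtracts the condition's aversion effect plus N(0, 60 s)
noise; the two chambers always sum to the 600 s phase.

Tuning-recovery cohorts draw LS peaks log-normally (median 4, log-SD 0.4)
and set `hs = slope·ls + ε`; when a target R² is given, the noise SD is
`slope·sd(ls)·√((1−R²)/R²)`.

What the generator does **not** emulate: correlated variability beyond
the shared gain, non-Poisson spiking (bursting, refractoriness),
unit-to-unit latency differences, slow drifts, or any movement-related
modulation.  Passing tests therefore show that the pipeline recovers
known structure under its own statistical assumptions — not that those
assumptions hold in vivo.

## Problem sizes and reproducibility

The bundled experiments use 9 sessions × 7 units × 30 trials/class with
20 Monte-Carlo repeats for the decoding ceiling, 100 permutations for the
chance level, 200 replicated cohorts for slope recovery, and 6 sessions
per regime in the worked example — sizes at which the reported means are
stable to well under their tolerance.  Every randomized stage receives a
31-bit child seed spawned from one root seed (`spawn_seeds`), so each
stage is independently reproducible and the full pipeline is bit-for-bit
deterministic for a fixed seed.
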