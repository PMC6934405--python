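# Methods

This note records the models the package implements, the defaults and
why they were chosen, the numerical decisions that affect results, and
what the synthetic-data generator does and does not emulate.

## Tone vocoder

The analysis chain divides the input into `n_channels` contiguous bands
equally spaced on the ERB_N-number scale, `E(f) = 21.4·log10(0.00437f + 1)`
(Glasberg–Moore constants for normal hearing). With the default 6 bands
over 100–7800 Hz the interior corners fall at 331.25, 725.14, 1396.02,
2538.70 and 4484.99 Hz; rounded to integers these are 331, 725, 1396,
**2539** and 4485. Published 6-band tables usually print 2538 for the
fourth corner — the half-Hz sits essentially on the rounding boundary,
and we round half away from zero. Carriers sit at the geometric mean of
each band's corners (the "logarithmic centre"): 182, 490, 1006, 1883,
3374, 5915 Hz. Printed tables sometimes give 185 Hz for band 1, which is
neither the geometric mean (182) nor the ERB-midpoint (200); we document
and keep the geometric mean.

**Filters.** No filter family is mandated by a roll-off specification
alone; we use Butterworth filters, with the order chosen as
`rolloff / 6` dB-per-octave-per-pole (24 dB/oct → 4 poles per skirt).
Filters are applied forward–backward (`sosfiltfilt`), so envelopes stay
time-aligned across channels; zero-phase application doubles the
effective slope (48 dB/oct) and deepens the corner attenuation from 3 to
6 dB. The corners and slopes quoted above are properties of the one-pass
design, which tests verify on the designed response.

**Envelope.** Half-wave rectification followed by the 45-Hz low-pass
(24 dB/oct), classic vocoder practice; the magnitude of the analytic
signal is available via `envelope_method="analytic"`. Residual negative
values after filtering are clamped to zero. Rectification scales the
baseband by 1/π; absolute scale is restored by level matching.

**Level matching.** The summed output is rescaled to the input's overall
RMS (`level_match="total"`); a per-channel alternative matches each
modulated carrier to its band signal's RMS. Silence maps to silence.
Carriers start at zero phase for determinism. All processing happens at
the input rate; nothing is resampled.

## Stimuli

AM tones are `a(t) = A·[1 + m·sin(2πf_m t + φ)]·sin(2πf_c t)`, divided by
`sqrt(1 + m²/2)` when compensation is on so the steady-state RMS equals
the unmodulated carrier's (the modulation power cue is cancelled
exactly over whole modulator cycles; tests verify 0.2 % agreement).
Raised-cosine on/off ramps are applied after compensation, so the
equated RMS refers to the steady state. The modulator is sine-phase
with `φ` supplied by the caller; trial assembly draws `φ ~ U[0, 2π)` per
interval from the track's seeded generator. Levels are in dB re full
scale; the nominal 70 dB SPL presentation level of the emulated studies
is a playback calibration constant with no digital counterpart, so it is
not a waveform property. Inter-stimulus intervals (750 ms AM tasks,
500 ms FD) are presentation timing, not waveform content, and live in
the schedule, not in the arrays.

## Adaptive staircases

All tracks are 3I-3AFC oddball with uniform target interval. Levels move
multiplicatively: AM detection tracks modulation depth `m` (start 1.0,
capped at 1.0, factors 1.58 then 1.26); AM-rate discrimination tracks
the rate increment `Δf_m` in Hz above the block's standard (start 50 %
of the standard, factors 1.4 then √1.4); frequency discrimination tracks
`Δf` in percent of the 800-Hz standard (start 50 %, factors 2 then √2).
Phase 1 is one-down/one-up; the first incorrect response switches the
track permanently to three-down/one-up with the smaller factor, which
converges where `p³ = ½`, i.e. 79.4 % correct. Decisions the sources
leave open, resolved here:

- the incorrect response that triggers the switch still moves the level
  by the phase-1 factor (the *next* move uses the small step);
- the FD task's phase-2 down/up rule is three-down/one-up, by symmetry
  with the AM tasks;
- the consecutive-correct counter resets after every level change
  (standard transformed up-down bookkeeping);
- levels clamp at a floor and cap rather than terminating the track;
- practice trials (3 "easy" at the start level, 2 "impossible" at the
  floor) are fixed-level, flagged, and excluded from stepping and
  analysis;
- one seeded generator per track supplies target interval, observer
  noise and distractor choice in a fixed draw order, so tracks are
  byte-reproducible.

Training schedules run 21 blocks × 60 trials (9 on day 2, 12 on day 3);
the standard modulation rate rotates through 4/8/16 Hz block by block
along one row of the cyclic 3 × 3 Latin square (per-participant row
choice), so every three consecutive blocks cover each rate once.

`converged_performance` estimates the rule's asymptote by averaging the
observer's *true* `p(correct)` over the levels visited in the final 20
of 100 trials across tracks. With the 1.26 factor this lands at 78–79 %
depending on the psychometric slope — slightly below the theoretical
79.4 % because the track oscillates around the fixed point and the
psychometric function is concave over the visited range; the bias
shrinks with the step size, and a one-down/one-up variant lands at 50 %
as transformed up-down theory requires. A brute-force stationary
distribution of the discretised (level × counter) Markov chain serves as
the independent oracle in tests.

## Simulated observers

The psychophysical observer is `p(x) = γ + (1−γ−λ)·Φ(β(log₁₀x − α))`
with γ = 1/3 (3AFC) and lapse λ ≤ 0.1. The stimulus axis is log10 of the
task level (depth, Δf_m, Δf %), which makes the multiplicative staircase
additive on the observer's axis. Defaults: β = 8 per log10 unit,
λ = 0.02; mean 79.4 %-thresholds of m ≈ 0.10 for AM detection, Δf_m ≈
1.6 Hz (20 % of the 8-Hz standard) for rate discrimination and Δf ≈
1.5 % for frequency discrimination — representative values for
normal-hearing adults on these tasks — with 0.20 log10 units of
between-subject spread.

The VCV responder is a three-feature channel: each of voice, manner and
place of articulation survives a trial with its transmission probability
`t`, otherwise the perceived category is resampled uniformly from the
feature's *other* categories. If all three survive, the stimulus
consonant itself is perceived (feature triples do not uniquely identify
consonants, so this convention is what makes perfect transmission yield
a diagonal confusion matrix); otherwise the response is uniform over the
consonants matching the perceived triple, falling back to uniform over
all 20 when nothing matches. Two consequences worth knowing:

- mutual information is invariant to relabeling, so `t = 0`
  (deterministic category flip) transmits *more* information than
  `t = 1/k` (uniform perception), which is the true zero-information
  point of a k-category feature;
- features are perturbed independently, whereas real consonant
  confusions correlate them. The defaults `t = (0.96, 0.95, 0.75)` were
  chosen from the exact enumeration of this channel so the study
  conditions reproduce realistic relative-IT magnitudes (≈ 71 % voice,
  74 % manner, 32 % place); under feature independence this puts percent
  correct near 69 %, somewhat above the ~60 % a human cohort shows at
  the same IT levels. Passing tests therefore demonstrate pipeline
  correctness on this channel model, not that real confusion structure
  is reproduced.

The whole-study generator draws, per subject, a threshold offset and a
transmission offset, runs the actual staircases against the subject's
observer, and simulates the VCV sessions (two pretraining blocks with
transmission deficits of 0.08 and 0.02 emulating rapid early learning,
then pre- and post-test). Injected pre→post effects default to the
magnitudes the emulated study reported: log10-threshold gains of
0.21/0.09/0.08 for the AMD-trained group on AMD/AMRD/FD, 0.07/0.23/0.07
for the AMR-trained group, 0.08/0.10/0.18 for controls, and transmission
gains of 0.018/0.016/0.012 (≈ 6/5.5/4 pp relative IT). Everything is
reproducible from one seed.

## Threshold estimation and QC

Track levels are log10-transformed and fitted by maximum likelihood
with γ fixed at 1/3 and λ fixed at 0.01 (sensitivity: any fixed λ in
[0, 0.05] via the `lapse` argument); the optimiser is Nelder–Mead from
two starts, with the slope unconstrained so anti-correlated tracks
surface as `negative_slope` rejections rather than boundary artefacts.
The reported threshold is the 79.4 %-correct point, matching the
staircase target. QC discards fits with non-positive slope or a
threshold outside the range of levels the track visited ("outside the
measured range" is operationalised as exactly that interval). Outliers
are flagged once (no re-application) at 2.5 × IQR beyond the quartiles,
computed with linearly interpolated quartiles, per group × task ×
session. Per-session thresholds keep block as a covariate; a
mean-of-blocks layout is a one-line aggregation of the emitted table.
Reversals are counted (direction changes among non-hold moves) but not
used for threshold estimation.

## Confusion and information transfer

Confusion matrices collapse vowel context and tally stimulus × response
counts over the 20-consonant inventory (12 voiced, 8 voiceless; manner
in four categories — nasal, fricative, approximant, plosive-initial,
with the affricates counted as plosive-initial; place in three — front,
middle, back). The shipped feature table
(`src/tevoc/data/feature_map.tsv`) uses standard articulatory
assignments — front = labial/labiodental, middle = dental/alveolar,
back = postalveolar/palatal/velar — and is an editable TSV; a validation
test enforces the inventory and the 12/8 voicing split. Information
transfer is the plug-in Miller–Nicely estimator (base-2, `0·log 0 = 0`),
and relative IT divides by the input entropy computed from the stimulus
marginals. No small-sample bias correction is applied by default (the
classic analysis applies none); a Miller–Madow flag exists.

## Analysis pipeline

Group assignment is sequential: subjects arrive in order, are
pre-assigned round-robin, and are moved to the highest-mean group if
their balancing score falls below every current group mean (lowest-mean
group if above every mean) — "considerably lower/higher" is
operationalised as outside the [min, max] of current group means — with
per-group capacity enforced so sizes never deviate from n/3. A balance
check warns if final group means differ by more than a configurable
tolerance (default 5 points).

Models: linear outcomes (log10 thresholds, relative IT) go to a linear
mixed model with by-subject random intercept plus a random slope for
test, simplified to intercept-only when the larger structure fails to
converge (the structure used is recorded); binary trial-level outcomes
go to a GEE logit with exchangeable within-subject correlation, the
standard frequentist treatment of correlated binary responses —
estimates are population-averaged and Wald-based, and confidence limits
use the asymptotic normal approximation. Reference levels are
control/pretest; block (psychophysics) and centred trial order (VCV) are
additive covariates. Pre/post contrasts per group and their between-group
differences are linear contrasts of the fixed effects with normal-theory
CIs. Satterthwaite/Kenward-Roger degree-of-freedom corrections are not
re-implemented; the backend's defaults apply.

## Problem sizes and numerical notes

The default synthetic study is 3 × 18 subjects with 2 × 30-trial tracks
per task and session and 60 VCV trials per session. Test-suite runs use
smaller instances (5–6 per group, 100-trial tracks for steady-state
analyses, 500-track ensembles for convergence estimates, 10⁵-trial
chains for the Markov comparison); these sizes give Monte-Carlo errors
comfortably inside the asserted tolerances. Steady-state visit counts
are thinned at stride 40 — where the measured level autocorrelation
vanishes — before χ² comparison with the stationary distribution, since
raw counts from a single chain are serially correlated and would
invalidate the test. WAV I/O is scipy's RIFF reader/writer, PCM16
(clipped, ≤ 1 LSB round-trip error) or float32, mono enforced with an
explicit down-mix flag.

## Known limitations

- The vocoder is a faithful generic tone vocoder, not a bit-exact clone
  of any particular processor; envelope extraction is a plain 45-Hz
  low-pass with no pitch tracking.
- The VCV channel ignores vowel context and acoustic confusability;
  feature errors are independent.
- Bayes factors for group comparisons are out of scope (they depend on
  priors and data this package does not model).
- Headphone calibration, hardware timing and human-facing presentation
  are out of scope; the nominal SPL is documentation only.
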