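# Methods

## The measurement problem

In the first months of life the auditory event-related potential (ERP)
to rare sounds reorganises: newborn responses are driven by stimulus
*intensity* (a loud white-noise deviant elicits the largest P3), whereas
by around five months the largest P3 is elicited by stimulus *novelty*
(sounds never heard before). The size of this shift — the delta-P3 —
can be read out from a passive oddball session and used as an individual
marker of neurodevelopment, to be related to behavioural outcome scores.

This package implements the complete measurement chain for that marker
on *synthetic* data with known ground truth: no infant recordings are
distributed, so every stage is validated against a forward model whose
true effect structure is chosen by construction.

## Oddball session model

A session presents 1000 sounds of 100 ms (5 ms ramps): 800 *Frequent*
standards (a 500 Hz tone), 100 *Infrequent* deviants (white noise) and
100 *Trial Unique* novel sounds, each novel identifier occurring exactly
once. Inter-stimulus intervals are drawn uniformly on [650, 750] ms
(mean 700 ms); the trial order is an unconstrained uniform shuffle
(`DesignSpec` makes the counts, durations and jitter configurable).
Condition counts are exact by construction, never probabilistic.
Acoustic content is metadata only: the ERP analysis never touches the
waveform of the sound, so Trial Unique variability is represented purely
as unique identifiers.

## Synthetic EEG forward model

Eight channels (Fz, FC1/2, C1/z/2, CP1/2; left-mastoid reference) at
500 Hz. Each ERP component is a Gaussian bump in time — chosen because
its window means have a closed form, which makes measurement tests
analytic — with a fixed peak latency and width per age point:

* 1 month: N1 (100 ms, σ 25, −4 µV), P3 (350 ms, σ 30), Nc (650 ms,
  σ 40, −3 µV)
* 5 months: P1 (70 ms, σ 8, +2 µV), N2 (100 ms, σ 8, −2 µV), P3
  (300 ms, σ 30), Nc (600 ms, σ 40, −4 µV)

Only the P3 carries condition, cohort and age effects; the other
components are condition-independent, matching the null findings for
early components. Components project onto the montage with fixed gains
(Fz = 1.0; all analyses read Fz). Stimulus markers precede the true
acoustic onset by a hardware timing delay (32 ms by default), and the
neural response is locked to the sound — so the synthetic recording
genuinely requires the offset correction the preprocessing applies.

Amplitude habituation is exponential: trial *k* (within-condition
ordinal) has amplitude a₀(1−r)^k. The published quantity is only a
first-half/second-half difference, for which any monotone decay
suffices; the exponential is the simplest with a closed-form session
mean, which the calibration below exploits.

**Calibration on the measured scale.** Cohort ground truth
(`CohortGroundTruth`) specifies, per age × condition, the *session-
averaged P3 window mean* in µV — i.e. the number the analysis pipeline
should recover. The generator back-solves the Gaussian peak amplitude
a₀ = target / (g · c), where g is the closed-form session-mean decay
factor and c the window-mean factor of the unit Gaussian on the sample
grid. Recovery tests therefore compare measured values to stored truth
without re-deriving the forward model.

Noise is white + 1/f (half/half power split, 5 µV total SD per channel
by default), plus a slow sinusoidal drift (20 µV, 30 s period, random
phase per channel) standing in for sweat artifact — deliberately inside
the high-pass stopband. A configurable fraction of epochs (5% default)
receives a smooth 400 µV Hann pulse on one random channel, placed so it
stays inside its own epoch; these are guaranteed to trip the ±200 µV
rejection rule even after band-pass filtering.

### Cohort presets

Presets encode the qualitative developmental patterns of the two study
populations on the measured scale (µV window means):

| cohort | age | Frequent | Infrequent | TrialUnique | Infreq. decay |
|--------|-----|----------|------------|-------------|---------------|
| UK     | 1m  | 2.5      | 5.0        | 3.0         | 0.004 / trial |
| UK     | 5m  | 2.0      | 3.5        | 5.5         | 0.02 / trial  |
| Gambia | 1m  | 2.5      | 4.5        | 3.0         | 0.004 / trial |
| Gambia | 5m  | 2.0      | 3.5        | 2.0         | 0.004 / trial |

The UK preset encodes the crossover (Infrequent > TrialUnique at 1 m,
reversed at 5 m; true delta-P3 = +4 µV) and an increase of Infrequent
habituation with age. The Gambia preset holds the Infrequent−TrialUnique
contrast at +1.5 µV at both ages, so its true delta-P3 is exactly zero,
and keeps the habituation rate age-constant. Note one deliberate
simplification: holding the contrast exactly age-stable requires the
Trial Unique amplitude to decline in parallel with the Infrequent
amplitude, rather than staying flat; we prioritised an exactly-null
delta-P3 ground truth because that is the property the marker tests
must discriminate. Frequent trials habituate fast (0.02/trial) at both
ages in both cohorts, so their half-session difference is small — the
"rapid early habituation" account of flat Frequent scores.

Between-subject variability adds independent N(0, 0.8 µV) offsets to
each age × condition target; that makes the true per-subject delta-P3
vary (SD ≈ 1.6 µV), which is what the outcome score couples to:
outcome = 95 + 2.2 × delta-P3 + N(0, 12) by default (composite-score
points; slope units are points per µV). Anthropometric z-scores
(WAZ/LAZ/HCZ/WLZ at both ages) are multivariate normal with cohort-
specific means and uniform cross-correlation 0.45, mirroring the
reported "all r > 0.3" collinearity; WHO growth-standard computation
from raw measurements is out of scope — z-scores are consumed as given.

`simulate_marker_table` is a marker-level fast path (no EEG rendering)
drawing true delta-P3, a noisy measured delta-P3, covariates and the
outcome directly; replicate studies (type-I calibration, power, the
R²-change envelope at n = 150 × hundreds of replicates) use it because
full signal synthesis at those problem sizes would add hours of compute
without exercising any additional code path.

## Preprocessing

Fixed automated chain, in order:

1. **Band-pass 0.5–30 Hz**, Blackman-window FIR of order 5500
   (5501 taps ≈ 11 s at 500 Hz), applied zero-phase by centred FFT
   convolution of the symmetric kernel; channel means are removed first
   and the band-pass design removes residual DC. Recordings shorter
   than the kernel raise an error naming the minimum length.
2. **Timing-offset correction**: markers advance by
   round(32.0 ms × fs / 1000) = 16 samples (rounding half away from
   zero). The offset is a per-session configurable scalar; the reported
   between-session SD of the delay (2.6 ms) is not modelled.
3. **Epoching** −200…+800 ms, inclusive endpoints (501 samples),
   optional baseline correction by the −200–0 ms channel mean
   (on by default, toggleable: the upstream description never mentions
   baselining, and all contrast-based quantities are invariant to the
   common offset it introduces or removes).
4. **Artifact rejection**: an epoch is invalid if *any* channel's
   peak-to-peak range exceeds 200 µV, or falls below 0.1 µV (flatline).
   The any-channel veto is the strictest reading of a per-epoch rule;
   `reject_channels=("Fz",)` restricts screening to the analysis
   electrode.
5. **Trial equalization**: the two larger conditions are down-sampled
   without replacement (seeded) to the smallest valid count, preserving
   presentation order. Equalization runs after rejection and before
   every downstream measure, including the habituation half-split.
6. **Inclusion**: datasets with fewer than 15 equalized trials per
   condition are discarded.

## Component quantification

All measures are taken at Fz. Mean amplitude (not peak amplitude) is
measured inside fixed age-specific windows, inclusive of endpoints on
the 2 ms grid:

* 1 month — N1 50–150 ms, P3 250–450 ms, Nc 550–750 ms
* 5 months — P1 60–80 ms, N2 90–110 ms, P3 200–400 ms, Nc 500–700 ms

Requesting a component undefined at an age point (e.g. N1 at 5 months)
raises a registry error rather than returning a number. The very early
5-month P1/N2 windows are kept as configured defaults; `WindowSpec` is
fully configurable for other conventions.

Peak latency is the window argmax (argmin for negative components),
ties breaking to the earliest sample. Latency inference uses the
leave-one-out jackknife: n grand averages of size n−1, the peak latency
of each, then a paired t or repeated-measures F across those n values
with the statistics deflated — t_c = t/(n−1), F_c = F/(n−1)² — to undo
the variance shrinkage grand-averaging induces; p-values come from the
corrected statistic. A `correct=False` toggle reports raw statistics.
For designs with a between factor, leave-one-out averages are formed
within each group (grand averages never mix groups). Latencies landing
on a window boundary are flagged in the result.

## Markers

**Habituation score**: kept epochs of a condition, in presentation
order, are median-split (odd counts put the middle epoch in the first
half); the score is first-half minus second-half P3 window mean, so
positive scores mean response decrement. A session-midpoint split is
available as an option (`split="session"`); whether halves should be
formed before or after equalization is not determined by the source
description — the default (after) guarantees equal condition counts in
the halves.

**Delta-P3**: (Infrequent − TrialUnique) P3 mean amplitude at 1 month
minus the same contrast at 5 months; defined only for subjects with all
four cells. The sign convention makes a developmental shift toward
novelty positive, matching the positive association with outcome.
Being a contrast of contrasts, delta-P3 is invariant to any constant
added to all four measures — which is why baseline-correction and
trial-overlap offsets (see limitations) do not bias it.

## Statistics

* **Mixed RM-ANOVA** (`mixed_rm_anova`): sphericity-assumed
  ("averaged univariate") split-plot analysis for up to two within
  factors and one between factor, computed via multivariate OLS of the
  subject × cell matrix on an effect-coded between design, with
  orthonormal within contrasts; F for each effect is the ratio of SSCP
  traces. This reproduces the classical Type-III split-plot table —
  e.g. with 169 subjects in two cohorts, Condition is tested on
  df (2, 334) and Age on (1, 167) — including with unequal group sizes.
  Hand implementation was necessary because no installed package fits a
  2-within × 1-between design; it is cross-checked in the tests against
  pingouin (1 × 1 mixed and 2-within designs) and against the squared
  paired t. Greenhouse–Geisser correction is available
  (`gg_correction=True`) but off by default, matching integer-df
  reporting. Partial eta squared satisfies
  η²p = F·df1/(F·df1 + df2) exactly.
* **Paired contrasts**: scipy paired t with Cohen's d = mean difference
  / SD of differences.
* **Correlation comparison**: Pearson r per cohort, Fisher r-to-z, and
  z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)). The comparison's p is reported
  one-sided (the convention matching the published z/p pair), with the
  two-sided value alongside.
* **Hierarchical regression** (Models 1 and 2): candidate
  anthropometric predictors (Model 1: WAZ/LAZ at 5 m; Model 2: z-score
  changes 1→5 m) are screened by univariate p (lowest wins, ties
  alphabetical, logged); the winner forms the null model, delta-P3 is
  added, and the R²-change is tested with the single-predictor F.
  Candidate pairs with |r| > 0.9 raise a collinearity warning.
  Anthropometric p-values across models are FDR-corrected
  (Benjamini–Hochberg, via statsmodels).
* **State check**: each asleep subject is greedily matched to the
  closest-count awake subject within ±5 good trials (nearest count
  first, without replacement; unmatched subjects excluded with a log),
  then Condition × State is tested in the mixed ANOVA.

Two-sided p-values are used throughout except the correlation
comparison (above).

## Numerical choices

* Rounding of sample offsets: nearest, half away from zero.
* Window endpoints inclusive; the ms grid is the 500 Hz sample grid
  (2 ms steps).
* Peak ties break to the earliest sample.
* Degenerate zero-variance ANOVA inputs return F = 0 (all-equal data)
  or F = ∞ (systematic effect with zero error), with a numerical floor
  proportional to the data scale.
* Zero-variance paired differences with nonzero mean flag an infinite
  t with a warning rather than raising.
* All generators are `numpy.random.default_rng` with explicit seeds;
  fixed seeds give bit-identical sequences, recordings and cohorts.

## Problem sizes used in the test suite

The generator's defaults are the study conditions (1000-trial sessions,
500 Hz, 8 channels). The test suite scales *simulation sizes*, never
thresholds: cohort-recovery runs use 40 subjects per cohort with
400-trial sessions (320/80/80 split scaled to 320/40/40); jackknife
power uses 12 subjects × 200 replicates at the waveform level;
calibration uses 1000 null replicates per test family at the marker
level. These sizes give Monte-Carlo standard errors comfortably inside
the asserted envelopes.

## What the synthetic data does and does not establish

Passing tests show the chain is *correct*: exact design bookkeeping,
rejection identical to a brute-force oracle, window means matching
closed forms, jackknife corrections matching the cited formulas, and
unbiased recovery of known effect structure at realistic noise levels.
They do not show the chain is *sufficient for real infant EEG*: real
data have non-Gaussian, non-stationary artifacts (movement, fussing),
ERP shapes that are not Gaussian bumps, trial-to-trial latency jitter,
topographies that vary across infants, and state effects richer than a
scalar gain. Two known small biases of the measurement chain are
visible even on synthetic data and are inherent to ERP practice rather
than bugs: adjacent-trial overlap (the previous trial's Nc leaks into
the baseline window at 700–850 ms onset spacing) shifts all condition
means by a common offset, and the 0.5 Hz high-pass removes a few
percent of slow component energy. Both cancel in the contrast-based
markers; absolute single-condition amplitudes should be interpreted
with that in mind.

## Known limitations

* EDF files can be read (via MNE) but not written; the native exchange
  format is the documented TSV dialect.
* The ANOVA requires complete within cells per subject; there is no
  mixed-model handling of missingness (explicitly out of scope).
* Sleep state is a scalar amplitude modifier in the generator; sleep
  microstructure is not modelled.
* The sequence generator imposes no minimum spacing between oddballs;
  a constrained order would need a custom generator.
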