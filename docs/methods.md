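# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Trial structure and the calcium kernel

All analyses assume trial-structured recordings: each stimulus (sweep,
looming, prey) is presented 8 times for 4 s at a 2 Hz volumetric frame
rate. A *trial window* spans the stimulus duration plus a post-stimulus
tail of twice the calcium decay constant, so the slow indicator's decay
is captured; at the defaults (τ = 3.5 s, 2 Hz) a window is 22 frames.
Windows of one stimulus share a length so responses can be averaged
across repeats.

The calcium kernel is a single-exponential decay, peak-normalized and
truncated where it falls below 1% of peak. τ defaults to 3.5 s —
appropriate for a slow nuclear-localized indicator; there is no rise
time, which at 2 Hz sampling is below one frame anyway. Regressors are
unit boxcars over (subsets of) stimulus presentations convolved causally
with this kernel; causality guarantees a regressor is exactly zero
before its first event.

## Sensory Index

The SI is formalized as a variance ratio: the variance of the
trial-averaged response (tiled at each window position) divided by the
variance of the actual trace over the concatenated windows, both after
subtracting the window-restricted mean. This makes SI

* exactly 1 for a perfectly repeatable response,
* invariant to gain and offset of the trace,
* ≈ 1/n for pure noise under n repeats. The exact finite-sample
  expectation is (1/n)·((L−1)/L)/((N−1)/N) for windows of L frames
  (N = nL total); the unit tests assert this exact value.

A constant trace has undefined SI and is excluded from ranking.

Selection is two-stage because periodicity alone also admits flat or
slowly ramping traces: first the top 10% of the active population by
Pearson correlation with the stimulus regressor (computed over the full
trace), then the top 15% *of that decile* by SI. Percentile thresholds
are computed within fish before any pooling, since absolute response
amplitudes are not comparable across animals. Counts use ⌈pct·n/100⌉
with ties broken by stable neuron-id order. Note the arithmetic
consequence: the cascade can select at most 1.5% of the scored
population per stimulus, which bounds achievable recall when more than
1.5% of neurons are genuinely stimulus-locked.

## Active neurons and the colocalization filter

A neuron is *active* when, for some stimulus or behavior, at least 30%
of the relevant trials are individually "responsive": the Pearson
correlation between the single-trial trace segment and the
kernel-convolved single-trial regressor segment reaches r ≥ 0.5. Both
the per-trial statistic and its threshold are exposed as configuration;
correlation was chosen over amplitude because it is invariant to the
trace's scale. For a behavior, the relevant trials are the paired
stimulus's presentations annotated with that behavior.

The cross-animal colocalization filter keeps a candidate neuron iff
same-class candidates from at least `min_fish` (default 2) *other* fish
lie within `radius_um` (default 20 µm) in the shared coordinate frame,
using a KD-tree per fish and class. An optional permutation test
compares the mean neighbor support against candidates redrawn uniformly
from each fish's full coordinate table. The filter is a one-pass
neighbor count over the input candidate set; on mutually supporting
(clustered) candidates it is idempotent.

## Trace surplus and MSI

The surplus subtracts the trial-averaged response within each window
and the non-window baseline mean elsewhere, so it is mean-centered
everywhere and sums to zero across windows at every within-trial time
point. The MSI is the Pearson correlation between the surplus and the
visuomotor regressor over the full trace.

A useful exact identity: for a noiseless neuron gated on n_b of n
trials with a matched kernel, the surplus is (1−n_b/n)·r in behavior
windows and −(n_b/n)·r in the others, giving MSI = √(1−n_b/n) — about
0.79 for 3 of 8 trials. MSI is therefore high but bounded away from 1
even in the ideal case; the 97th-percentile within-fish threshold, not
an absolute MSI value, defines SM neurons. Percentile ranks use the
Hazen definition ((rank−0.5)/n), so the 97th percentile selects exactly
the top 3%. Motor enhancement (mean peak response in behavior trials
minus no-response trials, per MSI-percentile bin over 90–99) provides a
data-driven check of that threshold; the elbow locator returns the grid
point of maximum discrete curvature, falling back to the top of the
grid when bins are too sparse to bend.

## Held-out behavioral decoding

For each held-out trial of the paired stimulus, SM neurons are
re-selected from the remaining trials only: trial average, surplus, and
visuomotor regressor are all restricted to the training windows, so no
held-out activity leaks into selection. The decoder's statistic is the
maximum over the trial window of the mean ΔF/F across selected SM
neurons; classification uses the midpoint between the training classes'
mean statistics — the simplest separable rule, exposed as a design
seam. The null repeats the entire procedure on behavior annotations
permuted within fish. With a single fish and 8 trials the permutation
space is small, and a permuted annotation occasionally coincides with
the true one; null accuracy distributions are therefore reported in
full rather than summarized by a single quantile.

## Behavior-conditioned partial correlation

Trials of the paired stimulus are split into behavior and nonbehavior
classes; each class's trial-averaged template is subtracted from its
own windows, making the class-mean residual exactly zero at every
within-trial time point. The partial correlation given behavior is the
Pearson correlation of two neurons' concatenated residuals; on
linear-Gaussian data with a binary behavior confound it agrees with the
textbook partial-correlation formula (verified to 0.02 at 10⁴ frames).

Because an SM neuron plausibly receives input from a sparse subset of
sensory neurons, it is summarized by the 90th percentile (linear
interpolation) of its partial correlations with the whole sensory
population; with fewer than 10 sensory neurons the percentile is
degenerate and a warning is issued. Significance uses a trial-shuffled
null: the SM residual's window segments are reordered by a random
permutation *within* trial class (999 draws by default), preserving
each segment's waveform, the marginals, the autocorrelation, and the
behavior structure, while destroying within-trial pairing; the sensory
residuals stay fixed. Empirical p-values use the add-one rule
(1+#{null ≥ stat})/(1+n_perm). Benjamini–Hochberg adjustment is applied
within area × behavior × fish, fractions significant are reported
pooled and per fish, and a one-sided Wilcoxon signed-rank test across
fish compares per-fish fractions to the chance level α.

Two controls are built into the tests: traces constructed as class
templates plus independent noise yield near-zero significant fractions
(the subtraction itself does not manufacture correlations), and under
the behavior-only scenario the p-values are calibrated.

## Physiology

Rhythmic-pixel masking uses the fraction of non-DC periodogram power in
the 1.5–5 Hz cardiac band; the threshold is the top quartile of that
fraction across pixels, floored at 0.2. The quartile uses the 'lower'
method so that when rhythmic pixels exceed a quarter of the ROI the
threshold stays at the background level instead of cutting into the
rhythmic cluster.

Beat detection smooths the masked-mean intensity with a 30 ms Gaussian
(well under one cardiac period, so peaks are preserved while frame
noise that would mislocalize them is suppressed), then finds local
maxima with a minimum separation of one period at the band's upper edge
and a prominence floor of twice the MAD of the detrended trace.
Instantaneous heart rate assigns each frame the reciprocal of the
enclosing inter-beat interval (piecewise constant; linear interpolation
between interval midpoints is available).

Bradycardia is flagged when the rate trace runs below
(baseline mean − 3·baseline SD) with the run's onset inside the
stimulus window; the baseline window must precede the stimulus and span
at least 10 s, and a zero-variance baseline falls back to a 0.05 Hz SD
floor. The "3 SD" exceedance reading of the definition is isolated in
this one operation and configurable.

Trial classification: eye convergence in the stimulus window → hunting;
fast large-amplitude swim → escape; no movement at all plus
bradycardia → freezing; two or more of these → excluded; none → none.
Immobility without bradycardia is *not* freezing. The rule is total and
order-invariant in its inputs.

## The synthetic-data generator

The generator emulates exactly the structure the analyses assume:
sensory neurons emit a boxcar response on every presentation of their
stimulus (per-neuron lognormal amplitude, σ = 0.2; per-trial lognormal
gain jitter, σ = 0.2), SM neurons respond only in trials of their
paired stimulus annotated with their behavior, mixed neurons carry both
components, and background neurons are pure noise. Drives are convolved
with the calcium kernel and contaminated with i.i.d. Gaussian noise
(σ = 0.2 ΔF/F); the default response amplitude of 0.6 gives an
amplitude SNR of 3. Per-trial behavior labels are drawn i.i.d. with
sweep freezing-dominant, looming escape-dominant, and prey
hunting-dominant probabilities. The interstimulus interval is
compressed to 20 s (the experimental 2 min only pads the recording);
class cluster centers in a shared coordinate frame are jittered 5 µm
per fish so planted classes colocalize across animals while background
neurons scatter.

Under a connectivity scenario, sensory trial-to-trial variability gains
a population-shared part: a common per-trial response gain and a common
within-trial co-fluctuation (σ = 0.3 before convolution, spanning the
full trial window) on top of half-amplitude private fluctuations.
This models attention/state-like signals that move a sensory population
together — precisely the single-trial structure connectivity inference
relies on; without it, a sparse readout could never correlate with most
of the population and the 90th-percentile statistic would be powerless
by construction. Under **H1**, each tectal SM neuron of the scenario
behavior adds `weight/k` times the stochastic component of each of its
k randomly chosen sensory inputs (weight 0.8, k = 3); connections are
recorded as ground truth. Under **H2**, SM neurons share only a
per-trial "decision" gain, with within-trial fluctuations independent
of the sensory population. H1 connections are confined to the tectum so
the isthmic (NI) SM population serves as an out-of-area control.

Heart-pixel videos oscillate at a prescribed instantaneous rate with
shared phase and per-pixel amplitude; beat times are the phase's 2π
crossings. Trial rate profiles wander smoothly (Gaussian noise
low-passed at 1 s, SD 0.3 Hz around 3.2 Hz); the 1 s timescale keeps a
15 s baseline window statistically representative of the whole trial —
with much slower wander the baseline under-estimates the process
variance and slow drifts masquerade as bradycardia. Programmed drops
step the rate to 3.5 trial-baseline SDs below the trial's own baseline
mean, matching how the detector measures excursions.

What the generator does **not** emulate: raw image formation, motion
artifacts, spike-train statistics beyond kernel convolution, correlated
(non-i.i.d.) measurement noise, overlapping or variable-duration
behaviors, and drift in neuron positions. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative assumptions, not robustness to every artifact of real
recordings.

## Scales, seeds, and numerical choices

Simulations run at desk scale: 3 fish × ~925 neurons (≈1,000-neuron
scored population, 2.5% planted sensory per stimulus, 2.5% SM per
behavior), 24 trials per fish, 199–999 permutations for
partial-correlation nulls, 100 permuted annotations for the decoding
null, and 200 trials for the bradycardia operating characteristics.
Every random stage takes an explicit seed; child seeds are spawned
through `numpy.random.SeedSequence`, so identical configurations yield
bit-identical outputs, and pipeline runs with the same seed write
byte-identical directories (HDF5 files are written without
modification-time tracking for this reason).

Degenerate inputs are handled explicitly: zero-variance traces are
flagged (SI undefined; MSI and partial correlation 0 with a warning),
empty trial classes and identity-only permutation spaces raise errors
naming the deficiency, and a single-fish colocalization call is skipped
with a warning rather than silently filtering.

## Known limitations

* With 8 trials and a slow kernel, residual traces have few effective
  degrees of freedom; trial-shuffled nulls are honest about this (they
  are wide), so per-neuron power depends on strong shared single-trial
  structure.
* The percentile cascade caps sensory selection at 1.5% of the scored
  population, bounding recall when planted prevalence exceeds that cap.
* At desk scale the 97th-percentile SM threshold yields few selections
  per fish, so the colocalization filter can be harsh on selection-level
  analyses; the partial-correlation validations therefore run on planted
  populations, keeping selection and inference concerns separate.
* Behavior annotations are taken as given per trial; within-trial
  behavior timing (onset latency, vigor) is out of scope.
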