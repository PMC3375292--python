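# Methods

This note documents the models and procedures implemented in `callsig`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real
recordings.

## Synthetic call model

A note is a downward frequency-modulated sweep with up to three
harmonics. Its instantaneous fundamental follows a monotone
piecewise-cubic (PCHIP) interpolant through anchor frequencies given at
relative positions 0, 0.5, 0.9 and 1.0 of the note; PCHIP preserves the
strictly-downward sweep between anchors, which linear interpolation also
would, but without slope discontinuities at the anchors (linear is
available as an option). The species profiles place the anchors at the
published per-species mean values of the fundamental at the start, 50%
and 90% positions, with mean duration and mean relative harmonic
amplitudes; the 100% anchor, which the species tables do not report, is
set slightly below the 90% value (continuing the 50→90% descent at 40%
of its rate) so the sweep stays monotone to the end. The small terminal
up-turn implied by the reported positive slope at the 90% position is
deliberately not emulated: the generator's defining invariant is a
monotone downward sweep, and an upturn would complicate both the
invariant and the tracking without changing anything the analyses test.

The waveform is a harmonic stack: partial *k*′ (1 = fundamental) is a
sinusoid at *k*′ times the instantaneous fundamental with amplitude
20 log₁₀(*a*<sub>k</sub>/*a*₀) dB relative to the fundamental. Partials
are gated to zero (with a 0.2 ms taper) wherever they would exceed 95%
of Nyquist — at 250 kHz sampling the 4th partial of the
highest-frequency species exceeds Nyquist over roughly the first fifth
of the note. A raised-cosine onset/offset ramp of 10% of the duration
at each end shapes the envelope; real notes' envelopes are not
described in the source material, and the exact ramp shape is
immaterial to every measurement except a slight attenuation of
track-endpoint energy. Noise is additive white Gaussian, scaled so the
ratio of peak short-time (0.5 ms) note power to noise power equals the
configured SNR; the default is 30 dB, the level at which tracking
accuracy is indistinguishable from noiseless within two FFT bins.

### Hierarchical variance structure

Every perturbable parameter (duration, each anchor frequency, each
harmonic offset) of a note is the species mean plus independent
Gaussian colony, individual, optional session, and note effects; colony
and individual effects are drawn once per level and shared by all notes
beneath it. Anchors past the 90% position are not perturbed
independently: they ride along with the 90% anchor's total effect, so
the profile's terminal shape is preserved and the small terminal
frequency gap cannot be inverted by noise. This is exactly the nested random-effects model the
variance-component analysis assumes. Gaussianity is an assumption — the
source material reports no within-individual distributional form — and
is flagged as such. Perturbations that break the downward-sweep
invariant are redrawn (up to 100 attempts, then an error reports that
the configured variance is too large for the profile), which truncates
the effective distributions slightly at extreme settings.

The default `realistic_sds` scales per-level standard deviations to the
species means (within-note effects largest, individual next, colony
smallest: 10/8/4% of duration, 6/4.5/2% of mean frequency, 2/1.5/0.75 dB
on harmonics), chosen so single-parameter individual repeatabilities
land near 0.2–0.35 — the regime of highly variable contact calls where
signature information is present but within-individual variation
dominates. Multi-note calls follow the species' note-count distribution;
later notes share the call's individual effects but draw fresh note
effects, with inter-note intervals Normal(21.5 ms, 1 ms) truncated above
5 ms. Sexes alternate across subjects and carry no acoustic effect by
default. Datasets are written as one 16-bit PCM WAV per
individual-session at half full scale (inside the 10–99% unclipped
screen) with a ground-truth annotation CSV; everything is reproducible
from the configuration seed.

What the generator does **not** emulate: echolocation pulses and
distress calls, room reverberation and microphone directionality,
frequency-dependent noise, amplitude modulation within notes,
non-Gaussian or correlated parameter variation, and drift across
recording sessions beyond an optional Gaussian session effect. Passing
round-trip and recovery tests on these synthetics therefore validates
the *estimators* — not the claim that real calls satisfy the model.

## Spectrograms and measurements

Spectrograms use 0.5 ms Blackman windows (125 samples at 250 kHz)
zero-padded to 512-point FFTs — a 488.28 Hz bin grid — with 50% overlap.
Note that the *resolution* is set by the window (≈3.4 kHz Blackman main
lobe), the padded grid only interpolates it; this is why harmonic peak
measurements survive the sweep-induced spectral broadening.

The fundamental is tracked per note by band-limited peak picking with a
continuity constraint. The anchor frame (strongest in-band energy)
picks the **lowest** local maximum within 25% of its in-band peak
magnitude rather than the global maximum: in two of the three species
the first harmonic carries *more* energy than the fundamental, so a
loudest-peak rule would lock onto a harmonic wherever it enters the
search band. From the anchor the track propagates outward, each frame's
search restricted to ±3 bins around its neighbour's peak (at the 0.25 ms
frame step this caps the trackable sweep rate at ≈5.8 kHz/ms, above the
steepest species' mean slope), with 3-point parabolic interpolation on
log magnitude for sub-bin precision. The per-frame track is resampled to
the 10% relative-position grid by linear interpolation in time; the
value at position 0 is linearly extrapolated from the first two frames,
because the first frame center sits half a window into the note and the
raw first-frame value would understate the onset frequency of steep
sweeps by more than a bin. Tracks with more than 30% of frames below a
noise-floor criterion are flagged low-confidence, not rejected.

The 36 measurements per note are: duration (from the annotation marks —
segmentation is taken as given, mirroring hand-labeled starts/ends);
fundamental frequency at the 10 positions 0–90%; frequency of most
energy (FME) of the fundamental and harmonics 1–3 and the time of each,
where partial *k*'s band at each frame is (*k*+1)·f₀(t) ± f₀(t)/2 —
half-widths chosen so bands tile the spectrum without overlap, the band
rule itself being a declared assumption; slopes at 20–80% in 10% steps
as central differences of the track over ±10%; concavities at the same
positions as second central differences; and the peak-magnitude ratio
of each harmonic band to the fundamental band in dB. A harmonic whose
band lies above Nyquist at every frame yields missing values for that
harmonic's fields. There is a documented tension in the source tables
between the 20–80% slope grid used for the discriminant variable set
and slopes reported at 10/50/90% in the species summary; the 36-vector
follows the 20–80% grid, and `slope_at`/`concavity_at` evaluate
arbitrary positions so either summary is producible.

Filtering: only first notes of calls at least 30 ms after the previous
note's offset enter the single-note analyses; individuals with fewer
than 45 notes are dropped (with an audit report); the double-note
analysis pairs the first two notes of multi-note calls and appends the
inter-note interval as a 73rd variable, with an optional reduced
variable set omitting the interior 20–40% and 70–80% frequencies.
An amplitude screen excludes notes whose peak sample falls outside
10–99% of full scale.

## Information capacity

The number of components to extract is decided by parallel analysis:
correlation-matrix eigenvalues are compared against the 95th percentile
of eigenvalues from 1000 random standard-normal datasets of identical
shape (the common default for this procedure; a permutation-of-columns
null is available). The leading run of observed eigenvalues above the
null percentile is retained.

PCA is computed on the correlation matrix — the variables mix ms, kHz,
kHz/ms and dB, so standardization is the only defensible scaling — and
the retained loadings are varimax-rotated with Kaiser normalization.
The rotation uses Kaiser's pairwise planar algorithm, in which the
optimal angle for each component pair has a closed form; the popular
SVD-based fixed-point iteration was found to stall at non-simple
stationary points on exactly the block-structured loadings these
analyses produce, so the pairwise form (which solves two-component
problems exactly) is used throughout. Component scores use the Bartlett
(weighted least squares) estimator with uniquenesses clipped below at
10⁻⁶.

Variance components for the declared random factors are estimated per
component by REML. Nesting is declared outermost-first (species ⊃
colony ⊃ individual) and inner level codes are prefixed with their
outer levels so nesting holds regardless of level naming. Single-factor
models use an in-package profiled REML — the likelihood is profiled
down to a one-dimensional bounded optimization over the variance ratio,
numerically exact (it reproduces the balanced-design ANOVA moment
estimator to better than 10⁻⁶). Multi-factor nested models go through
statsmodels `MixedLM` variance components with a sequence of optimizers
tried in turn. Negative components are truncated at zero with a
warning; a factor whose grouping exactly duplicates its outer factor's
(e.g. one colony per species in a small design) is dropped as
unidentifiable, with a warning. The source text contains an apparent
typo labelling within-individual variance with the total-variance
symbol; it is read here as *S*²<sub>w</sub>.

Signature information per component is
*H*<sub>i</sub> = ½ log₂(*S*²<sub>T</sub>/*S*²<sub>w</sub>) — the printed
form log₂(*S*<sub>T</sub>/*S*<sub>w</sub>) on standard-deviation scale —
with *S*²<sub>B</sub> the sum of the signature factors' components
(colony + individual by default; species excluded, configurable) and
*S*²<sub>T</sub> = *S*²<sub>B</sub> + *S*²<sub>w</sub>. Totals sum over
components; repeatability is *S*²<sub>B</sub>/(*S*²<sub>B</sub>+*S*²<sub>w</sub>).
Per-subset information estimates re-extract components on the subset by
default (global-model reuse by flag), since which variant produced the
published per-population figures is not stated. Factor attribution
weights each component's fractional variance share by the component's
explained-variance proportion, normalized so factors plus residual sum
to 100%.

## Discriminant analyses

Conventional DFA builds canonical discriminant functions from the
pooled within-class covariance (unit within-class variance scaling),
classifies by smallest pooled-covariance Mahalanobis distance to class
centroids with equal priors, and reports resubstitution and
leave-one-out rates (the leave-one-out loop uses exact rank-1 downdates
of the pooled SSCP inverse, verified against brute-force refitting).
Wilks' Λ = det(W)/det(T) is tested with Bartlett's approximation
χ² = −(n − 1 − (p+g)/2) ln Λ on p(g−1) degrees of freedom — the
specific χ² approximation is a choice, as the source names the test
family without a formula. The structure matrix reports pooled
within-class correlations of each variable with each discriminant
score, with a top-5 summary per function.

The pDFA takes a test factor and a control factor nested within it.
The training-set size per subject defaults to ⌊2n_min/3⌋ where n_min is
the smallest subject's note count, guaranteeing held-out notes for
every subject; the observed statistic is the mean held-out rate over
100 balanced training draws, and the null reshuffles the subjects'
test-factor labels (level sizes preserved) 1000 times, re-running the
full observed-stage procedure each time. The p-value is the plain
proportion of null rates at least as large as the observed rate, with a
+1/(N+1) variant by flag. Note the permutation ties: when a shuffle
reproduces the observed subject partition the null rate equals the
observed rate, so designs with very few subjects cannot reach p = 0.
Family-wise error over a battery of tests uses the Holm step-down
ladder. Two further summary statistics: a pooled two-sample two-tailed
t-test comparing per-bat classification rates between groups, and a
χ²(1) outlier test referring a candidate rate's squared deviation from
the mean of the *other* rates (scaled by their sample variance) — the
exclusion of the candidate from the reference moments is this package's
reading of the unreferenced test, and published values of it are not
reproducible without the unprinted inputs.

## Pipeline defaults and problem sizes

The end-to-end `run()` defaults simulate three populations (a captive
colony of 4, four wild singleton colonies, and a captive colony of 4 of
a second species) at 50–60 calls per bat — enough that every individual
clears the 45-note filter while keeping a full run around a minute.
The acceptance script scales Monte-Carlo studies similarly (100–200
replicates, 200-permutation nulls, 5 training draws per pDFA stage);
these sizes give standard errors comfortably inside the tested
tolerances and are stated in each test's docstring.

## Known limitations

- The generator's Gaussian, independent parameter perturbations are a
  modelling choice, not an observed property of vampire bat calls.
- Fundamental tracking assumes a single tonal sweep per annotation; it
  has no provisions for overlapping calls, subharmonics, or deterministic
  chaos in the source signal.
- `MixedLM`-based nested variance components can be fragile for factors
  with very few levels (species has only three); the per-component
  estimates are then dominated by sampling noise, exactly as in the
  original analysis design.
- pDFA p-values are discrete (multiples of 1/N); calibration holds in
  the super-uniform sense.
- Information estimates treat varimax-rotated components as
  independent; correlated residual structure between components biases
  H_s upward, a property inherent to the method rather than to this
  implementation.
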