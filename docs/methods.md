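# Methods

`hrvmp` implements a short-term heart-rate-variability (HRV) screening
pipeline for congestive heart failure (CHF): 256-beat RR segments are
decomposed by matching pursuit (MP) over a Gabor dictionary, 16 features
are derived from the decomposition, and a genetic algorithm (GA) searches
the 2^16 feature-subset space against the cross-validated error of a
k-nearest-neighbour (KNN) classifier. This note records the model, the
numerical choices, and what the synthetic data do and do not establish.

## Preprocessing

An RR series (one interval in ms per beat) is reduced to a 256-beat
window, which at typical heart rates spans roughly the five minutes of a
short-term HRV recording.

**Resampling.** The window is interpolated with a natural cubic spline
through the knots (cumulative beat time, interval value) and evaluated on
1024 equally spaced points spanning `[0, sum(intervals)]`. The nominal
rate is 4 Hz, but "1024 samples at exactly 4 Hz" is only consistent when
the 256 beats span 255.75 s; because the MP dictionary needs a fixed
signal length, we fix n = 1024 and record the effective rate
`fs = 1023 / duration` (4.995 Hz for 800 ms beats), which is then used
for every conversion of atom frequency to Hz and for all band edges. The
short lead-in before the first knot is covered by the spline's end
polynomial, which is exact for constant and linear series.

**Detrending.** Smoothness-priors detrending subtracts the trend
`(I + lam^2 D2' D2)^{-1} x` (D2 the second-difference operator), acting
as a time-varying high-pass filter. `lam = 500` — a common published
default for 4 Hz HRV, cutoff near 0.035 Hz — is used throughout and is
configurable. Larger `lam` removes less; lines are in the null space of
D2 and are removed exactly for any `lam`. The output mean is subtracted,
so segments entering MP are exactly zero-mean.

## Matching pursuit

The dictionary is the canonical dyadic Gabor family: scales `s = 2^j`,
`j = 1..log2(n)`, translations spaced `s/2`, frequencies spaced `pi/s` in
`[0, pi]` rad/sample — about 22.5k parameter triples for n = 1024, so the
family is strongly overcomplete. The phase is never gridded: for each
triple the residual is projected onto the span of the cosine/sine
quadrature pair (orthonormalised once at build time), which yields the
exact optimal-phase projection. Ties in atom selection go to the lowest
atom index, making runs bit-reproducible.

Each iteration subtracts the full 2-D projection onto the selected
triple, so the residual update obeys Pythagoras exactly and
`signal energy = sum(c_n^2) + final residual energy` holds to rounding
error. The loop runs M = 30 iterations (the reconstruction budget used
throughout) and stops early when the residual falls below 1e-13 of the
signal energy. Residual energies are recorded after every iteration;
they are non-increasing by construction. Coefficient magnitudes are
*not* monotone in general — only the residual energies are, and tests
assert exactly that.

Band logic assigns each atom wholly to the band of its centre frequency
(Task Force edges: VLF 0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz). A
band-restricted quadratic time-frequency energy integral would reduce to
this assignment for well-localised atoms; the cross-term-free per-atom
binning is the implemented reading.

## The 16 features

Fixed order: `E(VLF), E(LF), E(HF), E`; `VLF, LF, HF, HF/VLF, HF+LF`;
`Hw(LF), Hw(HF)`; `D(LF), D(HF), D(HF)/D(VLF), D(VLF)/D(LF),
D(LF)/D(HF)`.

* **Residual-energy decay** `E(band), E`: the mean over the M iterations
  of the (band-restricted) residual energy, divided by the signal
  energy. Coherent signals decay fast (low E); noise-like signals decay
  slowly (high E).
* **PSD band powers**: each band's subsignal (reconstruction from that
  band's atoms) is passed through a Welch periodogram — rectangular
  window, segment length 256, 50% overlap, all configurable — and the
  density is integrated over the band's bins. Absolute powers are stored
  per unit signal variance so every feature is invariant to rescaling
  the input; the HF/VLF ratio is formed from the normalised powers
  (identical to the raw ratio whenever VLF > 0). `HF+LF` is the sum of
  the two normalised band powers.
* **MP entropy** `Hw(band)`: Shannon entropy (bits) of
  `p_n = c_n^2 / sum(c^2)` — atoms are unit-norm so `c_n^2` is the atom
  energy — summed over the band's atoms. Normalisation is global (the
  band restricts the summation only), so the band entropies are
  sub-additive parts of the full spectrum entropy; per-band
  renormalisation is a documented alternative that was not adopted.
* **Frequency distribution** `D(band)`: fraction of the M atoms whose
  centre frequency falls in the band, plus ratios.

Ratios with denominators below 1e-12 are defined as numerator / 1e-12
capped at 1e6: features stay finite, and the MinMax scaling downstream
compresses the caps. Degenerate inputs (zero-variance segments) are
rejected rather than silently producing NaNs.

## Classification and validation

Features are MinMax-scaled per column to [0, 1] (constant columns map to
0). Scaling is applied to the full table before cross-validation — a
dataset-level preprocessing step — with a strict train-fold-only mode
available (`minmax="fold"`) for leakage-free comparisons.

KNN uses Euclidean distance with odd k (even k is rejected: a two-class
vote could tie); distance ties resolve to the lower training-row index
via a stable sort. Validation is a seeded 23-fold scheme — 69 subjects
give 23 folds of exactly 3 — and all held-out predictions are pooled
into a single confusion matrix: with fold size 3, per-fold sensitivity
and specificity are frequently undefined, so pooling is the only
well-defined reading. CHF is the positive class. Sensitivity is
TP/(TP+FN) and specificity TN/(TN+FP), the standard forms; undefined
rates are reported as missing, not zero. The selection fitness is the
error rate `theta = 1 - Ac/100`. Folds are random but seeded;
stratification is off by default and available as an option.

## GA feature-subset selection

Chromosomes are 16-bit inclusion masks; fitness is the cross-validated
KNN theta, so operationally this is a wrapper-style search even though
filter terminology is sometimes attached to such architectures.
Configuration: population 300, up to 100 generations, double-point
crossover with Pc = 0.7, per-bit mutation Pm = 0.05, linear rank
selection with pressure 2.0 (the dialect had to be fixed; pressure is
configurable), 2-elitism, and early stop when the best-ever fitness has
not strictly decreased for 30 consecutive generations. Fitness is
memoised per unique mask — the space has only 65 536 points — which
makes the default run cheap. Empty masks score theta = 1 rather than
being re-drawn.

## Synthetic data

Real recordings require external downloads, so the package ships a
generator that emulates the two populations' contrast. Each interval is
the mean RR plus sinusoids at fixed VLF/LF/HF frequencies evaluated at
the cumulative beat time, plus white and 1/f-coloured noise; fixed tones
keep band-power ground truth analytically known. When a target SDNN is
set, the composed fluctuation is rescaled to that overall SD (this pins
the between-class variability contrast; the band mix is unchanged).
Intervals are clipped to a physiological 200–2500 ms.

Presets (amplitudes in ms): NSR-like — mean RR 900, SDNN 50, tones
10/30/30 at 0.033/0.1/0.25 Hz, white 15, 1/f 18; CHF-like — mean RR 700,
SDNN 18, tones 25/4/1.5, white 1.0, 1/f 2.0. The VLF tone sits at
0.033 Hz, near the top of the VLF band, so that a useful fraction
survives the 0.035 Hz detrender cutoff; a tone much lower in the band
would be removed almost entirely and the VLF contrast would vanish at
the feature stage. Cohorts draw per-subject parameters with ±10% uniform
jitter on amplitudes, noise levels, SDNN and mean RR — enough within-
class spread to be non-trivial without destroying separability. The
default cohort is 40 NSR-like and 29 CHF-like subjects, one 256-beat
segment each, mirroring the study layout.

What the generator does **not** model: ectopic beats and artefacts,
non-stationary drift within a segment, respiratory frequency wander,
segment-selection variability from long recordings, and any coupling
between heart rate and variability beyond the preset means. Passing the
end-to-end tests therefore shows that the pipeline separates populations
with the *designed* spectral/structural contrast; it is not evidence
about performance on clinical recordings.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at the
study scale (69 subjects, 1024-sample segments, 30 atoms); heavier
Monte-Carlo checks use 100–200 segments. The GA acceptance checks use a
reduced population (50) and generation budget (30) on 8-feature tables,
where exhaustive search over all 255 masks is the oracle. Every source
of randomness flows from an explicit seed; repeated runs are
bit-identical.

## Known limitations

* The dictionary discretisation and the rank-selection dialect are
  canonical choices, not uniquely determined by the method description.
* Atom-to-band assignment ignores spectral leakage of wide (small-scale)
  atoms across band edges.
* The HF/VLF cap (1e6) is visible in NSR-like cohort means whenever a
  subject has no VLF atom; medians are unaffected and classification
  operates on MinMax-scaled values.
* Dataset-level MinMax scaling leaks fold information by construction;
  the fold-only mode exists for clean comparisons.
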