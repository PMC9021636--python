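# Methods

This note records the model, the numerical conventions, the synthetic study
conditions, and the design choices made where more than one reasonable
option existed. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The transform

The CWT is implemented as a cross-correlation on a unit channel grid
(Δx = 1):

    W(a, b) = a^(-1/2) Σ_i f(x_i) ψ((x_i − b)/a)

with the `a^(-1/2)` prefactor (some software uses `1/a`; the choice only
rescales rows per scale and does not affect per-row extrema positions, but
it does affect which scale wins the per-channel max — see "Resolution
behaviour" below). Scales are positive integers in all pipeline code;
the low-level routines accept any positive real.

**Centring.** Every mother wavelet is centred on the origin at load time,
so the translation parameter `b` addresses the wavelet's centre. This is
what makes two textbook properties hold at the *exact* extremum channels:
Haar coefficients of a locally symmetric peak/trough vanish at its centre
(first-derivative character), and a mexh coefficient is maximal and
positive at a peak centre (negated-second-derivative character, with the
peak-positive sign convention fixed for mexh and gaus2). With the
uncentred (left-edge) convention both zero crossings and maxima would be
offset by half the dilated support.

**Sampling conventions.**

- `haar`: closed form; the value at its jump points (−1/2, 0, 1/2 after
  centring) is defined as 0 (midpoint convention). The sampled kernel is
  then exactly antisymmetric, so coefficients vanish identically at
  symmetric extrema. Consequence: on an integer grid the Haar rows at
  scales 1 and 2 sample only jump points and are identically zero; Haar is
  useful from scale 3 up (and is excluded from calibration sweeps anyway
  because of its first-derivative character).
- `mexh`, `gaus2`: closed forms, L2-normalised, with effective supports
  (−10, 10) and (−8, 8); beyond these the tails are below 1e-13 of the
  peak, negligible at the engine's 1e-10 exactness target.
- `db2`, `sym2`, `coif1`, `meyr`, `bior2.x`, `rbio2.x`: sampled from the
  PyWavelets filter-bank limit (`wavefun`, level 12) and evaluated by
  linear interpolation, zero outside the sampled support. For the
  biorthogonal pairs the *decomposition* (analysis) wavelet is used. The
  sampled table is truncated where |ψ| < 1e-12·max|ψ| and then
  mean-corrected (ψ ← ψ − mean ψ): the raw Meyer samples carry a numerical
  mean of ~8e-4 which would otherwise violate admissibility; for the other
  families the correction is at machine-precision level.

**Boundary extension.** Signals are extended by the dilated kernel radius
before correlation and cropped back, so output length equals input length.
Default mode is symmetric half-point reflection (the least-artifact
standard for spectra); whole-point reflection and zero padding are
selectable. A kernel wider than twice the signal triggers a warning
(coefficients become extension-dominated); a kernel radius ≥ 10× the
signal length raises `ScaleTooLargeError`.

**Exactness.** `cwt_row` is algebraically identical to the dense
discretisation of the transform integral; the correlation is evaluated by
scipy with an FFT where beneficial, so agreement is at rounding level
(~1e-15 relative; the test suite asserts 1e-10 across all 15 wavelets).

## Max/min reconstruction

The scalogram over consecutive integer scales [a_min, a_max] is collapsed
per channel to its maximum and minimum coefficient. Default feature layout
concatenates both channels (2p features): peaks dominate the max channel,
troughs the min channel, and the transform's negative side lobes mean both
carry band-amplitude information. `max_only` / `min_only` layouts are
selectable.

**Resolution behaviour.** The per-channel maximum of a single Gaussian
band (sd σ) over scales is attained near a ≈ √5·σ and decays only as
a^(-1/2) beyond, so the max channel is dominated by moderately coarse
scales. Two consequences, established analytically and verified
numerically while designing the fixtures:

- An equal-width pair that merges in the composite (gap < 2σ) also merges
  in the max channel — the midpoint response exceeds the centre response
  at every scale up to 40.
- A weak narrow band riding on a broad neighbour's flank (a shoulder, no
  composite maximum of its own) cannot out-climb the neighbour's coarse
  envelope in the max channel either.

What the reconstruction *does* deliver is scale-free localisation: each
apparent band keeps a max-channel maximum within ±2 channels of its centre
(or of both centres, for sub-bands much closer than one width, which are
physically one apparent band), across widths from a few channels to tens of
channels, without choosing a single transform scale — and it feeds all of
that structure, plus the trough information, to the regression at once.
The canonical seven-band fixture reflects this: its two merged pairs are
separated by 3 channels (widths 13/7 and 12/6), the composite shows five
apparent maxima, and the max channel localises all seven centres to ±2.

## Calibration

PLS1 via NIPALS with mean-centring only (no autoscaling — standard for NIR
absorbance-like features). NIPALS is written in-house because PRESS and
UVE both need the nested coefficient vectors b_1…b_K from a single
deflation pass; scikit-learn's `PLSRegression(scale=False)` is used as an
independent oracle in the tests, never as the engine. Rank exhaustion
(vanishing deflated covariance, tolerance 1e-12 relative) stops the
deflation early with a warning.

- **PRESS**: leave-one-out over the calibration set — deterministic,
  standard in NIR work; one NIPALS pass per left-out sample yields the
  whole factor curve.
- **Factor rule**: scan k = 2…20; the first k−1 with
  PRESS(k)/PRESS(k−1) > 0.9 is selected; a zero PRESS(k−1) counts as
  exhausted improvement (select k−1); if no ratio exceeds the threshold
  the cap (or curve length) is used. The threshold is strict (a ratio of
  exactly 0.9 does not stop the scan). Cap and threshold are configurable.
- **Scale rule**: a_max ∈ {10, 15, 20, 25, 30, 35, 40} with a_min fixed at
  1 (both configurable); minimum RMSEC wins, ties to the smallest a_max.
  The selection loop computes the scalogram once per sample up to
  max(grid) and reads each range off with running extremes.
- **R_c / R_p** are Pearson correlations between reference and predicted
  values (calibration / prediction set respectively).
- **Sample splitting** for file-based runs: deterministic Kennard–Stone
  maximin selection on the raw spectra (default 80% calibration), so
  repeated runs are byte-identical.

## UVE

The feature matrix is augmented with an equal-width block of uniform noise
scaled to 1e-10·max|X| — small enough to leave the real-variable
coefficients unchanged (verified to 1e-6 in the tests), large enough to
carry coefficients of its own. Stabilities are mean/std (ddof = 1) of each
coefficient over the n leave-one-out submodels; a zero std flags the
variable and maps to a signed-infinity sentinel (0 when the mean is also
0, e.g. a constant-zero column). The cutoff is the largest noise-block
|stability| (strictest classical convention; a percentile mode is
available). Each of the default 100 repetitions draws fresh noise from a
child stream spawned off one master seed; retained sets are scored by the
leave-one-out PRESS of a PLS model restricted to them, the minimum-PRESS
set is reported, and `always_selected` is the intersection over
repetitions. Repetitions retaining nothing are skipped with a warning.

## Synthetic study conditions

`seven_band_spec` (the resolution fixture): 512 channels; seven Gaussian
bands (centre, sd, amplitude) = (70, 16, 1.00), (150, 13, 0.85),
(153, 7, 0.45), (245, 18, 1.05), (330, 12, 0.75), (333, 6, 0.40),
(432, 15, 0.90) on the quadratic baseline 0.30 + 8e-4·x − 1.2e-6·x²,
noise-free by default. The constants were chosen once so that the
composite visibly merges the two close pairs while remaining NIR-like in
band widths and dynamic range.

`recovery_spec` + `make_regression_dataset` (the calibration/UVE fixture):
512 channels; five Gaussian bands of sd 12–14 at centres 90, 180, 260,
340, 420 (well separated, ≥ 6σ, so band amplitude maps near-linearly into
the max/min features); spectral noise sd 1e-3; per-sample amplitudes
A_j ~ N(1, 0.15²) truncated at 0.05; y = A_0 + 0.7·A_2 − 0.5·A_4 + ε with
ε ~ N(0, 0.02) — so three bands are informative and two are
amplitude-varying decoys, sd(y) ≈ 0.19, and 0.02 is the irreducible noise
floor against which RMSEP is judged. Pipeline checks use n = 30
calibration and 30 independently drawn prediction samples.

What the generator emulates: overlapped Gaussian sub-bands, a smooth
baseline, white spectral noise, amplitude-driven property variation. What
it does not: instrument line-shape asymmetry, wavelength-dependent noise,
scatter/offset effects (MSC-type artefacts), nonlinear detector response,
or correlated constituent concentrations. Passing tests therefore
demonstrate the machinery and its statistical rules, not robustness to
those real-data effects.

## Numerical choices and degenerate inputs

- Scale-selection ties break to the smallest scale; `select_factor` is
  invariant to positive rescaling of the PRESS curve.
- Requested factor counts are clipped to min(n−1, p) (fit) and min(n−2, p)
  (PRESS) with warnings; constant y yields a zero coefficient vector and
  mean prediction.
- Signals must be finite, ≥ 2 channels, strictly increasing axis; datasets
  need n ≥ 3 (fits), n ≥ 4 (PRESS/UVE).
- All stochastic components (noise draws, UVE repetitions) flow from
  explicit `numpy.random.Generator` seeds; fits themselves are
  deterministic.

## Known limitations

- Max/min reconstruction cannot separate sub-bands that the composite
  itself merges at comparable widths (see "Resolution behaviour"); it is a
  feature-extraction step, not a deconvolution.
- PLS1 only (single property per fit); no uncertainty intervals on
  coefficients or predictions.
- The UVE stability statistic is computed from leave-one-out submodels,
  which for very small n makes the noise-block cutoff itself noisy; the
  100-fold repetition with the PRESS criterion is what stabilises the
  final selection.
- MAT input is limited to numeric 2-D variables (MATLAB dataset objects,
  as shipped in some public benchmarks, must be exported to plain matrices
  first).
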