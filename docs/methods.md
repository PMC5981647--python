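# Methods

## Forward model

The photoacoustic signal of a trace-gas mixture in the unsaturated regime is
linear in the component concentrations,

S(λ) = C · P(λ) · N_tot · Σᵢ cᵢ σᵢ(λ),

where C lumps cell geometry, microphone placement and acoustic-resonance
amplification, P(λ) is the optical power of the source, N_tot the total
molecular density, cᵢ the molar fraction (ppm × 10⁻⁶) and σᵢ(λ) the
absorption cross-section. The package works in arbitrary units and defaults
C = N_tot = 1 and P ≡ 1: any multiplicative constant common to calibration
and prediction cancels out of the regression, so nothing is gained by
modelling it. A non-flat P(λ) can be supplied; `normalize_by_power` divides
it back out per wavelength, exactly cancelling the source's emission curve
(checked numerically as an invariant). Whether a real instrument normalizes
by per-wavelength or scan-averaged power is an acquisition detail the model
deliberately leaves open; the per-wavelength form is the default because it
is what the forward model exposes.

The wavelength grid is uniform, 301 points over 3250–3550 nm (1 nm step).
A 0.2 nm average step is sometimes quoted for scanned-OPO acquisitions of
this window, but it is inconsistent with 301 points over 300 nm; the
301-point statement wins and both bounds and length are configurable.

## Synthetic cross-section library

Measured cross-sections of the six VOCs are not available in
machine-readable form, so `default_voc_library` synthesises them. Each
component is a baseline-free sum of one broad "backbone" band (FWHM
150–270 nm, centred mid-window — emulating the unresolved C–H stretch
envelope that makes every mid-size organic absorb across the whole 3.3 µm
region) plus 2–4 narrower Gaussian or Lorentzian bands (FWHM 15–75 nm)
carrying the component-specific structure. Amplitudes are rescaled so that a
100 ppm single-component spectrum peaks between 0.1 and 1 a.u. — a decade of
peak strengths emulating the differing per-component signal-to-noise ratios
of a real instrument.

The library contract is enforced by deterministic rejection sampling on the
seeded RNG stream: pairwise cosine similarity of the six σ curves strictly
inside (0.3, 0.95), rank 6 of the stacked 6×301 matrix. The same seed always
yields the same library, bit for bit.

What this emulates: strong, ubiquitous spectral overlap with no exclusive
marker wavelength, differing component strengths, linear mixing. What it
does not: real band positions and intensities of the six VOCs, instrument
drift, wavelength-calibration error, nonlinear (saturated) absorption,
acoustic-resonance dispersion. Passing tests therefore demonstrate that the
calibration machinery solves the stated class of unmixing problems, not that
it reproduces laboratory numbers for these specific molecules.

## Reference-set construction

One clean spectrum per component at the base concentration (100 ppm) is
scaled by the factor levels {0, 0.3, 0.7, 1} and summed over all
4⁶ = 4096 combinations; Y holds the matching ppm levels {0, 30, 70, 100}.
Row order is the lexicographic factor product with the last component
varying fastest, recorded in the output metadata. The all-ones row equals
the plain sum of the six singles; no separate copy of the originals is
appended.

Noise, 10% of the spectrum RMS read as the standard deviation of additive
i.i.d. Gaussian noise (the "noise power = 10% of spectrum power, defined as
RMS" convention equates power with RMS amplitude, not variance), is applied
in one of two modes:

* `per_reference` (default): independent noise on every generated row, with
  σ = 0.10 × RMS of that row. This is the "as if each reference had been
  measured" reading — signal-proportional noise, consistent with the ~5%
  amplitude fluctuation photoacoustic signals show — and it keeps the noise
  subspace full-rank, which is the statistically robust choice for
  augmentation.
* `originals`: the literal laboratory protocol — each of the six base
  spectra is perturbed once and the 4096 rows are rebuilt from the noisy
  singles. Noise is then exactly rank-6 and correlated across all rows
  sharing a component, and X remains an exact linear function of Y. One
  noise draw per original is used; repeated-replicate variants are out of
  scope.

The mode matters for interpretation: under `originals` a cross-validation
sees the same noise realisation in training and test folds and reports a
near-zero error, which flatters the model; under `per_reference` the
reported held-out error honestly includes the augmentation noise and is
therefore substantially larger (~12 ppm pooled std at the default settings
versus the low single-digit ppm a correlated-noise protocol yields).
Comparisons with historical figures obtained under the literal protocol
should keep this difference in mind.

## SIMPLS

Calibration mean-centers X and Y (no unit-variance scaling by default;
autoscaling is available via `scale=True`) and iterates on the cross-product
S = Xcᵀ Yc: the next weight vector is the dominant left singular vector of
the deflated S; the score t = Xc r is normalised to unit length; loadings
p = Xcᵀ t and q = Ycᵀ t are accumulated; S is deflated by projection against
an orthonormal basis of the x-loadings, maintained by Gram–Schmidt with one
re-orthogonalization pass. B = R Qᵀ, and prediction is
ŷ = ȳ + (x − x̄) B. Six factors is the default (one per component).

Numerical choices:

* Sign convention: each weight vector's largest-magnitude entry is made
  positive before use, fixing the SVD sign ambiguity so repeated fits are
  bit-identical. Predictions are invariant to this choice.
* Early stop: if the deflated cross-product norm falls below 1e-12 of its
  initial value (rank exhausted), fitting stops with a warning and the model
  records the achieved factor count.
* Degenerate inputs (zero-variance X, more factors than samples − 1 or than
  channels) raise explicit errors.
* Variance accounting: with orthonormal scores, factor a explains ‖p_a‖² of
  the centered X sum-of-squares and ‖q_a‖² of the centered Y sum-of-squares;
  cumulative fractions are nondecreasing and ≤ 1.

For a univariate response SIMPLS coincides with NIPALS PLS1 (tested against
an independent NIPALS implementation and scikit-learn); for multivariate
responses it does not coincide with NIPALS PLS2, so the multivariate
cross-check in the tests uses an independently written textbook
transcription of the SIMPLS recursion, and the full-rank limit is checked
against minimum-norm least squares.

Negative predicted concentrations are reported as-is (`raw`) and alongside a
clamped variant (elementwise max(0, ·)). Clamping is presentation-level:
for nonnegative true concentrations it can only shrink each squared
residual, so PRESS and RMSE weakly decrease — a property test covers this.

## Validation metrics

RMSE = √(PRESS/N) with N the total residual count; PRESS = Σ residual²;
bias = mean residual; std = sample standard deviation with the n−1
denominator (on the published 18-residual validation table the n−1 reading
reproduces the printed 3.93 ppm, whereas an n denominator would collapse to
the RMSE — so n−1 is the consistent convention). Residuals are ŷ − y.
Multi-component residual matrices are pooled entrywise. Tenfold
cross-validation shuffles rows with a seeded RNG into near-equal folds, fits
on k−1 folds, predicts the held-out fold, and pools; both the pooled
standard deviation and the pooled RMSE are reported, since historical
summaries of this workflow quote the two interchangeably.

The packaged validation table (18 integer-rounded predictions) yields
raw RMSE 3.808, std 3.918, PRESS 261, bias −1/18 ≈ −0.056 ppm; clamped RMSE
2.848, std 2.698, PRESS 146. The unrounded-model figures published for the
same experiment are 3.82/3.93/263 and 2.79/2.60/140: ordering identical,
values within rounding. The published sub-0.01 ppm bias is not recoverable
from the rounded table (which gives −0.056) and is not asserted anywhere.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| grid | 301 pts, 3250–3550 nm | the scan window and sampling of the measurement campaign |
| base concentration | 100 ppm | level of the single-component standards |
| scale factors | 0, 0.3, 0.7, 1 | the published augmentation levels |
| noise fraction | 0.10 | 10%-of-RMS noise convention |
| PLS factors | 6 | one latent factor per component |
| CV folds | 10 | tenfold protocol |
| molar volume | 22.414 L/mol | ideal gas at normal pressure (Tedlar-bag prep helper); overridable |

Tests and the acceptance script run the full 4096×301 corpus (construction
and a six-factor fit take well under a second; a five-seed tenfold CV a few
seconds). Monte-Carlo checks use 10⁴ noise draws and 100–1000 random
instances per property.

## Known limitations

* The library generator controls overlap only through pairwise cosine
  bounds; a draw can sit close to the 0.95 ceiling, making the unmixing
  problem harder than a typical measured library and inflating
  cross-validated errors (the 6-factor fit then explains ≈ 0.9 of the
  concentration variance at 10% per-row noise rather than the high-90s a
  better-conditioned library gives).
* Concentrations outside the calibrated 0–100 ppm span extrapolate linearly
  with no warning.
* No automatic factor-count selection; CV curves must be inspected manually.
* No modelling of acoustic resonance, modulation, cell geometry or
  microphone transfer functions, and no retrieval of reference
  cross-section databases.
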