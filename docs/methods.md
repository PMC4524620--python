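# Methods

This note records the models, conventions, numerical choices and known
limitations behind `nmrdecon`, at the level a maintainer or careful user
needs to interpret results.

## Lineshape model and conventions

A component peak is a phased Lorentzian
`I(ν) = h (cos φ − x sin φ)/(1 + x²)` with `x = 2(ν − ν₀)/w`.  The sign
convention is fixed so that positive `φ` tips the high-ppm (left) tail
down; the mirrored convention is equally valid and would simply negate
every fitted phase, so phases should be compared within one convention
only.  The FID simulator encodes phases as `exp(i(2πνt − φ − φ₀))` so a
fitted component phase equals the imposed offset under this convention.

Peak area uses the absorption closed form `(π/2) h w`, independent of
phase; fractional areas are normalised within one model.  For nearly
absorptive components (fixed-phase mode, |φ| ≤ π/50) this is exact to
0.2%.  For strongly phased components the signed integral of the observed
trace is `(π/2) h w cos φ`, so a near-dispersive component carries far
less real intensity than its nominal area; fractional areas of models
containing such components should be read with this in mind (see
"Variable-phase artifacts" below).

Axis convention: spectra are stored left (high ppm) to right (low ppm) on
an arithmetic ppm axis; `ppm(i) = left − i·(left−right)/(n−1)`.

## Model selection

Fits are compared with the residual-sum-of-squares profile form of the
Bayesian information criterion, `BIC = n ln(rss/n) + k ln(n)`, the
standard form for least squares with unknown Gaussian noise variance.
Only differences between models fit to the same data are meaningful;
`exp(ΔBIC/2)` approximates posterior odds.  A model whose rss is exactly
zero (perfect interpolation) has no defined BIC and is rejected.

Parameter counting: a variable-phase peak contributes k = 4 (height,
center, width, phase).  A fixed-phase peak contributes k = 3: its phase
may still move within ±π/50 numerically, but a parameter confined to a
band that cannot change the lineshape beyond the noise is treated as
fixed for statistical purposes.  This choice is what makes fixed- and
variable-phase fits comparable in the intended direction — on correctly
phased, non-exchange data the two modes reach essentially the same rss,
and the fixed-phase model then wins by about `p·ln n` (one fewer free
parameter per peak).  Counting 4 in both modes would make the
variable-phase fit never worse, since its optimum is nested above the
fixed-phase one.

The pipeline (defaults in parentheses):

1. **Region selection** (optional) and **baseline adjustment** (on).
2. **Forward build** (`max_peaks` = 12): residuals against the current
   model are scanned for the longest run of consecutive positive values;
   a new peak is initialised at the run midpoint with the run length as
   width and the run maximum as height, and all parameters are refit
   jointly.  If the new model's BIC does not beat the previous size, one
   retry is made at the single highest positive residual point.  Ties
   between equal-length runs go to the higher maximum, then leftmost.
3. **Seed selection**: the largest model with a lower BIC than the model
   with one fewer peak.
4. **Pruning** (`plimit` = 15): every single-peak deletion is tried per
   round and refit; the best reduced model is accepted while its BIC is
   within `plimit` of the best BIC seen.  Accepted reductions need not
   improve the BIC — they extend the candidate list with simpler models;
   the reported best model is always the global BIC minimum.
5. **Splitting**: a randomly chosen peak is replaced by two children at
   center ± FWHM/4 with half the parent area each (same width and phase)
   and the model refit; a split with the same or better BIC is kept, and
   the loop stops when a proposal exceeds the best BIC by more than 2.
   A safety cap (20 proposals) bounds the loop, since proposals landing
   in the (0, 2] window are discarded without stopping it.
6. **Monte-Carlo refinement** (10 refits): every parameter of the
   incumbent is redrawn from a Gaussian centred on its value with
   standard deviation `stderr × U(0, 200)/SNR` (stderr falling back to 1%
   of the value when the curvature estimate is unavailable), clipped into
   bounds, and refit.  Refits more than 2 BIC below the incumbent are
   flagged separately as new bests.

`plimit` doubles as the reporting window: all candidates within `plimit`
of the best BIC are presented.  Candidates within 2 BIC units of each
other should be treated as equally good.

Default bounds: height ∈ (0, 3 × data maximum]; center inside the
analysis region; width ∈ [3 × digital resolution, region span]; phase
±π/50 (fixed) or ±π (variable).  The digital resolution should be much
finer than the narrowest expected peak, or noise spikes become fittable.

## Baseline adjustment

Step 1 subtracts the mean of the two edge windows (1/30 of the width at
each end).  Step 2 re-adds the estimated signal tail that step 1 also
removed: the spectrum is modelled as a single centered absorption
Lorentzian with height equal to the maximum and width inferred from the
positive area (left Riemann sum, area = (π/2) h w), and that peak's tail
intensity *at the spectrum edge* is added back as a constant.  The
constant reading (rather than re-adding the full curved wing) is a
deliberate choice; for a spectrum whose signal is roughly centered the
two differ by less than the edge tail itself.  The whole correction is
exactly invariant to adding a constant to the input.

Two consequences worth knowing.  First, the correction is approximate by
construction (single-peak, centered model): on noiseless synthetic data
its residual error, not noise, is the largest deviation from the ideal
lineshape, which is why the exact-recovery checks on noiseless inputs run
with the stage disabled.  Second, on data that truly have no offset the
stage can only inject its own estimation error (edge-mean sampling error
≈ σ/√(2m)); under fully free phases that error is occasionally absorbed
by a spurious broad dispersive component (below).  Synthetic closed-form
exchange spectra are therefore deconvolved with the stage off in the
package's own measurements; experimental text exports, whose offsets are
real, keep it on.

## Variable-phase artifacts

With |φ| ≤ π free, a broad component at |φ| ≈ π/2 (or an inverted one at
|φ| ≈ π) is a cheap smooth background: it can absorb residual baseline
tilt or offset at the cost of k = 4 parameters while contributing almost
no absorptive intensity.  Such components appear in a minority of
variable-phase fits, inflate the nominal area shares of the model, and
are not population probes.  A best model containing a relatively sharp
strongly phased peak should be refit with a tighter phase bound
(e.g. ±π/4).  Phase-recovery checks in the test suite therefore match
fitted components to the true centers rather than averaging phases over
the whole model.

## Synthetic data

**FID route.**  Each peak contributes
`a · exp(i(2πνt − φ − φ₀)) · exp(−t/T₂)` with `T₂ = 1/(π·FWHM_Hz)` and
amplitude chosen to give the requested apex height; the first point is
half-weighted so the discrete transform has a flat baseline; complex
white Gaussian noise is added in the time domain; the real part of the
FFT is returned on a ppm axis referenced to the spectrometer frequency
(default 376.5 MHz, 1 ms dwell, 1 s acquisition).  When a target SNR is
requested, the time-domain sigma is set from the noiseless apex
(`σ_t = apex/(SNR·√N)`); note the *measured* max-over-RMS SNR is biased
high at low SNR because noise excursions inflate the apex estimate.

The nominal 1 ms dwell gives a 1000 Hz window that cannot hold peaks
drawn from the wide default distributions, so in the automatic mode the
dwell shrinks until every peak fits with 10 linewidths of padding plus
20%, and the window is then 2× oversampled.  The padding keeps Lorentzian
tails at the edge windows below ~0.3% of the apex (so the baseline and
SNR estimates see essentially pure noise); the oversampling keeps the
discrete-transform deviation from an ideal Lorentzian (which scales as
the square of dwell/T₂) far below realistic noise.  Pinning
`auto_spectral_width=False` uses the requested dwell exactly and warns
about aliasing peaks.

**Random draws.**  Peak count uniform on {0..12}; width and center from
normals (μ = 0.5 ppm, σ = 5 ppm and μ = 0, σ = 5 ppm; widths redrawn
until positive); intensities from a normal (μ = 1, σ = 0.6, redrawn
until positive) and normalised to sum to 1.  These wide distributions
produce heavily overlapping peaks on purpose: the method should merge
them rather than overfit.

**Chemical exchange.**  A single nucleus hopping among 2–4 sites follows
the steady-precession Bloch–McConnell lineshape
`I(ν) = Re[ 1ᵀ (i2π(νI − diag(shifts)) + diag(R₂) − K)⁻¹ p ]` with the
first-order rate matrix K (columns sum to zero, stationary on the
populations).  Two-site systems are built by detailed balance from the
total rate `k_ex = k₁ + k₋₁` (forward rate `k_ex·p₂`, reverse
`k_ex·p₁`); three- and four-site systems default to a linear-chain
topology with pairwise detailed balance, and any user rate matrix
satisfying the invariants is accepted.  The published kinetic-scheme
parameters behind the original four-site simulations are not available,
so only qualitative contracts (slow/fast limits, area conservation,
coalescence behaviour) are asserted for n > 2.  Coalescence of the
equal-population two-site lineshape is located by bisection on `k_ex`
over a fine noiseless axis (2¹⁴ points, prominence threshold 10⁻¹⁰ of
the apex, intrinsic R₂ ≤ 10⁻³ of the shift difference), reproducing the
analytic critical ratio π√2 ≈ 4.44.

**What the generators do not emulate.**  t₁ noise, solvent artefacts,
field inhomogeneity, scalar couplings, first-order phase error and
baseline roll are absent; passing tests demonstrate the selection
machinery under Gaussian noise and Lorentzian truth, not robustness to
every experimental nuisance.

## T₂ analysis

Region integrals (trapezoidal, over a closed ppm window) at a series of
delays are fit to `A·exp(−t/T₂)` by least squares; the 95% confidence
interval is the normal approximation from the covariance at the optimum.
The starting T₂ comes from a log-linear regression and keeps its sign,
so non-decaying series converge to a negative T₂ and are rejected rather
than drifting to the flat T₂ → ∞ plateau.  `FWHM = 1/(π T₂)` converts to
a Lorentzian linewidth.  When a long series loses signal at a constant
rate (e.g. sample precipitation), matched short-delay references taken
before and after the series correct each point: an integral acquired at
run-time fraction f is divided by `1 − f(1 − end/start)`; the delays
series carries per-point run-time fractions to honour randomised
acquisition order (an evenly spaced chronological order is assumed when
they are absent).  The "total delay" abscissa of a spin-echo series is
twice the variable delay (the echo forms at 2τ); the package takes the
delays it is given and leaves that bookkeeping to the caller.

## Numerical choices

- Optimiser: lmfit's bounded Levenberg–Marquardt; 2000 function
  evaluations, xtol = ftol = 10⁻⁸.  A fit never returns a larger rss
  than its starting point (the start is kept if the optimiser ends
  worse), which gives the rss-descent and nested-model monotonicity
  guarantees.
- The MINPACK bound transform has zero gradient exactly at a bound, so
  internally generated initial guesses are clipped 10⁻³ of the range
  *inside* the box; user-supplied starts at a bound stay there, honouring
  the box-constraint contract.
- Peak placement ignores positive residuals below 10⁻⁶ of the data
  scale, and splitting stops once the rss is at machine precision
  (< n·(10⁻¹⁰·scale)²): on exactly noiseless inputs, optimiser round-off
  would otherwise masquerade as structure and drive spurious model
  growth.
- BIC ties: comparisons are exact float comparisons; "within 2" windows
  use ≤.  Deletion rounds try all single deletions and keep the best, so
  pruning is order-independent.
- All randomness (splitting choices, Monte-Carlo perturbations,
  simulators) flows from seeded generators recorded in the outputs;
  reruns with the same seed are bit-identical.

## Problem sizes

The test suite and the acceptance script run on deliberately modest
problems — acquisition times of 0.15–0.5 s (≈ 10³–10⁴ points after the
automatic spectral width), exchange axes of 2¹¹–2¹⁴ points, at most 10–12
candidate peaks, and up to 20 random-draw spectra with ≤ 3 true peaks —
sizes at which every behaviour of the method is already expressed while a
full run stays in the minutes range on one core.  Larger spectra change
cost, not conclusions: the per-fit work is linear in the point count.
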