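# Methods

## Propagation model

The package treats every bio-optical product *y* as a deterministic
function of a multiband reflectance vector and approximates its
standard uncertainty to first order (FOFM — first-order first-moment,
the GUM law of propagation of uncertainty):

    u²(y) = Σ (∂f/∂xᵢ)² u²(xᵢ)          (uncorrelated inputs)
    u²(y) = gᵀ V g                       (correlated inputs)

Assumptions inherited from this linearization: input errors are
zero-mean with known second moments; the product is differentiable at
the operating point; curvature and discontinuities (maximum-band-ratio
switching, blend-window transitions) are neglected. The Monte-Carlo
engine exists precisely to measure what those neglected features cost:
for linear products (nflh) agreement is exact up to sampling error; for
ratio power laws it is excellent; for the blended chlorophyll the FOFM
estimate is known to run low when spectra sit inside the blend window,
and that residual disagreement is inherent to a first-order method, not
a defect to be tuned away.

All gradients are analytic, returned on the full input grid alongside
the product value, and each one is validated in the test-suite against
central differences (relative step 1e-5, absolute floor 1e-9, chosen to
balance truncation against rounding for reflectances of order 1e-3).

## Algorithms and their parameters

* **Band-ratio chlorophyll** (OC4-style): χ = log₁₀(max of blue-band
  ratios over green), Chl = 10^Σaₖχᵏ. Polynomial coefficients are
  configuration with heritage defaults; the gradient is nonzero only on
  the active blue band and the green band. Ties between blue bands are
  broken toward the shortest wavelength and flagged, since the
  derivative is discontinuous there.
* **Line-height chlorophyll** (color index): CI is the green-band
  deficit below the linear blue-red baseline, Chl = 10^(b₀+b₁·CI). On
  the bundled 16-band grid the red CI band is 665 nm (the heritage
  670 nm band is absent); the baseline weight is computed from the
  actual grid wavelengths.
* **Blended chlorophyll**: line height below 0.15 mg m⁻³, band ratio
  above 0.20, linear mixing between, with the weight driven by the
  line-height value. The gradient includes the ∂α/∂Rrs cross terms, so
  it is the complete first-order derivative of the blended value.
* **Kd(490)**: pure-water floor 0.0166 m⁻¹ plus 10^Σcₖχᵏ. The default
  is the heritage two-band (490/555) form; a multi-band blue list
  activates the same maximum-ratio selection as the chlorophyll band
  ratio.
* **POC**: a·(R₄₄₃/R₅₅₅)^b with the published a = 203.2 mg m⁻³,
  b = −1.034. Under spectrally flat uncorrelated relative uncertainty r
  the relative FOFM uncertainty is exactly |b|·√2·r for every positive
  spectrum — the structural identity the acceptance checks pin at
  1.46 / 7.31 / 14.6% for r = 1 / 5 / 10%.
* **nflh**: peak-band radiance above the linear baseline; linear, hence
  FOFM-exact. Rrs is converted to nLw by per-band mean solar
  irradiance (a bundled approximate table; configuration, not results),
  and gradients/perturbations are expressed consistently in whichever
  quantity is driven.

## GIOP inversion and its uncertainties

The forward model is the standard quadratic-in-u reflectance
approximation (g₁ = 0.0949, g₂ = 0.0794 sr⁻¹) over absorption
a = a_w + x_φ·a*_φ(λ) + x_dg·exp(−S_dg(λ−443)), S_dg = 0.018 nm⁻¹, and
backscattering b_b = b_bw + x_bp·(443/λ)^γ. γ is fixed before fitting
from the QAA-style blue-green rrs-ratio rule
γ = 2.0·(1 − 1.2·e^(−0.9·rrs₄₄₃/rrs₅₅₅)) and is not a free parameter.
Bundled a_w, b_bw and the chlorophyll-specific a*_φ shape are
approximate literature-style tables; no test result depends on their
exact values (unit tests use degenerate unit-shape configurations).

The fit minimizes the unweighted sum of squared sub-surface reflectance
residuals (rrs = Rrs/(0.52+1.7·Rrs)) over the 412–655 nm bands with
x ≥ 0 bounds. scipy's trust-region-reflective least squares is used — a
Levenberg–Marquardt-type damped scheme that, unlike the classical LM
implementation, honours the non-negativity bounds. Start point
(0.1, 0.01, 0.001), ftol = xtol = 1e-10, 200 evaluations maximum.
Non-convergence and degenerate inputs yield a flagged state rather than
an exception, mirroring per-pixel product-failure masking.

Parameter error covariance uses the Gauss–Markov sandwich
E_x = (JᵀJ)⁻¹Jᵀ V J (JᵀJ)⁻¹ with the analytic Jacobian J. With a
square invertible J this reduces to J⁻¹V(Jᵀ)⁻¹; the sandwich is the
generalization required because J is n-bands × 3. Two choices of V are
exposed: the radiometric Rrs covariance chained through the exact
interface-transform derivative (data uncertainty), and diag(ε²ᵢ) of the
optimal-fit residuals (model-misfit uncertainty, attributing the
residual entirely to model imperfection). Shape-model uncertainties
u(a*_φ), u(b*_bp) are deliberately not propagated; the derived-IOP
layer is the hook where a future extension would enter. Backscattering
is shifted between wavelengths by b_bp(λ) = b_bp(ref)·(ref/λ)^γ with
the full three-term variance including the b_bp–γ covariance.

## Monte-Carlo engine

Default 5,000 iterations; independent per-band Gaussian perturbations
for a u-vector, joint multivariate-normal draws for a covariance
matrix (an extension beyond the classic uncorrelated protocol, flagged
as such). Draws on which an algorithm raises a domain error (e.g. a
negative perturbed band feeding a log ratio) are counted and excluded;
a run with more than 50% failures errors out as "model undefined near
input". σ uses the unbiased n−1 denominator. Relative uncertainty is
reported against the unperturbed-model value (the MC mean is also
reported). Seeding is mandatory and results are bit-reproducible.

FOFM-vs-MC agreement is summarized in log space — multiplicative bias
10^mean(log₁₀MC − log₁₀FOFM) with MC as reference, and a Type-II
standardized-major-axis slope. SMA was chosen among Type-II estimators
for its symmetry (slope(x,y)·slope(y,x)=1); the choice is isolated in
one function and swappable.

## Uncertainty surfaces and covariances

Three radiometric-uncertainty regimes: flat relative (applied to |Rrs|
so rare negative bands still give non-negative u); a tabulated relative
uncertainty surface indexed by chlorophyll and wavelength — bilinear
within the grid, linearly extrapolated above the top chlorophyll level,
clamped below the bottom one, never extrapolated in wavelength; and
user-supplied covariance (built from a u-vector and a validated
correlation matrix, or read from CSV). The bundled demonstration
surface is synthetic and labeled as such; real sensor tables load from
the same CSV layout.

## Synthetic data

The generator draws chlorophyll log-uniformly over 0.03–1.3 mg m⁻³ and
sets the detrital/dissolved and particulate-backscattering amplitudes
by power-law scalings with log-uniform scatter
(x_dg = r·Chl^1.1, r ∈ (0.02, 0.04); x_bp = r·Chl^0.4,
r ∈ (0.0032, 0.0046)), then runs the package's own GIOP forward model
with γ made self-consistent with the ratio rule by fixed-point
iteration, so noiseless inversion recovers the truth table to numerical
precision. The scalings were calibrated once so that derived blended
chlorophyll spans the oligotrophic-to-mesotrophic envelope
0.04–1.28 mg m⁻³ (median near 0.11) and Kd(490) spans roughly
0.020–0.12 m⁻¹ — the ranges typical of open-ocean evaluation datasets.

Known limitations of the generator, and hence of what passing tests
demonstrate: spectra are noiseless by default and perfectly
model-consistent (GIOP round-trip tests are therefore self-consistency
checks; independence comes from the Monte-Carlo and finite-difference
oracles, not from the data); there is no chlorophyll fluorescence
emission, so synthetic nflh values are near-zero residual line heights
with correspondingly large relative uncertainties; no Raman scattering,
BRDF effects, coastal/turbid water types, or realistic sensor noise
covariance. Conclusions about real retrievals should rest on the
structural results (gradient correctness, scaling laws, MC agreement),
not on the synthetic medians themselves.

## Numerical choices

* Band matching: nearest grid wavelength within 3 nm of the nominal
  centre; a miss raises a missing-band error naming the target.
* Hyperspectral-to-multiband subsampling: unweighted boxcar mean over
  the closed 10 nm band interval (no sensor response function).
* Covariance validation: symmetry to 1e-12 relative, eigenvalues
  ≥ −1e-10 × the largest diagonal entry; a tiny negative gᵀVg from
  roundoff is clipped to zero with a warning, since PSD inputs
  guarantee non-negativity analytically.
* Problem sizes: structural acceptance checks use 100–200 synthetic
  spectra, 700–5,000 MC draws per spectrum, and 50 inversion
  round-trips — sizes at which the statistics under test are stable to
  well inside their tolerances.
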