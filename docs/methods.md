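# Methods

This note documents the models, conventions and numerical choices behind
`wetdom`, and what the synthetic-data generators do and do not emulate.

## Scope and data flow

The package covers the computational chain of a wetland dissolved-organic-
matter (DOM) study: (1) correction of absorbance spectra and
excitation-emission matrices (EEMs) and computation of CDOM optical
indices; (2) PARAFAC decomposition of an EEM collection with split-half
validation; (3) first-order kinetics of biodegradable DOC (BDOC)
incubations; (4) a lateral DOC mass balance with water-balance and
residence-time companions. A synthetic-data module generates every input
class with known ground truth, so the whole chain is testable without any
instrument data.

## Spectral corrections and indices

**Absorbance.** Spectra are stored as decadic absorbance with the cuvette
path length (default 1 cm). The Napierian absorption coefficient is
`a(λ) = ln(10)·A(λ)/ℓ` (1/m); `a254` is its value at 254 nm. SUVA254 is
the decadic absorbance at 254 nm per metre of path divided by DOC
(L mg C⁻¹ m⁻¹), the Weishaar convention. Both conventions coexist because
both quantities are conventionally reported.

**Spectral slopes.** `S` is fitted by nonlinear least squares to
`a(λ) = a(λ₀)·exp(−S(λ−λ₀))` over the requested window (seeded from a
log-linear fit), so a noiseless exponential is recovered exactly; the
slope ratio is `S_R = S₂₇₅₋₂₉₅ / S₃₅₀₋₄₀₀`. A log-domain ordinary
regression is deliberately not the primary estimator because it
down-weights the high-absorbance end of the window under multiplicative
noise; the nonlinear fit is the field's standard.

**EEM corrections.** Blank subtraction must precede Raman normalization,
enforced by monotone state flags on the `EEM` container. One Raman unit
is the trapezoidal integral of the blank's emission scan at excitation
350 nm over 371–428 nm (Lawaetz–Stedmon bounds; configurable). Because
the 2-nm emission grid does not land on 371 nm, the integral interpolates
the window endpoints so the result refers to the exact window. The
inner-filter effect is corrected by the absorbance (ABA) method,
multiplying each cell by `10^((A_ex + A_em)/2)` with absorbance rescaled
to a 1 cm path; a warning is issued when `A_ex + A_em > 1.5`, where the
one-step multiplicative correction becomes unreliable. Scatter (first and
second order Rayleigh, water Raman at a 3400 cm⁻¹ shift) is excised to
NaN within configurable half-widths (defaults 10/15/10 nm) and either
left missing — the default, because the PARAFAC fit can exclude the cells
from its objective — or linearly interpolated along emission.

**Fluorescence indices.** The fluorescence index uses the
corrected-instrument convention, em 470/520 nm at ex 370 nm (the legacy
450/500 pair is available). Peaks B (270/310) and T (275/340) are read at
single grid cells; A, M and C as maxima over their conventional emission
ranges (260/380–410, 312/380–420, 350/420–480). Requested wavelengths
snap to the nearest grid point; exact half-step ties round toward the
longer wavelength. A zero or missing T peak makes A:T undefined (NaN with
a warning) rather than infinite.

## PARAFAC

The trilinear model `X_ijk = Σ_f a_if b_jf c_kf` is fitted by alternating
least squares with nonnegativity on all three modes. Each factor-matrix
update solves row-wise nonnegative least squares on the
Cholesky-compacted normal equations (Gram matrix = Hadamard product of
the other two factors' Grams; right-hand sides from the matricised-tensor
times Khatri-Rao product), so each subproblem is only F×F. Loading
columns are normalized to unit maximum with scale absorbed into the
scores, which makes a score equal the component's Fmax in that sample;
percent contribution divides a sample's Fmax values by their sum.

*Missing cells* (excised scatter) are excluded from the objective by an
expectation-maximisation scheme: each sweep refills them with the current
reconstruction, so they contribute zero residual and never constrain the
factors. The recorded loss history is computed on observed cells only and
is monotone non-increasing.

*Acceleration.* Plain ALS creeps when components are collinear (the
classic swamp). Each iteration therefore also evaluates a line-search
extrapolation of the factors along the last step, accepted only when it
lowers the observed-cell loss — monotonicity is preserved and swamp
iteration counts drop several-fold.

*Initialisation and convergence.* Uniform random nonnegative starts
(default 10 restarts; best final loss kept), convergence when the loss
decrease falls below `tol` times the data's total sum of squares
(default 1e-8); `tol=0` iterates until the loss stalls completely, useful
when near-exact factors are wanted on noiseless data. All randomness
flows from an explicit seed; fits are bit-reproducible.

*Validation.* Split-half analysis shuffles the samples (seeded),
assigns them alternately to two halves, fits each half independently
(same seed — so a duplicated dataset split into identical halves yields
exactly identical models), matches components greedily by the product of
excitation and emission Tucker congruences, and passes when every matched
component exceeds the threshold (default 0.95). The combined (product)
congruence is the pass criterion; per-mode values are also reported.
Sample leverage `h_i = diag(A(AᵀA)⁻¹Aᵀ)` flags potential outliers above
three times the mean leverage F/n (configurable); removal is always left
to the user.

## BDOC kinetics

Replicates are averaged per time point (pooling is possible upstream).
The endpoint decay constant is `k = ln(C₀/C_T)/T` — written with the
decaying concentration in the denominator so that consumption gives a
positive rate, the convention in which these rates are reported; net
production yields a negative rate and a flag. The half-life is
`t½ = ln(2)/k`, undefined for non-positive rates. A log-linear regression
over all time points is provided as a robustness check; the two
estimators agree exactly on noiseless exponential data and differ under
noise concentrated at interior time points. The composition–lability
relation is a simple OLS of half-life on the initial A:T ratio with a
two-sided slope test.

## Mass balance

Monthly DOC flux is `Q·C/10⁶` Mg (mg L⁻¹ ≡ g m⁻³); annual site flux sums
flowing months, with no-flow months contributing zero. Multi-year records
are first collapsed to a representative year by averaging each calendar
month across the years with data; flowing months lacking a sampled
concentration carry the nearest sampled month's value (logged in the
result notes). Net DOC flux is output minus summed inputs (positive = net
source); the export ratio is out/in; the water balance is outflow minus
summed inflows with evaporation and groundwater deliberately excluded
(hooks exist for optional terms); residence time is wetland volume over
annual outflow; areal export scales the output flux by surface area.
Report tables round fluxes to 0.1 Mg, ratios to 0.01 and residence times
to 0.01 yr. The shipped example's wetland volume (1.0×10⁷ m³) is a
documented fixture constant consistent with the example's three
residence-time/outflow pairs, not a hard-coded default.

Note that annual flux columns in multi-year summaries are means of
per-year fluxes, which differ from the product of mean discharge and mean
concentration whenever the two covary; single-year (drought) rows are the
ones where the product identity holds.

## Synthetic data

EEMs are sums of components with Gaussian excitation and emission
profiles (peak positions exact by construction). The default library of
five components spans the conventional humic-like and protein-like
regions (ex/em maxima 265/422, 235/416, 265/478, 305/372, 280/328 nm)
with distinct, field-realistic widths — humic-like broad, the red-shifted
component broadest, protein-like narrow. Distinct shapes matter: two
library components share an excitation maximum, and identical widths
would make their excitation loadings identical columns, destroying the
uniqueness of the trilinear decomposition (Kruskal's condition fails);
with distinct widths the model is generically identifiable. Scores
default to lognormal (nonnegative, right-skewed, like field Fmax
distributions). Optional artefacts: additive Gaussian noise (a helper
converts a target SNR in dB to a noise sigma), Rayleigh 1st/2nd-order and
Raman scatter ridges, and inner-filter attenuation from a paired
synthetic absorbance spectrum. Not emulated: lamp drift, detector
saturation, wavelength-dependent instrument corrections — so passing
recovery tests demonstrate correctness of the estimators, not robustness
to every instrument artefact.

Absorbance spectra integrate a piecewise-constant slope function from a
reference wavelength, giving continuous spectra that are purely
exponential inside each window (fitted slopes recover the ground truth
exactly). Incubation series are `C₀·e^(−kt)` plus replicate noise on the
standard sampling days (0, 2, 7, 14, 21, 28; triplicates), with negative
draws clipped at a floor and counted. Budget scenarios validate their
tables and return an analytic truth computed by brute-force summation,
independent of the budget module.

All generators take explicit seeds and are bit-reproducible; there is no
hidden global random state. The study-scale simulation conditions used in
tests are a 50-sample collection at ~30 dB SNR on a coarsened grid
(excitation step 10 nm, emission step 4 nm), which preserves the
five-component structure while keeping tensor fits fast.

## Known limitations

- The PARAFAC fit handles missing cells but assumes a shared wavelength
  grid across samples; no interpolation between instruments.
- The endpoint kinetics estimator uses two time points only; multi-pool
  (reactivity-continuum) models are out of scope.
- The mass balance weights all flowing months equally; day-count
  weighting is not applied unless the inputs already encode it.
- Split-half validation uses one random halving per call (alternating
  after a seeded shuffle); exhaustive recombination schemes can be
  supplied via the `scheme` argument.
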