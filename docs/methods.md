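# Methods

This note documents the models implemented in `standlab`, the choices made
where the methodology was genuinely open, and what the synthetic experiment
does and does not establish.

## Data model

The atomic record is one measured tree: plot, census year, species code,
diameter at breast height D (cm), top height H (m). Trees are measured on a
sub-quadrat (0.25 ha by default) of a nominal 1-ha plot, so every per-hectare
quantity carries the expansion factor 1/area. Species map to four functional
groups (pine, oak, other conifer, other broadleaf) through a user-overridable
table; a packaged default covers the Durango mixed-conifer flora. Diameters
and heights are stored as floats in cm and m with no unit inference.

## Biomass, volume, productivity

Aboveground biomass per tree is a power law a·D^b with pine coefficients
(0.0726, 2.4459) applied to all conifers and oak coefficients
(0.0768, 2.4416) to all broadleaves; coarse-root biomass uses 0.016·D^2.668
for every tree. Outputs are kilograms per tree — the only reading consistent
with stand totals of tens of Mg ha⁻¹ at these densities — and stand biomass
is Σkg × expansion / 1000.

The physical cross-check M = V·ρ uses a Schumacher-form volume equation
V = a·D^b·H^c with wood specific gravity 0.43 (pines) and 0.60 (oaks)
g cm⁻³. The default volume coefficients (2.09e-4, 2.0, 0.45) are a
documented placeholder calibrated so that V·ρ tracks the allometric AGB over
the 5–40 cm range; the cross-check is diagnostic only and never gates any
result. Locally fitted coefficients can be supplied as a `VolumeEquation`.

Productivity is the census difference in standing biomass divided by the
interval ("method 2"): turnover within the interval is invisible, so the
value can be negative when mortality outpaces growth. By construction the
full-period value is exactly the interval-weighted mean of the sub-period
values; the tests assert this identity per plot.

## Diversity indices

Eight indices are computed from the species-count vector; stand density is
reported alongside them as the customary abundance-based companion, giving
the nine-column summary tables. All logarithms are natural. Simpson is the
finite-sample reciprocal form 1/Σ[nᵢ(nᵢ−1)/(N(N−1))]; an all-singleton
vector has zero concentration and Simpson is returned as +inf, flagged
undefined, and dropped pairwise from downstream regressions. Berger–Parker
is reported as N/n_max. These reciprocal conventions make larger = more
diverse and produce the familiar magnitudes (Si ≈ 3, B-P ≈ 2) for
~10-species stands with two dominants. Brillouin uses log-gamma, and
Brillouin ≤ Shannon always (tested as a property). SW and B-P depend on
proportions only; Simpson's finite-sample correction decays as 1/N and
McIntosh's square-root terms as 1/√N, so scale invariance is asymptotic and
is tested at 10× scaling with tolerances of that order.

## Species-abundance models

Four models are fitted per plot-census:

- **Broken stick** (no free parameters): expected abundance at rank i is
  (N/S)·Σ_{j≥i} 1/j, tested directly on ranked abundances.
- **Geometric series**: expected rank-i abundance N·C_k·k(1−k)^{i−1}; k is
  estimated by bounded 1-D least squares on the ranked abundances (maximum
  likelihood is available as an option; least squares is the default for
  robustness at S ≈ 10). A near-uniform vector drives k to its lower
  boundary, which is reported rather than treated as convergence failure.
- **Log series**: x solves S/N = ((1−x)/x)(−ln(1−x)) by bracketed root
  finding (the solution is checked to satisfy S = α ln(1+N/α) to 1e-6);
  α = N(1−x)/x. Expected species counts per doubling octave come from
  φ(n) = α xⁿ/n binned exactly as the data are.
- **Truncated lognormal**: the Preston curve S(R) = S₀ exp(−a²(R−R₀)²)
  fitted to octave species counts by nonlinear least squares; fewer than
  four occupied octaves flags a low-power fit.

Octaves are doubling classes [2^R, 2^{R+1}) with the classical
boundary-split rule: a species whose abundance is an exact power of two
contributes half to each adjacent octave; singletons belong wholly to
octave 0. Chi-square screening pools classes from the tail until every
expected value is at least 1 (a stricter ≥5 threshold is available as a
switch), with df = classes − 1 − free parameters, floored at 1 so the test
stays usable at plot scale. A model is "accepted" when p ≥ 0.05. The
calibration study simulates multinomial communities from the broken-stick
proportions at S = 10, N = 10⁴ — large enough that observed ranks identify
the true ranks essentially without error, where the nominal 95% acceptance
holds (at much smaller N the pre-test sorting of ranks makes the screen
mildly conservative).

## Three-parameter Weibull structure

The method of moments: the bias-corrected sample skewness g is matched to
the Weibull skewness function
g(α) = [Γ₃ − 3Γ₁Γ₂ + 2Γ₁³]/(Γ₂ − Γ₁²)^{3/2}, Γ_k = Γ(1+k/α), which is
strictly decreasing on α ∈ [0.05, 50]; the root is bracketed (Brent,
|Δα| < 1e-8). Then β = sd/√(Γ₂ − Γ₁²) and ε = mean − β·Γ₁. Useful anchors:
g = 2 gives α = 1 (the exponential case) and g = 0 gives α ≈ 3.60235.
Skewness outside the solvable range pins α at the nearer bracket end with a
flag. If ε falls below 0 it is clamped to 0, and if above the sample
minimum it is clamped to 0.99·min; in both cases β is re-derived from the
mean equation so the first moment is preserved. When no clamp fires the
fitted law reproduces the sample mean and sd to machine precision.

The estimator is unbiased at the scales used here, but the location
estimate inherits the Monte Carlo noise of the sample skewness (sd ≈ 0.053
at n = 10⁵ for the default study law), so recovery checks average the
estimate over 20 independent samples to measure accuracy rather than
single-draw noise.

Adequacy screening uses the one-sample KS statistic against the fitted CDF
with the parameter-free asymptotic p-value, even though the parameters come
from the same sample. This is anti-conservative and is retained for
comparability with conventional stand-structure practice; a
parametric-bootstrap screen (`ks_screen_bootstrap`) is provided for
calibrated p-values. Fits are per plot, per census, per variable (D and H),
pooled over species; pooled-across-plots fits are available for summary
laws. On the synthetic experiment only ~30% of plot-level fits pass the
screen: pooled plot samples are mixtures of per-group Weibull laws plus
regeneration cohorts, and the anti-conservative screen punishes that — a
reminder that the screen measures distributional purity, not usefulness.

## Diversity–productivity classification

For each index/productivity pairing, both S = a + bP + cP² and the linear
model are fitted by OLS. The verdict is *hump* when c is significantly
negative (t-test, α = 0.05) with the vertex −b/2c inside the observed P
range; *U* when c is significantly positive with b < 0 and an interior
vertex; otherwise *linear increasing/decreasing* by the linear slope's sign
when significant, else *none*. No multiple-testing correction is applied
across the 54-regression grid by default (a Holm option exists and only
demotes curved verdicts). Under the simulation study (n = 36, noise sd 1 on
index units, quadratic amplitude 4) each true shape is recovered in well
over 90% of replicates, and a pure line produces a spurious curved verdict
at about the nominal 5%.

## Growth and yield

Observations are plot-censuses with V (m³ ha⁻¹), BA (m² ha⁻¹), SI, mean
pine age t (yr), and IQ = oak stems / total stems. SI is an anamorphic site
index from a Schumacher guide curve H = A·exp(−B/t) fitted across all
dominant-height/age pairs (dominant height = mean H of the 100 thickest
pines per hectare), indexed at base age 50 yr: SI = H_dom·exp(B/t − B/50).

The multiplicative model V = b₀·BA^b₁·SI^b₂·t^b₃·IQ^b₄ is fitted by
nonlinear least squares on the volume scale, initialized from log-linear
OLS. Residuals are weighted by observed volume by default: volume errors in
stand data scale with stand size (multiplicative error), and relative
weighting keeps the b₄ t-test at its nominal level under that regime
(measured ~6% vs ~9% unweighted at n = 108, noise sd 0.1); `weights="none"`
restores the unweighted fit. Noise-free data regenerate the coefficients to
machine precision. Plots with IQ = 0 cannot enter this model (IQ^b₄ forces
V = 0) and are fitted separately as the pure-pine model without the IQ
term, mirroring the two-model contrast between clear-felled pine stands and
mixed stands; the linear form V = b₀ + b₁BA + b₂SI + b₃t + b₄IQ accepts all
plots. `project_yield` runs both fitted models along a BA(t) trajectory and
reports the volume-difference curve, its extremum, and any crossover age,
warning when the trajectory leaves the fitted age range.

## The synthetic experiment

`SimConfig()` defaults encode the trial conditions: 6 removal levels
(0–100% of basal area) × 6 replicates, censuses 1982/1993/2004, a 10-species
pool with geometric (k = 0.4) relative abundances led by a pioneer pine and
an oak (together ~65–75% of stems), per-group three-parameter Weibull
diameter laws (pine shape 2.3, scale 14, location 5 cm), a saturating
height–diameter curve H = 1.3 + 24(1−e^{−0.04D})^{1.6} with persistent
per-tree lognormal noise (sd 0.08), baseline density 900 stems ha⁻¹,
growth 0.3 cm yr⁻¹ boosted by removal, annual mortality 0.008, recruitment
18 ha⁻¹ yr⁻¹ entering at the 5-cm threshold. These values were chosen so
the 1982 census lands near the reference conditions for these forests
(mean density ≈ 1,065 ha⁻¹, richness 8–12 per plot, mean D 15–18 cm, mean
H ≈ 9 m) and are fixed; the seeded RNG uses one sub-stream per plot so
subsetting plots never perturbs the rest.

Treatment removal is deterministic largest-basal-area-first — the actual
selection rule of the historical trial is unrecorded, and largest-first
matches a commercial harvest. The 15 years between treatment and the first
analysed census are compressed into the initial state: removed stems are
90%-replaced by in-growth, and complete clearing triggers a dense pioneer
cohort (900 ha⁻¹ · removal⁸, i.e. effectively clear-cut-only) with a
smaller-diameter Weibull law, giving clear-felled plots their
characteristic high density and low richness. Clear-felled plots are kept
oak-free (regeneration and recruitment exclude oaks) so they form the
pure-pine subset of the two-model yield design. The configurable
`oak_effect` scales pine diameter increment by (1 + IQ)^b4-like exponent
(default 0.5), injecting a recoverable mixture effect.

What the generator does **not** emulate: spatial structure and competition,
climate variation (droughts), measurement error in D and H, species-specific
height–diameter allometry beyond a group offset, and dead-tree tracking in
output files. Consequently, passing tests demonstrate estimator correctness
and pipeline integrity under a known truth — not that real Durango stands
satisfy any particular model. The plot-level Weibull adequacy rate and the
sign pattern of the diversity–productivity grid in the simulation are
properties of the synthetic world (where thinning simultaneously raises
productivity and lowers diversity) and should not be read as predictions
for field data.

## Numerical notes and problem sizes

Root finding uses Brent bracketing throughout (log-series x on (0,1),
Weibull shape on [0.05, 50]); nonlinear fits use Levenberg–Marquardt /
trust-region with data-driven starts (Preston: mode octave; Schumacher:
log-linear OLS; yield model: log-linear OLS). Degenerate inputs (constant
samples, all-singleton vectors, empty plots, singleton treatment groups)
return explicit errors or flagged boundary states rather than silent
numbers. The bundled studies run at: Weibull recovery 20 × 10⁵ draws;
chi-square calibration 1,000 communities at S = 10, N = 10⁴; yield-model
calibration 500 replicates at n = 108; classification accuracy 500
replicates per shape at n = 36 — sizes chosen to hold Monte Carlo error
comfortably below the decision margins they feed.
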