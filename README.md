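# standlab

Stand-level analysis of repeatedly measured permanent forest plots, built
around the kind of thinning trial run in the mixed pine–oak forests of the
Sierra Madre Occidental: ~36 one-hectare plots spanning six basal-area
removal intensities (0–100%), each measured on a 0.25-ha sub-quadrat over
three censuses. The package is aimed at quantitative forest ecologists who
need to go from raw tree lists (plot, year, species, DBH, height) to
defensible statements about diversity, stand structure, biomass
productivity, and the effect of species mixture on timber yield.

## What it computes

- **Biomass and productivity** — per-tree allometry (AGB = a·D^b with
  separate pine/oak coefficients, coarse-root BGB = 0.016·D^2.668), stand
  totals in Mg ha⁻¹, the physical cross-check M = V·ρ against
  Schumacher-form volume, and census-difference productivity
  (B₂ − B₁)/(t₂ − t₁).
- **Diversity** — richness S, Margalef, Menhinick, Shannon–Wiener
  (SW = −Σ pᵢ ln pᵢ), Brillouin, reciprocal Simpson and Berger–Parker,
  McIntosh.
- **Species-abundance models** — geometric series, Fisher log series
  (α, x solved from S and N), Preston truncated lognormal over octaves, and
  the broken stick model, each screened by chi-square with acceptance at
  p ≥ 0.05.
- **Stand structure** — three-parameter Weibull (shape α, scale β,
  location ε) fitted to D and H by the method of moments (skewness → shape,
  sd → scale, mean → location), Kolmogorov–Smirnov adequacy screening, and
  probability queries over size classes.
- **Diversity–productivity relationships** — the full quadratic-regression
  grid S = a + b·P + c·P² with hump / U / linear classification from the
  significance and sign of c, 9 indices × 2 biomass components × 3 periods
  = 54 regressions.
- **Growth and yield with a mixture covariate** — V = b₀·BA^b₁·SI^b₂·t^b₃·IQ^b₄
  (and its linear analogue), where IQ is the oak share of stem density;
  mixed-stand vs pure-pine model projections over stand age.
- **A seeded synthetic experiment generator** that reproduces the trial
  design (treatments, replicates, censuses, two-dominant species structure,
  Weibull size laws, growth/mortality/recruitment, an injectable oak effect
  on pine growth), so every estimator above has a recoverable truth.

## Worked example

```sh
python analysis/01_simulate.py --seed 1     # writes results/simulation/
python analysis/02_stand_attributes.py
python analysis/03_diversity_and_sads.py
python analysis/05_relationships_and_yield.py
```

prints, among other things:

```
mean AGB productivity 1982-1993: 3.76 Mg/ha/yr over 36 plots
 year     Den    S   Mg   Mn   SW   Br   Si   Mc   BP
 1982 1041.89 8.56 1.38 0.55 1.32 1.26 2.95 0.41 1.92
clear-cut plots accept 50% of SAD nulls vs 65% elsewhere
regression grid: 54 rows
multiplicative model (n=90, r2=1.000):
  b1 = 1.0548 (p = 1.843e-95)
  b4 = 0.0100 (p = 0.2299)
max mixed-minus-pure volume difference: 5.1 m3/ha at age 15
```

Reading this: the simulated 1982 stands carry ~1,040 stems ha⁻¹ across ~9
species (Shannon ≈ 1.3, reciprocal Simpson ≈ 3 — two dominants over a
tail of minor species), aboveground productivity averages ~3.8 Mg ha⁻¹ yr⁻¹,
clear-felled stands have not recovered a mature abundance structure (fewer
species-abundance nulls accepted), basal area is by far the strongest yield
predictor (b₁ ≈ 1), and the oak-mixture term b₄ is small and positive, worth
a few m³ ha⁻¹ at mid-rotation in this simulation.

The same stages are importable directly (`standlab.diversity_profile`,
`standlab.fit_all`, `standlab.weibull_moments_fit`, ...), and a thin CLI
wraps the whole pipeline: `standlab simulate|analyze|report`.

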