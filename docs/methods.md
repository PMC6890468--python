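# Methods

## Scope and data flow

`reefbudget` reconstructs a reef oxygen budget from four incubation-scale
experiment designs:

1. **Dark incubations** — heterotrophic bacteria grown on producer exudates
   in the dark; DOC, dissolved O₂ and cell abundance measured at start and
   end give cell-specific carbon and oxygen demands,
   (start − end)/(cells_end − cells_start).
2. **Sealed producer chambers (POP bottles)** — a primary producer in a
   bell-shaped chamber whose headspace traps rising bubbles; dissolved
   endpoints give the net dissolved production rate
   ΔO₂·V/(A·t), and the headspace volume and O₂ fraction give the gaseous
   rate through the ideal gas law.
3. **Open-tank bubble counting** — bubbles leaving an organism per minute,
   normalized by area (bubbles min⁻¹ dm⁻²), with bubble diameters measured
   on a subsample (≥ 40 per treatment).
4. **Microscopy cell sizing** — cells modeled as cylinders with
   hemispherical caps, V = (π/4)w²(l − w/3), converted to mass with an
   allometric power law (default dry mass 435·V^0.86 fg, a configurable
   literature relationship; the package treats the coefficients as
   configuration, not ground truth).

All physics is computed in SI internally (Pa, m, K, mol); tables carry the
field's display units (µmol L⁻¹, mL, cm², days, bubbles min⁻¹ dm⁻²) and
conversions happen at the module boundary. Bubble *diameters* are accepted
where source tables print them and halved to radii explicitly (logged).

## Bubble model

Internal pressure p_i = p_e + 2σ_w/R_b with σ_w = 71.99 mN m⁻¹ (25 °C),
p_e = 1 atm; moles per bubble n_b = p_i·(4π/3)R_b³/(R·T) at T = 298.15 K.
For the observed bubble sizes (≥ 0.25 mm radius) the Laplace correction is
under 1% of ambient pressure, so the dominant scale is the R_b³ volume
term. The rate required to explain a chamber headspace is
ρ_b = (n_POP/n_b)/t_light/A_p, assuming constant production during the lit
hours (12 h per day by default; no diel modulation). Headspace moles are
evaluated at *external* pressure: once bubbles coalesce at the top of a
chamber, their curvature over-pressure is released. The quartiles of the
measured size distribution give a (low, central, high) rate band, with the
75% quantile radius producing the low bound (big bubbles ⇒ fewer needed).

## Mixing model

Producer rates are scaled to an idealized reef of 1 m² benthos and a 1 m
boundary layer of water; above that layer the producers' influence on the
oxygen pool is neglected. Ω^microb is built as (per-cell dark respiration
per day) × (endpoint cell concentration of the chamber experiment,
converted to cells m⁻³) — the endpoint concentration is taken as the
sustained reference community. The reef mixes the coral and algae classes
linearly in cover; loss fractions are ratios of mixtures and are evaluated
both directly and in the algebraically identical shifted-Hill form (the
Hill form is undefined when both producers have equal gross production, in
which case the code falls back to the direct ratio). Degenerate gross
production ⇒ NaN-flagged fractions, never silent NaN propagation.

The inverse operation, `solve_gross_ratio`, recovers
r = O_algae^gross/O_coral^gross from loss fractions m₀, m₁ at the cover
endpoints and m_A at an intermediate cover A:
r = (1−A)(m_A−m₀)/[A(m₁−m_A)]. Together with `model_from_fractions` this
reconstructs a complete two-producer model from published fractions alone;
the package uses that reconstruction when per-bottle source rates are not
available, and labels it synthetic/calibrated.

## Synthetic generator

The generator emulates *endpoint statistics only* — no mechanistic growth
or photosynthesis–irradiance dynamics. Noise families: Gaussian truncated
at physical bounds (by resampling) for continuous endpoints, Poisson for
per-minute bubble counts, log-normal for bubble diameters and cell
volumes. One pseudorandom substream per (seed, experiment kind, treatment
label), so adding a treatment never changes another treatment's draws, and
identical (design, seed) ⇒ byte-identical tables.

Default study conditions (5 replicate bottles; 48-h dark incubations; 4-day
chambers with 12-h light): treatment means are the published summaries —
net dissolved production 6.33 (calcifying) and 5.99 (fleshy macroalgae)
µmol cm⁻² day⁻¹; gas fractions 5.00 / 10.19 / 13.78 / 37.33 % for coral /
CCA / turf / macroalgae; Chaetomorpha ebullition 10.3 bubbles min⁻¹ dm⁻²
over a 60-min run; bubble diameters 0.64 ± 0.23 and 0.79 ± 0.27 mm;
community cell-volume median 0.1 µm³. Chamber endpoint cell concentrations
(5.2×10⁸ cells L⁻¹ coral, 4.9×10⁹ macroalgae) are set so that dark
per-cell respiration (~1.5×10⁻⁸ µmol cell⁻¹ day⁻¹) scales to volumetric
respiration of the order the budget requires.

Replicate-level dispersions are not published. Choices: gas fractions use
the published per-treatment SE·√5; net dissolved rates use a 25% CV
(published group SEs pool distinct organisms, and adopting them
per-treatment would imply bottles with negative total production — an
artifact of drawing net and gas independently when the real quantities are
positively correlated within a bottle); remaining dispersions are
placeholder CVs of 5–15%. The dissolved-O₂ probe saturates at 625 µmol L⁻¹
(20 mg L⁻¹); clamped endpoint values are stored as stated lower bounds
with a flag that propagates through every derived column — no imputation.

What passing tests show, and what they do not: the generators calibrate
exactly at zero noise and recover configured means within counting/delta
error at the default noise, so the *rate pipeline* is validated end to end;
they do not reproduce the skewness, bottle-level correlations, or outlier
structure of real incubation data. Two consequences are documented rather
than patched:

* **Truncation bias at high CV.** For near-zero means with large sd (coral
  gas volumes), resampling at the zero bound inflates the realized mean
  above the configured one; cohort gas fractions for calcifiers therefore
  run high relative to their nominal 5–10%.
* **Group-mean vs per-bottle calibration.** A 37.33% gas fraction at net
  5.99 µmol cm⁻² day⁻¹ implies ~88 bubbles min⁻¹ dm⁻² of 0.64 mm bubbles,
  an order above the measured 10.3, so the required-rate band of the
  synthetic chambers does not bracket the open-tank rate. The published
  consistency between the two rested on per-bottle areas and headspace
  moles from the supplementary source tables, which group means cannot
  reproduce. The inversion itself is verified by an exact round trip
  (headspace synthesized from known bubbles is recovered to 1e−12).

## Uncertainty and statistics

Measurement uncertainty propagates to first order assuming independent
errors: sd_f = √Σ(∂f/∂xᵢ)²sdᵢ², with central finite differences
(step max(10⁻⁶|x|, 10⁻⁹)). Default instrument terms: dissolved-O₂ probe
±3.1 µmol L⁻¹ (±0.1 mg L⁻¹), chamber volume ±10 mL, surface area ±2%,
timing ±5 min. Under the default study conditions the propagated
instrument error on treatment rates is ≥ 5× below the between-replicate
spread (and of the same order for controls), which is why the treatment
comparisons use replicate variation only.

Comparisons: Shapiro–Wilk per group, tie-corrected Kruskal–Wallis omnibus,
pairwise two-sided Wilcoxon rank-sum (exact null below n = 25 per group,
normal approximation above or under ties) with Benjamini–Hochberg FDR at
α = 0.05, and a compact letter display built by insert-and-absorb; the
multiplicity family is all pairwise comparisons within one response
variable. Paired designs (e.g. versus the initial community) use the
signed-rank test. OLS fits report slope, intercept, R² and the slope
t-test.

## Problem sizes and numerical choices

Randomized verification uses 10⁴ random models for the Hill/direct
identity (tolerance 10⁻¹² relative), 100 random radii for the bubble-physics
oracle, 500 seeded replications of the calibrated cohorts for parameter
recovery (3·SE bands from the configured dispersions via the delta
method), and 10⁴ cells for the volume-median check. The cover grid is 0–1
in steps of 0.01 (101 points). Ties in the letter display are broken by
treatment order of first appearance; truncated-normal resampling aborts
after 1000 rounds rather than looping on infeasible bounds.

## Known limitations

Two producer classes only (coral, fleshy algae); no hydrodynamic air–sea
exchange, advection or diel cycling; no multi-gas bubble partitioning or
dissolution during ascent; error propagation ignores covariances; the
biomass allometry coefficients are a configurable literature default. The
generator limitations above apply to any conclusion drawn from the
synthetic chain rather than the calibrated reconstruction.
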