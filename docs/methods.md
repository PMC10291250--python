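# Methods

This note documents the models, conventions and calibration behind
`xylemflow` — what is computed, which choices were genuinely open, and what
the synthetic generator does and does not emulate.

## Trait definitions and conventions

**Anatomy.** A measurement unit is a radial sector ("wedge", opening angle
20–70°) of a cross section with `n` conduit lumen areas (µm²). Diameters
are circle-equivalent, `d = 2√(A/π)`; lumen-area measurement preserves no
more shape information, and ellipse fitting of individual lumina is out of
scope. Traits:

* `CD = n / A_sector` (n mm⁻²),
* `F = 100 · Σ lumen / A_sector` (%),
* `D_h`: default `Σd⁵/Σd⁴`, the convention in which each conduit is
  weighted by its Poiseuille contribution (d⁴). The alternative
  `(Σd⁴/n)^¼` is implemented and selectable; the two coincide exactly for
  uniform conduits and `Σd⁵/Σd⁴ ≥ mean(d)` always. The d⁵/d⁴ default was
  chosen because it matches the ΣD⁴ weighting used everywhere else in the
  pipeline.
* `KS_pot = π ρ ΣD⁴ / (128 η A_sector)` with η = 1.002·10⁻⁹ MPa s and
  ρ = 998.2 kg m⁻³ (water, 20 °C). The reference area is the sector's own
  woody area; it is deliberately never mixed with the flow module's
  segment-level `A_xylem`. All computation is SI internally; µm/mm appear
  only at the I/O boundary.

**Flow.** `K_h = ṁ · l / Δp` with the mass flow in g h⁻¹ (the working
range of laboratory liquid flow meters), head in kPa, length in m, K_h in
kg m MPa⁻¹ s⁻¹. Flushing: stages are scanned in order and the first flush
whose relative gain over its predecessor is below a stability tolerance
(default 2 %, configurable — "stable" is an empirical call) is the plateau
`k_max`; if no pair stabilises, the maximum is used with a warning. The
pre-flush (native) `K_h` is retained as a plugging diagnostic but excluded
from `KS_hydr`, which is defined after flushing. `A_xylem` is the caliper
ellipse at the basal end for branches (minus the pith ellipse) and the
distal end for roots — the tubing-attachment ends.

**Huber value.** `HV = A_xylem / A_leaf`. Verbal definitions of HV are
frequently stated in both directions; the implemented direction is the one
consistent with the magnitudes this kind of study reports (10⁻⁴–10⁻³
m² m⁻²). `K_L = K_h(max)/A_leaf` is stored in SI; a configurable reporting
scale exists because K_L is often displayed on a scaled axis.

**Density.** `WD = dry mass / fresh volume` (g cm⁻³); segment volume is
the mean elliptical woody area of the two ends × length, pith-corrected
only for branches (roots and cores never are); core volume is the 5-mm
corer cylinder. Inputs are debarked dimensions — an upstream contract the
code cannot verify. A 0.2–1.2 g cm⁻³ plausibility band triggers a warning
only.

## Statistical layer

Samples are averaged per tree × organ (pseudo-replication guard); species
means are means of tree means. Leaf-habit contrasts (deciduous −
evergreen, gymnosperm excluded) and organ contrasts (root − branch) are
computed on species means as one-factor linear-model marginal-mean
differences, which for two groups is exactly the pooled-variance
two-sample computation (`df = N − 2`; the test suite pins this equality to
1e-10 against an OLS fit). Missing cells (a species without usable root
flow, a species without cores) are omitted, not imputed, and the df
adjusts. Conductivities are right-skewed; a log10 path is available, but
the contrast tables report raw-scale differences of group means, the form
in which such results are conventionally printed.

Tukey all-pairs tests use the studentized-range distribution with the
one-way pooled MSE (Tukey–Kramer under unequal n); the compact letter
display uses the insert–absorb algorithm, so two groups share a letter iff
their adjusted p ≥ α. α = 0.05 with a 0.10 "tendency" band in the
correlation flags. Correlation matrices are pairwise-complete Pearson on
species means (≥3 pairs per cell; no multiplicity control across the
matrix, matching field practice). Root:branch ratios are **means of
per-pair ratios** (tree-wise for well-replicated traits, species-wise
otherwise) — under heterogeneity this exceeds the ratio of group means,
and the distinction matters when comparing against published R:B values.

The tree-height analysis is a Gaussian random-intercept model
(species-level intercepts). The intercept variance is profiled out of the
ML likelihood over the variance ratio ψ = σ²ᵤ/σ²ₑ (1-D bounded search;
`V⁻¹` applied via rank-one group corrections), and the height slope's
p-value is a χ²₁ likelihood-ratio test against the no-slope model. This is
a deliberate, documented simplification relative to residual-df
approximations (Satterthwaite/Kenward–Roger are non-goals); the LRT is
mildly anticonservative at small group counts, which the type-I
calibration test brackets. Singular fits fall back to pooled least
squares with a warning.

## Synthetic-study generator

The generator emulates the sampling design of a 14-species campaign in a
seasonally dry subtropical highland forest: 5 drought-deciduous + 8
evergreen angiosperms + 1 conifer-like gymnosperm, 6 trees per species,
2 coarse-root + 3 branch flow/density segments per tree, anatomy sectors
on 3 trees per species, stem cores on 3–6 trees. Two realistic data
defects are built in: one deciduous species' root flow is discarded
(leakage scenario) and one evergreen species has no stem cores — both
exercise the df bookkeeping downstream.

**Within-sector calibration.** Conduit diameters are lognormal. For each
angiosperm habit×organ cell the target triple (D_h, CD, F) identifies the
lognormal exactly:

    σ_w² = ln( CD · (π/4) · D_h² / F ) / 7,   m = D_h · e^(−4.5 σ_w²).

Solved medians are ≈ 55/42 µm (deciduous/evergreen roots) and ≈ 35/28 µm
(branches) with geometric SDs 1.24–1.30. The gymnosperm cell is
under-determined and uses geometric SD 1.35 (a typical within-sample
spread) with its published density/fraction anchors; it is generated as a
high-CD/small-D_h outlier only, not a faithful tracheid model.

**Between-unit heterogeneity (the part that cannot be turned off).** For
any diameter distribution, power-mean inequalities give
`E[d⁴]/E[d²] ≤ (E[d⁵]/E[d⁴])²`, hence a homogeneous population can reach
at most `KS_pot ≤ (ρ/32η) · F · D_h²` — about half of the group-mean
conductivities this flora exhibits at its group-mean D_h and F. The group
means are therefore only attainable through between-species/tree
heterogeneity (a Jensen effect on ΣD⁴: species KS_pot is convex in the
diameter scale). The generator implements this with lognormal diameter
multipliers `u` (mean 1) at the species and tree level, with conduit
density co-varying as `u^(−1/2)` times a per-level normaliser
`e^(−0.375σ²)` — the unique coupling exponent that preserves the group
means of D_h, CD **and** F simultaneously while ΣD⁴ gains `e^(4σ²)` per
level. The total log-variance (species + tree, tree share fixed at 0.10)
is solved so that `r · E[KS_pot]` reproduces the target group means of
measured conductivity (root 9.5, branch 2.3 kg m⁻¹ MPa⁻¹ s⁻¹) at the
global flow ratio r = 0.25. Cells whose multiplier would push the
analytic lumen fraction above 92 % are thinned back to that bound (a
physical guard touching ≪1 % of cells, costing ~1–2 % of the calibrated
group means).

The cross-organ correlation ρ of the multipliers (same ρ at both levels)
is solved in closed form so that the expected deciduous tree-wise mean
root:branch ratio of KS_hydr equals 5.1:
`E[R:B] = R₀ · e^(12.25 σ²_tot (1−ρ)) · e^(ν²/3)`, giving ρ ≈ 0.81. A
consequence of matching both the group means and the deciduous
mean-of-ratios is that the evergreen mean-of-ratios comes out near 6–7
rather than the published 5.8 — the published group means force an
evergreen ratio-of-means of ≈5.1, and any heterogeneity strong enough to
satisfy the conductivity means pushes the mean-of-ratios above it; this
residual tension is inherent to the printed values, not a tunable.

**Flow, density, leaf area.** The final-flush flow inverts the
conductivity equation for `K_h = r · KS_pot(tree) · A_xylem` with
multiplicative lognormal noise (log-SD 0.25 per sample); flushing stages
approach the plateau from below with a final increment < 2 % so plateau
selection is exact; the initial stage is the plateau times a plugging
factor U(0.3, 1). Wood density is `WD = a_habit,organ − b·(F_species −
F̄_habit) + ε`, the root-level density–lumen-fraction trade-off (strong for
roots, weak for branches via a smaller slope and larger noise); stem WD is
the species' root WD plus a habit offset, which also makes root and stem
WD strongly correlated across species while branch WD stays decoupled.
Branch leaf areas are drawn so that the Huber value is centred on the
habit targets (26.4/13.9/0.7 ·10⁻⁴ m² m⁻²) with geometric SD ≈ 1.3.
Segment diameters, tree heights (species means and SDs of the emulated
flora) and conduit counts per sector (median 52, log-SD 0.4, matching
"57 ± 27 per sector" reporting) complete the tables. All randomness flows
from a single seeded generator in a fixed iteration order, so one seed
reproduces the study byte-identically.

**What the generator does not emulate.** Real radial position effects,
vessel grouping, non-circular lumina, temperature drift of viscosity,
species-specific diameter–density relationships beyond the printed group
structure, and any vulnerability/embolism behaviour. Passing
calibration-consistency tests therefore shows the *pipeline* is unbiased
for data with this covariance structure — not that real micrographs or
flow series are this clean.

## Imaging

Rendering packs non-overlapping ellipses (aspect drawn in [1, 1.3], areas
equal to the conduit lumina) into the wedge by dart-throwing with
bounding-circle rejection; a 60 % packing bound guards feasibility.
Rasterisation is done on a supersampled boolean grid and block-averaged
(anti-aliased edges), dark lumina on a light background, default pixel
size 0.5 µm px⁻¹ (light-microscopy scale). Segmentation: Otsu global
threshold (the histogram is strongly bimodal by construction) → connected
components → area filter → centroid-in-sector selection. Border conduits
are counted by centroid inclusion, which makes the density estimator
unbiased under random sector placement (checked by Monte Carlo). The
round-trip recovers conduit counts exactly and D_h within a few tenths of
a percent at ≤1 µm px⁻¹ for ≥100-conduit sectors; watershed splitting of
touching vessels is a non-goal because the renderer never produces them.

## Numerical choices and degenerate inputs

Zero/negative areas, heads, lengths and volumes are rejected with
`ValueError`s at the operation boundary. A sector whose drawn lumina
exceed 90 % of its nominal area is enlarged to fit them (warned) rather
than redrawn — redrawing would truncate the ΣD⁴ tail and bias KS_pot
downward. Identical groups produce a zero contrast with p = 1; zero
within-group variance rejects the Tukey computation; R:B pairs with a zero
denominator are dropped with a warning. The profile likelihood is searched
on log ψ ∈ [−10, 6] with an explicit ψ = 0 boundary comparison.

## Problem sizes used by tests and the acceptance script

Simulated quantities on the conductivity scale are strongly right-skewed
(the species multiplier enters ΣD⁴ at the 3.5th power), so single-study
estimates scatter widely — exactly as single field campaigns do. The
acceptance script therefore averages 200 independent studies (and takes
ratios of grand means, where the ratio-of-noisy-means bias vanishes); the
in-suite calibration check uses 20 studies with 3-σ Monte-Carlo bands; the
type-I calibration of the height model uses 200 replicates of an
8-species × 5-tree null design. Imaging round-trips run at 1 µm px⁻¹ with
100–140 conduits per sector.
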