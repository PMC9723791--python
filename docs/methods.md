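# Methods

This note documents the models, numerical choices and limitations behind
the package; the README shows what the code computes, this explains why it
is computed that way.

## The trait-scape model

The central object is a cultures × 9 trait table (strain, replicate,
environment metadata plus growth rate, cell size, chlorophyll-a,
granularity, lipids, ROS, α, ETRmax, Ik). Because the traits live on
incommensurable scales, every analysis starts by standardizing each trait
to mean 0 and sample SD 1 (ddof = 1); the PCA is therefore a
correlation-matrix PCA, computed as an SVD of the standardized data for
numerical stability. Conventions:

- proportion of variance of axis k = eigenvalue_k / 9 (the trace of a
  correlation matrix equals the trait count, so proportions sum to 1
  exactly, also under rank deficiency);
- trait contributions = 100 × squared unit-loading, so each axis column
  sums to 100;
- loading signs are arbitrary in PCA; each column is flipped so its
  largest-magnitude element is positive. All downstream distances are
  sign-invariant, so this is cosmetic but makes runs comparable;
- axes beyond the rank of the data get eigenvalue 0 and zero
  contributions, never NaN (tables with fewer cultures than traits are
  legal);
- the trait-scape proper is axes 1–2; all axes are retained for
  diagnostics.

The two-axis null for "no multivariate structure" is reported in two
flavours: 2/(T−1) (the rank-based expectation for T standardized traits,
25.0% for nine) and the naive 2/T (22.2%). The diagnostics op reports both,
labelled, because either denominator is defensible and published summaries
use the former.

### Centroid distances and reduced-trait recovery

Strains are compared by the variance-weighted distance between their mean
positions on the first two axes, distance = √((ΔPC1·a)² + (ΔPC2·b)²), with
a and b the percent variance of PC1 and PC2. Weights are kept as
percentages (0–100); since the recovery statistic is an R², any common
rescaling of the weights cancels, and this is asserted by test. Recovery of
a reduced trait-scape is scored by ordinary least squares of the reduced
pairwise centroid distances on the full ones, reporting adjusted
R² = 1 − (1 − R²)(m − 1)/(m − 2) for m strain pairs and one predictor. The
pairs share strains and are not independent; the OLS p-value is reported
as-is (matching standard practice for this statistic), and a Mantel-style
permutation p is available as a clearly-labelled extra diagnostic. The
distance regression uses a free intercept.

## Trait derivation

- **Growth rate.** Per-step rates μᵢ = (ln Fᵢ₊₁ − ln Fᵢ)/(tᵢ₊₁ − tᵢ); the
  reported maximum is the best mean over every contiguous window of 2, 3 or
  4 step rates (windows longer than the series are skipped, ties go to the
  earliest window). Windows operate on step rates, not raw points.
- **Cell size.** ESD = (FSC − intercept)/slope from a linear bead
  calibration (FSC regressed on bead diameter); the published instrument
  line ESD = (FSC + 194636)/75775 ships as the built-in default. FSC below
  the calibration range (ESD ≤ 0) is an error, not a clipped value.
- **Per-size traits.** Chlorophyll and granularity medians are divided by
  ESD; lipids are (post-stain − pre-stain)/ESD; ROS is
  ((stained − blank)/cell count)/ESD. Division is by ESD (linear), not
  ESD³ — the convention is relative, per-size normalization, not a volume
  model — and negative stain differences are preserved. Units are
  instrument-relative and treated as dimensionless.
- **Photophysiology.** The rapid-light-curve fit uses the Jassby–Platt
  saturating tangent ETR = ETRmax·tanh(αE/ETRmax), chosen because its
  parameters are exactly the three reported traits with Ik = ETRmax/α; a
  Webb exponential model is selectable (`model="exp"`). The fit is
  unweighted least squares with positivity bounds, initialized from the
  first-step slope and the curve maximum. Non-convergence yields missing
  traits rather than an exception; a culture missing any trait is excluded
  from PCA by the table validator.

## The synthetic experiment

The generator emulates the study design: 13 strains × 3 replicates in a
standard environment, a 5-strain subset additionally grown under a high
temperature/light (HT) and a low-nutrient (LN) treatment, plus
instrument-level outputs and a strain × strain percent-identity matrix.

Trait values follow a linear-Gaussian latent-factor model on the
standardized scale, z = Λf + shift(env) + δ + ε, mapped to natural units
by per-trait means and scales chosen to look like a diatom panel (cell
size ~9 ± 1.8 µm, growth ~0.8 d⁻¹, α ~0.3, ETRmax ~60, Ik ~200). The
default Λ has two orthogonal factors — a size factor loading cell size,
chlorophyll, granularity and lipids at 0.88–0.95, and a photophysiology
factor loading α, ETRmax and Ik at 0.80–0.88 — with weak cross-loadings
for growth rate (0.15, 0.10) and ROS (0.10, 0.30), so the generated tables
show four near-orthogonal trait groups. Strain factor vectors are drawn
N(0, diag(1.4², 0.8²)): the dominant size factor reproduces the empirical
regime in which the first axis carries roughly half the variance and
inter-strain distances are driven mainly by size-related traits, which is
what makes a four-trait scape with one size representative recover the
full scape well while a subset without any size trait does not. Replicate
noise defaults to 0.35 SD per trait; with these defaults the population
two-axis fraction is 0.794 and 13-strain realizations scatter around it
(roughly 74–85%).

Environment shifts are mean vectors shared across strains plus a small
per-strain deviation (SD 0.15), drawn once per strain × environment and
shared by its replicates — this is what makes whole-phenotype "strategies"
reproducible by construction. The LN default has a negative chlorophyll
and positive lipid component while both traits load positively on the size
factor, planting the across-strain-positive / within-strain-reversed
trade-off. The HT default moves mainly photophysiology and ROS, so
treatments separate from standard chiefly along the photophysiology-
dominated axis.

Instrument-level data are generated at summary level (per-sample medians),
since only medians enter the analysis. Growth series are
F(t) = F₀e^{μt}·e^{σz} with optional lag and plateau; light curves are the
tanh model plus additive noise; cytometry medians invert the per-ESD
normalizations exactly; bead FSC medians lie on the built-in calibration
line. One deliberate simplification: the table's Ik trait is generated by
the factor model like every other trait, so it is statistically — not
numerically — consistent with ETRmax/α per culture; the derivation module
applied to the emitted light curves returns Ik = ETRmax/α exactly. The
identity matrix draws off-diagonals independently of the phenotype factors
(the null the analysis tests), with a "coupled" mode for power checks.

All randomness flows from one seed through labelled SeedSequence
substreams (factors, table noise, plasticity, identity, growth, light), so
identical configs give byte-identical outputs.

What the generator does *not* emulate: per-event cytometry, non-Gaussian
trait distributions, trait-specific plasticity variance, batch effects, or
mechanistic physiology. Tests passing on this generator show the methods
recover known linear-Gaussian structure at realistic noise; they do not
certify behaviour under real instruments' artefacts.

## Clustering support

Replicate phenotypes are clustered by UPGMA (average linkage, delegated to
scipy's deterministic nearest-neighbor-chain implementation) on Euclidean
distances between standardized trait vectors. Support uses a multiscale
bootstrap that resamples *traits* (features) with replacement at sizes
round(r·9) for r ∈ {0.5, …, 1.4} — with nine traits that spans 5–13
features, so BP estimates are coarse and the probit-scale machinery needs
care: BP values of exactly 0 or 1 are clamped to 1/(2B) and 1 − 1/(2B);
the per-node fit z(s) = v√s + c/√s uses weights from the delta-method
binomial variance B·φ(z)²/(BP(1 − BP)); AU = 1 − Φ(v − c) and the
smoothed BP₀ = 1 − Φ(v + c). Nodes whose BP sits at a bound on every scale
(the root always does) are flagged degenerate and reported with AU 0 or 1
directly. Cluster identity across bootstrap trees is exact member-set
equality. B defaults to 1000 per scale; per-scale RNG substreams come from
the master seed. Observation resampling is deliberately not the default —
with n = 3 replicates per strain it would be nearly meaningless — and the
method quantifies sensitivity of the tree to the trait panel, not sampling
of cultures.

## Plasticity

Relative change = (value − strain's standard-environment mean)/that mean,
computed on raw trait scales before any standardization; baselines with
magnitude ≤ 10⁻⁹ raise rather than explode (lipid and ROS differences can
legitimately cross zero). The strategy PCA standardizes the change table
by default (a covariance-scale variant is available since changes are
already dimensionless); environment clustering is summarized by the ratio
of mean between-environment to mean within-environment pairwise distances
on the first two axes, with a label-permutation null. Strains measured
only in the standard environment can optionally be shown as zero-change
rows, off by default because their placement in a change space is a
presentation choice, not data.

## Problem sizes and determinism

Default test and acceptance runs use the 13-strain experiment; seed
batteries (20 seeds for recovery medians, 100–200 for null calibrations,
100 Monte-Carlo light-curve fits, B = 1000 bootstrap for planted-cluster
support) were sized so a full run completes in a few seconds to minutes on
one CPU while keeping Monte-Carlo error well below the margins being
tested. Every stochastic entry point takes an explicit seed, and the
pipeline writes a content-hashed manifest so identical config + seed is
verifiable as identical output.

## Known limitations

- Group identification on default 13-strain data recovers the planted
  four-group partition in roughly 60% of seeds; with so few strains,
  sample correlations near the 0.7 threshold flip edges. This mirrors the
  fragility of threshold-based grouping on real panels; the block-structure
  tests use configurations where the partition is unambiguous.
- The AU machinery is the non-selective (classical) variant; no
  selective-inference correction is applied.
- The reduced-recovery regression treats strain pairs as independent; its
  p-values are optimistic, which is why the package reports (and tests)
  the R² contrast rather than leaning on those p-values.
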