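# Methods

This note documents the models, estimators, numerical choices and known
limitations of `thermodiv`. It is the package's own account of its
science; every empirical number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## Scientific setting

The package implements the analysis chain used to ask whether lineage
diversification in a large plant clade is associated with temperature:
contemporary temperature niche (from occurrence records), binary
tropicality (geographic and climatic), phylogenetic niche conservatism,
and deep-time dependence of speciation/extinction on a global
paleotemperature curve. Inputs are a rooted, time-calibrated ultrametric
phylogeny (branch lengths in Myr), per-species occurrence tables
(decimal lon/lat, optionally a per-record annual-mean temperature), a
paleotemperature series (age in Myr BP vs temperature), and optional
clade sampling fractions.

## Occurrence cleaning and niche classification

Records are removed when coordinates are missing, out of range, exactly
zero in either axis, or integer-valued in *both* axes. The integer test
is exact representation equality after parsing (`v == floor(v)`): the
targeted artifact is whole-degree truncation, not proximity. The
either-zero plus both-integer reading is deliberate; removing every
record with one integral coordinate would discard large numbers of
legitimate records.

Geographic outliers are removed in a single pass per species: with at
least 4 kept records, distances `d_i` to the centroid are computed as
plain Euclidean distances in degrees (no projection, matching the
simplicity of the classical filter); rows with
`d > mean(d) + 3 * sd(d)` (sample sd) are dropped. With zero distance
spread nothing is removed. Because the filter works in raw degrees it is
not dateline-aware; the synthetic generator therefore keeps injected
outlier displacements unwrapped.

Tropicality: *geographic* — tropical iff the mean latitude of kept
records lies within ±23.43677° (boundary inclusive); *climatic* —
non-tropical iff strictly more than 50% of kept records fall outside
tropical cells of a user-supplied mask (ties classify as tropical). The
default synthetic mask is `|lat| <= 23.43677`; a real climatological
mask (e.g. Köppen's year-round >18 °C criterion) can be supplied as a
function or grid. MAT is the arithmetic mean of kept records'
temperatures; species without temperature data are flagged and excluded
from MAT analyses only.

## Tip rates and community grids

The tip speciation proxy is the DR statistic: for tip *i* with rootward
edges e₁ (pendant), e₂, … the equal-splits measure is
`ES_i = Σ_j len(e_j) · 2^{-(j-1)}` (root edge excluded) and
`DR_i = 1 / ES_i`. Tip age is the age of the tip's parent node. Tip
metrics require a dated ultrametric tree.

Community summaries use an equal-area grid built on the cylindrical
(Lambert) equal-area projection: cells are rectangles in
(longitude, sin latitude), which makes all spherical cell areas exactly
equal by construction; the default target is 322 km², reproduced to
<0.01% with the whole partition summing to the Earth's surface area.
This replaces the hexagonal discrete global grid used by some tools: the
statistical role (equal-area binning for cell medians) is identical and
the construction is deterministic with no extra dependency. Cell ids are
(row, column); points on cell boundaries go to the lexicographically
smaller adjoining cell. Within a cell each species counts once,
regardless of record count; medians use the even-size mean-of-central-
values convention.

## Trait–rate tests

*Continuous (es-SIM style).* Observed statistic: Pearson ρ between the
trait and log DR (log because tip rates are right-skewed; a raw-scale
option exists). Null: `n_sim` Brownian traits simulated on the same tree
with σ² set to the ML Brownian rate of the observed trait (GLS
estimate), each correlated against the fixed DR values. Two-tailed p by
symmetric absolute-value counting with the +1 finite-sample correction,
`p = (1 + #{|ρ_null| ≥ |ρ_obs|}) / (n_sim + 1)`.

*Binary (FiSSE style).* State rates are mean DR per state; the statistic
is λ̂₁ − λ̂₀. Null: neutral symmetric Mk characters at the ML flip rate
q̂, floored at one expected transition per total tree length to avoid a
degenerate zero-rate null; monomorphic null draws are discarded;
monomorphic *observed* states return an NA result (small clades fail
this test in practice, and the pipeline reports them as NA rather than
erroring).

*Pagel's λ.* The shared-path covariances are scaled by λ while tip
variances stay Brownian. On ultrametric trees the covariance diagonal is
constant, so the λ-transform preserves the eigenvectors of C; one
eigendecomposition per tree then makes each profile-likelihood
evaluation O(n). A direct Cholesky path is kept as a cross-check; the
two agree to 1e-8 on test trees. λ̂ maximises the profiled likelihood on
[0, 1] (bounded scalar search, 1e-8 tolerance, endpoints checked); the
LRT against λ = 0 uses a plain 1-df χ² (no boundary halving), chosen as
the signal-vs-none contrast.

*Multiple testing.* Hochberg's step-up: NAs are dropped from the family,
`adj_(i) = min_{j ≥ i} (m − j + 1) p_(j)` capped at 1. Verified against
R's `p.adjust` and against two published per-order screens bundled in
`thermodiv.datasets` (17 continuous-test p-values adjusting 0.0060 →
0.0960; 15 binary-test p-values adjusting 0.0020 → 0.0300).

*Cross-clade replication.* One-sample t on mean ρ, paired t on the state
rates, and OLS of the rate ratio on a clade covariate with the overall
F-test. Welch (unequal-variance) t-tests are used everywhere a
two-sample contrast appears, because equality of variances is never
guaranteed for these quantities.

## Time- and temperature-dependent birth–death models

With t in Myr before present, r(t) = ∫₀ᵗ (λ − μ) ds and
F(t) = ∫₀ᵗ e^{r} λ ds, the probability that a lineage at age t leaves no
sampled descendant is Φ(t) = 1 − e^{r(t)}/(1/f + F(t)) and the
one-surviving-lineage propagator is
Ψ(s,t) = e^{r(t)−r(s)} [(1/f + F(s))/(1/f + F(t))]². The reconstructed
tree's likelihood multiplies f per tip, λ at each branching time and Ψ
per edge, conditioned on the crown age and survival of both crown
lineages (divide by λ(t₁)(1 − Φ(t₁))²). Crown conditioning (not stem) is
used because the input trees are crown clades; ordinal-subtree analyses
are therefore comparable.

Rate families per dependency (time or interpolated temperature T(t)):
constant, linear (base + slope·x), exponential (base·e^{slope·x});
extinction additionally has a `zero` (pure-birth) family. The model set
per dependency is the 3×3 birth–death grid plus 3 pure-birth models — 12
models, 24 over both dependencies. Evaluated extinction is clamped at 0
from below; a non-positive speciation rate anywhere on the age span
returns a large penalty rather than raising, so optimisers can recover.

Quadrature: r and F are accumulated by composite Simpson's rule on a
grid that contains every node age and every curve knot plus a uniform
refinement (default 2000 intervals; fits use 400–800). Midpoint values
of r needed for the F integrand come from half-interval Simpson. This
reaches ~1e-9 relative accuracy at a fraction of adaptive-solver cost;
it is validated against the Yule closed form (<1e-6) and an independent
step-1e-4 trapezoid oracle (<1e-5 across all 12 temperature models).

Fitting: bounded L-BFGS-B, base rates on the log scale
(λ₀ ∈ [1e-6, 10], μ₀ ∈ [~0, 10]), slopes on the natural scale bounded to
±1 per Myr or per °C. The slope bound is deliberately tight: beyond ~1
the exponential families overflow, and an extinction rate exploding
toward the root drives the crown-survival probability to ~0, where the
conditioned likelihood becomes numerically meaningless; a hard guard
(log survival < −30 → penalty) backs this up. The first start is a
moment guess (λ₀ ≈ (n−2)/tree length, μ₀ = λ₀/10, zero slopes); further
starts draw log-uniform bases and N(0, 0.05) slopes. The convergence
flag requires at least two starts (when available) within 0.01 logL of
the best.

Model choice uses AIC = 2k − 2logL, ΔAIC, and Akaike weights
`exp(−Δ/2)` normalised to 1. Rate-through-time tables sample λ, μ and
r = λ − μ at 100 equally spaced ages from crown to present ("100
time-unit slices" read as 100 equally spaced points). The
rate-vs-temperature regression pairs each slice's r with T at the same
age, fits r = a + bT (OLS) and r = a·e^{bT} (nonlinear least squares),
and picks the winner by Gaussian-residual AIC; a non-convergent
exponential fit falls back to linear with a flag.

δ¹⁸O series are converted by a configurable affine map T = a − b·δ¹⁸O
(defaults 16.5, 4.3 — a convenience, not an asserted calibration; a
converted-temperature CSV is the canonical input). Smoothing is a
centered rolling mean (default width 5) whose half-width shrinks
symmetrically at the series ends; queries outside the age range clamp to
the endpoint values.

## State-dependent diversification (BiSSE/HiSSE)

Standard coupled ODEs for per-state extinction probabilities E_i and
subtree densities D_i, with sampling entering the tip initial conditions
(D = f for compatible states, E = 1 − f). On an ultrametric tree every
tip shares the same E initial condition, so E(t) is a single global
function of age, and given E the D system is linear; the implementation
integrates E together with one fundamental matrix W(t) of the D system
(rescaled by e^{φ(t)}, φ′ = mean diagonal, to stay conditioned) in a
single adaptive solve per likelihood evaluation, then propagates every
branch by k×k linear algebra with the scalar factor accumulated in log
space. This is exact up to solver tolerance (1e-9 relative; 1e-7 inside
optimiser line searches, with the final likelihood re-evaluated at full
tolerance) and is validated against an independent fixed-step RK4 on
two-tip trees and against the product oracle below.

Root treatment: likelihood-weighted (FitzJohn) averaging over root
states, each state's contribution divided by λ_i (1 − E_i)² — the
analog of the crown conditioning in the birth–death module. Under
state-independent parameters the BiSSE likelihood then factorises
exactly into (crown-conditioned birth–death likelihood) × (Mk character
likelihood with the same FitzJohn root), which the tests verify to
1e-4 on random 50-tip trees.

The four-model comparison set: `bisse_null` (shared λ, μ; two q's;
k = 4), `bisse_free` (k = 6), `hisse_cid` (diversification tied to the
hidden state only; k = 6), and `hisse_full` (free net diversification r
across the four observed×hidden states, one shared relative extinction
ε = μ/λ, one shared transition rate; k = 6). `hisse_full` is
parameterised as (r_i, ε, q) with λ_i = r_i/(1 − ε); this reconstructs
the published winning-model constraint ("equal transition rates and
relative extinction, different diversification rates") as a mask; the
exact constraint structure of the original two hidden-state models was
not published in full, so the set is a faithful reconstruction rather
than a copy. Dual transitions are fixed at zero; hidden-state
transitions share one rate. Sampling fraction is a single global f by
default, per-observed-state optional.

## Synthetic data

All generators are deterministic given (parameters, seed) and attach a
truth record. The state-dependent tree simulator is an exact Gillespie
walk on the growing tip set starting from two crown lineages,
conditioned on reaching the stop by rejection (cap 1000). For n-tip
stops the clock advances to the moment of the next (unexecuted) event
after the target is reached: stopping exactly at the n-th birth would
leave zero-length pendant cherries whose tip covariance is singular,
violating downstream preconditions. Age stops end exactly at the target
age. Incomplete sampling drops each extant tip independently with
probability 1 − f. A thinning-based simulator handles rates that vary
with absolute age (for temperature-driven scenarios).

Brownian traits are drawn from the exact multivariate normal with
λ-scaled off-diagonal covariance; binary characters flip by Poisson
parity along branches. Occurrence clouds are isotropic Gaussians in
degrees around per-species centers with longitude wrap at ±180;
artifacts are injected at deterministic counts `round(rate × n)` (at
least 1 when the rate is positive) so recall checks are sharp. The
`cramer_like` curve spans 113→0 Myr with long-term cooling from a hot
Late Cretaceous plus an early-Eocene peak and a mid-Miocene local
optimum — the qualitative shape, not the values, of deep-time
temperature reconstructions.

What the generators do *not* emulate: spatial range structure beyond a
point cloud, sampling heterogeneity across space, measurement error in
branch lengths, or any correlation between record density and niche.
Passing tests therefore demonstrate estimator correctness and
calibration under the stated models, not robustness to every real-data
pathology.

## Study conditions used by the acceptance battery

Problem sizes were chosen so the whole battery runs on a single CPU in
minutes: 50-tip trees for the factorisation oracle (30 reps), 300-tip
state-dependent trees for the twofold-contrast recovery (100 reps, true
λ₁/λ₀ = 2 with μ = 0.03, q = 0.01), a 100-tip tree with 200 neutral
Brownian traits for type-I calibration (null simulations n = 200), a
500-tip tree with 50 + 50 replicates for signal recovery, and 150-tip
constant-rate trees (50 reps) plus temperature-driven trees (30 reps)
for model-selection calibration. The temperature-driven generator uses
λ(T) = 5.9·e^{−0.25T} over a 50-Myr crown span: the span covers the
curve's mid-Miocene optimum, whose non-monotonicity is what makes
temperature-dependence identifiable against pure time-dependence at
all — over short, monotone stretches of the curve the two families are
nearly interchangeable and no method could separate them.

## Known limitations

- The BD and SSE likelihoods require binary, ultrametric trees;
  polytomies are accepted by the tree layer but rejected by the
  likelihood modules (no silent random resolution).
- The degree-space outlier filter is not dateline- or projection-aware.
- DR is a speciation-rate proxy; extinction is intentionally not
  interpreted from it.
- The λ-vs-time identifiability caveat above applies equally to real
  data: temperature-dependent model support is only meaningful when the
  clade's age span includes non-monotone temperature history.
- Single global sampling fraction per analysis; no per-lineage sampling
  models.
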