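# Methods

## The beta-diversity partition

Beta diversity is quantified as the total variance of the community matrix
after Hellinger transformation. Each site row is divided by its total and
square-rooted, so site profiles are unit vectors and Euclidean distances
between them are ecologically meaningful (joint absences carry no weight,
and `BD_total = SS_total/(n−1)` is bounded by 1). The partition is purely
algebraic: the squared deviation of every cell from its species column mean
is summed by column (SCBD) or by row (LCBD) and divided by the total. Both
sets of contributions sum to one by construction; the implementation checks
this to 1e-10 and is verified in the test suite against an independent
brute-force double loop.

Degenerate inputs are errors, not silent NaNs: a site with zero total
abundance cannot be Hellinger-transformed (the offending site is named),
and a matrix whose transformed rows are all identical has no beta diversity
to partition — downstream regression on undefined fractions must be
impossible, so `SS_total = 0` raises.

Internal orientation is sites = rows, species = columns, because Hellinger
profiles are site profiles; readers and the CLI accept the transposed
species × sites layout via an orientation flag.

## Effective SCBD: the occurrence correction

Raw SCBD is hump-shaped in occupancy: species present at one site or at
every site contribute little to turnover regardless of their biology. To
compare species with different occupancies, SCBD is regressed on occurrence
probability `p` (occupied sites / sites) with a quadratic beta regression —
the response lives in (0,1), so a beta likelihood in the mean–precision
parameterization with a logit link is the natural model:

    logit(μ_i) = b0 + b1·p_i + b2·p_i²,  SCBD_i ~ Beta(μ_i·φ, (1−μ_i)·φ)

The effective SCBD is the **raw-scale residual** `SCBD_i − μ̂_i`, not a
deviance or Pearson residual; this keeps the corrected metric in
contribution units and sums of corrected contributions interpretable.

Numerics: the likelihood is maximized over `(b0, b1, b2, log φ)` by L-BFGS
from a least-squares-on-logit start with a moment start for φ, then
polished with Newton steps on the analytic score until the gradient norm is
≲1e-8; fits report the gradient norm and a convergence flag, and
non-convergence raises with the last iterate. SCBD values of exactly 0
(possible when a species' transformed profile is constant) are squeezed by
`y* = (y(N−1)+0.5)/N` before fitting, with a logged warning. The occurrence
predictor is left uncentered on its natural [0,1] scale so coefficients
map directly onto occupancy plots. φ is a single constant (no dispersion
submodel). Species occupying all sites (`p = 1`) are valid; species never
observed are rejected upstream. The 95% confidence band for the fitted
curve is a delta-method band on the logit scale, back-transformed, so it
respects the (0,1) range.

The likelihood is concave in the coefficients at fixed φ for interior data
(checked numerically in tests), and parameter recovery at the study's
species count is verified by simulation (n = 2000 draws recover generating
coefficients within ±0.15).

## Phylogenetic predictors

Patristic distances (sum of branch lengths along the unique tip-to-tip
path) come from the parsed Newick tree; tips absent from the community —
including any outgroup used to root the tree — are pruned, while community
species missing from the tree are a hard error, since such gaps should be
resolved (e.g. with congeneric proxy placements) before analysis, not
silently dropped.

Plot-level MPD is the unweighted mean patristic distance over pairs of
co-occurring species (presence-based, the conventional default); an
abundance-weighted variant (weights `a_j·a_k`) is available by flag. Plots
with fewer than two species have no pairs and are flagged NaN, never zero.
The species-level MPD predictor is the mean of plot MPD over the plots the
species occupies — chosen for symmetry with how site environments are
lifted to species level — with an alternative lift (mean distance from the
focal species to its co-occurring neighbours) behind a flag, because the
plot-to-species lift is a genuine modeling choice with no single canonical
answer.

## Species-level predictor table

Environmental predictors are unweighted means over occupied plots (a
species in ten plots gets the mean aridity and soil of those ten plots —
its realized niche). The five soil variables, which have heterogeneous
units, are collapsed by PCA on the **correlation** matrix; the first-axis
score is the soil composite, sign-fixed so the first soil column loads
non-negatively (the sign of a principal axis is otherwise arbitrary).
Collinearity among candidate predictors is screened by iterating: compute
`VIF_j = 1/(1−R²_j)`, drop the worst predictor above the threshold
(default 10; ties broken by column order; infinite VIFs from exact
collinearity removed first), repeat. The screen is reported and logged in
the run manifest rather than silently mutating the model table.

C3/C4 relative abundance divides each species' plot abundance by the plot
total over species sharing its photosynthetic pathway; per plot these
values sum to one within each pathway, and the species-level predictor is
again the occupancy mean. SLA is leaf area (cm²) over dry mass (g).

Note an emergent property worth knowing: occupancy-mean aggregation makes
species-level aridity and soil means strongly correlated even when the
site-level variables are only moderately coupled, because wide-ranging
species all shrink toward the landscape average. The VIF screen flags this
on the default synthetic scenario; the inferential stages still accept the
full predictor set, and the screen's verdict travels with the manifest.

## GLMs and the recursive path model

The interaction GLMs are ordinary least squares (a Gaussian GLM with
identity link) of effective SCBD on a focal environmental axis, trait main
effects, and focal × trait two-way interactions — one family per focal
axis (aridity, soil), matching how moderation by traits is usually
displayed; prediction grids hold the moderator at its 25th percentile,
mean, and 75th percentile. Rank-deficient designs raise with the aliased
terms named.

The path model is a recursive (acyclic) system over observed variables:
default structure aridity → soil; {aridity, soil} → each of the five
species attributes; all seven → effective SCBD. For recursive models with
independent errors, equation-wise least squares is the maximum-likelihood
solution, so each endogenous equation is solved directly from the sample
covariance `S` (ddof = 1); exogenous covariances are saturated at their
sample values. The implied covariance is assembled by path tracing,
`Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ`, and compared to `S` through the ML discrepancy
`F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − m`, giving `χ² = (n−1)F` (roundoff below
1e-10 is snapped to an exact zero so saturated models report χ² = 0),
SRMR over the standardized residual covariance (lower triangle including
the diagonal), GFI from the weighted residual traces, and CFI against the
independence model. Variables are z-standardized by default (off by flag)
so path coefficients are comparable across differently scaled traits.

Direct effects are edge coefficients; total effects are the geometric
series `(I−B)⁻¹ − I`, which sums coefficient products over all directed
paths, and indirect effects subtract the direct edge — verified in tests
against exhaustive path enumeration. Because summaries of indirect
influence are sometimes reported as the mediator-equation coefficients
rather than path products, both are emitted, labeled distinctly.

Backward elimination repeatedly proposes removing the least significant
path (largest Wald p); a removal is accepted iff AICc
(`−2logL + 2k + 2k(k+1)/(n−k−1)`, k counting path coefficients, error
variances and exogenous (co)variances) decreases, and the search stops
when no removal decreases AICc. A path that is its target's only parent is
never removed, since that would orphan the equation. A statistical
property of this rule worth stating: removing a single truly superfluous
path is accepted only when its likelihood-ratio statistic falls below
≈2 + O(k/n), which for a χ²₁ statistic happens with probability ≈0.84 —
AICc-guided pruning of one redundant path is expected to succeed in about
five of six replicates, not always. Fit indices are assessed jointly
(SRMR < 0.08, GFI/CFI > 0.95, χ² p > 0.05 as conventional adequacy
guides), none gating alone.

Shapiro–Wilk statistics and Q-Q quantile data are produced as an advisory
normality report; they never gate the pipeline.

## The synthetic landscape generator

The generator produces seeded landscapes with known ground truth so every
stage is testable without field data. It emulates a sparse dryland plant
community: by default 84 plots and 67 species (the scale the pipeline
targets), an aridity-index gradient over [0.03, 0.3] (arid to semi-arid),
and five soil variables sharing one latent fertility axis correlated with
aridity at 0.5. The soil noise standard deviation (0.6 per variable)
implies an equicorrelation of ≈0.74 and hence ≈79% of soil variance on the
first PCA axis — a realistically dominant first soil axis.

Abundances follow a Gaussian niche model: species j's expected count at
site i is `exp(a_j)·exp(−(z_i − o_j)²/(2σ²))` on the standardized aridity
axis, with niche breadth σ = 1 (broad niches; lower it for stronger
turnover), optima `o_j` evolved by Brownian motion on a unit-depth
pure-birth tree and blended with independent noise by the `mpd_signal`
weight (1 = fully heritable optima, 0 = no phylogenetic signal), and peak
log-abundance `a_j` shifted by standardized log-traits (height +0.3,
SLA −0.3, leaf production +0.2) and a C3 indicator (+0.25). Counts are
negative-binomial (size 1.5, i.e. moderately overdispersed) thinned to
zero with probability 0.1. Species or sites left entirely empty are
redrawn (up to 100 attempts) so scenario dimensions stay fixed for tests.
Trait magnitudes (height ~ lognormal(30 cm), SLA ~ lognormal(80 cm²/g),
leaf count ~ lognormal(40), 70% C3) are plausibility choices for a dryland
flora, not calibrated to any particular survey.

What the generator does **not** emulate: spatially explicit dispersal,
temporal dynamics, raster-derived environments, observation error in
traits, and correlated trait evolution on the tree. Passing tests
therefore demonstrate that the statistical machinery recovers known
structure under a well-specified niche model — not that the model captures
every feature of real survey data.

## Problem sizes and numerical choices

The test suite and the reproduction script run the full chain at the
default 84 × 67 scale (a complete run takes a few seconds) and use
simulation sizes of 150–5000 observations for recovery checks, 10–50
replicates for Monte-Carlo properties. Tolerances: algebraic identities at
1e-10..1e-12; ML-vs-OLS agreement for path models at 1e-4 (limited by the
generic optimizer oracle, not the closed form); simulation recoveries at
the sampling-error scale stated per test. All randomness is
`numpy.random.default_rng` seeded explicitly; the pipeline derives named
per-stage substreams from one root seed by hashing, so stages are
reproducible independently.
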