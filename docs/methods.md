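# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flow through the pipeline.

## Trait aggregation

Each observation is one population-level record of a trait (a mean `x_s`,
an optional dispersion, an optional sample size `n_s`). Species values are
sample-size-weighted means, Σx_s·n_s / Σn_s, with a missing `n_s` taken as
1 — literature records frequently omit sample sizes, and counting such a
record once is the least-assumption default. The reported per-species
sample size is Σn_s.

Worker size variation (WSV) is the coefficient of variation of worker head
width ×100: the numerator is the unweighted sample (n−1) standard
deviation of the observation means, the denominator the weighted species
mean. It is undefined (and the species excluded from that trait) with
fewer than two observations. Queen–worker dimorphism (QWD) is
100·(Q − W)/Q; the queen denominator bounds the measure above by 100 when
queens are the larger caste, matching the observed range of the system
(maximum ≈ 84%), whereas a worker denominator would exceed 100 for
leafcutters. The convention is switchable (`denominator="worker"`).

Analysis transformations: square root for WSV, natural log for QWD and
colony size. A species whose aggregated QWD is non-positive (possible
under measurement noise when the castes are near-monomorphic) cannot be
log-transformed; the pipeline treats that cell as missing, consistent with
dropping incomplete species at model time rather than at aggregation time.

Two data-quality checks are included: an OLS regression of the transformed
trait on ln Σn_s across species (a significant slope would indicate the
measure reflects study effort), and a paired t-test comparing per-species
means from two measurement sources (df = n−1; all-zero differences give
t = 0, p = 1 by convention).

## MRP supertree

Source trees are used as published and must be rooted. Baum/Ragan coding
produces one binary character per non-root internal node: clade members 1,
other taxa in that source 0, absent taxa `?`. Characters are equally
weighted by default (no recoverable weighting scheme exists for the
original analysis); per-source-tree weights can be supplied.

Safe taxonomic reduction removes a taxon whose scored entries are all
identical to another retained taxon's: it cannot influence the optimal
relationships and would only erode consensus resolution. The removal log
records an attachment taxon so removed taxa can be re-grafted as its
sister after the search.

Parsimony length is computed by a two-state Sankoff dynamic programme
(`?` = either state, cost-free), which equals Fitch counting on binary
trees and remains exact on polytomies. The search additionally places an
implicit all-zero outgroup at the root (per-character cost
min(c0, c1 + 1)): without it, parsimony is rooting-invariant and all
rerootings of a topology tie, so the strict consensus of the optimal set
would collapse; the all-zero outgroup is the standard MRP device for
preserving the rootedness of the source trees. The public
`fitch_length` reports the plain, rooting-invariant length.

The ratchet (defaults: 200 iterations, reweight fraction 0.25, weight
multiplier 2) alternates hill-climbing under perturbed and original
weights using first-improvement SPR moves in randomized order, keeping
every distinct topology no longer than the best found (cap 10 000). After
the iterations the best set is closed under equal-length SPR neighbours so
ties are represented in the consensus. The search is deterministic given
its seed. For n ≤ 8 taxa an exhaustive enumerator over all rooted binary
topologies provides the exact optimum and serves as the oracle in tests.

rQS support compares each supertree clade with each source tree after
restricting both to their shared taxa: +1 if the restricted clade occurs
in the source, −1 if the source contains an incompatible clade
(overlapping but not nested), 0 if uninformative (fewer than two shared
members, the whole shared set, or an unresolved source). The default
score divides (support − conflict) by the number of source trees; a
variant divides by informative votes only. Both are exposed because the
cited method's normalization is ambiguous; note that with partially
overlapping sources only the informative-only variant can reach +1
everywhere. The character bootstrap resamples columns with replacement,
re-runs the ratchet at reduced settings, and averages rQS per clade and
per replicate.

## Dating

Calibrations are fixed point ages (Myr) attached to MRCAs of taxon sets or
to labelled nodes; tips are age 0. A calibrated descendant at least as old
as a calibrated ancestor is rejected with both nodes named. Undated nodes
are interpolated in preorder: a node with dated parent age t_a takes an
age inside (t_d, t_a), where t_d is the largest age among its dated
descendants and m counts the undated nodes on the path to that descendant.
Mode `even` gives t_a − (t_a − t_d)/(m+1), which reproduces uniform
spacing exactly on chains; mode `yule` divides the bracket in proportion
to pure-birth expected waiting times 1/k, with k = 2 for the first
sub-interval below the dated ancestor and +1 per undated split passed —
the deterministic analogue of a pure-birth expectation. `even` is the
default because it is parameter-free and reproducible; both modes preserve
calibrated ages exactly, keep ages strictly decreasing towards the tips
and yield ultrametric trees. Branch lengths are parent age minus child
age. No molecular-clock estimation is attempted: users with a chronogram
supply it directly.

## PGLS and multimodel inference

For response y and design X over n species, y ~ N(Xβ, σ²V(λ)) with
V(λ) the shared root-to-MRCA path-length matrix whose off-diagonals are
multiplied by λ ∈ [0, 1]. β and σ² are concentrated out (GLS estimate and
RSS/n), leaving a 1-D profile likelihood in λ maximized by bounded scalar
search (tolerance 1e-6) with the endpoints checked explicitly; boundary
optima report exactly 0 or 1. Phylogenetic signal of a single trait is the
ML λ of the intercept-only model.

Conventions:

- AICc = −2logL + 2k + 2k(k+1)/(n−k−1), with k counting the regression
  coefficients, σ², and λ when it is estimated (`count_lambda=False`
  switches to excluding λ). AICc is refused when n − k − 1 ≤ 0.
- Coefficient standard errors use the unbiased residual variance
  RSS/(n−p); the likelihood and AICc use the ML variance RSS/n.
- r² is 1 − RSS_V/TSS_V in the whitened space (TSS from a GLS
  intercept-only fit at the same λ); a likelihood pseudo-r²,
  1 − exp(2(logL₀ − logL)/n), is also reported.

Collinearity is screened by ordinary (non-phylogenetic) VIFs — VIF
measures design collinearity, not residual structure — eliminating the
largest until all are below 3; perfectly collinear columns report an
infinite VIF. The candidate set is all covariate subsets including the
intercept-only model, with an interaction admitted only alongside both
main effects. Akaike weights are normalized over the full candidate set;
models with ΔAICc > 7 are uninformative and excluded from averaging but
retained in the weight denominator. Averaging is "natural": a covariate's
slope is averaged over informative models containing it with renormalized
weights, and its unconditional standard error combines within-model
variance and between-model spread (Σw̃·sqrt(se² + (β − β̄)²)); CIs use a
normal 1.96 multiplier (t-based available). The cumulative weight W of a
covariate sums full-set weights of every model containing it.
Phylogenetic uncertainty is propagated by refitting the selected model
(covariates with W > 0.4) on each tree of a sample and reporting the mean
slope with the 2.5–97.5 percentile interval expressed as a half-width;
half-widths are reported at 3 decimals, so a printed ±0.000 means
sub-resolution spread.

## Climate covariates

Grids are regular lat/lon rasters in a plain-text format (header: ncols,
nrows, cellsize_arcmin, xll, yll, nodata; first row northernmost). All
layers are block-mean aggregated (missing cells ignored; all-missing
blocks stay missing) to a common 10-arcmin lattice — roughly the 20 km²
locality-precision threshold — before extraction; nearest-neighbour
aggregation is available. Cells are half-open [west, east) × [south,
north) and the seam of a global grid wraps east, so every point maps to
exactly one cell. Localities with a stated precision above 20 km² are
discarded; repeated localities are deliberately not deduplicated, so they
weight the species mean the same way repeated observations do. Per-species
covariates are means over locality cells, plus mean latitude.

## Synthetic studies

`make_study` draws a Yule chronogram (waiting time exponential with rate
k at k lineages, root rescaled to 37.7 Myr), evolves ln colony size as
Brownian motion affinely rescaled to span ln 16 – ln 6×10⁶ workers, and
builds √WSV = 1.0 + 0.4·ln(colony size) + ε with ε multivariate normal,
λ = 0.9 and unit tip variance (rate σ²/root age); ln QWD follows the same
pattern with slope 0.16. Climate enters with zero effect by default, so
the environmental covariates are true nulls. Defaults mirror the target
system's scale: 40 species, 12 source trees at 75% taxon overlap,
2–6 localities per species inside a neotropical extent, four climate
fields (two linear gradients, two sinusoid mixes) generated at 5 arcmin so
the pipeline's resampling step is exercised.

Observation tables are lognormal around the species truths (keeping means
positive) with 5% relative noise, 3–6 observations per trait, integer
sample sizes 1–30 blanked with probability 0.2. Worker head-width
observations are dispersed with relative sd equal to the species' true
CV/100, so the aggregation stage must actually estimate WSV from scatter
rather than read it off; with ~4–8 observations this adds realistic
estimation noise to the response. A small fraction of localities carries a
coarse stated precision (> 20 km²) to exercise the filter.

What the generator does not emulate: taxonomic synonymy and name
mismatches, biased or clustered literature coverage, spatially
autocorrelated climate error, allometry between head width and body size,
and non-Yule diversification. Passing end-to-end tests therefore
demonstrates the statistical machinery recovers known structure under
idealized sampling, not that real attine data are free of those
complications.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-for-bit
reproducible. The bundled verification runs use desk-scale sizes chosen to
exercise each stage thoroughly: 200 datasets of 50 tips for parameter
recovery, 100 generated studies of 40 species for end-to-end detection,
12-taxon round trips with 6 source trees for the supertree stage, and
exhaustive-enumeration oracles at ≤ 6 taxa. The end-to-end runs use the
study's true chronogram for the regression stage; the supertree and dating
stages are validated by their own round trips, and running a full ratchet
per study would add nothing statistically at these sizes.

## Known limitations

- Only Pagel's λ residual structure is offered (no OU or early-burst).
- Calibrations are point ages without uncertainty; no rate models.
- The ratchet is a heuristic: optimality is guaranteed only where the
  enumeration oracle applies (≤ 8 taxa), elsewhere supported by restarts
  and plateau closure.
- MRP with equal weights cannot represent differing source-tree quality
  unless per-source weights are supplied.
- Safe taxonomic reduction uses the simple subsumption rule; more
  aggressive variants exist.
- Grids must share a lattice after resampling; no projection support
  beyond geographic coordinates.
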