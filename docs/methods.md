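# Methods

This note documents the models, conventions and numerical choices behind
`islandrad`, and what the synthetic fixtures do and do not establish.

## Trees and the speciation-event survey

Trees are rooted, may contain polytomies, and carry optional per-branch
support values whose dialect (0–100 "percent" or 0–1 "unit") is recorded at
read time. Newick parsing is delegated to dendropy; writing is direct.
Tip labels are matched exactly after trimming surrounding whitespace and
unifying spaces to underscores, because Newick writers disagree on the
separator. Branches without a support value are never collapsed by
`collapse_low_support`: absence of evidence is not low support.

A *sister pair* is a strictly bifurcating two-tip clade (cherry) of focal
species; a polytomy of three or more focal tips yields no pair because it
contains no unambiguous cherry. Each pair records whether its closest
relative is a single tip or a clade. `survey_nodes` partitions the internal
nodes of each (monophyletic) focal clade into *assessable* events — the
MRCAs of sister pairs, plus the MRCAs of pair-and-closest-relative when
that relative is a single tip — and deeper *substrate-only* events (every
remaining internal node). A cherry nested inside another pair's
closest-relative clade is still its own pair; deduplication happens only at
the survey level.

### The encoded New Caledonian species tree

`islandrad.newcaledonia` transcribes the published species-tree topology of
the New Caledonian arecoid palm radiation (37 sampled species in four
multi-species focal clades plus one single-tip lineage, embedded among
western Pacific relatives). Genus-level structure and most species-level
sister pairs are fixed verbatim by the published description; the handful
of placements left unresolved there (five *Basselinia* species; the
attachment of the *Chambeyronia lepidota* pair) are filled with one
resolution consistent with the published event totals, and one *Basselinia*
tip carries a placeholder label. The survey on this encoding yields 19
assessable and 13 substrate-only events; per-clade counts are
Chambeyronia 5/2, Burretiokentia+Cyphophoenix 4/4, Basselinia 7/6,
Clinospermatinae 3/1. Branch lengths play no role in the enumeration.

## Alignment filters and gene ranking

Gap characters are `-` and `?`; `N` is an observed-but-ambiguous base and
never counts as a gap. `strip_gappy_columns` removes columns whose gap
fraction reaches the threshold (default 0.7), so retained columns are
strictly below it; the operation is idempotent. `filter_by_occupancy`
keeps an alignment when at least `ceil(fraction x total_samples)` rows hold
any data; the integer threshold is reported explicitly so externally quoted
row counts can be audited against it (for 113 samples at 40 % the computed
threshold is 46). Gene ranking for dating is a stable lexicographic sort:
bipartition concordance with the species tree (descending), then tree
length (descending), then root-to-tip variance (ascending, population
convention — divide by n); a must-include list is appended for loci that
uniquely cover otherwise-missing taxa. A star gene tree has concordance 0
by convention (no resolved split carries agreement).

## Occurrence cleaning, rasters, ranges

The cleaner applies, in order: coordinate validation, zero-coordinate
removal, uncertainty > 100 km, collection year before 1945, caller-supplied
geographic masks, and exact per-species coordinate duplicates (first record
kept). Records lacking a year or an uncertainty pass those filters by
default (they cannot fail a test they lack data for); `strict=True` flips
this. Every input record appears in the report with one named verdict;
coordinates are never modified. Reference geometry for marine/centroid/
institution/native-range filters is not bundled: masks are supplied by the
caller as `f(lon, lat) -> bool`.

Rasters are regular lon/lat grids read and written as ESRI ASCII text.
Cells are half-open, `[x, x+d) x (y-d, y]`: a point on a vertical edge
belongs to the cell whose left edge it is, a point on a horizontal edge to
the cell whose top edge it is (the grid's top boundary is included in row
0). Extraction is point-in-cell with no interpolation. Distribution ranges
are sets of occupied cells at a configurable cell size (default 0.01°,
about 1 km, matching common environmental-raster resolution); ranges are
cells, not hulls, which makes the 50 % overlap rule well defined. Two
ranges are sympatric when either is covered ≥ 50 % by the other,
allopatric when they share no cell, parapatric otherwise.

## Continuous preferences

Occurrence-level value vectors are compared with the classical
pooled-variance unpaired Student's t-test (df = n1+n2−2, two-sided); a
Welch option exists. With zero pooled variance, equal means give t = 0 and
p = 1, unequal means are an error. No multiple-testing correction is
applied across pairs by default; raw p-values and α = 0.05 verdicts are
reported.

Ancestral values are estimated under Brownian motion by maximum likelihood
with a linear-time two-pass (up/down) Gaussian message-passing scheme whose
estimates coincide with the generalized-least-squares solution implied by
the shared-path-length tip covariance; the test suite checks this against
an explicit GLS solve. The ML rate is the mean of squared standardized
contrasts divided by n (ML, not REML); per-node estimation variances are
σ̂² times the conditional message variance. Reconstruction takes one value
per tip (species means of occurrence values, by convention); the t-tests
use the full occurrence vectors. Zero-length sister branches with distinct
fixed values are rejected as non-identifiable.

## Discrete (substrate) preferences

Substrate is a k = 3 state character (ultramafic, schistose, limestone)
under an equal-rates Mk model parameterized by the total leaving rate μ
(Q_ij = μ/(k−1) off-diagonal), with the closed-form transition probability
P_ii(t) = 1/k + (1−1/k)·exp(−μtk/(k−1)). Polymorphic tips use ambiguity
coding (partial 1 on each observed state); missing tips are the full set.
The root prior is uniform (configurable).

The Bayesian search is Metropolis–Hastings on μ with a log-scale random
walk whose step adapts during burn-in towards 20–50 % acceptance, an
exponential prior with mean 10 on μ, two independent runs of 25 000
generations by default and a 25 % burn-in. Marginal ancestral-state
probabilities come from the pruning up-down pass at thinned retained
samples (default every 25th) and are averaged within and then across runs
after a convergence check (posterior means within half a pooled SD); low
effective sample size warns rather than fails. ESS uses the
initial-positive-sequence autocorrelation estimator.

Transition calling: at an assessable node, the two daughter sides' extant
substrate sets are compared directly — any set difference counts, including
one species on two substrates against a sister on one. At deeper nodes the
node's maximum-a-posteriori state is compared with each daughter's
representative (daughter MAP, or a tip's observed set); MAP ties or
probabilities below 0.5 are reported "uncertain" and not counted. The
deep-node rule is a documented formalization; published analyses of this
kind typically read transitions off posterior pie charts without stating an
explicit rule.

## Ancestral ranges

Ranges are subsets of an ordered area system (≤ 26 areas) capped at
`max_areas` = 3 by default; the state space lists the null range first,
then subsets by cardinality (232 states for 11 areas). Anagenesis: range
expansion into area b at rate d·Σ_{a∈R} m_ab and per-area extirpation at
rate e; singletons decay to the absorbing null range. Distance-scaled
dispersal uses m_ab = (dist_ab/d̄)^x with d̄ the mean off-diagonal
distance; the normalization decouples x from d, and x = 0 recovers the
distance-free model. Cladogenesis follows the family event tables (DEC,
DIVALIKE, BAYAREALIKE, each optionally with founder-event jumps); each
eligible ordered outcome carries its class weight (y = v = (3−j)/3 for
DEC, (2−j)/2 for DIVALIKE, y = 1−j for BAYAREALIKE, jumps weight j) and
weights are normalized per parent range. When no outside area is eligible
for a jump the jump outcomes are simply absent and the remaining weights
renormalize.

The likelihood is Felsenstein pruning with per-branch propagators exp(Qt)
(eigendecomposition with an expm fallback when ill-conditioned), daughter
messages combined through the event table at nodes, and a uniform root
prior over non-null states. Node marginals are reported for the state
immediately before cladogenesis, with the null range excluded and rows
renormalized. Fitting maximizes the likelihood by Nelder–Mead over
transformed parameters (log d, log e; j and x squashed into their boxes
[0, j_max) and [−5, 0]) from several jittered starts (default 5), because
+J surfaces are multimodal. Model comparison uses AICc with n = number of
tips and the conventional support bands (Δ ≤ 2 substantial; 4–7
considerably less; > 10 essentially none, threshold configurable). No
time-stratification is implemented.

An optional survival-conditioned likelihood divides by the probability
that every tip retains a non-null range (computed by a second pruning pass
with all tips ambiguous over non-null states). It exists because data
simulated — or, in nature, sampled — conditional on all lineages surviving
with a range otherwise bias the extirpation rate downward; the default
remains unconditioned for comparability with standard range-inference
software.

## Survey assembly

Each assessable event pools its two sides (occurrence vectors
concatenated, cells and substrate sets unioned for the pair side of
pair-vs-relative comparisons) and sets four flags: range (parapatric or
allopatric — allopatric is taken a fortiori as a range difference),
precipitation and elevation (t-test significant at α), substrate (set
inequality). Missing data degrade only the affected flag to
"not-assessable". The tally applies the minimum-transition rule — a
transition flagged at both a pair node and its enclosing pair-plus-relative
node is counted once, at the deeper node — then cross-classifies events
with/without range transitions by their ecological-transition combination,
with deep-node substrate calls tallied separately.

## Synthetic data

All generators are pure functions of (parameters, seed); one master seed
derives per-layer seeds so regenerating one layer never perturbs another.
Trees come from a forward Gillespie birth–death simulation started at a
crown split, conditioned on the requested number of survivors by rejection,
with the present placed at the moment the next event would have occurred
(strictly positive terminal branches, ultrametric). Continuous traits are
recursive Gaussian increments; discrete characters and ranges are Gillespie
simulations along branches (with cladogenetic draws from the event table),
with full histories and event logs retained. Occurrence clouds are Gaussian
blobs with planted defect records appended at stated counts and recorded in
a ledger; rasters are planar gradients with optional seeded noise so
extracted values are analytically known.

The planted survey scenario is fully deterministic: ten species occupy
rectangular cell blocks on two orthogonal gradients (precipitation varies
only west–east, elevation only north–south), so every overlap class,
t-test verdict and substrate comparison is known by construction, including
one event whose ecological transition is absorbed by the minimum-transition
rule. What these fixtures do *not* emulate: spatial sampling bias,
autocorrelated occurrence noise, raster misregistration, non-Brownian trait
evolution, and rate heterogeneity across branches — passing tests therefore
demonstrate correctness of the implemented rules, not robustness of the
method to violations of its assumptions.

## Problem sizes and test design

The test suite runs the recovery experiments at the following sizes, chosen
to mirror a Miocene-scale island radiation while staying desk-scale:
Brownian rate recovery on 50 replicates of 100-tip trees; Mk rate coverage
on 40 replicates of 100-tip trees with truths drawn from the Exp(10) prior
(so the central 90 % posterior interval is calibrated by construction) and
2 500-generation chains; DEC dispersal/extirpation recovery on 20
replicates of 50-tip trees of several tens of Myr depth (birth rate
0.08/Myr) over five areas, fitted with four Nelder–Mead starts under the
survival-conditioned likelihood. Simulator-versus-likelihood χ² checks use
fixed 2- and 3-tip trees with a few thousand replicates at α = 0.01.

Known limitation: even with survival conditioning, the extirpation rate of
DEC-style models is only weakly identified from extant ranges — its MLE on
a single 50-tip dataset at e = 0.02/Myr has a relative spread wider than a
factor of two (boundary estimates at 0 occur), because extirpation is
confounded with dispersal and survivorship. The dispersal rate d recovers
within a factor of two in nearly all replicates; e does not, and the
corresponding recovery check documents this honestly rather than relaxing
its bound.
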