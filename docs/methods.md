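# Methods

`sealusage` estimates at-sea space use of a central-place foraging seal
population from two partial data sources — telemetry tracks from a sample of
tagged animals, and terrestrial counts of animals hauled out on shore — and
combines them into population-scaled usage maps with cell-wise 95%
confidence intervals. This note records the models, the choices made where
the design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Analysis grid and at-sea distance

All surfaces live on a regular grid of 600 m square cells with a land/sea
mask; 600 m matches the median two-hourly step length of harbour seals
(`detect_resolution` reports the median consecutive-step distance as a
diagnostic). Sea cells form a lattice graph with 16-connectivity (queen +
knight moves; edge weights 600, 600·√2, 600·√5 m); a diagonal or knight move
is admissible only when the cells it passes over are sea, so paths never cut
across land. Distances are multi-source Dijkstra shortest paths; onshore
sources (haul-outs) are seeded through their 8-adjacent sea cells at zero
cost, i.e. distances start at the waterline. On open water the
16-neighbour lattice overestimates Euclidean distance by at most ~2.8%
(8-connectivity, available via `connectivity=8`, is ~8.2%).

## Telemetry preparation

Records with missing fields are dropped, duplicate (animal, timestamp) rows
keep the first occurrence, and animals with fewer than `min_fixes` (default
10) usable fixes are excluded with a logged reason. Tracks are linearly
interpolated onto an exact two-hourly clock anchored at each segment's first
fix; gaps longer than 24 h split the track and are never interpolated
across (transmission outages would otherwise fabricate straight-line
traverses). An interpolated fix is flagged hauled-out only when both
bracketing observed fixes are hauled out at the same position.

Trips are maximal runs of at-sea fixes bounded by haul-out events. Each
at-sea fix is associated with one haul-out: fixes at or before the trip's
temporal midpoint with the departure haul-out, later fixes with the
destination (ties to departure); trips truncated by a track end associate
wholly with their single bounding haul-out. The midpoint rule is a
symmetric, deterministic resolution of "departure or destination". Animals
with no haul-out record at all cannot be anchored to a cluster and are
excluded.

## Haul-out clustering

Haul-out cells are the union of cells containing hauled-out telemetry fixes
and surveyed cells with a positive count. A surveyed zero is data; an
unsurveyed cell is missing — the two are never conflated. The most recent
count per cell wins (ties broken by the larger count, logged).

Cells aggregate by centroid (UPGMC) agglomeration on the matrix of shortest
*at-sea* distances between them, so cells on opposite shores of an isthmus
do not merge. Two implementation choices:

* The waterline-to-waterline measurement omits the legs inside the onshore
  cells themselves and can return 0 for adjacent cells, so pairwise
  distances are floored at the straight-line centre distance (a sea path
  can never be shorter than the straight line).
* Merging is strict (distance < cut scale) and a single merge tree is cut
  at every scale, with heights monotonised by a running maximum. This
  guarantees the cluster count is non-increasing in scale (centroid linkage
  can otherwise invert) and makes the minimum 0.6 km scale perform no
  clustering, as the scan intends. An alternative clustering on raw cell
  coordinates is available via `method="coords"`.

The working scale is picked by an at-most-one-change (AMOC) change-point
search on the cluster-count-versus-scale series (scales 0.6–15 km in 0.6 km
steps): an exhaustive single-break least-squares fit over the 25 scales,
returning the first scale after the break. A flat series returns the
minimum scale with a warning.

Clusters visited by at least one tagged animal are *telemetry* clusters;
clusters known only from counts are *null* clusters. Telemetry clusters
with a zero count receive a provisional count of one and all counts are
rescaled multiplicatively so the grand total equals the original surveyed
total (otherwise their telemetry would be discarded in population scaling).

## Per-animal usage surfaces and weighting

Each animal's at-sea fixes associated with a cluster are smoothed with a
bivariate normal kernel evaluated at sea-cell centres × cell area, masked
to sea and renormalised to one. Evaluating at centres rather than
integrating over cells incurs a second-order error, negligible for 600 m
cells against kilometre-scale bandwidths.

One 2×2 bandwidth matrix is selected per animal from *all* of its at-sea
locations. The default selector is a plug-in: the data are sphered with
the sample covariance, the fourth-order integrated density derivative
functionals ψᵣ are estimated pairwise with a normal-scale pilot
g = n^(−1/8), and the asymptotic MISE

  AMISE(H) = (4πn)⁻¹|H|^(−1/2) + ¼ Σ H-quadratic form in ψ₄

is minimised over SPD matrices (Cholesky parameterisation, Nelder–Mead,
started at the normal-scale matrix n^(−1/3)Σ̂). Degenerate point clouds
fall back to a ridged normal-scale matrix with a warning. For n > 2000 the
O(n²) functional estimates use a random subsample.

Animals contribute to a cluster in proportion to their *fitted* discovery
rate (index of information content): the count of distinct sea cells
visited over the tag lifespan, regressed with a log-link overdispersed
Poisson model on a fixed-df (4) cubic spline of lifespan plus a tag-type
factor. A fixed-df spline keeps the fit deterministic and testable; with a
single tag type the factor is dropped, with no lifespan spread the smooth
is dropped (both logged). Fitted rates are normalised to sum to one within
each cluster's contributors, and the weighted mixture is renormalised, so
every cluster surface sums to exactly one.

## Habitat model (null-cluster pathway)

Clusters without telemetry get model-predicted usage. Presences are the
at-sea fixes; each presence contributes five pseudo-absences drawn
uniformly from the sea cells *reachable from its haul-out cluster* — this
matches the availability structure of central-place trips better than
study-area-wide sampling (which remains possible by passing a common cell
set). The model is a binomial logit GEE with independence working
correlation: point estimates are the ordinary logistic MLE; the covariance
is the panel-clustered sandwich with no small-sample correction, so
singleton panels reduce it exactly to HC0. Panels are animals for
presences; each pseudo-absence is its own panel.

The linear predictor always holds deployment year (factor) and at-sea
distance (linear). Other covariates (depth, sediment fractions, tidal
power ½ρU³ with ρ = 1027 kg m⁻³, peak spring/neap flows) enter as linear
terms or cubic B-spline smooths with 4 degrees of freedom — boundary knots
at the training extremes and one interior knot at the covariate mean, on
covariates standardised to mean 0, sd 1 (parameters stored and reused at
prediction). Variance inflation factors above 5 flag mutually exclusive
pairs (spring and neap peak flows are near-collinear by construction);
interactions are not offered.

Model selection is forward, scored by the fold pass score (FPS) of a
5-fold cross-validation blocked on haul-out cluster (clusters are packed
greedily into folds balanced on presence counts; no cluster is split).
Per fold, usage exp(η̂) is predicted for held-out cells; cells are sorted
by prediction into 40 equal-count bins (any remainder spread over the
leading bins — our deterministic reading of "equal areas with a moving
window"); per bin the mean prediction is compared with the summed observed
presences by a one-sided Spearman test at α = 0.05, one-sided because a
habitat model is validated by *positive* concordance. FPS = passed
folds / 5, so FPS ∈ {0, 0.2, …, 1}; by construction it is invariant under
strictly monotone transforms of the predictions. Candidates (linear and
spline variants both offered) join the model while FPS strictly increases;
ties go to the candidate declared earlier, and to the linear variant within
a candidate.

Null-cluster prediction fixes year at the training median, takes distance
from the cluster's own at-sea distance surface, exponentiates the linear
predictor over reachable cells and normalises to one. Response curves with
95% bands come from a parametric bootstrap β* ~ N(β̂, V̂).

## Uncertainty and population scaling

Within-cluster variance — the sensitivity of a normalised surface to which
animals were tagged — is the per-cell empirical variance across animals'
surfaces in data-rich clusters (≥ 7 tagged animals by default; configurable,
and the pipeline falls back to all multi-animal clusters with a warning
when a small campaign leaves fewer than three). It is regressed on the log
scale (guaranteeing positive predictions):

  log(s²+ε) = a + b·log(mean usage+ε) + c·(number of animals),  ε = 10⁻¹²

Data-poor telemetry clusters are predicted at their own sample size; null
clusters at sample size 0. When all contributing clusters share one sample
size, c is not identifiable and is fixed at 0.

Cluster populations are counts divided by haul-out probability (the
fraction of the population ashore during a survey). Probability draws come
from a beta distribution moment-matched to a configurable (mean, sd) —
default (0.72, 0.05), a placeholder for an external estimate, not a claim —
truncated to (0.01, 0.99), with a logit-normal fallback when the moments
are infeasible. Bootstrap mean and variance of count/p* give the cluster
population estimate; by Jensen's inequality the mean exceeds count/p̄.

Each cluster surface is scaled by N̄·f, where f is the mean fraction of
two-hourly fixes at sea (equal weight per animal). Treating population N
and usage u as independent,

  Var(f·N·u) = f²(N̄²σ²ᵤ + ū²σ²ₙ + σ²ᵤσ²ₙ),

and cells get normal-approximation 95% intervals truncated below at zero
(Monte-Carlo percentile intervals would be a straightforward alternative;
the normal form is the default for determinism). Cluster maps are summed
assuming independence across clusters; provenance records the fraction of
total usage from telemetry clusters versus the habitat model. The grand
total therefore equals Σ_clusters N̄·f exactly.

## Synthetic worlds

The generator supplies every input with known ground truth:

* **Seascape** — a smoothed Gaussian field thresholded at the requested
  land fraction; only the largest 8-connected sea component is kept.
* **Covariates** — smooth Gaussian random fields: softplus depth, lognormal
  current speed U with tidal power ½·1027·U³, spring/neap flows as scaled
  copies of U, and sand/gravel/mud by an additive logistic-normal transform
  of two correlated fields (positive, summing to one by construction).
* **Haul-outs and counts** — sites placed in spatial groups on the coast
  (group centres separated by ≥ 5 km, members within ~900 m), counts
  multinomially allocated, and a survey covering a configurable fraction of
  coastal cells with survey years 2008–2015; unsurveyed cells carry an
  explicit missing marker.
* **Telemetry** — animals alternate geometric haul-out bouts (mean 6 steps)
  and at-sea trips (mean 12 steps = 24 h at the two-hourly interval) —
  realistic alternation standing in for unmodelled trip behaviour. Tag
  lifespans are exponential with a 168 h floor, giving the short/long
  lifespan contrast the discovery-rate weighting corrects; tagging effort is
  spread round-robin over a random subset of sites (default 70%), so some
  counted sites have no telemetry and become null clusters.

The at-sea walk is a Metropolis-type biased random walk: proposals uniform
over the symmetric 16-neighbourhood, accepted with min(1, exp(β·Δx)) where
x holds the at-sea distance from home (per km), and sand and tidal power as
z-scores over sea cells (defaults β = (−0.35, 0.6, 0.4): distance e-folding
~3 km keeps most usage within 10–20 km of the haul-out; positive sand and
power preferences mimic sandy-sediment and tidally energetic foraging
habitat). Because the proposal is symmetric the walk is reversible with
stationary occupancy exactly ∝ exp(β·x) — the exponential-of-linear-
predictor form the habitat model estimates. A softmax step choice
(probability ∝ exp(β·x) over neighbours) was rejected: it is reversible
with respect to exp(β·x)·Σ_neighbours exp(β·x), roughly the *square* of the
intended preference on smooth fields. Verified directly: a 4·10⁵-step
unbroken chain recovers β to ±0.01 by Poisson occupancy regression.

**What the synthetic tests do not show.** Real tracks carry positional
error, tidally and diurnally structured behaviour, behavioural states and
inter-annual redistribution, none of which are emulated. And finite trips
restarted at the haul-out are a *transient* of the walk: under short trips
(the 12-step default) observed occupancy has not mixed to the stationary
distribution and fitted habitat coefficients are attenuated relative to the
generating β — a caution that applies equally to fitting exp-linear
habitat models to short-excursion central-place foragers. The parameter
recovery experiment therefore simulates conditions under which the
estimand is actually realised: strong distance decay (−0.8 per km, a small
and quickly-mixed home range), trips of mean 300 steps, chains thinned 4×.
Under those conditions sandwich standard errors are well calibrated
(sd of estimation errors ≈ mean reported SE) and 95% intervals cover the
generating sand/tidal-power coefficients at the nominal rate. The fitted
*distance* coefficient is never a recovery target: it absorbs trip
geometry (finite trips must return home) on top of distance preference.

## Problem sizes and determinism

The default pipeline world is 60×60 cells (36×36 km) with 12 haul-out
sites in 8 groups, 300 animals counted, 30 tagged; a full run takes ~20 s
on one core and is bit-identical under a fixed seed (every stochastic
stage derives its generator from the master seed). The test suite uses
40×40 worlds; the parameter-recovery study runs 50 replicates. The
synthetic demo lowers the data-rich threshold from 7 to 3 tagged animals
because its campaigns tag far fewer animals than the 54 of a full field
study; the threshold is configuration, not science.

Numerical conventions: ε = 10⁻¹² stabilises log-scale variance
regressions; spline evaluation outside the training boundary knots clamps
to the boundary with a warning; KDE bandwidth optimisation failures fall
back to the normal-scale matrix; cluster merge ties and fold-packing ties
are broken deterministically (cell index order, shuffled-then-greedy with
a seeded generator). Rasters are persisted as ESRI ASCII grids — a
plain-text format every GIS reads — and vector outputs as GeoJSON.
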