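# Methods

## Data model

The canonical containers are pandas DataFrames.  A delivery record carries
demographics (age, race, ethnicity, education, payor), prenatal-care
adequacy (APNCU category), medical risk factors (count category, tobacco
use, preterm birth, plurality), delivery characteristics (presentation,
method, infant transfer, NICU-related abnormal condition, WIC receipt,
antenatal steroids, maternal transfusion), the county of residence, a
transport flag, and origin/destination facility IDs.  The destination is
always the delivery facility; the origin exists only for transported
records.  One transport is recorded per delivery — multi-hop transfers are
not representable, matching the structure of birth records.  Facilities
carry an ordered level of care (Birth Center < Level I < II < III < RPC), a
health-system ID, a designated perinatal region (DPR), and an obstetric
flag; RPC implies obstetric.  Counties carry a Rural-Urban Continuum Code
(1–9) and a DPR.

Rurality of a record is the rurality of its county of residence (urban =
RUCC 1–3, suburban 4–6, rural 7–9); records with an unknown county get an
explicit Unknown class, which is carried as its own level in every table
and model rather than being dropped.

## Inclusion cascade

Network analyses use transports between obstetric facilities: records are
excluded if not transported, if either endpoint is missing, or if either
endpoint is non-obstetric.  Facility IDs absent from the roster are treated
as non-obstetric (dropped) but logged separately, since data errors and
genuinely out-of-roster facilities cannot be distinguished downstream.  The
`FilterReport` identity `retained = transported − missing − non-obstetric`
is enforced on construction and property-tested.  County transport rates
deliberately use *all* transported deliveries, not the network-eligible
subset: the rate describes where transported people live, and no
obstetric-endpoint restriction applies to that question (a flag allows the
network subset).

## Rates

A county's rate is 1000 × resident transports / resident births.  Zero-birth
counties get an undefined (NaN) rate with a warning, never 0.  Class
summaries are unweighted means over counties (each county counts once
regardless of birth volume) with population SD (ddof = 0, switchable);
zero-transport counties are included in the means and flagged for hashing
in choropleths.  Quantile bins are rate-ordered with ties broken by county
ID; if all defined rates are equal the binning collapses to one bin with a
warning.

## Transport network

Nodes are facilities appearing in at least one retained transport; directed
edges carry transport counts.  Self-transports (origin = destination) are
rejected.  Isolated roster facilities are excluded from the graph and from
node-percentage denominators by default; per-region output also reports the
all-roster denominator, since "share of facilities participating" is
meaningful under both conventions.  A node counts as inter-region active if
it is an endpoint of any cross-region edge in either direction.  The
neighbor share of inter-region volume is computed against a user-supplied
symmetric region adjacency (data, not hardcoded geography).

## Community detection

The directed graph is symmetrized by summing the two directions (edge
weights are raw transport counts — "transporting among each other most
frequently" is a volume statement), then partitioned by maximizing weighted
Newman–Girvan modularity at resolution γ (default 1):

    Q = (1/2m) Σ_uv [w_uv − γ k_u k_v / 2m] δ(c_u, c_v)

With no self-loops, the single-community partition scores exactly
1 − 1 = 0, and the all-singletons partition scores −Σ(k_u/2m)² < 0; both
are frozen as closed-form test cases (two disjoint triangles give Q = 0.5).

The optimizer is a seeded multilevel greedy (Louvain) search: local moves
to the best neighboring community (strictly positive gain, deterministic
ID-sorted tie-breaks), aggregation into supernodes with internal weight as
self-loops, repeated to a fixed point.  Because greedy search on small
dense weighted graphs has many local optima, the default runs 8 restarts —
the first from all-singletons, the rest from random coarse partitions of
2–5 groups — and keeps the best score.  All randomness derives from the
`DetectionParams.seed`, so identical inputs give identical partitions.  The
reported modularity is recomputed independently from the assignment.

For graphs of at most 10 nodes an exhaustive oracle enumerates all Bell(n)
set partitions via restricted-growth strings (lexicographic order; first
optimum kept, which fixes ties deterministically) and returns the global
optimum.  The validation suite checks that the heuristic never exceeds this
bound and attains it on ≥ 95% of random small weighted graphs, and that it
recovers planted partitions (6 communities × 12 nodes, p_in = 0.6,
p_out = 0.02) with mean adjusted Rand index ≥ 0.9 over 20 seeds.

## Concordance

Facilities in the partition are cross-tabulated against their DPRs.
Dominance is the modal counterpart per row/column, ties resolved to the
lowest ID and flagged.  Percent mismatch of a community is the share of its
facilities outside its dominant region (and symmetrically for regions).
Independence is tested with the plain Pearson chi-square statistic —
no continuity correction and no exact-test fallback, matching how such
tables are conventionally reported; all-zero rows/columns are dropped with
a warning before computing df = (R−1)(C−1), and small expected counts
trigger a warning, not a method switch.  Type-I error calibration is
verified by simulation (1,000 independent 6×8 tables; rejection rate at
α = 0.05 within [0.035, 0.065]).  The adjusted Rand index (delegated to
scikit-learn) quantifies partition agreement in recovery tests.

## Association models

Unadjusted odds ratios come from collapsed 2×2 tables: OR = ad/bc with the
Woolf interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and the Wald p-value on
the log OR, which coincides with the univariate logistic Wald test for a
binary contrast.  Zero cells are reported literally (OR 0 or ∞, interval
(0, ∞), degenerate flag); no Haldane–Anscombe correction is applied by
default because published tables print such entries as-is.

The multivariate model for inter-region transport is maximum-likelihood
logistic regression fitted by iteratively reweighted least squares:
Newton steps β ← β + (XᵀWX)⁻¹Xᵀ(y − p), convergence when max|Xᵀ(y − p)| <
1e-8 or 50 iterations.  Rank-deficient designs raise an error naming the
aliased terms.  Coefficients beyond ±12 on the log-odds scale are flagged
as probable complete separation and the fit is marked non-converged rather
than silently reported.  Categorical terms are dummy-coded against stated
reference levels with Unknown kept as an explicit level; levels with fewer
than 20 observations can be pooled into "Other" (the pipeline applies this
to every model covariate, keeping references intact).  The implementation
is cross-checked against statsmodels GLM to ~1e-8 in the test suite, and
its Wald intervals are calibrated by simulation: over 200 replicate
registries of 100,000 deliveries with planted log-ORs, pooled 95% CI
coverage must land in [0.92, 0.98].

## Synthetic registry generator

Statewide birth records are restricted, so the generator emulates the
structure the analysis assumes.  Design choices:

- **Covariate marginals** come from the published total-column counts of a
  774,639-delivery statewide cohort; WIC, steroid, and transfusion shares
  (not tabulated there) are set to plausible statewide values (40%, 3%,
  0.3%).  Covariates are sampled independently — only marginals are
  published; a config hook accepts overridden marginals.
- **Transport model**: Bernoulli(logistic(β₀ + Σ effects)) with default
  log-OR effects matching the published unadjusted structure for rurality,
  payor, preterm, plurality, tobacco, and medical-risk count (a rare
  outcome makes marginal and conditional ORs nearly equal, so planted
  effects are recoverable as empirical unadjusted ORs).  The intercept is
  calibrated exactly: with independent covariates the expected prevalence
  is a finite sum over the product of effect-bearing marginals, solved for
  β₀ by bisection; the default target is 0.42%.
- **Geography**: counties draw RUCCs from a distribution mirroring a state
  with many rural counties; births are assigned by a two-stage draw (class
  by published birth shares 81.5/11.8/4.0% plus 2.8% unknown county, then a
  uniform county within class), so birth volume concentrates in urban
  counties while county counts skew rural.
- **Destination mechanism** (consequences published, mechanism not): an
  upward indicator ~ Bernoulli(0.95) is drawn first and the origin sampled
  conditional on it (non-RPC origins for upward draws), making the realized
  upward fraction binomially exact.  A region gate keeps the destination in
  the origin's region with probability `intra_region_affinity` (default
  0.83 → ~17% inter-region share), otherwise an adjacent region is chosen
  with a small leak (0.03) to non-neighbors (~95% + neighbor share).  Among
  candidates, same-system facilities get weight 3 and, for upward draws,
  RPCs get weight 20 — regional centers are the designed destination of
  upward transport, and this yields an upward-to-RPC share near 87%.  When
  a gated candidate set is empty the region gate takes precedence over
  direction (so affinity 1 keeps every transport in-region exactly); the
  rare relaxations are counted in the ground truth.
- **Filter work**: 16% of transports are degraded (missing origin or
  non-obstetric destination, 50/50) so the inclusion cascade has real work
  and the network-eligible fraction lands near 0.36%.
- **Determinism**: facilities, counties, and deliveries draw from separate
  streams split off the master seed, so resizing one roster does not
  perturb the others; identical config + seed gives identical output.

What the generator does **not** emulate: covariate correlations, real
geography (distances, drive times), multi-hop transports, out-of-state
flow, temporal trends, and facility-level volume heterogeneity beyond the
level/system/region structure.  Passing recovery tests therefore show the
estimators are correct under the stated model, not that real transport data
meet its assumptions.

## Problem sizes and tolerances

The default test registry is 80,000 deliveries (the full published cohort
scale of ~775k is reachable via config); the acceptance script uses 200,000
for network metrics and 200 × 100,000 for CI coverage.  Monte-Carlo
assertions use 3–4 binomial standard errors at the simulated size.  The
published rural Woolf interval is matched to ±0.005 per bound — the
published rounding path is unknown, and the last digit can differ
legitimately.  Dominance and quantile ties break by ID; modularity
comparisons use a 1e-9 absolute guard; IRLS convergence is max|score| <
1e-8.

## Known limitations

- Louvain is a heuristic: optimality is guaranteed only where the ≤10-node
  oracle can check it; on larger graphs quality is supported by the planted
  benchmark, not proof.
- The chi-square test is asymptotic; facility-level tables are small, so
  the expected-count warning fires routinely and p-values near thresholds
  deserve caution.
- At small transport counts the inter-region model's sparse contrasts
  (e.g. destination level of care) separate; the fit reports this honestly
  instead of producing estimates, which mirrors the degenerate entries seen
  in published tables at much larger scale.
- Woolf intervals and Wald tests share the usual large-sample caveats for
  near-zero cells; degenerate entries are flagged, not corrected.
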