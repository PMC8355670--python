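# Methods

`areabayes` infers *contact areas*: groups of geographically situated
entities (languages in the motivating application) whose categorical traits
are more similar than either of two confounders can explain — the universal
baseline preference for a trait state, and inheritance within a family.
This note describes the model, the sampler, the synthetic-data generator
and the numerical choices the implementation makes where more than one
reasonable design existed.

## Model

Data are a matrix `X[l, f]` of categorical states for entities `l ∈ L` and
features `f ∈ F`; each feature has its own finite state set `S_f`
(`N_f ≥ 2`). Each entity has a point location and optionally a family label
`φ(l)`. A configuration `Z = {Z_1, …, Z_K}` of pairwise-disjoint entity
subsets represents candidate contact areas.

Every cell is modelled as a draw from a three-component mixture of
categorical distributions,

    P(X_lf = s) = w_u,f · α_{f,s}  +  w_i,f · β_{f,φ(l),s}  +  w_c,f · γ_{f,Z(l),s},

with a per-feature weight triple `w_f = (w_u, w_i, w_c)` on the simplex.
`α_f` is the universal distribution of feature `f`, `β_{f,φ}` the
distribution inside family `φ`, `γ_{f,k}` the distribution inside area
`Z_k`. For an entity outside every area the contact weight is zeroed and
the remaining weights re-normalized; entities without a family are treated
symmetrically for the inheritance weight. The joint likelihood is the
product of cell probabilities over all non-missing cells; missing cells
contribute a factor 1 (the mixture factorizes over cells, so skipping a
cell marginalizes it exactly).

**Active weight components.** When a run has no families (confounder
granularity "none") the inheritance weight is pinned to zero and the weight
prior and proposals live on the (universal, contact) sub-simplex; likewise
the contact weight when `K = 0`. A component with no groups never enters
the likelihood, so leaving its weight free would only report the prior back
and dilute every weight summary. Family versus clade granularity is purely
a matter of how the family column is coded.

## Priors

- Every weight triple and probability vector has an independent Dirichlet
  prior; the default is uniform (`ψ = (1, …, 1)`). Informative priors are
  parameterized as `ψ_n = 1 + μ_n · ρ` with mean `μ` and precision `ρ`, and
  can be derived from an empirical count table (μ = relative frequencies;
  features missing from the table fall back to uniform with a warning).
- The geo-prior on an area is either uniform or cost-based:
  `log P(Z_k) = −λ · c_k` (unnormalized), where `c_k` is the mean edge cost
  of the linkage graph over the area's members — minimum spanning tree by
  default, with Delaunay-restricted edges or the complete graph as
  alternatives. Using the *mean* keeps the prior agnostic to area size.
  Configurations with overlapping areas have prior zero. Normalizing
  constants are omitted; they are fixed within a run, so posteriors from
  runs with different `λ` or cost matrices are not comparable.
- Area sizes have a uniform prior on `[m_min, m_max]` (default 3 to
  min(50, |L|−1)); sizes outside the bounds have prior zero. A uniform
  form was chosen so the size prior does not fight the deliberately
  size-agnostic geo-prior.
- There is no prior over `K`; `K` is scanned externally and compared by
  DIC.

Numerical details: Dirichlet log-densities are computed from
`scipy.special.gammaln` (equality with `scipy.stats.dirichlet.logpdf` is
asserted in the tests); the MST uses Kruskal with edges ordered by
(cost, smaller index, larger index), which makes degenerate tied inputs
reproducible — the mean edge cost is the same for every MST regardless.
Delaunay linkage falls back to the MST with a warning on degenerate
(e.g. collinear) point sets.

## Sampler

Metropolis–Hastings over `Θ = {Z, w, α, β, γ}` with two proposal families:

- **Simplex blocks** (one feature's weight triple or one probability
  vector): a Dirichlet random walk `y ~ Dir(κx + ε)` (default `κ = 30`,
  `ε = 1e−4`), for α/β/γ mixed 50/50 with an independence draw from
  `Dir(ψ + n)`, where `n` counts the states observed in the block's scope
  (all entities for α, the family for β, the area members for γ). The
  independence part is a quasi-Gibbs jump to the sharp profile the block's
  members support; the counts over-attribute cells to the component, but
  the Hastings ratio uses the full mixture-kernel density in both
  directions, so the stationary distribution is exact. Without it the
  random walk needs tens of thousands of steps to sharpen a vector, and
  the area configuration equilibrates against half-converged vectors.
- **Area moves**: grow / shrink / swap on a uniformly chosen area. Grow
  draws an unassigned entity with probability `∝ exp(−rank/g)` of its cost
  rank to the area (default `g = 10`); shrink removes a uniform member;
  swap is shrink-then-grow. The grow distribution has full support over
  unassigned entities, so every move has a reverse move with positive
  probability and the Hastings ratio (menu sizes and candidate
  probabilities, both directions) is finite; a truncated candidate set was
  tried first and froze the chain, because interior members could never be
  removed once the reverse grow could not reach them. Moves violating the
  size bounds are auto-rejected, as are proposals whose Dirichlet draw
  lands on the simplex boundary in floating point (measure-zero).

Likelihood and prior are cached per cell and per parameter block and
updated incrementally; cache-versus-recompute agreement to 1e−9 is part of
the test suite. Default operator mix: areas 40%, weights 20%, α 10%,
β 15%, γ 15% — area moves mix slowest. Operators whose target does not
exist in a run (β without families, area/γ at K = 0, weights with a single
active component) are dropped and the rest re-normalized.

**Warm-up.** The area posterior is highly multimodal: an area can sit
anywhere in space, and a chain that equilibrates its probability vectors
against a badly placed area is in a local mode separated by a wide valley
(the vectors must soften, the area must migrate, then re-sharpen). Before
the main chain, `warmup_chains` (default 10) short independent chains
(default 5000 steps, capped at a tenth of the run) are run from random
initializations, and the main chain continues from the end state with the
highest log-posterior. Warm-up only selects a starting point — the
stationary distribution is untouched and the burn-in fraction (default
20%) is still discarded. Initial areas are seeded as a random entity plus
its `m_min − 1` nearest unassigned neighbours; after the first area, seed
entities are drawn with probability proportional to their cost to the
areas already seeded, so a multi-area chain starts with its slots spread
over the region instead of contesting one neighbourhood.

One seeded generator (`numpy.random.default_rng`) drives every stochastic
decision; the same seed reproduces a run bit-identically. Chain defaults
for full analyses are generous: millions of
steps with 20% burn-in and ~10⁴ retained samples; the bundled benchmarks
use 10⁵–3·10⁵ steps on 100-entity problems, where the chains reach stable
membership frequencies in a fraction of that budget.

## Selection and post-processing

- **DIC**: `DIC = D̄ + p_D` with `D̄` the posterior mean deviance
  (`D = −2 log L`) and `p_D = var(D)/2` (sample variance, ddof 1). The
  `D̄ − D(Θ̄)` variant is unavailable because the posterior mean of the
  discrete `Z` is undefined. `K` is selected as the smallest value whose
  successor improves DIC by less than a relative threshold `τ` (default
  0.02 — "levels off" needs an operational definition); a curve that is
  still falling at the end of the scan selects the largest `K` with a
  warning.
- **Label matching**: area slots are exchangeable, so labels can switch
  along the chain. Samples are aligned by greedy maximum-Jaccard matching
  against a running reference initialized from the first retained sample;
  only labels are permuted.
- **Membership frequencies** are per-entity fractions of retained samples
  in each (matched) slot; rows need not sum to 1.
- **Area ranking** uses the mean per-sample summed log cell-likelihood
  over a slot's members, tie-broken by mean size. This is a substitute
  statistic for "relative posterior probability" of an area (the exact
  statistic this substitutes for is not fully specified in the
  published description); output metadata flags it as such.
- **Gabriel graph** summaries connect an area's consensus members; edge
  `(a, b)` exists iff `d²(a,b) < d²(a,c) + d²(b,c)` for every other point
  `c` (strict, so cocircular cases drop the edge; duplicate points
  suppress their twins' edges with a warning). Edge weight is the
  posterior frequency of the two endpoints sharing the slot.
- **ESS**: `n / (1 + 2 Σ ρ_t)` with the autocorrelation sum truncated at
  the first non-positive adjacent pair; constant chains report `n` with a
  degenerate-chain warning; antithetic chains may report more than `n`.

## Synthetic data

The generator emulates the model's own assumptions: uniform locations in a
rectangle, 2–4 states per feature, probability vectors drawn from
symmetric Dirichlets whose concentration controls expected entropy, and
cells drawn component-first from the entity's effective weights (equal in
law to the marginal mixture; verified by a χ² test).

Two design choices matter for what the benchmarks do and do not show:

- **Signal placement** (`distinct_signals`, default on): planted
  family/area vectors are permuted so their modal state lands on the state
  the confounders dis-prefer (for multiple areas, on distinct states where
  the inventory allows). A contact signal is *defined* by differing from
  the confounder distributions — a sharp vector that happens to coincide
  with the universal mode carries no areal evidence, and planting signals
  blindly produces unidentifiable scenarios in which no method could
  separate the effects.
- **Designed feature types**: for weight-recovery analyses a feature can
  be made decisive by construction (a fixed near-deterministic contact
  vector on the confounder-dis-preferred state) or indecisive by
  construction (contact vector set equal to the universal vector, so the
  data carry no information about that feature's weights and its weight
  posterior stays prior-wide). An early draft used a high-entropy random
  contact vector as "indecisive", but a near-uniform vector still differs
  from a skewed universal vector and is therefore informative.
- **Universal skew**: `α` is drawn at concentration 0.5 in the benchmarks
  (typical categorical traits have a clearly preferred state), planted
  family vectors at 0.05–0.1, contact vectors at 0.1–0.3 depending on the
  benchmark; the canonical experiment set uses contact weight 0.5–0.6.

Benchmarks plant areas and families as spatial clusters and run with a
cost-based geo-prior (rate λ = 10 per region unit of mean MST edge cost),
reflecting the assumption that contact requires spatial proximity. The
full-scale experiment presets use 951 entities × 30 features; the
benchmark scenarios use 100 entities so a complete chain runs in about a
minute. Passing benchmarks therefore shows correct inference *under the
model's own generative assumptions* at moderate scale; it does not show
robustness to misspecified confounders, non-uniform spatial processes,
correlated features, or real-data feature coding decisions.

## Known limitations

- The inheritance weight is weakly identified when only one small family
  is present: the family vector `β` can absorb the family's empirical
  distribution, biasing `w_i` upward (visible in the confounder-separation
  benchmark as a slight pull of family members toward the area slot).
  More families, larger families, or an informative `β` prior mitigate
  this.
- With a uniform geo-prior, high-entropy "blob" configurations — many
  weakly matching entities and a softened contact vector — can accumulate
  appreciable posterior mass at desk scales; the cost-based geo-prior and
  warm-up largely remove them.
- Single-chain inference: replicate chains (different seeds) are the
  intended convergence check; no within-chain adaptation is performed.
- No reversible-jump over `K`, no overlap between areas, no per-cell
  component indicators, no phylogenetic (tree-structured) inheritance.
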