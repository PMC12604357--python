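# Methods

## Data model

A linkage database is a long-format table with one row per (species,
production class, hazard, consequence, indicator) link plus three ordinal
metadata columns: impact of welfare consequence (Low=1, High=2, attached to
the consequence), ease of hazard mitigation and ease of indicator use
(Easy=1, Moderate=2, Difficult=3, attached to the hazard and indicator
respectively). Rows are deduplicated on the five label fields; labels are
whitespace-trimmed and matched case-sensitively (case-folding could silently
merge distinct indicators). Within one species/class view an entity must
carry a single rating — expert-consensus elicitation produces one rating per
entity, so a conflict is treated as a data error, not resolved by vote. The
same entity rated differently in *different* views only warns: a hazard's
mitigability can legitimately differ between production contexts. Entity
lists in a view are sorted lexicographically; all downstream tie-breaking
inherits that order, which makes every result bit-for-bit reproducible.

## Scoring

Per indicator and view, five factors: hazard coverage and consequence
coverage (counts of distinct linked entities), easiness, impact and
mitigation. The "ease" ordinals are direction-reversed with
(L+1) − value, L = 3 levels, so that larger is always better. Some sources
write the equivalent 5 − value; because every factor is subsequently
max–min normalised, any positive affine transform of a raw factor yields
identical normalised values, objectives and selections — the property-test
suite proves this, so the choice of offset is immaterial.

Impact and mitigation must be reduced to one scalar per indicator although
an indicator links to several consequences/hazards. We use the *mean* over
the distinct linked consequences (impact) and distinct linked hazards
(mitigation). A sum would re-encode coverage, which the objective already
carries through its own term; the mean keeps the factors independent. This
aggregation rule is a design choice of this package, not a claim about how
any particular dataset was originally scored.

Max–min normalisation maps each factor to [0, 1] within the current
species/class view (selections are made per species, so cross-species
pooling would let one species' range distort another's scores). A constant
factor maps to 0 everywhere: it cannot discriminate between indicators, and
any constant is selection-equivalent. Normalisation happens before the
coverage composite α·ĤC + β·ĈC is formed.

## Set objectives

Per-indicator objectives are not additive in coverage: two indicators
covering the same consequences contribute their full individual scores to a
sum but no new information to a monitoring programme. Both conventions are
therefore exposed:

* **additive**: Objective(S) = Σ objective_i. Simple, but rewards
  redundancy.
* **union** (default for the exact solver): the coverage term is
  ω_cov·(α·|∪hazards(S)|/H + β·|∪consequences(S)|/C), i.e. distinct
  entities covered by S normalised by the view totals, while easiness,
  impact and mitigation remain additive over S. Union coverage is a
  monotone submodular set function (tested), which is what produces
  diminishing returns and the saturating cumulative-coverage curves.

The budget is |S| ≤ K, not == K: in union mode an indicator adding nothing
is never forced in. Equal-valued optima resolve to the smallest, then
lexicographically earliest, set — a plain lexicographic rule would prefer
padding a set with a zero-gain indicator whose label happens to sort early,
contradicting the ≤ K semantics.

## Selectors

*Greedy*: rank by objective_i (ties lexicographic), take the top K. Runs in
O(n log n); blind to overlap.

*Exact*: depth-first branch-and-bound with backtracking over
include/exclude decisions. Indicators are explored in descending
individual-objective order; the incumbent is initialised with the greedy
solution; the bound at each node adds the top-r remaining additive gains
(precomputed per suffix) and, in union mode, the coverage headroom
reachable from the remaining indicators' pooled hazard/consequence masks —
an admissible (never-underestimating) optimistic completion, so pruning
cannot cut off an optimum. Because the bound is non-increasing along the
sorted candidate loop, a failed bound prunes the whole remaining suffix.
Pruning uses strict inequality at tolerance 1e−9 so equal-valued optima
survive for the tie-break. Entity sets are bitmask integers; progress is
logged every 10,000 nodes; a wall-clock limit (default 10 s, checked every
2,048 nodes and before the search starts) returns the incumbent with status
`time_limited` instead of raising.

*Exhaustive*: recursive enumeration of all 2^n − 1 non-empty subsets of
size ≤ K, capped at 20 indicators. It is the independent oracle for the
exact solver in the test suite and deliberately shares no bounding logic
with it.

The combination-table utility additionally reports all *minimal* subsets
whose union coverage equals the full shortlist's. Attainment is upward
closed, so minimality is decided by checking the drop-one subsets.

## Analysis harnesses

* **Cumulative curves**: union coverage percent of the k-selection for
  k = 1..K, in hazard, consequence or hazard×consequence ("combination
  space") dimensions. The asymptote is the whole-set coverage, not
  necessarily 100%. Greedy curves plateau where the next-ranked indicator
  adds nothing; exact union-mode curves rise monotonically.
* **Scenarios**: five shipped presets over the weight quadruple
  (coverage, easiness, impact, mitigation) — (8,0,0,0), (2,2,2,2),
  (5,3,0,0), (5,0,3,0), (5,0,0,3) — all summing to 8.0 for comparability
  and shipped as `presets.yaml`. Presets set the four ω weights only;
  α = β = 1 balances hazard and consequence coverage equally. Selections
  are invariant to uniform scaling of the quadruple (argmax scale
  invariance, tested).
* **Robustness**: univariate perturbation of one ω by −50%/0/+50% with all
  weights based at 1.0 and K = 10, reporting each selection and the matrix
  of pairwise shared-indicator counts (the numbers a Venn diagram would
  display).
* **Sweep**: the coverage weight varied over a grid, with the selected
  set's objective decomposed into per-factor contributions that sum to the
  total.
* **Benchmark**: wall-clock mean and 95% t-interval per K over repeated
  runs. Timings are hardware-bound, so the harness asserts protocol shape
  only and no test or acceptance check ever compares absolute runtimes.
  Multivariate (joint) weight perturbation is out of scope.

## Synthetic data

Real linkage databases are built from expert-elicited risk assessments and
are typically not redistributable, so the generator emulates their
structure rather than any specific contents:

1. a bipartite hazard↔consequence layer is sampled first (every hazard and
   consequence linked at least once; extra links with a density parameter),
   mirroring the risk-assessment logic chain;
2. indicators then attach to hazard–consequence *pairs*, coupling their
   hazard and consequence coverage;
3. a broad/narrow mixture controls degrees: default 25% broad indicators
   with 8–24 linked pairs and 75% narrow with 1–4, which reproduces the
   qualitative saturating coverage curves with plateaus. Default entity
   counts (92 indicators, 58 hazards, 16 consequences) follow the largest
   species view in the motivating case studies;
4. metadata is sampled once per entity (default: Low/High equiprobable,
   ease levels uniform), so rating conflicts cannot arise;
5. an optional planted subset receives a partition of all pairs, giving
   instances whose full-coverage optimum is known by construction.

What the generator does **not** emulate: correlated metadata (e.g.
hard-to-use indicators being broader), heavy-tailed degree distributions,
hazards shared across species, or any real database's label semantics.
Passing tests therefore demonstrate algorithmic correctness on structurally
realistic inputs, not quantitative agreement with any particular species'
curves.

Two deterministic proof-of-concept fixtures ship with known minimal-subset
structure, each verified by brute force before being returned:
`laying_hen` (6 indicators, 14 hazards, 6 consequences, exactly one minimal
3-subset attaining the full 6-indicator coverage) and `broiler`
(6 indicators, 18 hazards, 9 consequences, exactly two minimal 4-subsets
sharing three members).

## Numerical choices and reporting

* Objective comparisons use absolute tolerance 1e−9; below it values are
  ties and the set tie-break applies.
* Coverage percentages are reported to one decimal place with half-up
  rounding (17/26 → 65.4, 7/16 → 43.8).
* Degenerate inputs: empty factor vectors, empty views, empty files and
  unknown labels raise typed errors; a constant factor normalises to 0.
* Problem sizes in the test and acceptance suites: oracle-equivalence runs
  use 50 random instances of 8–15 indicators at K = 5 under all five
  presets in both modes, a size at which exhaustive enumeration is a
  practical oracle while still exercising non-trivial pruning.

## Known limitations

* The additive non-coverage terms grow with |S| while the union coverage
  term is bounded by ω_cov·(α+β); with balanced weights and large K the
  objective can favour feasibility factors over marginal coverage. This is
  a property of the weighted-sum model, visible in the sweep harness.
* Ordinal three-level metadata gives many indicators identical factor
  values, so equal-valued optima are common; the deterministic tie-break
  makes the returned set reproducible but other equally good sets may
  exist (the combination table enumerates them for small shortlists).
* The exact solver is exponential in the worst case; the time limit, not
  the bound, is the guarantee of bounded runtime on adversarial instances.
* Hazards are treated as mutually exclusive; interactions between hazards
  (multifactorial welfare problems) are not modelled.
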