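# Methods

## Model

A probabilistic signaling network is a directed graph `G = (V, E, P)` with
node set `V` (genes), directed edges `E` (interactions), and an edge
probability function `P : E → [0, 1]`. Edges exist independently of each
other. Two node subsets are designated: sources `S` (membrane receptors)
and targets `T` (reporters / transcription factors). The *signal
reachability* `R_P[s,t]` is the probability that at least one directed
`s→t` path consists entirely of present edges — two-terminal reliability,
which is #P-complete to evaluate in general.

The empirical counterpart `C[s,t]` is the absolute Pearson correlation
between the expression profiles of `s` and `t` across the samples of one
condition. The inference problem is: given `V, E, S, T, C`, find `P`
minimizing `‖C − R_P‖₂`. One invocation fits one condition; fitting each
condition's expression subset separately yields condition-specific
probability vectors over a shared edge ordering.

### Assumptions

* Edge presence events are mutually independent.
* Coexpression magnitude is a meaningful proxy for end-to-end signal
  transmission between a receptor and a reporter (sign is discarded:
  inhibitory cascades anticorrelate but still transmit signal).
* The topology is fixed and trusted; only existence probabilities are
  unknown.
* Self-loops are irrelevant (they cannot affect `s→t` connectivity for
  `s ≠ t`) and are dropped at parse time with a warning. Duplicate directed
  edges are rejected — the model has exactly one probability per
  interaction.

## Exact reachability engine

Each edge `e_i` is associated with the binomial `p_i x_i + q_i y_i`,
`q_i = 1 − p_i`. Multiplying the binomials yields an *xy-polynomial*: a sum
of terms `a · x_S y_{Θ∖S}` (exactly the edges in `S` among the processed
set `Θ` are present; `a` is that outcome's probability) plus free terms
`b x*` (target already reached) and `c y*` (target already cut off). Free
terms absorb both branches of any further multiplication. After each
multiplication the polynomial is collapsed:

* **path test** — if the subgraph with edge set exactly `S` contains a
  directed `s→t` path, the term's mass moves to `b`;
* **cut test** — if deleting the term's absent edges `Θ∖S` from the edge
  universe leaves no `s→t` path, the mass moves to `c`.

When all binomials are multiplied every term has collapsed and
`b = R_P[s,t]`. Total mass `b + c + Σa = 1` is checked after every step and
an `EngineError` is raised if it drifts beyond 1e-9 (in practice the
arithmetic conserves mass exactly up to rounding).

Implementation notes:

* **Pairwise semantics.** `R_P` is defined per `(s, t)` pair; the engine
  runs single-source/single-target collapse tests, and the matrix is
  assembled pair by pair. `s = t` returns 1 by the empty-path convention
  (receptor and reporter sets are disjoint in practice).
* **Relevant-edge pruning.** An edge `(u, v)` with `u` unreachable from `s`
  or `t` unreachable from `v` lies on no `s→t` walk, so its binomial
  multiplies the polynomial by `p + q = 1` and splits every term into two
  branches with identical path/cut status. Such edges are skipped entirely;
  connectivity between `s` and `t` is unchanged because no `s→t` path can
  use them.
* **Multiplication order.** Edges are multiplied in breadth-first discovery
  order from the source, so path collapses fire as early as possible and
  the live term count stays small. Any order gives the same final
  polynomial; this is purely a performance heuristic. A configurable cap
  (default 2·10⁶ live terms) aborts with a clear error on adversarial
  topologies instead of exhausting memory.
* **Memoized path/cut tests.** Tests are keyed by the edge subset and
  cached per `(s, t)` pair inside a reusable `ReachabilityEngine`, so
  repeated evaluations across GA candidates and hill-climbing sweeps
  amortize their graph searches.
* **Oracle.** `brute_force_reachability` enumerates all `2^|E|` subsets
  (refusing beyond 20 edges) and is used throughout the tests as an
  independent check; it shares no code path with the polynomial engine
  beyond the subset path test.

### Deferred-edge linearization

Deferring one edge's binomial to the very end leaves, just before the last
multiplication, a polynomial `Σ a_i x_{S_i} y_{Θ∖S_i} + b x* + c y*` whose
surviving terms are exactly the outcomes where the deferred edge decides
reachability. The final reached coefficient is `α + β p_e` with `α = b` and
`β = Σ a_i`. The engine returns `(α, β)` per pair; the contract
`R(p_e) = α + β p_e` for all `p_e ∈ [0, 1]` is verified in the tests
against full evaluations at five probe points.

## Phase 1 — genetic algorithm

* Population: 50 random vectors, entries i.i.d. U[0,1].
* Fitness: `F_ψ = 1 − ‖C − R_ψ‖₂ / |S×T|` (1 at a perfect match; the norm
  of an |S|×|T| matrix of entries in [−1, 1] cannot exceed |S×T|).
* Gap: `g_ψ = Σ (C − R_ψ)`. Positive means aggregate underestimation.
* Crossover (50 children per generation, parents drawn
  fitness-proportionally, distinct): entrywise max when both gaps are
  positive, min when both negative, fitness-proportional random pick on
  mixed signs. A gap of exactly 0 is treated as positive so the rule is
  total and deterministic.
* Mutation: every entry of every solution in the enlarged population of 100
  is resampled from U[0,1] with probability 0.01.
* Selection: the 5 highest-fitness solutions survive outright; 45 more are
  drawn from the remaining 95 without replacement with probability
  proportional to fitness. All-zero fitness degenerates to a uniform draw;
  if fewer than 45 weights are strictly positive a 1e-12 uniform floor
  keeps the draw well-defined.
* The returned solution is the best ever archived (a superset guarantee
  over "best of the final population": the two differ only if a late
  mutation damages the incumbent).
* Iterations default to 100 and are configurable; convergence speed depends
  on the instance and no universal count exists.

All randomness flows from a single caller-supplied seed through one
`numpy.random.Generator`, making runs bit-reproducible.

## Phase 2 — hill climbing

For each edge `e` in ascending index order (fixed across sweeps for
reproducibility), the per-pair linearizations give the 1-D objective
`SSE(p_e) = Σ_{s,t} (C − α_st − β_st p_e)²` — a convex quadratic whose
unconstrained minimizer is `p_e = Σ β_st (C − α_st) / Σ β_st²`, clipped to
`[0, 1]` (convexity makes the nearest boundary optimal outside the box).
Edges with `Σ β_st² = 0` influence no pair; their probability is left at
its incoming value and reported as non-identifiable. Each update is an
exact coordinate minimization, so the SSE sequence is non-increasing and
bounded below by 0; the loop terminates when a full sweep improves the SSE
by less than the tolerance (default 1e-9 absolute, with a 1000-sweep safety
cap).

The descent objective is the sum of squared differences; the reported
fitness and quality apply the square root. The two have the same argmin, so
the choice affects only reporting, not the fitted probabilities.

## Empirical reachability front end

Expression input is a genes × samples table. Rows with missing values are
rejected at load — no silent pairwise-complete correlation or imputation.
Zero-variance genes make the correlation undefined and are rejected by
name. At least 3 samples are required. An optional two-column mapping file
translates probe identifiers to gene symbols; matching is exact and
case-sensitive. `C` entries are `|r|`, clipped into `[0, 1]` against
rounding in collinear cases.

## Synthetic data generator

The generator emulates the study design the package targets — a curated
signaling topology plus an empirical reachability matrix — at sizes where
the exact engine and both optimizers can be tested end to end:

* **Topology:** a random DAG on ordered nodes with forward edges only
  (curated signaling excerpts are largely acyclic; the engine itself
  handles cycles, and `allow_cycles` rewires an edge backwards for stress
  tests). The first `n_sources` nodes accept no incoming edges (roots) and
  the last `n_targets` emit none (sinks); edge sets are rejection-sampled
  (up to 200 attempts) until every target is reachable from at least one
  source. Defaults in the CLI: 20 nodes, 25 edges, 3 sources, 3 targets —
  a desk-scale analogue of a small curated pathway.
* **Ground truth:** `P*` i.i.d. U[0,1]; `C_clean = R_{P*}` computed by the
  exact engine.
* **Noise:** additive Gaussian in C-space, clipped to `[0, 1]`. Noise is
  applied where the optimizer consumes its input; the expression simulator
  below covers the upstream path. Noise-free instances are the reference
  condition for recovery tests.
* **Expression simulator:** source nodes get i.i.d. standard-normal latent
  activity; every other node, in topological order, sums `p_e ×` parent
  activity over incoming edges plus Gaussian noise. This produces
  receptor–reporter correlations that grow with path strength and is
  sufficient for exercising the coexpression front end; it makes no claim
  to transcriptional realism (no regulation logic, no heteroscedastic
  measurement error, no batch structure).

What passing tests on these instances shows: the engine is exact, the
optimizers converge and recover reachability, and the pipeline is
deterministic under a seed. What they do not show: that coexpression is a
faithful reachability proxy in any particular biological dataset, or that
fitted probabilities on real data are identifiable — on real networks many
edges are partially confounded, and only reachability-space quality is
guaranteed.

## Analytics

* **Quality**: `100 (1 − ‖C − R_ψ‖₂ / |S×T|)` percent; 100 is a perfect fit.
* **Entropy of the probability spread**: histogram over ten bins
  `[0, 0.1), …, [0.9, 1]` (final bin closed), natural logarithm,
  `0 log 0 := 0`. The log base only rescales comparisons; nats are used.
* **Condition distances**: Euclidean distance between the probability
  vectors of condition pairs, plus each condition's mean distance to the
  others.
* **Outstanding interactions**: per edge, mean `μ_e` and population
  (N-denominator) standard deviation `σ_e` over all conditions; a
  `(condition, edge)` pair is flagged when `|p − μ_e| ≥ 2σ_e` and
  `σ_e > 0` (a constant edge is never flagged; an sd floor of 1e-12 guards
  against floating-point dust). The per-condition gene set `L` collects
  both endpoints of every flagged edge — the input for downstream gene-set
  enrichment, which is out of scope here.
* **Removal centrality**: `centrality(v) = Σ_{(s,t), s≠v≠t} R[s,t] −
  R_without_v[s,t]`, where `R_without_v` deletes every edge incident to
  `v`. Non-negative by monotonicity; zero for nodes off every
  source→target path. This is an operational definition chosen for this
  package (other reachability-based centralities exist) and is labelled
  `removal_centrality` in output.

## Numerical choices and degenerate inputs

* Plain double precision throughout; conservation drift tolerance 1e-9;
  engine-vs-oracle test tolerance 1e-12; linearization contract tolerance
  1e-9.
* Probability serialization uses 6 decimals, well beyond any test
  tolerance; files round-trip through the readers.
* Empty source/target sets, unknown nodes, malformed files, out-of-range
  probabilities, ragged matrices, and re-multiplied edges all raise typed
  errors (`ParseError`, `ValidationError`, `EngineError`) rather than
  propagating garbage.
* Acceptance-style checks run at desk scale (networks of 6–25 edges,
  2×2 or 3×3 reachability matrices, 20–100 repetitions), sizes chosen so
  the whole suite completes in seconds while still exercising every code
  path; the engine itself has no intrinsic size limit other than the term
  cap.

## Known limitations

* The xy-polynomial can still grow exponentially on dense, highly
  interleaved topologies; the term cap turns that into a clean failure.
  Networks at the scale of curated pathway diagrams (tens of edges) are
  unproblematic.
* The GA's crossover heuristic uses the *aggregate* gap sign; it can pick
  the wrong direction for individual edges when over- and underestimation
  cancel. Phase 2 corrects this locally but only to a local optimum.
* Fitted probabilities are generally not unique (non-identifiability);
  downstream condition contrasts inherit this caveat, which is why
  analytics operate on the fitted vectors as descriptive profiles rather
  than as estimands with confidence statements.
* Bidirectional interactions must be encoded as two explicit directed
  lines; the parser treats every line as one directed edge.
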