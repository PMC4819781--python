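# Methods

`ratconn` analyses directed, strength-graded macroscale connectomes: graphs
whose nodes are brain regions and whose edges are axonal projections
reported by tract-tracing experiments, each carrying an ordinal strength
class from 1 (very weak) to 7 (very strong) or an explicit *unknown*
marker.  This note documents the models, conventions, and numerical
choices behind every stage, and what the synthetic study conditions do and
do not establish about real data.

## Conventions and containers

The in-memory orientation is always **source → target**: edge `(s, t)`
means a projection from region `s` to region `t`, stored at entry `(s, t)`
of the adjacency matrix.  Collation databases that record "projection from
*j* to *i*" as matrix entry `(i, j)` are transposed exactly once, at read
time (`convention="bams_target_source"`); nothing downstream ever
re-orients.

Unknown strength is a sentinel distinct from 0, because an edge of unknown
weight is still an edge: all binary analyses include such edges, while
weight analyses drop them.  The container reports both the unknown count
and the weighted fraction, since collation databases may count
unknown-strength edges incident to discarded regions differently from the
filtered graph.

**Node filtering.** Regions with no connections, or with connections only
amongst themselves, are removed before analysis.  Operationally the filter
keeps the largest weakly connected component (ties broken toward the
component containing the lowest region id) and removes isolated nodes and
mutually isolated islands.  This is equivalent to the iterative closure
"remove, re-check" reading of the rule and is idempotent.

## Binary graph metrics

* **Degrees.** In-degree = afferent count (column sum), out-degree =
  efferent count (row sum).
* **Clustering** uses the literal neighbourhood-density definition for
  directed graphs: the neighbours of *i* are the union of its in- and
  out-neighbours; C_i is the number of directed edges among them over
  n(n−1).  This is deliberately *not* the Fagiolo triangle decomposition;
  the two agree on symmetric graphs but differ on directed ones.  Nodes
  with fewer than two neighbours are flagged NaN and excluded from the
  mean.
* **Path length** L_i averages directed BFS distances over *reachable*
  targets only; unreachable counts are reported beside the average rather
  than folded in.  Global efficiency (mean of 1/d with 1/∞ = 0) is the
  preferred global statistic for sparse subgraphs precisely because it
  absorbs disconnected pairs gracefully; the diameter is the maximum
  finite distance.
* **Betweenness** is directed shortest-path betweenness with fractional
  credit over tied shortest paths (Brandes accumulation, via networkx),
  normalized by (N−1)(N−2).  Tie handling is a documented choice: the
  definition itself does not dictate it.
* **Communicability** is the matrix exponential of the binary adjacency;
  entry (s, t) sums walks of all lengths weighted 1/n!.  The global value
  is the mean off-diagonal entry; the local communicability of edge s→t is
  entry (s, t) in the internal orientation.

**Weighted variants.** Weighted clustering (geometric-mean triangle
weights over max-scaled strengths) and weighted path length (edge length =
1/strength, unknown weights falling back to length 1) are provided only to
form weighted/binary contrast ratios.  They are flagged non-canonical:
ordinal 1–7 classes are not ratio-scale quantities, and every headline
analysis here is binary.

## Null models

Degree-preserving randomization uses directed double-edge swaps: edges
(a→b, c→d) become (a→d, c→b) unless that creates a self-loop or an
existing edge.  The attempt budget is 100 swap attempts per edge (a
well-mixed regime at this density; the swap acceptance rate is reported
via the per-null swap counter).  One global seed expands into independent
per-null substreams (`SeedSequence.spawn`), so ensembles are reproducible
and order-independent.  Hard invariant, asserted in tests: every null
preserves every node's in- and out-degree exactly.

Empirical p-values default to the add-one rule p = (1 + #{null ≥ obs}) /
(1 + n_null), which cannot return 0 from a finite ensemble; the raw
"fraction of nulls exceeding" rule is available as `rule="raw"`.  With
999 nulls and an observation beating all of them, the add-one rule prints
p = 0.0010.

Small-worldness: γ = C/⟨C_random⟩, λ = L/⟨L_random⟩, SW = γ/λ; modularity
is normalized the same way (Q/⟨Q_random⟩).

## Community structure

Modularity is defined and maximized on the **symmetrized** binary graph
(an undirected edge wherever a projection exists in either direction);
directed information re-enters through the metrics layered on top.
Partitioning is spectral: recursive leading-eigenvector bisection of the
(generalized) modularity matrix with Kernighan–Lin style node-moving
refinement after each bisection, accepting a bisection only when it
increases Q.  The algorithm is deterministic; the seed parameter exists
for interface uniformity and for the hierarchy's null threshold below.

**Hierarchy.** Level 2 re-partitions each top module's induced subgraph.
A sub-split is accepted only when its modularity exceeds **mean + 2 SD of
the Q the same algorithm attains on degree-preserving rewires of that
subgraph** (20 undirected double-edge-swap nulls).  A plain "Q > 0" rule
would subdivide every module, because even random dense graphs admit
partitions of mildly positive Q; matching the search against its own null
is the stopping rule this package adopts.  Modules that fail the test
contribute exactly one submodule.

**Participation coefficient.** P_i = 1 − Σ_s (k_is/k_i)² with total
(in+out) degree; an edge contributes one endpoint count per direction.
**Module diversity** p_i is the fraction of modules containing at least
one neighbour of *i* (the node's own module counts only via neighbours —
"connected to" is read literally).  Edge module diversity is the product
p_i·p_j of the endpoints.

## Hubs and rich club

The rich-club coefficient Φ(k) is the directed density E_>k/(N_>k(N_>k−1))
of the subgraph induced by nodes with total degree **strictly greater
than** k, reported wherever N_>k ≥ 2.  Φ_norm(k) divides by the ensemble
mean; per-k p-values are empirical.  The significant range is the longest
contiguous run of k with p below the threshold (0.01 by default).

Hub scores count appearances in the top ⌈0.33·N⌉ ranks on five criteria:
in-degree, out-degree, betweenness, participation (descending) and path
length L_i (ascending); nodes with score ≥ 4 are hubs.  Ties at the rank
boundary are all included — degrees are small integers and any exclusion
order would be arbitrary.  Undefined metric values rank last.  The 0.33
fraction is configurable.  The hub-set density Φ(H) is compared against
the same node-index set in every null.

## Edge analysis

Edges are classified rich-club (hub→hub), feeder-out (hub→non-hub),
feeder-in (non-hub→hub) or local; intra- vs intermodular by the top-level
partition; bidirectional iff the reverse edge exists.  Projection distance
is the Euclidean distance between region centres-of-mass (when
coordinates are available; otherwise distance and cost sections are
skipped with notice).  Wiring cost = distance × strength.  The HL ratio
divides a node's high-strength (>4) edge count by its low-strength (≤4)
count, each edge contributing to both endpoints; nodes with no
low-strength edges are flagged infinite and excluded from correlations.
Out/in-degree ratios below 0.5 mark neural sinks, above 1.5 neural
sources.  "Strong" means strength ≥ 6, "very strong" strength 7.

**Perturbation.** Each edge is removed alone and the percentage change in
L, C, global communicability and the edge's local communicability is
recorded, on the binary network (weights only bin the edges afterwards).
Removal is exact recomputation, not incremental update: ~1,400 removals ×
cheap N≈67 metrics is well within budget and far simpler to audit.
Removals that disconnect a pair are flagged; the pair then drops from L
under the reachable-pairs policy.

## Weight-class subgraphs

A^w keeps exactly the strength-w edges over the full node set.  Its
clustering, modularity, efficiency and diameter are normalized by the
means over degree-preserving rewires **of A^w itself** — "equal density
and equal degree sequence" — because each class must be judged against
its own wiring budget, not the whole network's.  Each subgraph gets its
own ensemble and seed; profiles over fewer than 3 connected nodes are
flagged insufficient, and the number of active nodes is reported so
consumers can filter noisy Q values.

## Statistics

Group contrasts use label-permutation tests on the difference of means,
two-sided by default, with the add-one p rule.  The null resampling is
canonicalized (subsets of the smaller group's size drawn from the sorted
pool), which makes `test(A, B)` and `test(B, A)` return *identical*
two-sided p-values rather than merely asymptotically equal ones.
Zero-variance pools return p = 1 with notice.  Correlations are Pearson's
r with the t-transform p (df = n − 2); no multiple-testing correction is
applied anywhere, matching the analysis this pipeline reproduces.

## Synthetic study conditions

The generator emulates a BAMS-like collation connectome; its defaults are
the study conditions and are frozen:

* 67 regions, target directed density 0.316 (the cross-module wiring rate
  p_out is *solved* from the density target, so the expectation always
  lands on it); 3 top modules containing 1/2/3 submodules
  (p_in_sub = 0.90, p_in_top = 0.40).
* 14 hubs spread across submodules, hub–hub pair density 0.85 with 94 %
  reciprocity; hub–periphery rates 0.85 (same module) / 0.50 (cross);
  background reciprocity 0.5.
* 8 planted sources and 7 sinks: their unidirectional edges orient out of
  sources / into sinks with probability 0.95, and their pairs reciprocate
  at only 0.25 — directional heterogeneity that real collation networks
  show and that a homogeneous block model lacks.
* Spatial embedding: well-separated module centres, submodule offsets,
  per-node jitter in a 10×10×10 box, so intra-module edges are short.
* Strengths: a pair-level latent score (base 4.1, −0.20 per SD of edge
  length, +0.30 intramodular, +0.40 per hub endpoint, Gaussian noise
  SD 1.7) rounded into 1–7.  **Very strong projections are modelled as
  local circuits**: the 5 nodes nearest each submodule's centroid form a
  circuit whose internal pairs draw from a tight latent centred at 7.1,
  while non-circuit pairs reach class 7 only in the far noise tail.  This
  is what gives the class-7 subgraph its strongly clustered, locally
  ordered character (normalized clustering ≫ 1, low normalized
  efficiency) — a random subsample of dense blocks would not, because
  degree-preserving nulls reproduce exactly that.  4.3 % of edges have
  their strength masked as unknown.

The latent-score coefficients were calibrated once, by simulation, to hit
the intended distance–strength correlation (≈ −0.21 on average over
seeds), the intramodular > intermodular strength contrast, and plausible
class shares (classes 1 and 7 each a few percent, class 4–6 the bulk),
and then frozen.

**What passing tests show — and what they do not.** Recovery of planted
modules (NMI ≥ 0.9), hubs (Jaccard ≥ 0.8), sources/sinks, the rich-club
significance and the weight-class profile ordering demonstrates that the
pipeline's machinery measures what it claims on data whose ground truth
is known.  It does not validate the biological claims on real data: the
generator has exact block structure, Gaussian geometry, and independent
edge sampling, whereas real connectomes have degree heterogeneity within
classes, spatially continuous parcellations, and correlated measurement
error across studies.  Real-data headline values (SW ≈ 1.16, a
significant rich-club range near 50 ≤ k ≤ 52, 14 named hubs) depend on
the specific database snapshot and are reproduced only by running the
pipeline on such an export.

## Problem sizes and determinism

Default fidelity is 1,000 rewired nulls and 10,000 permutations (the
`full` preset).  The analysis drivers and the acceptance script use 200
nulls, 2,000 permutations and 60 nulls per weight class — sizes chosen so
the full battery completes in a few minutes while keeping the add-one p
floor (1/201 ≈ 0.005) below every significance threshold used.  All
randomness flows from explicit integer seeds; regenerating any output
with the same seed is bit-identical.

## Known limitations

* Directed clustering and the hierarchy stopping rule are documented
  choices among several defensible conventions; numbers depending on them
  (e.g. submodule counts on marginal contrasts) can differ under other
  conventions.
* The exact submodule counts (1, 2, 3) are recovered reliably only when
  sub-block contrasts are strong; at the default noisy conditions the
  count for the finest module occasionally collapses by one.
* Q on near-empty weight-class subgraphs is noisy; consumers should
  filter on the reported active-node count.
* The weighted metric variants are contrast-ratio devices, not calibrated
  weighted network statistics.
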