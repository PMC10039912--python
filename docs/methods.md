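# Methods

## Problem setting

Disease-disease networks (diseasomes), drug-drug networks (drugomes) and
drug-disease networks can be built from many data types — shared genes,
variants or symptoms, shared drug targets or indications, and significant
comorbidity in patient records. If different data types carry information
about the same underlying disease mechanisms, networks built from them
should agree more than expected by chance, both globally and around
individual nodes. `netged` quantifies that agreement with a decomposable
graph edit distance (GED) under a degree-preserving permutation null, plus
shortest-path proximity statistics on heterogeneous
drug-protein-protein-disease networks.

## Network construction

* **Jaccard networks.** For an association table mapping entities to
  annotation sets `A_i`, entities *i*, *j* are connected iff
  `|A_i ∩ A_j| ≥ min_shared` (default 1), with weight
  `w_ij = |A_i ∩ A_j| / |A_i ∪ A_j|` ∈ (0, 1]. Entities with empty
  annotation sets are treated as missing data and removed before
  construction.
* **Comorbidity networks.** With `N` patients, incidences `I_i` and
  co-occurrence counts `C_ij`, the phi correlation is
  `φ_ij = (C_ij N − I_i I_j) / sqrt(I_i I_j (N − I_i)(N − I_j))` — the
  Pearson correlation of the two binary diagnosis indicators. Significance
  comes from the one-tailed Fisher exact test (upper hypergeometric tail),
  corrected with Benjamini-Hochberg across **all** unordered disease pairs
  (including never-co-occurring pairs, whose p is 1 — the conservative
  choice of testing family). An edge requires adjusted p ≤ α (default
  0.05) and φ > 0; the weight is φ. Diseases diagnosed in every patient
  have an undefined φ denominator and are excluded from testing with a
  warning.
* **Bipartite and heterogeneous networks.** Indication networks come
  directly from the drug → disease table; target-based drug-disease edges
  require a disease gene whose encoded protein is a drug target. The
  heterogeneous network joins disease-protein, protein-protein and
  drug-protein layers; it is unweighted and shortest paths are hop counts.
* **ICD-10 harmonization** truncates codes to three characters, removes the
  non-disease chapters XV, XVI, XVIII–XXII (resolved by an editable
  code-range table), then drops diseases with incidence below 5 — in that
  order, because incidence is only well-defined at the final granularity.
  The operation is idempotent and never removes patients, so `N` is stable.
* **Hierarchy pruning** (for symptom vocabularies such as HPO) removes
  annotation terms in the top *k* levels; a multi-parent term's level is
  its **minimum** depth over all root paths, which prunes conservatively
  (a term is removed only if it is shallow via some path).
* **ID mapping** expands one-to-many mappings to all targets and unions the
  annotation sets of entities that collapse onto one target; unmapped
  terms are dropped and counted, mirroring the inherently lossy nature of
  vocabulary mappings.

## Graph edit distance

Compared networks are first **aligned**: restricted to their common node
set V. With identical node sets, the optimal node map is fixed to the
identity and only edge edits remain:

    GED(G1, G2) = Σ_{uv ∈ E1∩E2} sub(uv) + Σ_{uv ∈ E1\E2} del(uv)
                + Σ_{uv ∈ E2\E1} ins(uv)

The local distance `GED(G1, G2, u)` applies the same sums to the
neighborhoods of *u*; each edge uv is seen from both endpoints, so

    GED(G1, G2) = Σ_u GED(G1, G2, u) / 2,

and cluster distances are half-sums over node subsets. The implementation
computes the global distance directly over edge sets and asserts the
decomposition identity (exact for uniform costs; absolute tolerance 1e-9
otherwise — all accumulation is double precision).

Three edge edit cost schemes:

* **uniform** — sub = 0, del = ins = 1; the global GED is `|E1 Δ E2|`;
* **weight** — per-network scores `x(uv) = w(uv) / max w`;
* **rank** — ascending weight ranks divided by the edge count, tied
  weights receiving the average rank of their block (this makes scores
  independent of edge enumeration order, which the bare sort rule is not).

For weight/rank: `sub(uv) = |x1(uv) − x2(uv)|`, `del(uv) = x1(uv)`,
`ins(uv) = x2(uv)`. Normalization is strictly per network, so the
weight-based GED is invariant to rescaling all weights of one network by a
positive constant.

## Permutation null and statistics

Each network of a pair is randomized independently by **attempted
double-edge swaps**: `(a,b),(c,d) → (a,d),(c,b)`, rejecting swaps that
would create a self-loop or parallel edge. This preserves the node set,
edge count and exact degree sequence. Weights travel with the rewired
edges (`w(a,b) → (a,d)`, `w(c,d) → (c,b)`), preserving the weight multiset
so the weight/rank schemes remain defined on rewired networks. The default
is 100 attempted swaps per edge, a standard mixing heuristic, exposed as a
parameter. Each ensemble member draws its own substream seed from
(base seed, network index, member index), so ensembles are reproducible
regardless of generation order. The swap loop is JIT-compiled (numba) with
a bit-identical pure-Python fallback.

Empirical P-values use the pseudo-count convention

    P = (1 + #{i : GED(G1,G2) ≥ GED(G1^i,G2^i)}) / (1 + B),

with B = 1000 by default, so the attainable floor is 1/(B+1); ties count
toward the numerator. The same formula applies per node (local distances)
and per cluster. A one-sided Mann-Whitney U test asks whether the original
local distances are stochastically smaller than the pooled permuted ones.
**No multiple-testing adjustment is applied anywhere**, because the
analyses draw meaning from the fraction of non-significant results, which
adjustment would inflate; every report carries an explicit
`p_values_adjusted: false` provenance flag.

MWU implementation: full permutation enumeration when `C(n1+n2, n1)` ≤
20,000 (exact under ties; covers the small-sample oracle regime); scipy's
exact U distribution for tie-free samples with pooled size ≤ 200; the
tie-corrected normal approximation with continuity correction otherwise.
Degenerate input (all values identical) returns p = 1 with a warning.

**Shortest-path proximity.** Hop distances between all node pairs of a
requested type pattern (disease-disease, drug-drug, drug-disease) present
in both the heterogeneous network and a reference network are split into
X1 (pairs that are reference edges) and X0 (all other evaluated pairs);
a one-sided MWU tests X1 < X0. Unreachable pairs are excluded from both
multisets — MWU needs finite ranks — and reported as a count.

## Synthetic data

The generators reproduce the statistical structure the analyses presume,
not the look of any real database:

* **Mechanism model** (association-table pairs): 100 entities, 10 latent
  mechanisms, one mechanism per entity per data type, disjoint annotation
  pools of size 8 per mechanism and data type, plus 2 uniformly random
  noise annotations per entity. The overlap parameter ρ is the probability
  that an entity's data-type-2 mechanism copies its data-type-1 mechanism;
  ρ = 0 makes the two tables independent given the entity identities and
  ρ = 1 with zero noise makes shared annotations coincide exactly. Disjoint
  pools make both boundary cases exact; the noise term gives edges varied
  weights and degrees, which real association data always has.
* **Comorbidity model**: disease marginals stay at their stated
  prevalences; a planted pair with relative risk RR is drawn per patient
  from the 2×2 joint distribution with P(both) = RR·p_i·p_j, which is
  feasibility-checked. Unplanted diseases are independent Bernoulli draws.
  Benchmark conditions: N = 10,000 patients, 20 diseases at prevalence
  0.05, RR = 5 for the planted pair.
* **Random networks**: uniform simple graphs with i.i.d. weights, used for
  oracle and property tests.

What the synthetic data does **not** emulate: realistic degree
distributions of curated databases, ontology-structured vocabularies,
annotation biases (well-studied diseases have more genes), or age/sex
structure in patient records. Passing benchmarks therefore demonstrates
the correctness and calibration of the machinery under its stated
assumptions, not biological conclusions about real diseasomes.

## Calibration findings and numerical choices

Measured on the mechanism model at ρ = 0 (2,000 node-level tests, B = 200):

* **weight-based costs** give approximately uniform node-level empirical
  P-values (fraction ≤ 0.05 ≈ 0.06) — this continuous statistic is the one
  the calibration benchmark uses;
* **uniform costs** are conservative (fraction ≈ 0.03): integer-valued
  local distances produce ties, which the ≥ rule counts toward the
  numerator;
* **rank-based costs** are mildly anti-conservative at the node level
  (fraction ≈ 0.11): rewiring randomizes the coupling between edge weights
  and topology, which rank scores amplify. Global-level statistics are not
  visibly affected.

The shortest-path proximity MWU is mildly anti-conservative under the null
(≈ 9% rejections at nominal 5% on the planted benchmark) because reference
edges arrive in mechanism cliques, so the evaluated pairs are not
independent. This dependence is intrinsic to the X0/X1 design and applies
equally to real data; single p-values near the threshold should be read
accordingly.

Benchmark problem sizes (200 random pairs of 50 nodes / 150 edges; B = 200
ensembles for calibration and power; 50 comorbidity replicates; 20
proximity replicates) were chosen so the full validation runs in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

* Node edit costs are out of scope: networks are always aligned first, so
  node operations never occur. The GED is therefore not a general-purpose
  graph distance.
* Rewiring treats bipartite graphs as plain simple graphs; swaps may
  introduce within-part edges. Degree sequences are still preserved.
* How weights should accompany rewired edges is a modeling choice; the
  carriage rule used here preserves the weight multiset deterministically
  but is not the only defensible option.
* The empirical P floor of 1/(B+1) limits resolution; B must be raised for
  smaller P-values.
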