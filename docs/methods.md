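# Methods

## Problem and approach

Network dismantling asks for a small set of nodes whose removal breaks a
network's largest connected component (LCC) below a target size — the
combinatorial core of targeted attack, optimal immunization, and
robustness analysis. Exact dismantling is NP-hard, so `gdismantle`
learns a heuristic: a graph attention network is trained on *optimally*
dismantled small synthetic graphs, where exhaustive enumeration is
feasible, and the learned per-node score p_n ∈ [0, 1] — interpretable
as the probability that a node belongs to a (sub-)optimal dismantling
set — then ranks nodes of arbitrary networks for a *static* attack
(scores computed once, never updated during the removals).

## Training data

Small synthetic networks (25 nodes by default) are drawn from three
generators: Barabási–Albert (preferential attachment, `m ∈ {1,2,3}`
uniform), Erdős–Rényi (`p ∈ [0.08, 0.25]` uniform), and the static
power-law model (degree exponent ∈ [2.0, 3.0], edge count 1–2 per node;
generated through igraph). Each network is dismantled exactly by brute
force: subsets are enumerated in lexicographic order by increasing
cardinality until the first cardinality k at which at least one subset
brings the LCC to at most `t = ceil(0.18 · N)` (for N = 25, t = 5); all
size-k solutions are collected. A node's label is the fraction of
optimal sets containing it, so labels lie in [0, 1] and sum exactly
to k — nodes that appear in many optimal sets are more critical, and
the regression target encodes that graded criticality.

The enumeration's inner loop is a bitmask breadth-first search with
early exit (a component is abandoned as soon as it exceeds t), roughly
two orders of magnitude faster than per-subset graph copies; only nodes
in components larger than t are enumerated, since a minimum solution
can never contain a node of an already-small component. A safety cap
(default N ≤ 30) guards against combinatorial blow-up. Disconnected
graphs are kept; when the LCC already meets the target the result is
k = 0 with the single empty set.

A second corpus family, `build_forced_corpus`, generates graphs whose
minimum dismantling set is a structurally forced singleton — stars (the
hub) and two cliques joined through a doubly-attached bridge node (the
bridge) — with node ids randomly permuted. Because the optimum is known
and unique, these families provide a transparent end-to-end recovery
check for the whole pipeline: a trained scorer must put the forced node
on top. The bridged-clique target is set to the larger clique size, the
tightest LCC target its single cut node attains; stars use the default
18%.

## Node features

Four structural descriptors per node, chosen for low cost: degree;
the chi-squared statistic of the degrees over the node's neighborhood
(with the neighbor-degree mean as the expectation:
`χ²(v) = Σ_{u∈Nb(v)} (deg(u) − d̄)² / d̄`, 0 for isolated nodes —
a heterogeneity measure that highlights nodes sitting between hubs and
periphery); the local clustering coefficient (0 for degree < 2); and
the k-core number. The exact normalization of the χ² statistic is a
design choice — the Pearson-style form above follows the clique-feature
lineage that motivated these descriptors. Features are not normalized
by default; an optional per-network min–max rescale exists behind a
flag. Any caller-supplied per-node measure can replace or extend the
built-ins (e.g. a single centrality as the only feature, to "enhance"
that centrality's attack).

## Model

The scorer is a stack of 1–4 multi-head graph-attention (GAT) layers.
Each layer is paired with a node-wise linear layer of matching width
whose output is **summed** with the attention output (a residual
connection) before the ELU nonlinearity; heads are concatenated and
every layer carries an additive bias. The final embeddings feed a 1–4
layer perceptron regressor ending in a sigmoid, which constrains p_n to
[0, 1]. Attention uses LeakyReLU with negative slope 0.2 and dropout
0.3 on the normalized attention coefficients (training only); every
node attends to its full neighborhood plus itself (no sampling), so
isolated nodes fall back to self-only aggregation and the whole map is
permutation-equivariant with an L-layer receptive field of L hops.

The network is implemented natively in numpy with hand-derived
backpropagation (gradient-checked against numerical differentiation in
the test suite); the training graphs are 25 nodes, so dense per-graph
N×N attention matrices are cheap and the implementation stays
dependency-light and deterministic.

Training minimizes the mean squared error between p_n and the
brute-force labels — the labels are rates in [0, 1] and the head is a
regressor, which makes MSE the natural choice. One graph per
optimization step (full-batch nodes), Adam with default moments at the
fixed learning rate 1e-5, 50 epochs. Initialization is Glorot uniform;
given a seed, runs are bit-for-bit reproducible. Hyperparameters are
validated against the grid: channels {5, 10, 20, 30, 40, 50}, heads
{1, 5, 10, 15, 20, 30} (concatenated), regressor widths {20, 30, 40,
50, 100}. `grid_search_select` trains each candidate configuration and
keeps the one with the lowest mean dismantling AUC on caller-supplied
validation graphs (ties: fewer removals, then earlier config). The
default shipped configuration is 3 attention layers × 30 channels × 10
heads with two 40-wide regressor layers.

## Attacks, AUC, reinsertion

A static attack visits nodes once in descending score order (ties:
ascending node id) and removes each node that currently belongs to the
LCC — nodes outside it are skipped without consuming a removal — until
`LCC ≤ ceil(target_fraction · N)`; the default target is 10% of the
network. If destroying the original LCC leaves a previously skipped
smaller component above the target (a corner case the single-pass rule
cannot fix), additional passes run until the target holds, so the
final-LCC guarantee is unconditional.

Robustness is the area under LCC(x)/N over the removal index x,
integrated with composite Simpson's rule; an odd trailing interval is
closed with the trapezoid rule, and a single point integrates to 0.
The AUC is reported unnormalized over the removal index (internal
consistency is what matters for comparisons); a normalized-by-width
variant sits behind a flag.

Greedy reinsertion then prunes the removal set a posteriori: among
removed nodes whose return keeps the LCC within target, the one whose
post-reinsertion component is smallest is restored (ties: ascending
id), repeatedly, until no single reinsertion is feasible — so the
output set is a subset of the input and maximal in that sense. On small
graphs the pruned set can never be smaller than the brute-force
optimum, a property the tests assert.

Baseline attacks rank by degree or betweenness (or their inverses,
lowest first), either statically or recomputed after every removal
(dynamic).

## Early warning

The model's own virtual dismantling defines how much damage a network
tolerates: S_o is the removal prefix up to the percolation point, and
Ω_m = Σ_{n∈S_o} p_n. Percolation is marked by the first maximum of the
second-largest component (SLCC) size — the standard percolation
indicator — rather than the 10% target; the target-based definition is
available as a mode. The baseline uses the raw virtual dismantling
without reinsertion (tolerance is about the attack trajectory, not the
pruned set).

For an arbitrary attack removing set S, Ω = min(Ω_s/Ω_m, 1) with
Ω_s = Σ_{n∈S} p_n. Ω is non-decreasing and bounded in [0, 1] by
construction; it approaches 1 quickly when structurally critical nodes
fall, long before the LCC curve shows the collapse. Ω′ is the unit-step
backward difference (Ω′(0) = Ω(0)), tracking attack intensity; PI is
the score of each removed node. The first response time is
`collapse_index − first index with Ω ≥ 0.5` — positive when the
warning is timely, negative when it comes after the collapse, undefined
if the level is never reached. SLCC of a single-component graph is 0.

Articulation-point traces record, removal after removal, the number of
cut vertices of the current graph (via biconnected components) and how
many of them lie in the not-yet-removed tail of the removal list.

## Problem sizes and test design

The test suite trains the default configuration on 500 forced-family
networks for the full 50 epochs (a few minutes on one CPU) and checks
≥ 90% top-1 recovery of the forced optimum on 50 held-out graphs. The
qualitative early-warning experiment uses a generated toy of two
20-cliques joined by a 10-node bridge path (50 nodes — the same scale
regime as training, so feature ranges stay in-distribution): a dynamic
betweenness attack must drive Ω past 0.5 strictly before the SLCC
peak, while an inverse-betweenness attack's Ω stays below it at every
equal removal count. Brute-force enumeration is cross-checked against
an independent networkx-based oracle on ensembles of graphs with
N ≤ 12 (exhaustively for N ≤ 9); articulation points are cross-checked
against igraph.

## What the synthetic data does and does not show

The generators cover heavy-tailed and homogeneous random topologies at
small size, and the forced families give unambiguous optima; they do
not reproduce the degree correlations, clustering profiles, community
structure, or scale of real infrastructure and biological networks.
Passing tests therefore demonstrate that the pipeline learns and
generalizes the structural signal present in its training distribution
and that every algorithmic contract holds — not that dismantling
performance on a particular empirical network will match any published
benchmark.

## Known limitations

- Exhaustive labeling is exponential; the corpus builder is practical
  only for ~25–30-node training graphs (the method's point: train
  small, predict large).
- The numpy network targets small graphs during training; scoring very
  large networks (≫10⁴ nodes) builds dense attention matrices per
  graph and would need a sparse implementation.
- Exact betweenness in the dynamic baseline attacks is O(N·E) per
  removal; intended for toys and mid-sized networks.
- Ω depends on a trained model; with a degenerate all-zero scorer the
  baseline Ω_m is 0 and the statistic is undefined (an explicit error).
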