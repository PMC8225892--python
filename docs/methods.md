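# Methods

This note records the models implemented in `genenet`, the conventions and
numerical choices behind them, what the built-in generators do and do not
emulate, and the package's known limitations.

## Pattern algebra and graph conventions

Barcodes are integers `0 .. 2^b − 1` with the leftmost character of the
string form as bit 1 (most significant), so lexicographic order of the
fixed-width strings equals numeric order.  A pattern is stored as a pair
of bitmasks (active positions, required values); membership is the single
comparison `(code & mask) == bits`, and the meet of two patterns is a mask
union unless two fixed bits disagree, in which case the member sets are
disjoint.  Enumeration is guarded at `b ≤ 24`.

Graphs are directed at the base level — a rule reads source → destination —
and a multigraph: each ordered pair carries the number of rules covering
it.  Self-loops arise whenever a rule's two member sets overlap and are
kept in the multigraph.  All component, density, degree and attack
analyses operate on one fixed derived view: symmetrized, deduplicated,
self-loops removed.  Empirical density is unique undirected non-loop edges
over `C(N, 2)`.  This convention is forced by the RG density derivation,
whose exponent `2r` counts rule *sides* — a node pair is linked if either
orientation of any rule covers it — and it is applied uniformly so that
simulated and analytic quantities are always commensurable.

`unique_link_count` has two independent routes: materializing the union of
expansions, and inclusion–exclusion over rule subsets with sources and
destinations intersected separately (the biclique structure factorizes
each intersection term into a member-count product).  The second route is
exponential in the number of rules and intended for small rule sets; the
tests use the pair as a cross-check.

## Topology heuristics

* **Scale-free.**  Variant 1 emits `b + 1` rules `(0^(b−i) X^i) O
  (X^(b−i) 0^i)`, i = 0..b.  The nested member sets make the union's
  degree sequence exact: one node of degree `2^b` and `2^(j−1)` nodes of
  degree `2^(b−j)`, the finite-size form of `p(k) = 0.5 k^-1` for both
  in- and out-degree.  Variants 2 and 3 widen the source sets by two or
  three `X`s per step while destinations shrink one at a time
  (`b/2 + 1` and `b/3 + 1` rules).  With the stated source → destination
  edge direction this places the steep `k^-2` / `k^-3` law on the
  out-degree (source-side) distribution and the shallow `k^-1/2` /
  `k^-1/3` branch on the in-degree; the slope tests measure the
  source-side sequence.
* **Feed-forward.**  Layer identities are caller-supplied patterns with
  pairwise-disjoint member sets (validated, naming the first shared
  barcode); L layers chain into L − 1 rules, each rule's destination being
  the next rule's source.  No layer-sizing scheme is imposed.
* **Binary tree.**  A FIFO buffer seeded with the root `0^(b−1) 1`; each
  dequeued barcode emits `(barcode) O (drop-first-bit · X)` and enqueues
  its two children until barcodes starting with 1 (the leaves) are
  reached: `2^(b−1) − 1` rules over the `2^b − 1` non-zero barcodes.  The
  algorithm is the specification; the resulting graph is verified to be a
  rooted complete binary tree.
* **Hierarchical.**  Depth `d` uses `b = 3d` bits read as `d` groups,
  outermost first; within a group, `000` is the center and `1XX` the
  four peripheral positions, giving the `5^d`-node universe.  Each of the
  `5^(d−1)` valid prefixes gets a clique-forming rule pair
  (periphery–periphery and periphery–center), and each level `ℓ = 1..d−1`
  adds `5^(d−1−ℓ)` rules attaching the (ℓ+1)-fold peripheral nodes of a
  block to its center.  The depth parameter counts 3-bit groups: `d = 2`
  is the 25-node module with 5 clique groups and 1 top rule.  The
  `strict`/`collapsed` mode flag names one and the same construction; it
  exists so topology tests state explicitly which construction they
  assert.
* **Homophily.**  Overlap `o` emits `(p)O(p)` for every pattern with
  exactly `o` fixed positions (`C(b,o)·2^o` rules); in the simple
  undirected view this is exactly the Hamming-threshold graph
  `edge(u,v) ⇔ Hamming(u,v) ≤ b − o`, checked against a brute-force
  oracle.

## The random genetic model

Each rule side places its `x` passive bits on a uniformly random size-`x`
subset of the `b` positions (independently per side and per rule) and
draws the active bits as fair coins; rules are sampled with replacement.
Two samplers share this law: a `Pattern`-level one for inspectable rule
sets and a vectorized one used by the Monte-Carlo estimators (members are
generated by depositing counter bits into per-rule passive positions, so
cost scales with the edge count `r · 4^x`).

Analytics, with `π = 2^(x−b)` and `N = 2^b`:

* density `ρ = 1 − (1 − π²)^(2r)`;
* degree law `P(k) = Σ_{r_i} Binom(2r, π)(r_i) · Binom(N, q(r_i))(k)`
  with `q = 1 − (1 − π)^{r_i}` — the conditional binomial is used with
  `N` (not `N − 1`) trials, a discrepancy far below any tolerance used;
* critical rule counts: mean degree one,
  `r = log(1 − 2^−b) / (2 log(1 − 2^{2(x−b)}))`, and node coverage,
  `r = 2^{b−x−1}`;
* saturation forms treating rule draws with replacement — density over the
  pool of `2^{b−x−1}(2^{b−x} − 1)` set pairs, LCC/N and #CC/N over the
  `2^{b−x}` sets with exponent `2r` (the two fractions sum to one by
  construction, and all three depend on `b − x` only);
* rule count for a target mean degree, with its two limits: `b − x`
  constant gives `r ∝ ⟨k⟩/N` (rule bicliques grow as `N²`), and
  `b − x ≫ 1` gives `r = ⟨k⟩N / 2^{2x+1}`.

The degree mixture treats rule overlap only through `q`, so it is smooth
while the simulated law is a staircase: a node that joins one rule side
acquires ≈ `2^x` links at once, concentrating mass just above multiples of
`2^x`.  Means agree to a fraction of a percent across regimes, and the
CCDFs converge as overlaps proliferate, but in absolute terms the
staircase risers keep the sup-distance between predicted and simulated
CCDFs near 0.1 even in the connected regime — the smoothness limitation
is inherent to the approximation, not a sampling artifact, and the test
suite records it.

Monte-Carlo defaults follow the study conditions: density sweeps average
20 seeded draws per parameter point, degree histograms pool runs in the
hundreds, and component statistics come from `scipy.sparse.csgraph` on the
touched-node subgraph.  Phase scans spawn one child generator per grid
cell from a single `SeedSequence`, so cells are independently reproducible.

## Set-level mapping

`SetLevelGraph` holds per-set sizes and an undirected edge list with
self-loops allowed; expansion replaces a set edge by the full biclique and
a set self-loop by the clique-with-loops on that set.  Density analytics
include self-loop slots in both denominators (set level:
`ρ = 2R / (2^{b−x}(1 + 2^{b−x}))`; node level with `N = 2^b`,
`L = R·4^x`), and their exact ratio tends to one when `2^b` and `2^{b−x}`
are both large — the mapping preserves density, a conclusion that does not
depend on the loop convention.  The constant-size degree law lives on
multiples of `2^x` (a node's degree is `2^x` times its set's degree);
variable sizes give `⟨K⟩ = ⟨k⟩⟨s⟩`,
`var(K) = ⟨k⟩var(s) + ⟨s⟩²var(k)`, hence Fano factor `⟨s²⟩/⟨s⟩` at a
Poisson set level, and the full mixture pmf is computed by exact k-fold
convolution of the size distribution (feasible because set-level degrees
are small; the moments are the primary surface).

The set-level sampler has two modes: exactly-R edges, and Bernoulli
`G(n, p)`.  The degree-law predictions assume independent edges, so
distribution-shape tests use the Bernoulli mode (a fixed edge count
underdisperses set degrees detectably at ~10⁴ samples); density
comparisons are insensitive to the choice.

## Operator formalism

A label's weight row is `+1 / −1 / 0` for required-on / required-off /
passive bits, with offset `d = b + 1 − (#required-on)`; since inputs are
binary and weights bounded by one, a score of `b + 1` is reachable only by
exact matches, so the indicator `f(z) = [z = b+1]` reproduces pattern
matching with no false positives.  A rule set becomes the deduplicated
label list plus a binary interaction matrix `O`, and
`B = H(L O Lᵀ)` with strict Heaviside (`H(0) = 0`) equals the simple
directed adjacency of the expanded rule set — asserted exhaustively on
small spaces and on random rule sets.  Node expression vectors are the raw
barcode bits; no sparse recoding is applied.

## Robustness

Attacks remove nodes one at a time.  `random` draws a uniform permutation;
`targeted` removes the current highest-degree node with degrees recomputed
after every removal, implemented with a lazy-deletion heap whose ordering
breaks degree ties toward the smallest node label, making the greedy
attack deterministic and replayable.  Traces record the LCC relative
to the initial giant component; by default after every removal (the LCC is
recomputed only when the removed node belonged to it, since removals
elsewhere cannot change it), or only at caller-given removal fractions on
dense graphs where per-step recomputation would dominate.  ER baselines
are `G(n, p)` with `p` set to the symmetrized simple density of the graph
under comparison.

The headline contrasts are directional: over 100 paired runs per
parameter set, targeted attacks leave RG networks with a lower median
relative LCC than density-matched ER networks at 10% removal, and in the
sparse regime random attacks shrink RG giant components gradually (unions
of dense bicliques) while ER giant components are tree-like and lose large
fractions to single cut vertices — compared through the largest
single-removal drop per trace.

## What the generators do and do not emulate

The samplers produce the idealized study conditions: exact biclique
expansion, exactly `x` passive bits per rule side, uniform barcode usage,
and deterministic link realization.  Real identity-based systems deviate
in ways the package deliberately does not model: per-bit wildcard
probabilities, sparsity-biased barcodes, probabilistic realization of a
rule's links, and preference-weighted link formation are all out of scope,
as are non-binary or variable-length identity alphabets and edge-removal
(bond) percolation.  Passing tests therefore certify the combinatorics and
the analytic companion under the stated assumptions, not fidelity to any
particular measured connectome.

## Problem sizes and tolerances

Exact checks (worked examples, oracle equivalences, degree sequences) run
on full enumerations at `b ≤ 12`.  Stochastic checks use: density sweeps
at `b = 12` with 20 draws per point (3% relative); degree CCDFs at
`b = 11` pooling 200 draws; phase structure at `b = 11` with 10–30 draws
per grid cell (the N/2 crossing located by linear interpolation between
grid points and required to fall between the two critical rule counts);
robustness with 100 paired runs per condition.  Component statistics treat
an edgeless graph as having LCC 1 and `N` components, zero of which
contain a linked node.
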