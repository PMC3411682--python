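# Methods

## Model and scope

`netcascade` operates on simple undirected binary graphs. Edge lists are
the only input format: the first two whitespace-separated tokens of each
line are node labels, so labels cannot contain whitespace; `#` lines are
comments; extra columns (e.g. weights) are ignored with a warning so
weighted lists degrade gracefully to binary. Self-loops are removed and
duplicate or reversed-duplicate lines collapse to one edge; the parse
report accounts for every input line
(`input_lines = retained + loops + duplicates + skipped`). Because an
edge list cannot express a degree-0 node, input isolates are
unrepresentable by construction; isolated nodes can only arise *during*
analysis, as secondary extinctions. Directed edges, edge weights,
partial knock-downs and node/edge addition are out of scope.

The declared network type (`ppi`, `genetic`, `ecological_bipartite`, …)
is metadata only; no algorithm branches on it.

## Topology conventions

- **Density** `2|E| / (|V|(|V|−1))` for ≥ 2 nodes, defined as 0 below;
  **average degree** `2|E| / |V|`.
- **Average path length** is the mean shortest-path distance over
  *connected ordered pairs only*; with no connected pair it is NaN. The
  `|V|`-substitution for unreachable pairs is applied **only** in
  closeness, where that convention is defined, never in the average path
  length.
- **Closeness** `(|V|−1) / Σ_i d'(v,i)` with `d'(v,i) = |V|` for
  unreachable `i`; an isolated node therefore scores exactly `1/|V|`.
  Undefined (an error) on single-node networks.
- **Betweenness** is unnormalised, counts each unordered pair once,
  excludes the endpoints, and lets pairs with no connecting path
  contribute 0. These choices make the undirected star hub score exactly
  `n(n−1)/2`. The Brandes algorithm (networkx, `normalized=False`)
  implements precisely this sum; the test suite verifies it against an
  independent matrix-power oracle on every connected graph with ≤ 6
  nodes.
- **Eigenvector centrality** is the principal eigenvector of the 0/1
  adjacency matrix, computed by power iteration from the uniform positive
  vector and rescaled so the maximum entry is 1 (max-normalisation keeps
  the closed forms clean: star leaf/hub ratio `1/√n`, complete graphs all
  1). Numerical choice: iteration uses the shifted matrix `A + I`, which
  has the same eigenvectors with all eigenvalues moved by +1 — plain
  iteration on `A` oscillates with period 2 on bipartite graphs and never
  converges. Convergence is declared when successive max-normalised
  iterates differ by < `tol` (default 1e-10) in max norm, within
  `max_iter` (default 10000) steps; non-convergence raises an error
  carrying the last iterate. On disconnected graphs the iteration
  localises on the component with the largest spectral radius (the +1
  shift preserves the ordering); other components decay to ~0.
- **Connected components** are labelled 1..k in decreasing size, ties
  broken by smallest member label — a total order that makes component
  colouring and CSVs deterministic.

## Perturbation semantics

A perturbation event removes all its targets *simultaneously*;
secondaries are evaluated once, afterwards. Secondary extinction is
exactly "degree fell to 0": one round suffices, because removing an
already-isolated node cannot isolate anyone else. Secondaries are
removed from the remaining network (they are non-functional), so all
after-summaries describe the functional sub-network and the remainder
never contains isolates. Node conservation
(`|before| = |remaining| + |primaries| + |secondaries|`) holds for every
node perturbation. When an edge perturbation strips an unnamed node of
all its interactions, that node is a secondary, never a primary. Group
size is unlimited.

## Cascades

Sequential cascades remove one primary per step. The default ranking is
**static** — nodes sorted once by initial degree, descending or
ascending, and removed in that order — with **dynamic** re-ranking after
every removal available as an option, since the attack-tolerance
literature uses both. Ties are always broken lexicographically by label.
Ranked nodes that already vanished as secondaries are skipped without
consuming a step, and the percentage axis counts realised primary
removals over the original node count. Random order is a Fisher–Yates
shuffle of the label-sorted node list driven by numpy's seeded
`default_rng`; replicate *r* uses `seed + (r − 1)`, and the realised
permutation is recorded on each curve (and in the run manifest) for
auditability. Collapse is the first step after which no functional node
remains; curves truncated by `max_steps` may report no collapse.

Per-step summaries honour `recorded_metrics`: the all-pairs BFS behind
`avg_path_length` dominates run time on large graphs, so cascades that
only trace size/connectivity skip it.

## Synthetic fixtures

The generators supply the structural motifs the analyses assume, with no
external data: `star` (single point of failure), `path`, `complete`,
`erdos_renyi(n, p, seed)` (isolated nodes dropped to stay edge-list
representable), `barabasi_albert(n, m, seed)` (scale-free hubs),
`bipartite_web(n_rows, n_cols, connectance, seed)` (two-class
interaction web, every row and column guaranteed ≥ 1 interaction) and
`two_modules_bridge(k)` (a low-degree connector whose removal splits two
cliques). The preferential-attachment variant is documented because
variants differ: the seed graph is an (m+1)-clique and each arrival
attaches to m *distinct* nodes with probability proportional to current
degree, fixing the edge count at `C(m+1,2) + m(n−m−1)`. All generators
are bit-deterministic in their seed.

These fixtures reproduce hub dominance, two-class structure and module
connectors, but not features of real interactomes or food webs such as
degree correlations, clustering hierarchies or empirical connectance
patterns — so passing tests demonstrate correctness of the simulation
machinery, not conclusions about any particular real network.

## Problem sizes and defaults

The attack-tolerance property — generalist-first cascades collapse
earlier than specialist-first ones — is checked on
Barabási–Albert(n=200, m=2) networks over 50 seeds, a size at which the
scale-free contrast is unambiguous while a full double cascade takes
well under a second; the acceptance script reports the fraction of seeds
(in percent) where descending collapse precedes ascending, with the mean
collapse steps of both regimes. Conservation is checked on 50 mixed
ER/BA fixtures of 30 nodes across all ranking modes. Exhaustive
centrality validation covers every connected labelled graph with ≤ 6
nodes (27 475 graphs) plus 100 random ≤ 8-node graphs against a
matrix-power brute-force oracle.

## Known limitations

- Rendering (Fruchterman–Reingold via networkx `spring_layout`) is
  best-effort and not bit-reproducible; all scientific content lives in
  the CSVs, which are byte-stable for fixed inputs and seeds.
- Rankings by betweenness/closeness/eigenvector are not exposed; degree
  is the ranking property.
- Eigenvector centrality requires at least one edge and is meaningful
  per dominant component only on disconnected graphs.
- The empirical examples that motivate the behavioural contracts (a
  food web of 219 species and 812 interactions, pollinator webs) are not
  shipped; their published dimensions appear only as analytic identities
  (average degree 2·812/219 ≈ 7.4) that any graph with those dimensions
  satisfies.
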