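# netcascade

Perturbation and co-extinction cascade analysis for undirected networks.

Many real-world systems — protein–protein interaction maps, genetic and
metabolic networks, plant–pollinator webs, social networks — share a
"robust, yet fragile" architecture: they tolerate random losses well but
can disintegrate quickly when their most connected members are attacked.
`netcascade` simulates such disturbances on any binary undirected network
and quantifies the damage at every step, for researchers who need to
identify the nodes critical to a system's integrity or to compare how
alternative extinction sequences unfold.

## The model

A network is a simple undirected graph *G = (V, E)*: no self-loops, no
duplicate edges, no weights or directions. A **primary extinction** is
the deliberate removal of one or more nodes (with their incident edges)
or of individual edges. Any surviving node thereby left with degree 0
has lost its entire support to the remaining sub-network: it is counted
as a **secondary extinction** (co-extinction) and removed from the
functional remainder as well. Perturbations can be applied

- **singly or in clusters** — a group of nodes/edges removed
  simultaneously, with secondaries evaluated once for the whole event;
- **sequentially** — one node per step, ranked by degree from generalists
  (highest degree) to specialists or vice versa, or in a seeded random
  shuffle, re-analysing the reduced network after every removal until
  **complete collapse** (no linked node remains);
- as a **leave-one-out scan** — every node removed in turn from a fresh
  copy, producing one comparable row per node.

At each state the package reports the standard global indicators
(size *S{G}*, density *2|E| / (|V|(|V|−1))*, average degree
*K{G} = Σk(i)/S{G}*, average shortest-path length, component structure)
and four per-node centralities: degree *k(i) = |N(i)|*, shortest-path
betweenness (unnormalised, each unordered pair counted once), closeness
*(|V|−1)/Σ d(v,i)* with *|V|* substituted for unreachable pairs, and
eigenvector centrality (principal eigenvector of the adjacency matrix,
rescaled to maximum 1). Sequential runs yield **co-extinction curves**
— any indicator traced against the percentage of primary removals —
which can be aligned and compared across extinction sequences.

## Worked example

Input is a plain-text edge list, one interaction per line, two
whitespace-separated labels (loops are dropped, duplicates collapse):

```python
from netcascade import (CascadeSpec, parse_edge_list, remove_nodes,
                        run_cascade, summarize, curve_to_csv)

text = ("ntrk1 grb2\nntrk1 shc1\nntrk1 plcg1\ngrb2 sos1\n"
        "shc1 grb2\nplcg1 prkca\nprkca raf1\nsos1 hras\n")
net, report = parse_edge_list(text, net_type="ppi")
s = summarize(net)
print(net.size, net.edge_count, round(s.density, 3), round(s.avg_path_length, 2))
# 8 8 0.286 2.57

res = remove_nodes(net, ["ntrk1"])          # single targeted perturbation
print(sorted(res.secondaries), res.after.component_sizes)
# [] (4, 3)            <- no co-extinctions, but the network fragments in two

curve = run_cascade(net, CascadeSpec(order="descending"))  # generalists first
print(curve_to_csv(curve))
```

```
step,primary,n_secondaries,cumulative_secondaries,remaining_size,pct_removed,density,avg_degree,avg_path_length,n_components
1,grb2,0,0,7,12.5,0.2380952381,1.428571429,1.909090909,2
2,ntrk1,1,1,5,25,0.3,1.2,1.25,2
3,plcg1,0,1,4,37.5,0.3333333333,1,1,2
4,prkca,1,2,2,50,1,1,1,1
5,sos1,1,3,0,62.5,0,0,,0
```

Reading the trace: removing the best-connected protein fragments the
network immediately (two components after step 1); by step 5 every
remaining node has lost its support and the network has completely
collapsed after only 5 of 8 possible primary removals (62.5% node loss),
with 3 secondary extinctions along the way.

The same analyses are available from the shell — `netcascade stats`,
`metrics`, `render`, `perturb`, `cascade`, `scan`, `fixture`, `compare` —
each writing fixed-layout CSVs, a run manifest, and (for `render`) a
component-coloured Fruchterman–Reingold drawing:

```bash
netcascade fixture --kind barabasi_albert --n 200 --m 2 --seed 1 --out ba.txt
netcascade cascade ba.txt --order descending --out results/
```

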