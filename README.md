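# vcsrnet

Versioned compressed-sparse-row storage, composition and proximity querying
of context-specific biological networks.

## The problem

Biological interaction data is increasingly context-specific: a protein
interactome filtered per tissue, eQTL catalogues per tissue, disease
ontologies and gene–disease associations shared across all contexts.  These
networks are *versions* of each other — a tissue-specific PPI network is
mostly the generic interactome plus a small residual — yet analyses that
compare or combine contexts usually rebuild and store each integrated
network separately, which is wasteful in both memory and time: the number of
useful combinations (any subset of tissues, by union or intersection) is
exponential in the number of contexts.

`vcsrnet` stores an entire family of overlapping network versions in a
single compressed structure, composes any combination of versions at query
time, and answers random-walk-with-restart (RWR) proximity queries — e.g.
"which disease phenotypes are closest to this genomic locus in liver *and*
pancreas?" — on the composed network.  It is aimed at systems-biology
tooling that serves many network variants from one in-memory store.

## The data structure

A standard CSR matrix keeps a weight array `A`, a column-index array `JA`
and a row-offset array `IA` with `adj_i = JA[IA[i] .. IA[i+1]-1]`.
`vcsrnet` extends this to a **version tree**: each node is a network version
obtained from its parent by adding edges, and the network at a node is the
cumulative edge set along its root path.  All versions share one `A`/`JA`
pair — ancestral edges are never re-stored — while each version owns a
segment of an *augmented IA array* delimited by an offset array `D`
(`IA^(d) = IA[D[d] .. D[d+1]-1]`).  An augmented entry is a 4-tuple
`(e0, e1, e2, e3)` with a 2-bit type flag in the low bits of `e3`:

* **N (normal)** — one `JA` segment: offset `e0`, length `e1`;
* **S (split)** — two `JA` segments, `(e0, e1)` and `(e2, e3>>2)`, merged on
  read, letting a child reuse the parent's adjacency and append only its new
  edges;
* **C (compressed row set)** — a run of `e1` entries copied verbatim from
  the version's *key-frame* segment starting at absolute index `e0`.

When a vertex with a split row gains `t` more edges, the row is either split
again (old second segment merged with the new edges and re-appended) or, if
the prospective second segment would reach the first (`e3 + t >= e1`),
*joined* back into a single normal row.  The join keeps duplication across a
chain of versions near `O(r log l)` instead of the `Theta(r l)` cost of
storing every version's adjacency separately.  Unchanged runs of row
descriptors are collapsed into `C` entries against a key-frame version
(array `K`); a new version whose segment no longer compresses well (ratio
above the threshold `h`, default 0.5) becomes its own key-frame, so
decompression never chases more than one hop and row access is independent
of tree depth.

## Composition and proximity

* **Vertical integration** materializes one version as a plain CSR matrix
  (optionally pruned to the part reachable from the query seeds).
* **Horizontal integration** combines sibling versions (tissues) by edge
  union or intersection.  One pass over the row descriptors partitions
  vertices into `S_p` (descriptors bitwise identical in every composed
  version — gathered from a single version) and `S_n` (gathered from each of
  the `b` versions), so composing `b` versions costs `O(bE)`.
* **Proximity** solves `x = (1 - a) W x + a r` where `W` is the
  column-stochastic matrix of the composed network, `r` the seed indicator
  and `a` the restart probability.  Besides plain power iteration (error
  factor `1 - a` per step) a Chebyshev semi-iterative solver reaches the
  same fixed point with asymptotic factor
  `mu(a) = 2(1-a)/(2 + sqrt(2a - a^2)) < 1 - a`
  (at the default `a = 0.05`: `mu = 0.822` vs `0.95`, about 5x fewer
  iterations on slowly-mixing networks).

## Worked example

Generate a small synthetic 3-tissue family, build the store, inspect it and
run a proximity query from protein `P0001` over the union of two tissues:

```text
$ vcsrnet generate --out-dir layers --k 3 --seed 7
wrote layers/manifest.json (3 tissues)

$ vcsrnet build --manifest layers/manifest.json --out fam.vcsr
wrote fam.vcsr: 9 versions, 498 vertices (deepest version)

$ vcsrnet stats --graph fam.vcsr
versions            9
len(A)              5234
len(JA)             5234
len(IA)             2699
bytes (versioned)   170408
bytes (separate)    436904
compression ratio   2.564x
  v0   ontology     ontology
  v1   association  associations
  v2   genericPPI   generic-ppi
  v3   tissuePPI    ppi-adipose
  ...

$ vcsrnet query --graph fam.vcsr --layers GD,GA,GP \
    --tissues adipose,amygdala --mode union --seeds P0001 \
    --kind disease --out ranked.tsv
wrote ranked.tsv: 100 vertices ranked (chebyshev, 87 iterations)

$ head -4 ranked.tsv
# label	kind	score	rank
D0087	disease	0.002034191967462844	1
D0015	disease	0.0019827399828891757	2
D0019	disease	0.0015336837859541556	3
```

The 9 versions (ontology, +associations, +generic PPI core, one residual-PPI
and one eQTL version per tissue) occupy 2.56x less space than storing each
version as its own CSR matrix.  The query composes the two tissue versions
by edge union, column-normalizes the result and ranks disease vertices by
their RWR proximity to the seed protein; scores sum to the number of seeds,
so individual values are small.

The same pipeline is available as a library:

```python
from vcsrnet import (FamilyParams, generate_family, build_version_tree,
                     QuerySpec, resolve_query, column_stochastic,
                     restart_vector, rwr_chebyshev, rank_vertices)

inputs = generate_family(FamilyParams(k=3, seed=7))
g, meta, registry = build_version_tree(inputs)
spec = QuerySpec(layers=("GD", "GA", "GP"), tissues=("adipose", "amygdala"),
                 mode="union", seeds=("P0001",))
net, seeds = resolve_query(g, meta, registry, spec)
pv = rwr_chebyshev(column_stochastic(net), restart_vector(seeds, net.n_vertices))
pv.vertex_ids = net.vertex_ids
print(rank_vertices(pv, registry, kind_filter="disease")[:3])
```

## Layout

```
src/vcsrnet/core.py       versioned CSR store (augmented IA, split/join,
                          key-framed compression)
src/vcsrnet/builder.py    layered inputs -> heterogeneous version tree
src/vcsrnet/integrate.py  extraction, S_p/S_n partition, union/intersection
src/vcsrnet/proximity.py  column-stochastic RWR, power + Chebyshev solvers
src/vcsrnet/synthetic.py  deterministic layered-family generators
src/vcsrnet/io.py         TSV edge lists, manifests, binary container
src/vcsrnet/cli.py        generate / build / add-version / extract /
                          compose / query / stats
docs/methods.md           models, parameters, numerical choices, limitations
```
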