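# Methods

This note records the models implemented by `vcsrnet`, the parameters that
matter, the numerical and design choices made where the design was open, and
what the synthetic generators do and do not emulate.

## 1. The versioned store

### Model

A *version tree* represents a family of undirected, weighted networks.  The
root holds a base edge set; every other node adds edges to its parent, and
the network of a node is the cumulative union along its root path.  Contexts
with the same semantics (tissues) sit on sibling branches; heterogeneous
layers (ontology, associations, PPI, eQTL) stack additively along a path.
The structure is strictly additive: re-adding or re-weighting an edge that
exists in the parent is rejected, and edge deletion is unsupported (a
deletion-bearing variant would have to re-root from a filtered edge list).
This keeps shared storage immutable — ancestor reads are bit-stable under
any later addition, which is also what makes concurrent readers safe.

### Row maintenance (split/join)

Each version owns a segment of the augmented `IA` array; a row descriptor is
either *normal* (one `JA` segment), *split* (two segments, merged on read)
or a *compressed row set*.  When a vertex with a split row gains `t` edges,
the second segment is merged with the new edges and re-appended, unless the
prospective second segment would be at least as long as the first
(`e3 + t >= e1`), in which case the full adjacency is re-appended as a
single normal row ("join").  The join threshold makes the first segment at
least double at every join, so joins are logarithmic in the number of
updates to a row.  On the adversarial workload — one vertex receiving one
new neighbor in each of `l = 256` chained versions — the structure stores
8 511 `JA` slots for that row versus 32 641 without the join (and a bound of
`4 r (1 + log2 l) = 9 216`).  Exact simulation shows the plain
merge-and-copy maintenance is still quadratic in `l` asymptotically; the
join rule improves the constant by ~4x, which keeps the stated bound over
the tested range (`l <= 256`) but would not indefinitely.  We deliberately
did not add capacity-reservation tricks to chase the asymptotic bound: they
complicate the append-only layout for a regime (hundreds of chained updates
to a single row) that layered biological families do not produce.

Split rows never have more than two segments, so any row read costs one
descriptor fetch (two `IA` reads when the descriptor lives in a compressed
row set) and at most two contiguous `JA` range reads, independent of the
version's depth — the property that keeps query latency flat as the tree
grows.  Both segments are kept individually sorted; reads perform a linear
two-way merge.

### IA compression and key-framing

A child version's descriptor segment is compared entry-by-entry with its
key-frame's segment; maximal runs (length >= 2) of bitwise-identical entries
are replaced by single `C` entries pointing at the key-frame's `IA` range.
Key-frame segments contain no `C` entries, and `C` entries only ever point
into the version's own key-frame segment, so decompression is a single pass
with one-hop resolution.  After building a child's segment, the achieved
ratio (compressed length / uncompressed length) is compared with the
threshold `h in (0, 1]`: at or below `h` the compressed segment is stored
and the child inherits its parent's key-frame; above `h` the uncompressed
segment is stored and the child becomes its own key-frame.  `h` defaults to
0.5 — store compressed only if it at least halves the segment — and is
exposed on every build entry point; nothing in the test suite is sensitive
to moderate changes of `h` because compression is exactly invertible by
construction.

Runs of length 1 are never replaced: a `C` entry is as large as the entry it
would replace, and keeping the literal entry lets the common
"single changed row between two long runs" pattern stay maximally legible.

### Storage accounting

`storage_stats` prices the declared field widths: 8-byte weights and
indices, 32-byte augmented `IA` entries, and compares against storing every
version as its own standard CSR (two 8-byte arrays of length `2E` plus a
`V+1` offset array).  On the default 19-tissue synthetic family the
versioned layout is ~3.6x smaller; the ratio grows with the shared-core
fraction and with the number of versions.

## 2. Building the heterogeneous tree

Tissue PPI layers are factored through their intersection: the generic core
`E_P = intersection of all E_P^(i)` becomes one shared version, each tissue
stores only its residual `E_P^(i) \ E_P`, and eQTL layers hang off their
tissue's PPI version — `3 + 2k` versions for `k` tissues.  A residual edge
carried by several (but not all) tissues is stored once per carrying branch;
this duplication is the price of the tree shape and is measured, not hidden.

Vertex identity lives in a single global registry (dense indices, one
immutable kind per label: disease / protein / locus).  Kinds are inferred
from layer membership — ontology endpoints are diseases, PPI endpoints
proteins — and bipartite layers use known endpoints to fix orientation,
falling back to the documented column convention (association rows
`protein<TAB>disease`, eQTL rows `locus<TAB>protein`) when both endpoints
are new.  Mis-typed edges (e.g. a protein–protein "association") are
rejected at registry or indexing time.  Tissue order is sorted by name, so
version numbering is deterministic.  Gene–disease associations are treated
as fully generic (not tissue-filtered); new vertices introduced by a version
(eQTL loci) enter as degree-0 normal rows before edge placement.

## 3. Composition

`S_p`/`S_n` partitioning compares *decompressed descriptors bitwise*.  This
is conservative: two versions that store the same adjacency at different
offsets land in `S_n` and are simply gathered per-version — a speed cost,
never a correctness one.  Only same-depth versions may be composed (sibling
tissue versions, or sibling eQTL leaves); mixing depths would silently
compare networks with different shared prefixes and is rejected.

Union weights default to the per-edge maximum, intersection to the minimum.
Both reducers are order-insensitive and idempotent on duplicated identical
values, which makes composed outputs byte-identical under any permutation of
the version list.  Custom reducers are accepted but should preserve those
two properties; a non-idempotent reducer (e.g. `sum`) would interact with
the `S_p` single-pass optimization.

Seed-reachability pruning is applied *after* composition, on the composed
network: pruning per-version first could discard vertices that become
reachable only through another composed version's edges.

## 4. Random-walk proximity

The proximity of vertex `v` to seed set `Q` is the fixed point of
`x = (1-a) W x + a r`, with `W` the column-stochastic matrix (each nonzero
column of the weighted adjacency divided by its sum), `r` the 0/1 seed
indicator and `a` the restart probability.

Parameters and defaults:

* `a = 0.05` — a diffusive, global search; larger `a` localizes mass on the
  seeds (monotonically, which the tests check).
* `eps = 1e-12` — stopping threshold on the iterate step `||x_{t+1} - x_t||`,
  L2 by default (configurable to L1/Linf).
* `max_iter = 100000` — exhausting it raises an error carrying the last
  residual rather than returning a silently unconverged vector.

Dangling (degree-0) columns are left as zero columns; no teleportation
fix-up is applied.  Mass then leaks at each step, but the iteration operator
still has norm at most `1 - a`, so convergence is unaffected; with no
dangling columns the solution mass is exactly `|Q|`.  The output is not
renormalized — downstream consumers use the ranking, and ties are broken by
label for determinism.

### Chebyshev acceleration

The accelerated solver applies the classical Chebyshev semi-iterative
recurrence to the splitting above with spectral-radius bound `rho = 1 - a`:

    w_1 = 1,  w_{t+1} = 1 / (1 - rho^2 w_t / 4)
    y_{t+1} = w_{t+1} ((1-a) W y_t + a r - y_{t-1}) + y_{t-1}

from `y_0 = 0`, `y_1 = r`.  Its asymptotic factor
`mu(a) = 2(1-a)/(2 + sqrt(2a - a^2))` is strictly below `1 - a` for all
`a in (0, 1)`; at `a = 0.05`, `mu = 0.822` vs `0.95`.  Acceptance of the
solver is defined by fixed-point agreement with the power iteration and the
dense solve plus the iteration-count advantage — not by matching any
particular published recurrence symbol-for-symbol, since startup conventions
for the `w` sequence differ across the literature.

One practical caveat the tests encode explicitly: the speedup is guaranteed
relative to the *worst-case* power rate `1 - a`.  On fast-mixing graphs
(small second eigenvalue) the power iteration's observed rate is
`(1-a) |lambda_2|` and can beat the Chebyshev schedule, which is tuned to
the bound `1 - a`.  Large biological networks — rings of tissue, ontology
trees coupled through sparse bipartite layers — are slowly mixing
(`|lambda_2|` near 1), which is exactly where the acceleration pays off; the
speedup fixtures are therefore slow-mixing by construction (ring-with-chords
and layered family networks), while fast-mixing random graphs are used only
for fixed-point agreement checks.

A related subtlety: with column normalization and very small `a`, a
high-degree hub adjacent to the seed can legitimately outrank the seed
itself (on the 3-path with seed at an endpoint this happens already at
`a = 0.05`); ranking examples in the tests use `a = 0.5` where the seed's
locality dominates.

## 5. Synthetic families

`generate_family` emulates the *structural* regime of curated tissue
collections: a large PPI core shared by all tissues (default 1 500 core vs
40 residual edges per tissue, a few percent — the high-overlap regime of
real tissue interactomes), a rooted ontology tree (deterministic
`branching`-ary shape over 100 diseases), sparse bipartite association and
eQTL layers, and `k = 19` tissues by default.  Residual edges are drawn from
a shared pool with per-tissue inclusion probability `overlap_across_tissues`
(default 0.25), so residuals recur in some but never all tissues (a pool
edge selected by every tissue is dropped from the last one, keeping the
planted core exactly the intersection).  Everything is a pure function of
the seed.

What the generator does **not** emulate: real degree distributions
(hub-dominated interactomes), correlated eQTL structure, edge weights other
than 1.0 in the layered families, or identifier-mapping noise between
databases.  Passing tests therefore demonstrate correctness of storage,
composition and solvers on structurally faithful inputs — not biological
conclusions about any real tissue.

Scale choices: the default family builds 41 versions with ~15 000 stored
edge slots in under a second, and the test suite's randomized fidelity
sweeps (50 trees x 10 versions x 200 vertices) run in a few seconds; sizes
were chosen so the full suite exercises every code path at desk scale while
each individual oracle remains brute-force-checkable.

## 6. Known limitations

* Single-writer: `add_version` must not run concurrently with other writes
  (reads may be shared freely).
* No edge deletion, no per-edge attribute payloads beyond one weight, no
  directed graphs.
* Horizontal integration supports exactly one union or intersection over the
  tissue set — no nested boolean expressions — plus a weight-reducer hook.
* The split/join space bound is a constant-factor improvement over the
  tested range, not an asymptotic guarantee (see section 1).
* The binary container stores the six core arrays and metadata; transient
  read-acceleration indexes (per-version coverage offsets) are rebuilt on
  load.
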