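"""Deterministic generators for versioned-network test families.

Real inputs for the layered disease/protein/locus model come from curated
databases (a phenotype ontology, curated gene-disease associations,
tissue-specific protein interactomes, tissue eQTL catalogues).  The
generators here emulate their *structural* regime — a large PPI core shared
by all tissues with small, partially overlapping per-tissue residual edge
sets, a rooted ontology tree, and bipartite association/eQTL layers — at
sizes convenient for testing.  They make no attempt to match real degree
distributions.

All generation is a pure function of the parameters: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import LabeledEdge, LayeredInputs
from .core import EdgeList, GraphInputError, VersionedCSR

__all__ = [
    "FamilyParams",
    "generate_family",
    "two_version_fixture",
    "random_version_tree",
]


@dataclass(frozen=True)
class FamilyParams:
    """Sizes and overlap structure of a synthetic layered family.

    Defaults describe a scaled-down family in the regime of curated
    tissue-specific interactomes: 19 tissues whose PPI networks share a large
    common core (residuals are a few percent of the core), sparse bipartite
    association and eQTL layers, and a shallow ontology tree.
    """

    k: int = 19
    n_proteins: int = 300
    n_diseases: int = 100
    n_loci: int = 120
    core_edges: int = 1500
    residual_edges: int = 40
    overlap_across_tissues: float = 0.25
    eqtl_edges: int = 60
    ontology_branching: int = 3
    association_edges: int = 120
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "k": self.k,
            "n_proteins": self.n_proteins,
            "n_diseases": self.n_diseases,
            "n_loci": self.n_loci,
            "core_edges": self.core_edges,
            "residual_edges": self.residual_edges,
            "eqtl_edges": self.eqtl_edges,
            "association_edges": self.association_edges,
        }
        for name, value in counts.items():
            if value < 0 or (name == "k" and value < 1):
                raise GraphInputError(f"invalid {name}={value}")
        if not (0.0 <= self.overlap_across_tissues <= 1.0):
            raise GraphInputError(
                f"overlap_across_tissues must be in [0, 1], got "
                f"{self.overlap_across_tissues}"
            )
        if self.ontology_branching < 1:
            raise GraphInputError("ontology_branching must be >= 1")
        n_pairs = self.n_proteins * (self.n_proteins - 1) // 2
        need = self.core_edges + self.residual_edges * (self.k + 1)
        if need > n_pairs:
            raise GraphInputError(
                f"cannot place {need} distinct protein pairs among {n_pairs}"
            )
        if self.association_edges > self.n_proteins * self.n_diseases:
            raise GraphInputError("more association edges than protein-disease pairs")
        if self.eqtl_edges > self.n_loci * self.n_proteins:
            raise GraphInputError("more eQTL edges than locus-protein pairs")


_TISSUES = (
    "adipose", "adrenal", "amygdala", "brain", "heart", "liver", "lung",
    "mammary", "ovary", "pancreas", "pituitary", "prostate", "salivary",
    "skeletal_muscle", "small_intestine", "spleen", "stomach", "testis",
    "uterus",
)


def _tissue_names(k: int) -> list[str]:
    names = list(_TISSUES[:k])
    names += [f"tissue_{i:02d}" for i in range(len(names), k)]
    return sorted(names)


def _sample_protein_pairs(
    rng: np.random.Generator,
    labels: list[str],
    count: int,
    taken: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Sample ``count`` distinct unordered protein pairs avoiding ``taken``."""
    n = len(labels)
    out: list[tuple[int, int]] = []
    while len(out) < count:
        draw = rng.integers(0, n, size=(2 * (count - len(out)) + 8, 2))
        for a, b in draw:
            if a == b:
                continue
            key = (int(min(a, b)), int(max(a, b)))
            if key in taken:
                continue
            taken.add(key)
            out.append(key)
            if len(out) == count:
                break
    return out


def _sample_bipartite(
    rng: np.random.Generator, n_left: int, n_right: int, count: int
) -> list[tuple[int, int]]:
    taken: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    while len(out) < count:
        draw = rng.integers(0, [n_left, n_right], size=(2 * (count - len(out)) + 8, 2))
        for a, b in draw:
            key = (int(a), int(b))
            if key in taken:
                continue
            taken.add(key)
            out.append(key)
            if len(out) == count:
                break
    return out


def generate_family(params: FamilyParams) -> LayeredInputs:
    """Generate a layered family: ontology, associations, tissue PPIs, eQTLs.

    Tissue PPIs are built as ``core + residual_i`` where the core is common to
    all tissues and residual edges are drawn from a shared pool (each tissue
    includes a pool edge with probability ``overlap_across_tissues``, so
    residual edges can recur in several tissues without ever being shared by
    *all* of them) topped up with globally unique per-tissue edges.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    diseases = [f"D{i:04d}" for i in range(params.n_diseases)]
    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    loci = [f"L{i:04d}" for i in range(params.n_loci)]

    # rooted ontology tree: vertex i attaches to (i-1) // branching
    ontology: list[LabeledEdge] = [
        (diseases[(i - 1) // params.ontology_branching], diseases[i], 1.0)
        for i in range(1, params.n_diseases)
    ]

    association = [
        (proteins[p], diseases[d], 1.0)
        for p, d in _sample_bipartite(
            rng, params.n_proteins, params.n_diseases, params.association_edges
        )
    ]

    taken: set[tuple[int, int]] = set()
    core_pairs = _sample_protein_pairs(rng, proteins, params.core_edges, taken)
    pool_pairs = _sample_protein_pairs(rng, proteins, params.residual_edges, taken)

    k = params.k
    names = _tissue_names(k)
    inclusion = rng.random(size=(k, len(pool_pairs))) < params.overlap_across_tissues
    if k >= 2:
        # a pool edge carried by every tissue would join the core; drop it
        # from the last tissue so the planted core stays exactly the core
        everywhere = inclusion.all(axis=0)
        inclusion[-1, everywhere] = False

    tissue_ppi: list[list[LabeledEdge]] = []
    for i in range(k):
        pairs = list(core_pairs)
        pairs += [p for p, inc in zip(pool_pairs, inclusion[i]) if inc]
        short = params.residual_edges - (len(pairs) - params.core_edges)
        if short > 0:
            pairs += _sample_protein_pairs(rng, proteins, short, taken)
        tissue_ppi.append([(proteins[a], proteins[b], 1.0) for a, b in pairs])

    tissue_eqtl: list[list[LabeledEdge]] = []
    for _ in range(k):
        pairs = _sample_bipartite(
            rng, params.n_loci, params.n_proteins, params.eqtl_edges
        )
        tissue_eqtl.append([(loci[a], proteins[b], 1.0) for a, b in pairs])

    return LayeredInputs(
        ontology_edges=ontology,
        association_edges=association,
        tissue_ppi=tissue_ppi,
        tissue_eqtl=tissue_eqtl,
        tissue_names=names,
    )


def two_version_fixture(h: float = 0.5) -> VersionedCSR:
    """A hand-sized two-version store exercising the normal->split transition.

    Version 0 is the 5-vertex graph 0-1, 1-2, 2-3, 3-4, 1-4; version 1 adds
    the single edge 1-3, so rows 1 and 3 become split rows while all other
    rows are shared with the root.
    """
    root = EdgeList(
        edges=[(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0), (1, 4, 1.0)],
        n_vertices=5,
    )
    g = VersionedCSR.from_edge_list(root, h=h)
    g.add_version(0, EdgeList(edges=[(1, 3, 1.0)], n_vertices=5))
    return g


def random_version_tree(
    seed: int,
    n_versions: int = 6,
    n_vertices: int = 50,
    root_edges: int = 80,
    added_edges: int = 12,
    h: float = 0.5,
) -> tuple[VersionedCSR, list[tuple[int, EdgeList]]]:
    """A random version tree plus its build plan (for oracle reconstruction).

    The root holds a random graph; each later version picks a random parent
    and adds random edges not present in that parent.  Returns the built
    store and the plan ``[(parent_id, additions), ...]`` whose entry 0 is
    ``(0, root_edge_list)``.
    """
    rng = np.random.default_rng(seed)
    pair_budget = n_vertices * (n_vertices - 1) // 2

    def sample_edges(count: int, forbidden: set[tuple[int, int]]) -> EdgeList:
        count = min(count, pair_budget - len(forbidden))
        chosen: list[tuple[int, int, float]] = []
        local = set(forbidden)
        while len(chosen) < count:
            a, b = (int(x) for x in rng.integers(0, n_vertices, size=2))
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in local:
                continue
            local.add(key)
            w = round(float(rng.uniform(0.1, 2.0)), 3)
            chosen.append((key[0], key[1], w))
        return EdgeList(edges=chosen, n_vertices=n_vertices)

    root = sample_edges(root_edges, set())
    g = VersionedCSR.from_edge_list(root, h=h)
    plan: list[tuple[int, EdgeList]] = [(0, root)]
    cumulative: list[set[tuple[int, int]]] = [root.pair_set()]
    for _ in range(1, n_versions):
        parent = int(rng.integers(0, g.n_versions))
        adds = sample_edges(added_edges, cumulative[parent])
        vid = g.add_version(parent, adds)
        plan.append((parent, adds))
        cumulative.append(cumulative[parent] | adds.pair_set())
        assert vid == len(plan) - 1
    return g, plan
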