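"""Assemble a heterogeneous version tree from per-layer edge lists.

The layered model couples four kinds of biological networks over a shared
vertex space:

* a rooted disease-ontology network over *disease* vertices,
* a bipartite gene-disease association layer (*protein* <-> *disease*),
* ``k`` tissue-specific protein-protein interaction (PPI) networks, and
* ``k`` tissue-specific bipartite eQTL layers (*locus* -> *protein*).

The tree factors the tissue-specific PPIs through their shared core: the
generic PPI is the intersection of all tissue edge sets, each tissue version
stores only its residual edges, and eQTL layers hang off their tissue's PPI
version.  For ``k`` tissues the tree has ``3 + 2k`` versions::

    v0 ontology -> v1 +associations -> v2 +generic PPI core
        v2 -> v(2+i)   +tissue-i residual PPI edges    (i = 1..k)
        v(2+i) -> v(2+k+i) +tissue-i eQTL edges

A PPI edge absent from the core but shared by several tissues is stored once
per tissue branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import EdgeList, GraphInputError, VersionedCSR

__all__ = [
    "KIND_DISEASE",
    "KIND_PROTEIN",
    "KIND_LOCUS",
    "LAYER_ONTOLOGY",
    "LAYER_ASSOCIATION",
    "LAYER_GENERIC_PPI",
    "LAYER_TISSUE_PPI",
    "LAYER_TISSUE_EQTL",
    "LabeledEdge",
    "VertexRegistry",
    "LayeredInputs",
    "VersionInfo",
    "VersionMeta",
    "compute_generic_core",
    "build_registry",
    "build_version_tree",
]

KIND_DISEASE = "disease"
KIND_PROTEIN = "protein"
KIND_LOCUS = "locus"

LAYER_ONTOLOGY = "ontology"
LAYER_ASSOCIATION = "association"
LAYER_GENERIC_PPI = "genericPPI"
LAYER_TISSUE_PPI = "tissuePPI"
LAYER_TISSUE_EQTL = "tissueEQTL"

#: (source label, target label, weight)
LabeledEdge = tuple[str, str, float]


class VertexRegistry:
    """Bijective label <-> dense-index map with an immutable kind per vertex."""

    def __init__(self) -> None:
        self._index: dict[str, int] = {}
        self._labels: list[str] = []
        self._kinds: list[str] = []

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def add(self, label: str, kind: str) -> int:
        """Register ``label`` as ``kind``; idempotent for a consistent kind."""
        idx = self._index.get(label)
        if idx is not None:
            if self._kinds[idx] != kind:
                raise GraphInputError(
                    f"vertex {label!r} registered as {self._kinds[idx]}, "
                    f"cannot re-register as {kind}"
                )
            return idx
        idx = len(self._labels)
        self._index[label] = idx
        self._labels.append(label)
        self._kinds.append(kind)
        return idx

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise GraphInputError(f"unknown vertex label {label!r}") from None

    def label(self, idx: int) -> str:
        return self._labels[idx]

    def kind(self, idx: int) -> str:
        return self._kinds[idx]

    def kind_of(self, label: str) -> str:
        return self._kinds[self.index(label)]

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    @property
    def kinds(self) -> list[str]:
        return list(self._kinds)

    def indices_of_kind(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self._kinds) if k == kind]

    def to_dict(self) -> dict:
        return {"labels": self._labels, "kinds": self._kinds}

    @classmethod
    def from_dict(cls, d: dict) -> "VertexRegistry":
        reg = cls()
        for label, kind in zip(d["labels"], d["kinds"]):
            reg.add(label, kind)
        return reg


@dataclass
class LayeredInputs:
    """Label-space edge lists for every layer of the heterogeneous model."""

    ontology_edges: list[LabeledEdge]
    association_edges: list[LabeledEdge]
    tissue_ppi: list[list[LabeledEdge]]
    tissue_eqtl: list[list[LabeledEdge]]
    tissue_names: list[str]

    def __post_init__(self) -> None:
        k = len(self.tissue_names)
        if k < 1:
            raise GraphInputError("at least one tissue is required")
        if len(self.tissue_ppi) != k or len(self.tissue_eqtl) != k:
            raise GraphInputError(
                f"layer counts disagree: {k} tissue names, "
                f"{len(self.tissue_ppi)} PPI lists, {len(self.tissue_eqtl)} eQTL lists"
            )

    @property
    def k(self) -> int:
        return len(self.tissue_names)


@dataclass
class VersionInfo:
    label: str
    layer_type: str
    tissue: str | None = None


@dataclass
class VersionMeta:
    """Per-version labels and layer roles for a built tree."""

    versions: list[VersionInfo] = field(default_factory=list)

    @property
    def tissue_names(self) -> list[str]:
        return [v.tissue for v in self.versions if v.layer_type == LAYER_TISSUE_PPI]

    def version_for(self, layer_type: str, tissue: str | None = None) -> int:
        for i, info in enumerate(self.versions):
            if info.layer_type == layer_type and info.tissue == tissue:
                return i
        raise GraphInputError(
            f"no version with layer {layer_type!r}"
            + (f" and tissue {tissue!r}" if tissue else "")
        )

    def to_dict(self) -> dict:
        return {
            "versions": [
                {"label": v.label, "layerType": v.layer_type, "tissue": v.tissue}
                for v in self.versions
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VersionMeta":
        return cls(
            versions=[
                VersionInfo(v["label"], v["layerType"], v.get("tissue"))
                for v in d["versions"]
            ]
        )


def _pair_key(e: LabeledEdge) -> tuple[str, str]:
    u, v, _ = e
    return (u, v) if u <= v else (v, u)


def compute_generic_core(
    tissue_ppi: list[list[LabeledEdge]],
) -> tuple[list[LabeledEdge], list[list[LabeledEdge]]]:
    """Split tissue PPI edge lists into their shared core and per-tissue residuals.

    The core is the edge-set intersection over all tissues (edge identity is
    the unordered label pair; the weight is taken from the first tissue).
    ``core + residuals[i]`` reproduces tissue ``i``'s edge set exactly.
    """
    if not tissue_ppi:
        raise GraphInputError("cannot take the core of zero PPI networks")
    key_sets = [{_pair_key(e) for e in layer} for layer in tissue_ppi]
    core_keys = set.intersection(*key_sets)
    core = [e for e in tissue_ppi[0] if _pair_key(e) in core_keys]
    residuals = [
        [e for e in layer if _pair_key(e) not in core_keys] for layer in tissue_ppi
    ]
    return core, residuals


def build_registry(inputs: LayeredInputs) -> VertexRegistry:
    """Register every label with its kind inferred from the layer it occurs in.

    Ontology endpoints are diseases and PPI endpoints proteins.  For the
    bipartite layers, an endpoint whose kind is already known fixes the
    orientation; when both endpoints are new, the documented column
    convention applies (association rows are ``protein<TAB>disease``, eQTL
    rows are ``locus<TAB>protein``).  An edge whose known endpoint kinds
    contradict the layer (e.g. a protein-protein association) is rejected.
    """
    reg = VertexRegistry()
    for u, v, _ in inputs.ontology_edges:
        reg.add(u, KIND_DISEASE)
        reg.add(v, KIND_DISEASE)
    for layer in inputs.tissue_ppi:
        for u, v, _ in layer:
            reg.add(u, KIND_PROTEIN)
            reg.add(v, KIND_PROTEIN)

    def resolve(u: str, v: str, kind_a: str, kind_b: str, layer_name: str):
        """Assign kinds (kind_a, kind_b) to the (u, v) columns, letting
        already-known endpoints override the column order."""
        ku = reg.kind_of(u) if u in reg else None
        kv = reg.kind_of(v) if v in reg else None
        if ku is None and kv is None:
            reg.add(u, kind_a)
            reg.add(v, kind_b)
            return
        if ku == kind_a or kv == kind_b:
            pass  # column order already correct
        elif ku == kind_b or kv == kind_a:
            u, v = v, u
            ku, kv = kv, ku
        if (ku not in (kind_a, None)) or (kv not in (kind_b, None)):
            raise GraphInputError(
                f"{layer_name} edge ({u!r}, {v!r}) must connect a {kind_a} "
                f"to a {kind_b}, got {ku or kind_a}-{kv or kind_b}"
            )
        reg.add(u, kind_a)
        reg.add(v, kind_b)

    for u, v, _ in inputs.association_edges:
        resolve(u, v, KIND_PROTEIN, KIND_DISEASE, "association")
    for layer in inputs.tissue_eqtl:
        for u, v, _ in layer:
            resolve(u, v, KIND_LOCUS, KIND_PROTEIN, "eQTL")
    return reg


def _index_edges(
    edges: list[LabeledEdge],
    registry: VertexRegistry,
    allowed_kinds: set[frozenset[str]],
    layer_name: str,
) -> list[tuple[int, int, float]]:
    out = []
    for u, v, w in edges:
        iu, iv = registry.index(u), registry.index(v)
        pair = frozenset((registry.kind(iu), registry.kind(iv)))
        if pair not in allowed_kinds:
            raise GraphInputError(
                f"{layer_name} edge ({u!r}, {v!r}) connects "
                f"{registry.kind(iu)}-{registry.kind(iv)} vertices"
            )
        out.append((iu, iv, float(w)))
    return out


def build_version_tree(
    inputs: LayeredInputs,
    registry: VertexRegistry | None = None,
    h: float = 0.5,
) -> tuple[VersionedCSR, VersionMeta, VertexRegistry]:
    """Build the full versioned store for a set of layered inputs.

    Returns the store, per-version metadata and the vertex registry
    (constructed with :func:`build_registry` when not supplied).  Versions:
    ontology, +associations, +generic PPI core, then one residual-PPI version
    and one eQTL version per tissue — ``3 + 2k`` in total.
    """
    if registry is None:
        registry = build_registry(inputs)

    onto = _index_edges(
        inputs.ontology_edges, registry, {frozenset((KIND_DISEASE,))}, "ontology"
    )
    assoc = _index_edges(
        inputs.association_edges,
        registry,
        {frozenset((KIND_DISEASE, KIND_PROTEIN))},
        "association",
    )
    core_edges, residuals = compute_generic_core(inputs.tissue_ppi)
    core = _index_edges(
        core_edges, registry, {frozenset((KIND_PROTEIN,))}, "generic PPI"
    )
    residuals_ix = [
        _index_edges(r, registry, {frozenset((KIND_PROTEIN,))}, "tissue PPI")
        for r in residuals
    ]
    eqtl_ix = [
        _index_edges(
            layer, registry, {frozenset((KIND_LOCUS, KIND_PROTEIN))}, "eQTL"
        )
        for layer in inputs.tissue_eqtl
    ]

    def span(*edge_lists: list[tuple[int, int, float]]) -> int:
        m = -1
        for edges in edge_lists:
            for u, v, _ in edges:
                m = max(m, u, v)
        return m + 1

    meta = VersionMeta()
    n0 = span(onto)
    g = VersionedCSR.from_edge_list(EdgeList(onto, n0), h=h)
    meta.versions.append(VersionInfo("ontology", LAYER_ONTOLOGY))

    n1 = max(n0, span(assoc))
    g.add_version(0, EdgeList(assoc, n1))
    meta.versions.append(VersionInfo("associations", LAYER_ASSOCIATION))

    n2 = max(n1, span(core, *residuals_ix))
    v_core = g.add_version(1, EdgeList(core, n2))
    meta.versions.append(VersionInfo("generic-ppi", LAYER_GENERIC_PPI))

    ppi_version: dict[str, int] = {}
    for name, res in zip(inputs.tissue_names, residuals_ix):
        vid = g.add_version(v_core, EdgeList(res, max(n2, span(res))))
        ppi_version[name] = vid
        meta.versions.append(VersionInfo(f"ppi-{name}", LAYER_TISSUE_PPI, name))
    for name, eq in zip(inputs.tissue_names, eqtl_ix):
        parent = ppi_version[name]
        nv = max(g.n_vertices(parent), span(eq))
        g.add_version(parent, EdgeList(eq, nv))
        meta.versions.append(VersionInfo(f"eqtl-{name}", LAYER_TISSUE_EQTL, name))
    return g, meta, registry
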