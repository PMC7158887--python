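"""File formats: TSV edge lists, layer manifests and the binary store container.

Edge lists are tab-separated ``source<TAB>target[<TAB>weight]`` with ``#``
comments and an optional header line; a missing weight column defaults to
1.0.  A manifest (JSON, or YAML when PyYAML is available) maps layer roles
and tissue names to edge-list files.

The store container is a little-endian binary file:

=======  ========================================================
offset   content
=======  ========================================================
0        magic ``b"VCSR"``
4        format version (uint64, currently 1)
12       key-frame threshold ``h`` (float64)
20..     seven length-prefixed arrays, in order:
         ``A`` (float64), ``JA`` (uint64), ``IA`` (uint64, 4 words
         per entry; the length prefix counts entries), ``D``, ``K``,
         ``parent``, ``n_vertices`` (uint64 each)
=======  ========================================================

Each length prefix is a uint64 element count.  A JSON sidecar at
``<path>.meta.json`` holds the version metadata and the vertex registry.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path

import numpy as np

from .builder import LabeledEdge, LayeredInputs, VersionMeta, VertexRegistry
from .core import GraphInputError, IntegrityError, VersionedCSR

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_manifest",
    "write_manifest",
    "save_graph",
    "load_graph",
]

log = logging.getLogger("vcsrnet")

_MAGIC = b"VCSR"
_FORMAT_VERSION = 1


def read_edge_list(path: str | Path) -> list[LabeledEdge]:
    """Parse a TSV edge list; duplicate unordered pairs with equal weights
    collapse with a warning, conflicting weights are an error."""
    path = Path(path)
    edges: list[LabeledEdge] = []
    seen: dict[tuple[str, str], tuple[float, int]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GraphInputError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError:
                    if lineno == 1:
                        continue  # header line
                    raise GraphInputError(
                        f"{path}:{lineno}: malformed weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            if not np.isfinite(w):
                raise GraphInputError(f"{path}:{lineno}: non-finite weight {w!r}")
            if w < 0:
                raise GraphInputError(f"{path}:{lineno}: negative weight {w!r}")
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                w0, first_line = seen[key]
                if w0 == w:
                    log.warning(
                        "%s:%d: duplicate edge (%s, %s) collapsed "
                        "(first seen on line %d)", path, lineno, u, v, first_line,
                    )
                    continue
                raise GraphInputError(
                    f"{path}:{lineno}: edge ({u!r}, {v!r}) repeated with "
                    f"conflicting weights {w0!r} vs {w!r}"
                )
            seen[key] = (w, lineno)
            edges.append((u, v, w))
    return edges


def write_edge_list(edges: list[LabeledEdge], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\tweight\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{w!r}\n")


def write_manifest(inputs: LayeredInputs, out_dir: str | Path) -> Path:
    """Write one TSV per layer plus a ``manifest.json`` tying them together."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edge_list(inputs.ontology_edges, out_dir / "ontology.tsv")
    write_edge_list(inputs.association_edges, out_dir / "association.tsv")
    tissues = {}
    for name, ppi, eqtl in zip(
        inputs.tissue_names, inputs.tissue_ppi, inputs.tissue_eqtl
    ):
        write_edge_list(ppi, out_dir / f"ppi_{name}.tsv")
        write_edge_list(eqtl, out_dir / f"eqtl_{name}.tsv")
        tissues[name] = {"ppi": f"ppi_{name}.tsv", "eqtl": f"eqtl_{name}.tsv"}
    manifest = {
        "ontology": "ontology.tsv",
        "association": "association.tsv",
        "tissues": tissues,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> LayeredInputs:
    """Load the layered inputs described by a JSON or YAML manifest."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        manifest = yaml.safe_load(text)
    else:
        manifest = json.loads(text)
    base = path.parent
    for role in ("ontology", "association", "tissues"):
        if role not in manifest:
            raise GraphInputError(f"manifest {path} is missing the {role!r} role")
    tissue_names = sorted(manifest["tissues"])
    tissue_ppi, tissue_eqtl = [], []
    for name in tissue_names:
        entry = manifest["tissues"][name]
        tissue_ppi.append(read_edge_list(base / entry["ppi"]))
        tissue_eqtl.append(read_edge_list(base / entry["eqtl"]))
    return LayeredInputs(
        ontology_edges=read_edge_list(base / manifest["ontology"]),
        association_edges=read_edge_list(base / manifest["association"]),
        tissue_ppi=tissue_ppi,
        tissue_eqtl=tissue_eqtl,
        tissue_names=tissue_names,
    )


def _write_array(fh, arr: np.ndarray) -> None:
    fh.write(struct.pack("<Q", arr.shape[0]))
    fh.write(arr.astype(arr.dtype.newbyteorder("<"), copy=False).tobytes())


def _read_array(fh, dtype: str, ncols: int = 1) -> np.ndarray:
    raw = fh.read(8)
    if len(raw) != 8:
        raise IntegrityError("truncated container: missing array length")
    (n,) = struct.unpack("<Q", raw)
    nbytes = n * ncols * 8
    buf = fh.read(nbytes)
    if len(buf) != nbytes:
        raise IntegrityError("truncated container: short array payload")
    arr = np.frombuffer(buf, dtype=np.dtype(dtype).newbyteorder("<")).copy()
    return arr.reshape(n, ncols) if ncols > 1 else arr


def save_graph(
    g: VersionedCSR,
    meta: VersionMeta | None,
    path: str | Path,
    registry: VertexRegistry | None = None,
) -> None:
    """Serialize a store to the binary container plus its JSON sidecar."""
    path = Path(path)
    with path.open("wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Qd", _FORMAT_VERSION, g.h))
        _write_array(fh, np.asarray(g._A, dtype=np.float64))
        _write_array(fh, np.asarray(g._JA, dtype=np.uint64))
        ia = np.asarray(g._IA, dtype=np.uint64).reshape(-1, 4)
        fh.write(struct.pack("<Q", ia.shape[0]))
        fh.write(ia.astype(ia.dtype.newbyteorder("<"), copy=False).tobytes())
        for arr in (g._D, g._K, g._parent, g._n_vertices):
            _write_array(fh, np.asarray(arr, dtype=np.uint64))
    sidecar = {
        "meta": meta.to_dict() if meta is not None else None,
        "registry": registry.to_dict() if registry is not None else None,
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_graph(
    path: str | Path,
) -> tuple[VersionedCSR, VersionMeta | None, VertexRegistry | None]:
    """Load a store saved by :func:`save_graph`; arrays round-trip bit-exactly."""
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise IntegrityError(
                f"{path} is not a versioned-CSR container (magic {magic!r})"
            )
        raw = fh.read(16)
        if len(raw) != 16:
            raise IntegrityError("truncated container header")
        fmt, h = struct.unpack("<Qd", raw)
        if fmt != _FORMAT_VERSION:
            raise IntegrityError(f"unsupported container format version {fmt}")
        a = _read_array(fh, "f8")
        ja = _read_array(fh, "u8")
        ia = _read_array(fh, "u8", ncols=4)
        d = _read_array(fh, "u8")
        k = _read_array(fh, "u8")
        parent = _read_array(fh, "u8")
        n_vertices = _read_array(fh, "u8")
        if fh.read(1):
            raise IntegrityError("trailing bytes after container payload")

    g = VersionedCSR(h=h)
    g._A = [float(x) for x in a]
    g._JA = [int(x) for x in ja]
    g._IA = [tuple(int(x) for x in row) for row in ia]
    g._D = [int(x) for x in d]
    g._K = [int(x) for x in k]
    g._parent = [int(x) for x in parent]
    g._n_vertices = [int(x) for x in n_vertices]
    if len(g._D) != len(g._n_vertices) + 1 or g._D[-1] != len(g._IA):
        raise IntegrityError("inconsistent version offsets in container")
    from .core import FLAG_COMPRESSED  # local to avoid polluting module surface

    g._seg_cover = []
    for vid in range(len(g._n_vertices)):
        cover, pos = [], 0
        for e0, e1, _, e3 in g._IA[g._D[vid] : g._D[vid + 1]]:
            cover.append(pos)
            pos += e1 if (e3 & 0x3) == FLAG_COMPRESSED else 1
        g._seg_cover.append(cover)

    meta = registry = None
    sidecar_path = Path(str(path) + ".meta.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sidecar.get("meta"):
            meta = VersionMeta.from_dict(sidecar["meta"])
        if sidecar.get("registry"):
            registry = VertexRegistry.from_dict(sidecar["registry"])
    return g, meta, registry
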