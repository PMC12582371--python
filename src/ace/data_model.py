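"""Mosaic data containers, bridge-connectivity checks, and file IO.

A *mosaic* dataset is a collection of batches, each measured with a subset of
the dataset's modalities.  Within a batch, all modality matrices describe the
same physical cells in the same order (bridge batches are physically paired
assays, so pairing is by cell identifier).  Batches measuring two or more
modalities are *bridge* batches; they connect modalities into a graph which
must be connected for alignment to be possible.

Cell order is canonicalized at construction: within a batch, rows are sorted
by cell identifier.  All downstream row indices refer to this order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class MosaicError(ValueError):
    """Raised for invalid mosaic structure or malformed input files."""


#: Canonical modality names; ADT is an alias for Protein (the same readout).
_MODALITY_ALIASES = {
    "rna": "RNA",
    "gex": "RNA",
    "atac": "ATAC",
    "protein": "Protein",
    "adt": "Protein",
    "histonemark": "HistoneMark",
    "histone-mark": "HistoneMark",
    "histone_mark": "HistoneMark",
}


def canonical_modality(name: str) -> str:
    """Map a free-form modality name onto the built-in set, case-insensitively.

    Unknown names are kept verbatim (user-defined modalities are allowed).
    """
    return _MODALITY_ALIASES.get(name.strip().lower(), name.strip())


def _as_dense_float(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        matrix = matrix.toarray()
    arr = np.asarray(matrix, dtype=np.float64)
    if arr.ndim != 2:
        raise MosaicError(f"expected a 2-D cells x features matrix, got shape {arr.shape}")
    return arr


@dataclass
class BatchRecord:
    """One batch: a map modality -> cells x features matrix plus cell ids.

    ``measured_set`` always equals the key set of ``matrices``.  A batch with
    two or more measured modalities is a candidate bridge batch.
    """

    batch_id: str
    matrices: dict[str, np.ndarray]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise MosaicError(f"batch {self.batch_id!r}: no modality matrices")
        self.matrices = {canonical_modality(m): _as_dense_float(x) for m, x in self.matrices.items()}
        self.cell_ids = [str(c) for c in self.cell_ids]
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise MosaicError(f"batch {self.batch_id!r}: duplicate cell identifiers")
        for mod, mat in self.matrices.items():
            if mat.shape[0] != n:
                raise MosaicError(
                    f"batch {self.batch_id!r}: modality {mod!r} has {mat.shape[0]} rows "
                    f"but the batch has {n} cells"
                )
            if not np.all(np.isfinite(mat)):
                raise MosaicError(f"batch {self.batch_id!r}: modality {mod!r} contains non-finite values")
        # canonical cell order: sorted by identifier
        order = np.argsort(np.asarray(self.cell_ids, dtype=object))
        if not np.array_equal(order, np.arange(n)):
            self.cell_ids = [self.cell_ids[i] for i in order]
            self.matrices = {m: x[order] for m, x in self.matrices.items()}

    @property
    def measured_set(self) -> frozenset[str]:
        return frozenset(self.matrices)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def is_bridge(self) -> bool:
        return len(self.matrices) >= 2


@dataclass
class MosaicDataset:
    """The full mosaic: ordered batches, modality list, optional labels.

    ``cell_type_labels`` maps batch_id -> per-cell category array aligned to
    the batch's canonical cell order; it is used for evaluation only.
    Pairing across modalities within a batch is implicit: row i of every
    modality matrix of a batch is the same physical cell.
    """

    batches: list[BatchRecord]
    modalities: list[str] = field(default_factory=list)
    cell_type_labels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        seen_ids = set()
        for b in self.batches:
            if b.batch_id in seen_ids:
                raise MosaicError(f"duplicate batch id {b.batch_id!r}")
            seen_ids.add(b.batch_id)
        observed: list[str] = []
        for b in self.batches:
            for m in b.matrices:
                if m not in observed:
                    observed.append(m)
        if not self.modalities:
            self.modalities = observed
        else:
            self.modalities = [canonical_modality(m) for m in self.modalities]
            missing = [m for m in observed if m not in self.modalities]
            if missing:
                raise MosaicError(f"batches measure modalities not declared in the dataset: {missing}")
        if self.cell_type_labels is not None:
            for bid, labels in self.cell_type_labels.items():
                b = self.batch(bid)
                if len(labels) != b.n_cells:
                    raise MosaicError(f"cell type labels for batch {bid!r} have wrong length")
                self.cell_type_labels[bid] = np.asarray(labels)

    # -- lookups -----------------------------------------------------------
    def batch(self, batch_id: str) -> BatchRecord:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(batch_id)

    @property
    def n_cells(self) -> int:
        return sum(b.n_cells for b in self.batches)

    def bridge_batches(self) -> list[BatchRecord]:
        return [b for b in self.batches if b.is_bridge]

    def all_rows(self) -> list[tuple[str, str]]:
        """Global (batch_id, cell_id) index over every cell, in batch order."""
        return [(b.batch_id, c) for b in self.batches for c in b.cell_ids]

    def modality_rows(self, modality: str) -> list[tuple[str, str]]:
        """(batch_id, cell_id) index over cells measuring ``modality``."""
        m = canonical_modality(modality)
        return [(b.batch_id, c) for b in self.batches if m in b.matrices for c in b.cell_ids]

    def modality_matrix(self, modality: str) -> np.ndarray:
        """Row-stacked feature matrix over all batches measuring ``modality``."""
        m = canonical_modality(modality)
        blocks = [b.matrices[m] for b in self.batches if m in b.matrices]
        if not blocks:
            raise MosaicError(f"no batch measures modality {m!r}")
        return np.vstack(blocks)

    def modality_batch_labels(self, modality: str) -> np.ndarray:
        m = canonical_modality(modality)
        return np.asarray(
            [b.batch_id for b in self.batches if m in b.matrices for _ in b.cell_ids], dtype=object
        )

    def types_for(self, rows: Sequence[tuple[str, str]]) -> np.ndarray:
        """Cell-type labels for a (batch_id, cell_id) index (evaluation only)."""
        if self.cell_type_labels is None:
            raise MosaicError("dataset carries no cell type labels")
        pos = {
            (b.batch_id, c): i for b in self.batches for i, c in enumerate(b.cell_ids)
        }
        return np.asarray([self.cell_type_labels[bid][pos[(bid, cid)]] for bid, cid in rows])


@dataclass
class BridgeGraph:
    """Modalities as nodes, multimodal batches contributing clique edges."""

    nodes: list[str]
    edges: list[tuple[str, str, str]]  # (modality, modality, batch_id)

    def _graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((a, b) for a, b, _ in self.edges)
        return g

    @property
    def is_connected(self) -> bool:
        g = self._graph()
        if g.number_of_nodes() == 0:
            return False
        return nx.is_connected(g)

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self._graph())]


def build_bridge_graph(ds: MosaicDataset) -> BridgeGraph:
    """Build the modality-connectivity graph from multimodal batches.

    A batch with modality set S contributes an edge for every unordered pair
    in S (a tri-modal batch yields a triangle).
    """
    edges = []
    for b in ds.batches:
        mods = sorted(b.matrices)
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                edges.append((mods[i], mods[j], b.batch_id))
    return BridgeGraph(nodes=list(ds.modalities), edges=edges)


def require_connected(g: BridgeGraph) -> None:
    """Raise unless every modality lies in one bridge-connected component."""
    if not g.nodes:
        raise MosaicError("no batches: the mosaic contains no modalities to connect")
    comps = g.components()
    if len(comps) > 1:
        comps_str = ", ".join("{" + ", ".join(sorted(c)) + "}" for c in comps)
        raise MosaicError(
            f"modalities are not bridge-connected; components: {comps_str}. "
            "Every modality needs at least one multimodal batch linking it to the rest."
        )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _load_modality_file(spec, modality: str):
    """Load one modality of one batch; returns (matrix, cell_ids or None)."""
    if isinstance(spec, Mapping):  # explicit MTX triple
        mat = scipy.io.mmread(str(spec["mtx"]))
        mat = _as_dense_float(mat)
        cells = pd.read_csv(spec["barcodes"], header=None)[0].astype(str).tolist()
        return mat, cells
    path = Path(spec)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        mat = _as_dense_float(scipy.io.mmread(str(path)))
        barcodes = path.with_name(path.stem + "_barcodes.tsv")
        cells = None
        if barcodes.exists():
            cells = pd.read_csv(barcodes, header=None)[0].astype(str).tolist()
        return mat, cells
    if suffix in {".csv", ".tsv", ".txt"}:
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            mat = _as_dense_float(df.to_numpy(dtype=np.float64))
        except (TypeError, ValueError) as exc:
            raise MosaicError(f"{path}: non-numeric entries in feature matrix") from exc
        return mat, df.index.astype(str).tolist()
    if suffix == ".h5ad":
        import anndata

        ad = anndata.read_h5ad(str(path))
        layer = None
        if isinstance(spec, str) and "::" in spec:  # pragma: no cover - convenience
            layer = spec.split("::", 1)[1]
        X = ad.layers[layer] if layer else ad.X
        return _as_dense_float(X), ad.obs_names.astype(str).tolist()
    raise MosaicError(f"unknown input format for {path} (expected .mtx/.csv/.tsv/.h5ad)")


def load_mosaic(
    batch_files: Mapping[str, Mapping[str, object]],
    cell_type_labels: Mapping[str, Sequence] | None = None,
) -> MosaicDataset:
    """Load a mosaic from per-batch, per-modality files.

    Parameters
    ----------
    batch_files
        ``{batch_id: {modality: file_spec}}`` where file_spec is a path to a
        ``.mtx`` (with a ``<stem>_barcodes.tsv`` sibling, or given explicitly
        as ``{"mtx": ..., "barcodes": ...}``), a ``.csv``/``.tsv`` dense table
        with cell ids in the first column, or an ``.h5ad`` container.
    cell_type_labels
        Optional ``{batch_id: labels}`` aligned to the files' cell order.

    All modalities of a batch must name the same cells; rows are re-ordered
    to the canonical (sorted-identifier) order.  Features are never merged
    across modalities.
    """
    batches = []
    ct: dict[str, np.ndarray] | None = {} if cell_type_labels else None
    for batch_id, mod_files in batch_files.items():
        mats: dict[str, np.ndarray] = {}
        ids_ref: list[str] | None = None
        for modality, spec in mod_files.items():
            mat, cells = _load_modality_file(spec, modality)
            if cells is None:
                cells = ids_ref if ids_ref is not None else [f"cell{i}" for i in range(mat.shape[0])]
            if ids_ref is None:
                ids_ref = cells
            elif set(cells) != set(ids_ref):
                raise MosaicError(
                    f"batch {batch_id!r}: cell identifiers of modality {modality!r} do not "
                    "match the batch's other modalities"
                )
            elif cells != ids_ref:
                # align this modality onto the reference order before BatchRecord sorts
                lookup = {c: i for i, c in enumerate(cells)}
                mat = mat[[lookup[c] for c in ids_ref]]
            mats[modality] = mat
        assert ids_ref is not None
        batches.append(BatchRecord(batch_id=batch_id, matrices=mats, cell_ids=list(ids_ref)))
        if ct is not None and batch_id in cell_type_labels:  # type: ignore[operator]
            labels = np.asarray(cell_type_labels[batch_id])  # aligned to file order
            order = np.argsort(np.asarray(ids_ref, dtype=object))
            ct[batch_id] = labels[order]
    return MosaicDataset(batches=batches, cell_type_labels=ct or None)


def write_mosaic(ds: MosaicDataset, out_dir) -> Path:
    """Write a mosaic as per-batch CSV tables plus a JSON manifest.

    ``load_mosaic_dir(write_mosaic(ds))`` round-trips the dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"modalities": list(ds.modalities), "batches": {}}
    for b in ds.batches:
        entry: dict = {}
        for mod, mat in b.matrices.items():
            fname = f"{b.batch_id}_{mod}.csv"
            df = pd.DataFrame(mat, index=b.cell_ids)
            df.to_csv(out / fname, index_label="cell_id")
            entry[mod] = fname
        manifest["batches"][b.batch_id] = entry
        if ds.cell_type_labels and b.batch_id in ds.cell_type_labels:
            pd.DataFrame(
                {"cell_id": b.cell_ids, "cell_type": ds.cell_type_labels[b.batch_id]}
            ).to_csv(out / f"{b.batch_id}_cell_types.csv", index=False)
            entry["cell_types"] = f"{b.batch_id}_cell_types.csv"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_mosaic_dir(in_dir) -> MosaicDataset:
    """Read a mosaic written by :func:`write_mosaic`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    batch_files: dict[str, dict[str, object]] = {}
    labels: dict[str, Sequence] = {}
    for bid, entry in manifest["batches"].items():
        files = {m: str(root / f) for m, f in entry.items() if m != "cell_types"}
        batch_files[bid] = files
        if "cell_types" in entry:
            df = pd.read_csv(root / entry["cell_types"])
            labels[bid] = df["cell_type"].to_numpy()
    ds = load_mosaic(batch_files, cell_type_labels=labels or None)
    ds.modalities = [canonical_modality(m) for m in manifest["modalities"]]
    return ds


def write_embeddings(emb: np.ndarray, ids: Sequence[tuple[str, str]], path) -> None:
    """Write a cells x d embedding as a delimited table with id columns first."""
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim != 2:
        raise MosaicError(f"embedding must be 2-D, got shape {emb.shape}")
    if emb.shape[0] != len(ids):
        raise MosaicError(f"embedding has {emb.shape[0]} rows but {len(ids)} ids were given")
    df = pd.DataFrame(emb, columns=[f"e{j}" for j in range(emb.shape[1])])
    df.insert(0, "cell_id", [c for _, c in ids])
    df.insert(0, "batch_id", [b for b, _ in ids])
    # repr-level float formatting so read-back is exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_embeddings(path) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Read an embedding table written by :func:`write_embeddings`."""
    df = pd.read_csv(path, dtype={"batch_id": str, "cell_id": str})
    ids = list(zip(df["batch_id"].tolist(), df["cell_id"].tolist()))
    emb = df.drop(columns=["batch_id", "cell_id"]).to_numpy(dtype=np.float64)
    return emb, ids


def write_embeddings_h5ad(embeddings: Mapping[str, np.ndarray],
                          ids: Sequence[tuple[str, str]], path) -> None:
    """Write one or more named embeddings as obsm slots of an h5ad container."""
    import anndata

    n = len(ids)
    for name, emb in embeddings.items():
        if np.asarray(emb).shape[0] != n:
            raise MosaicError(f"embedding {name!r} has wrong row count")
    ad = anndata.AnnData(
        X=np.zeros((n, 1)),
        obs=pd.DataFrame(
            {"batch_id": [b for b, _ in ids], "cell_id": [c for _, c in ids]},
            index=[f"{b}:{c}" for b, c in ids],
        ),
    )
    for name, emb in embeddings.items():
        ad.obsm[f"X_{name}"] = np.asarray(emb, dtype=np.float64)
    ad.write_h5ad(str(path))
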