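"""Synthetic mosaic generator with known ground truth.

The generator emulates the structure the integration model assumes: a shared
low-dimensional cell-state space with discrete cell types; per-modality
linear feature maps plus Gaussian noise; additive per-batch shifts within
each modality (horizontal batch effects); and a mosaic missingness pattern
with at least one bridge batch.  It makes no attempt at realistic count
distributions — it validates algorithms, not biology — though a count-like
variant (exponentiate-and-Poisson) exists for feature-imputation tests.

Two experimental manipulations used in robustness studies are built in:
restricting the fraction of cell types shared across batches
(``shared_type_proportion``) and subsampling bridge-batch cells
(``bridge_downsample``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ace.data_model import (
    BatchRecord,
    MosaicDataset,
    MosaicError,
    build_bridge_graph,
    canonical_modality,
    require_connected,
)


@dataclass
class ModalitySim:
    """Feature-map parameters for one simulated modality."""

    name: str
    n_features: int
    loading_scale: float = 1.0


@dataclass
class MosaicSimSpec:
    """Parameters of a simulated mosaic.

    ``missingness`` maps batch_id -> measured modality names; batch sizes are
    given in the same order via ``cells_per_batch``.  ``batch_effect_sd``
    scales an additive per-(batch, modality) shift vector — purely additive
    by design so that mean-centring provably removes it.
    """

    n_cell_types: int = 4
    cells_per_batch: Sequence[int] = (300, 200, 200)
    modalities: Sequence[ModalitySim] = field(
        default_factory=lambda: [ModalitySim("RNA", 300), ModalitySim("Protein", 40)]
    )
    missingness: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "bridge": ("RNA", "Protein"),
            "rna_only": ("RNA",),
            "adt_only": ("Protein",),
        }
    )
    latent_dim: int = 8
    centroid_scale: float = 3.0
    latent_jitter_sd: float = 0.5
    noise_sd: float = 0.3
    batch_effect_sd: float = 0.5
    shared_type_proportion: float = 1.0
    bridge_downsample: float = 1.0
    count_like: bool = False
    balanced_types: bool = True
    allow_disconnected: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cells_per_batch) != len(self.missingness):
            raise MosaicError("cells_per_batch and missingness must have the same length")
        if not (0 < self.shared_type_proportion <= 1):
            raise MosaicError("shared_type_proportion must lie in (0, 1]")
        if not (0 < self.bridge_downsample <= 1):
            raise MosaicError("bridge_downsample must lie in (0, 1]")


@dataclass
class MosaicTruth:
    """Ground truth accompanying a simulated mosaic."""

    cell_types: dict[str, np.ndarray]  # batch_id -> per-cell type label
    latent: dict[str, np.ndarray]  # batch_id -> cells x latent_dim
    shifts: dict[tuple[str, str], np.ndarray]  # (batch_id, modality) -> shift vector
    loadings: dict[str, np.ndarray]  # modality -> latent_dim x n_features
    pairing: list[tuple[str, str]]  # (batch_id, cell_id) of bridge cells


def _batch_type_pool(spec: MosaicSimSpec, batch_index: int) -> np.ndarray:
    """Cell types available to one batch under shared_type_proportion.

    The first ``ceil(prop * T)`` types are shared by every batch; each
    remaining type is private to one batch (assigned round-robin), mirroring
    benchmark designs that vary cell-type overlap across batches.
    """
    T = spec.n_cell_types
    n_shared = max(1, math.ceil(spec.shared_type_proportion * T))
    pool = list(range(n_shared))
    n_batches = len(spec.cells_per_batch)
    for extra, t in enumerate(range(n_shared, T)):
        if extra % n_batches == batch_index:
            pool.append(t)
    return np.asarray(pool)


def simulate_mosaic(spec: MosaicSimSpec) -> tuple[MosaicDataset, MosaicTruth]:
    """Draw a mosaic dataset and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    mods = {canonical_modality(m.name): m for m in spec.modalities}
    centroids = rng.normal(scale=spec.centroid_scale, size=(spec.n_cell_types, spec.latent_dim))
    loadings = {
        name: m.loading_scale * rng.normal(size=(spec.latent_dim, m.n_features)) / np.sqrt(spec.latent_dim)
        for name, m in mods.items()
    }

    batches: list[BatchRecord] = []
    cell_types: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}
    shifts: dict[tuple[str, str], np.ndarray] = {}
    pairing: list[tuple[str, str]] = []

    for bi, (batch_id, measured) in enumerate(spec.missingness.items()):
        measured = [canonical_modality(m) for m in measured]
        n = int(spec.cells_per_batch[bi])
        is_bridge = len(measured) >= 2
        if is_bridge and spec.bridge_downsample < 1.0:
            n = max(2, int(round(n * spec.bridge_downsample)))
        pool = _batch_type_pool(spec, bi)
        if spec.balanced_types:
            reps = np.tile(pool, n // len(pool) + 1)[:n]
            types = rng.permutation(reps)
        else:
            types = rng.choice(pool, size=n)
        latent = centroids[types] + rng.normal(scale=spec.latent_jitter_sd, size=(n, spec.latent_dim))
        cell_ids = [f"c{i:05d}" for i in range(n)]  # already in canonical sorted order
        mats: dict[str, np.ndarray] = {}
        for mod in measured:
            if mod not in mods:
                raise MosaicError(f"batch {batch_id!r} measures undeclared modality {mod!r}")
            shift = rng.normal(scale=spec.batch_effect_sd, size=mods[mod].n_features)
            X = latent @ loadings[mod]
            if spec.noise_sd > 0:
                X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
            X = X + shift
            if spec.count_like:
                X = rng.poisson(np.exp(X / np.std(X))).astype(np.float64)
            mats[mod] = X
            shifts[(batch_id, mod)] = shift
        batches.append(BatchRecord(batch_id=batch_id, matrices=mats, cell_ids=cell_ids))
        cell_types[batch_id] = types
        latents[batch_id] = latent
        if is_bridge:
            pairing.extend((batch_id, c) for c in cell_ids)

    ds = MosaicDataset(
        batches=batches,
        modalities=list(mods),
        cell_type_labels=cell_types,
    )
    if not spec.allow_disconnected:
        try:
            require_connected(build_bridge_graph(ds))
        except MosaicError as exc:
            raise MosaicError(f"missingness pattern yields a disconnected mosaic: {exc}") from exc
    truth = MosaicTruth(
        cell_types=cell_types, latent=latents, shifts=shifts, loadings=loadings, pairing=pairing
    )
    return ds, truth


def easy_mosaic(seed: int = 7) -> tuple[MosaicDataset, MosaicTruth]:
    """Canonical 700-cell fixture: 4 types, one RNA+ADT bridge, two unimodal batches.

    Bridge batch of 300 cells measured with RNA (300 features) and protein
    (40 features), plus 200 RNA-only and 200 ADT-only cells; latent dim 8,
    feature noise sd 0.3, additive batch-effect sd 0.5.
    """
    spec = MosaicSimSpec(
        n_cell_types=4,
        cells_per_batch=(300, 200, 200),
        modalities=[ModalitySim("RNA", 300), ModalitySim("Protein", 40)],
        missingness={
            "bridge": ("RNA", "Protein"),
            "rna_only": ("RNA",),
            "adt_only": ("Protein",),
        },
        latent_dim=8,
        noise_sd=0.3,
        batch_effect_sd=0.5,
        seed=seed,
    )
    return simulate_mosaic(spec)
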