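"""ACE-spec: modality-specific embeddings and missing-modality imputation.

Modality alignment can erase information unique to one modality.  ACE-spec
therefore trains a second, fully independent encoder per modality with the
specificity loss (each cell its own positive; other cells of the same
modality as negatives), which preserves within-modality variation.  The
missing modalities of each batch are then *imputed*: for each cell and each
missing modality m_j, the cell's shared-space embedding from each measured
modality m_t is matched to its k nearest neighbours among the shared-space
embeddings of all cells that do measure m_j; the neighbours'
modality-specific embeddings are averaged (k = 2 by default), and the
per-source-modality imputations are averaged with equal weight 1/|T_b|.
The same matching transfers raw feature profiles instead of embeddings.
The final ACE-spec consensus is the unweighted mean over all modalities'
(measured or imputed) specific embeddings.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ace.align import SharedEmbedding, TrainConfig
from ace.data_model import MosaicDataset, MosaicError
from ace.losses import LossConfig, specificity_loss_with_grad
from ace.nn import Adam, EncoderSpec, MLPEncoder, default_encoder_spec
from ace.preprocess import ModalityInput


@dataclass
class SpecificEmbedding:
    """One modality's specific embeddings; rows may be measured or imputed."""

    modality: str
    rows: list[tuple[str, str]]
    values: np.ndarray
    imputed_mask: np.ndarray | None = None  # False = measured, True = imputed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.rows):
            raise MosaicError("SpecificEmbedding rows/values mismatch")
        if not np.all(np.isfinite(self.values)):
            raise MosaicError("SpecificEmbedding contains non-finite values")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(len(self.rows), dtype=bool)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)


@dataclass
class ImputationConfig:
    """Cross-modality matching parameters: k neighbours, similarity metric."""

    k: int = 2
    metric: str = "cosine"  # or "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise MosaicError("k must be a positive integer")
        if self.metric not in {"cosine", "euclidean"}:
            raise MosaicError(f"unknown matching metric {self.metric!r}")


def default_spec_train_config(seed: int = 0) -> TrainConfig:
    """Specific-model optimizer defaults: lr 1.75e-4, batch 512, 10 epochs."""
    return TrainConfig(lr=1.75e-4, batch_size=512, epochs=10, seed=seed)


def train_spec(
    inputs: Mapping[str, ModalityInput],
    enc_specs: Mapping[str, EncoderSpec] | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[dict[str, MLPEncoder], dict[str, list[float]]]:
    """Train one independent encoder per modality with the specificity loss.

    Mini-batches are drawn uniformly without replacement per epoch from ALL
    cells measuring the modality (not only bridge cells); no other
    modality's data is ever read.
    """
    train_cfg = train_cfg or default_spec_train_config()
    loss_cfg = loss_cfg or LossConfig()
    encoders: dict[str, MLPEncoder] = {}
    traces: dict[str, list[float]] = {}
    for mod, mi in inputs.items():
        if mi.values.shape[0] < 2:
            raise MosaicError(f"modality {mod!r} has fewer than 2 cells; loss degenerate")
        # independent, reproducible stream per modality
        rng = np.random.default_rng([train_cfg.seed, zlib.crc32(mod.encode()) % 2**31])
        spec = (enc_specs or {}).get(mod) or default_encoder_spec(mod, mi.p)
        enc = MLPEncoder(spec, rng)
        opt = Adam(enc.parameters(), lr=train_cfg.lr)
        trace: list[float] = []
        n = mi.values.shape[0]
        for _ in range(train_cfg.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, train_cfg.batch_size):
                idx = perm[start:start + train_cfg.batch_size]
                if idx.size < 2:
                    continue
                out, cache = enc.forward(mi.values[idx], train=True, rng=rng)
                loss, dZ = specificity_loss_with_grad(out, loss_cfg)
                if not np.isfinite(loss):
                    raise MosaicError(
                        f"non-finite specificity loss for {mod!r} at step {len(trace)}"
                    )
                opt.step(enc.backward(cache, dZ))
                trace.append(loss)
        encoders[mod] = enc
        traces[mod] = trace
    return encoders, traces


def encode_specific(
    encoders: Mapping[str, MLPEncoder],
    inputs: Mapping[str, ModalityInput],
) -> dict[str, SpecificEmbedding]:
    """Encode measured cells into each modality's specific space."""
    return {
        mod: SpecificEmbedding(
            modality=mod, rows=list(mi.rows), values=encoders[mod].encode(mi.values)
        )
        for mod, mi in inputs.items()
    }


def knn_match(
    queries: np.ndarray,
    candidates: np.ndarray,
    k: int,
    metric: str = "cosine",
) -> np.ndarray:
    """Indices of each query's k nearest candidates, deterministic ties.

    Neighbours are ordered by (similarity desc, candidate index asc); ties on
    similarity break toward the lower index.  Exact (all-pairs) search.
    """
    queries = np.asarray(queries, dtype=np.float64)
    candidates = np.asarray(candidates, dtype=np.float64)
    if metric == "cosine":
        qn = np.linalg.norm(queries, axis=1, keepdims=True)
        cn = np.linalg.norm(candidates, axis=1, keepdims=True)
        qn[qn == 0] = 1.0
        cn[cn == 0] = 1.0
        sim = (queries / qn) @ (candidates / cn).T
    else:
        d2 = (
            np.sum(queries**2, axis=1)[:, None]
            + np.sum(candidates**2, axis=1)[None, :]
            - 2.0 * queries @ candidates.T
        )
        sim = -d2
    idx_grid = np.broadcast_to(np.arange(candidates.shape[0]), sim.shape)
    order = np.lexsort((idx_grid, -sim), axis=1)  # similarity desc, index asc
    return order[:, :k]


def _completed_modality(
    modality: str,
    ds: MosaicDataset,
    shared: Mapping[str, SharedEmbedding],
    source_values: np.ndarray,
    cfg: ImputationConfig,
) -> SpecificEmbedding:
    """Complete one modality over all cells by cross-modality kNN transfer.

    ``source_values`` are the rows being transferred (specific embeddings or
    raw feature profiles), aligned to ``shared[modality].rows``.
    """
    cand_rows = shared[modality].rows
    cand_shared = shared[modality].values
    if len(cand_rows) == 0:
        raise MosaicError(f"modality {modality!r} is measured by no cell; cannot impute")
    k = cfg.k
    if k > len(cand_rows):
        warnings.warn(
            f"k={cfg.k} exceeds the {len(cand_rows)} candidate cells for "
            f"{modality!r}; clamping",
            stacklevel=2,
        )
        k = len(cand_rows)

    lookup = {
        mod: {rc: i for i, rc in enumerate(se.rows)} for mod, se in shared.items()
    }
    all_rows = ds.all_rows()
    d = source_values.shape[1]
    values = np.zeros((len(all_rows), d))
    mask = np.zeros(len(all_rows), dtype=bool)
    pos = 0
    for b in ds.batches:
        nb = b.n_cells
        row_ids = [(b.batch_id, c) for c in b.cell_ids]
        if modality in b.matrices:
            take = [lookup[modality][rc] for rc in row_ids]
            values[pos:pos + nb] = source_values[take]
        else:
            acc = np.zeros((nb, d))
            measured = sorted(b.matrices)
            for mt in measured:
                q = shared[mt].values[[lookup[mt][rc] for rc in row_ids]]
                nbrs = knn_match(q, cand_shared, k, cfg.metric)
                acc += source_values[nbrs].mean(axis=1)
            values[pos:pos + nb] = acc / len(measured)
            mask[pos:pos + nb] = True
        pos += nb
    return SpecificEmbedding(modality=modality, rows=all_rows, values=values, imputed_mask=mask)


def impute_missing_embeddings(
    shared: Mapping[str, SharedEmbedding],
    specific: Mapping[str, SpecificEmbedding],
    ds: MosaicDataset,
    cfg: ImputationConfig | None = None,
) -> dict[str, SpecificEmbedding]:
    """Complete every modality's specific embeddings over all cells.

    Measured rows are copied verbatim; missing rows are imputed by
    shared-space kNN matching against all cells measuring the modality,
    averaging the matched cells' specific embeddings, then averaging over
    the querying batch's measured modalities with equal weights.
    """
    cfg = cfg or ImputationConfig()
    out = {}
    for mod in ds.modalities:
        if mod not in specific:
            raise MosaicError(f"no specific embedding for measured modality {mod!r}")
        if list(specific[mod].rows) != list(shared[mod].rows):
            raise MosaicError(f"shared/specific row mismatch for modality {mod!r}")
        out[mod] = _completed_modality(mod, ds, shared, specific[mod].values, cfg)
    return out


def impute_missing_features(
    shared: Mapping[str, SharedEmbedding],
    ds: MosaicDataset,
    cfg: ImputationConfig | None = None,
    modality: str | None = None,
    features: np.ndarray | None = None,
) -> SpecificEmbedding:
    """Impute raw feature profiles of one modality for cells missing it.

    Same matching logic as :func:`impute_missing_embeddings`, but the
    transferred rows are the modality's raw cells x D feature matrix
    (``features`` overrides the matrices stored in ``ds``).  As a convex
    combination of observed profiles, imputed rows of a non-negative input
    stay non-negative.
    """
    cfg = cfg or ImputationConfig()
    if modality is None:
        raise MosaicError("impute_missing_features: modality must be named")
    if features is None:
        features = ds.modality_matrix(modality)
    features = np.asarray(features, dtype=np.float64)
    if features.shape[0] != len(shared[modality].rows):
        raise MosaicError("feature rows not aligned to the modality's measured cells")
    return _completed_modality(modality, ds, shared, features, cfg)


def consensus_spec(
    specific: Mapping[str, SpecificEmbedding],
    ds: MosaicDataset,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Unweighted per-cell mean over ALL modalities' completed embeddings."""
    all_rows = ds.all_rows()
    mats = []
    for mod in ds.modalities:
        if mod not in specific:
            raise MosaicError(f"missing completed embedding for modality {mod!r}")
        se = specific[mod]
        if list(se.rows) != all_rows:
            raise MosaicError(
                f"modality {mod!r} is incomplete: completed embeddings must cover all cells"
            )
        mats.append(se.values)
    return np.mean(mats, axis=0), all_rows
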