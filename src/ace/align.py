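"""ACE-align: joint encoder training on bridge batches and consensus assembly.

One encoder per modality maps its reduced, batch-corrected inputs into a
shared d-dimensional space.  Training samples mini-batches of paired cells
from bridge batches (a batch chosen with probability proportional to its
cell count, then cells without replacement) and minimizes the alignment
contrastive loss over the batch's measured modalities.  After training,
every cell of every batch is encoded, and a per-cell consensus is formed as
a weighted average over the cell's measured modalities — by default a
one-hot weight on RNA (or protein when RNA is absent) for multimodal
batches, and weight 1 on the single modality otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ace.data_model import MosaicDataset, MosaicError
from ace.losses import LossConfig, ace_align_loss_with_grad
from ace.nn import Adam, EncoderSpec, MLPEncoder, default_encoder_spec
from ace.preprocess import ModalityInput


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam)."""

    lr: float = 2e-4
    batch_size: int = 512
    epochs: int = 100
    seed: int = 0


@dataclass
class SharedEmbedding:
    """One modality's aligned embeddings over all cells measuring it."""

    modality: str
    rows: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.rows):
            raise MosaicError("SharedEmbedding rows/values mismatch")
        if not np.all(np.isfinite(self.values)):
            raise MosaicError("SharedEmbedding contains non-finite values")


@dataclass
class AlignModel:
    """Trained per-modality encoders plus the per-step loss trace."""

    encoders: dict[str, MLPEncoder]
    loss_trace: list[float] = field(default_factory=list)
    step_batches: list[str] = field(default_factory=list)


def _bridge_index(ds: MosaicDataset, inputs: Mapping[str, ModalityInput]):
    """For each bridge batch, per-modality row offsets into the ModalityInputs."""
    out = []
    for b in ds.bridge_batches():
        offsets = {}
        for mod in b.matrices:
            if mod not in inputs:
                raise MosaicError(f"no ModalityInput provided for modality {mod!r}")
            sl = inputs[mod].block_slices().get(b.batch_id)
            if sl is None:
                raise MosaicError(
                    f"ModalityInput for {mod!r} has no rows for batch {b.batch_id!r}"
                )
            offsets[mod] = sl
        out.append((b, offsets))
    return out


def sample_bridge_minibatch(
    ds: MosaicDataset,
    inputs: Mapping[str, ModalityInput],
    n: int,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray, dict[str, np.ndarray]]:
    """Sample aligned per-modality input rows from one bridge batch.

    The bridge batch is chosen with probability proportional to its cell
    count; ``n`` cells are drawn without replacement (all cells if the batch
    is smaller).  Returns ``(batch_id, local_cell_indices, {modality: rows})``
    restricted to the batch's measured modalities.
    """
    index = _bridge_index(ds, inputs)
    if not index:
        raise MosaicError("no bridge batch: cannot sample paired cells")
    sizes = np.array([b.n_cells for b, _ in index], dtype=float)
    choice = rng.choice(len(index), p=sizes / sizes.sum())
    batch, offsets = index[choice]
    take = min(n, batch.n_cells)
    idx = np.sort(rng.choice(batch.n_cells, size=take, replace=False))
    blocks = {
        mod: inputs[mod].values[sl][idx] for mod, sl in offsets.items()
    }
    return batch.batch_id, idx, blocks


def train_align(
    inputs: Mapping[str, ModalityInput],
    ds: MosaicDataset,
    enc_specs: Mapping[str, EncoderSpec] | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> AlignModel:
    """Jointly train all modality encoders on bridge mini-batches.

    One epoch is ``ceil(total bridge cells / batch_size)`` gradient steps.
    Deterministic given ``train_cfg.seed`` (single-threaded numpy).
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(train_cfg.seed)

    encoders: dict[str, MLPEncoder] = {}
    optimizers: dict[str, Adam] = {}
    for mod, mi in inputs.items():
        spec = (enc_specs or {}).get(mod) or default_encoder_spec(mod, mi.p)
        if spec.input_dim != mi.p:
            raise MosaicError(
                f"encoder spec for {mod!r} expects input dim {spec.input_dim}, "
                f"ModalityInput has p={mi.p}"
            )
        encoders[mod] = MLPEncoder(spec, rng)
        optimizers[mod] = Adam(encoders[mod].parameters(), lr=train_cfg.lr)

    n_bridge = sum(b.n_cells for b in ds.bridge_batches())
    if n_bridge == 0:
        raise MosaicError("no bridge batch: alignment training is impossible")
    steps_per_epoch = max(1, math.ceil(n_bridge / train_cfg.batch_size))

    model = AlignModel(encoders=encoders)
    for epoch in range(train_cfg.epochs):
        for _ in range(steps_per_epoch):
            bid, _, blocks = sample_bridge_minibatch(ds, inputs, train_cfg.batch_size, rng)
            mods = list(blocks)
            outs, caches = {}, {}
            for mod in mods:
                outs[mod], caches[mod] = encoders[mod].forward(blocks[mod], train=True, rng=rng)
            loss, dZ = ace_align_loss_with_grad([outs[m] for m in mods], loss_cfg)
            step = len(model.loss_trace)
            if not np.isfinite(loss):
                raise MosaicError(f"non-finite alignment loss at step {step}")
            for mod, g in zip(mods, dZ):
                grads = encoders[mod].backward(caches[mod], g)
                optimizers[mod].step(grads)
            model.loss_trace.append(loss)
            model.step_batches.append(bid)
    return model


def encode_shared(
    encoders: Mapping[str, MLPEncoder],
    inputs: Mapping[str, ModalityInput],
) -> dict[str, SharedEmbedding]:
    """Encode every cell of every batch into the shared space (dropout off)."""
    out = {}
    for mod, mi in inputs.items():
        out[mod] = SharedEmbedding(
            modality=mod, rows=list(mi.rows), values=encoders[mod].encode(mi.values)
        )
    return out


#: Default one-hot alignment consensus: prefer RNA, then Protein, then first
#: measured modality — multimodal batches take exactly one modality's rows.
_CONSENSUS_PRIORITY = ("RNA", "Protein")


def default_align_weights(measured: Sequence[str]) -> dict[str, float]:
    if len(measured) == 1:
        return {measured[0]: 1.0}
    for pref in _CONSENSUS_PRIORITY:
        if pref in measured:
            return {m: (1.0 if m == pref else 0.0) for m in measured}
    return {m: (1.0 if m == sorted(measured)[0] else 0.0) for m in measured}


def consensus_align(
    shared: Mapping[str, SharedEmbedding],
    ds: MosaicDataset,
    weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Per-cell weighted average over measured modalities, for all cells.

    ``weights`` (modality -> weight in [0, 1]) are restricted to each batch's
    measured set and renormalized to sum to 1; ``None`` uses the default
    one-hot scheme.  Single-modality batches pass through unchanged.
    """
    lookup = {
        mod: {rc: i for i, rc in enumerate(se.rows)} for mod, se in shared.items()
    }
    d = next(iter(shared.values())).values.shape[1]
    rows = ds.all_rows()
    consensus = np.zeros((len(rows), d))
    pos = 0
    for b in ds.batches:
        measured = sorted(b.matrices)
        if weights is None:
            w = default_align_weights(measured)
        else:
            w = {m: float(weights.get(m, 0.0)) for m in measured}
            tot = sum(w.values())
            if tot <= 0:
                raise MosaicError(
                    f"batch {b.batch_id!r}: consensus weights vanish on measured set {measured}"
                )
            w = {m: v / tot for m, v in w.items()}
        for c in b.cell_ids:
            vec = np.zeros(d)
            for m in measured:
                if w[m]:
                    vec += w[m] * shared[m].values[lookup[m][(b.batch_id, c)]]
            consensus[pos] = vec
            pos += 1
    return consensus, rows
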