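"""End-to-end orchestration: simulate -> preprocess -> align -> spec -> evaluate.

Every run directory is stamped with the config hash and global seed; stage
wall times and loss traces are logged.  On a stage failure, partial outputs
are retained alongside a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ace.align import SharedEmbedding, TrainConfig, consensus_align, encode_shared, train_align
from ace.config import RunConfig
from ace.data_model import (
    MosaicDataset,
    build_bridge_graph,
    load_mosaic_dir,
    require_connected,
    write_embeddings,
    write_mosaic,
)
from ace.losses import LossConfig
from ace.metrics import aggregate_scores, evaluate_embedding
from ace.nn import EncoderSpec, default_encoder_spec
from ace.preprocess import ModalityInput, correct_batches, reduce_modality
from ace.spec import (
    ImputationConfig,
    consensus_spec,
    encode_specific,
    impute_missing_embeddings,
    train_spec,
)
from ace.synthetic import easy_mosaic


def small_data_train_configs(seed: int = 0) -> tuple[TrainConfig, TrainConfig]:
    """Training profile for small datasets (hundreds of cells).

    The published defaults (batch 512, lr 2e-4) are tuned for datasets of
    1e4+ cells, where one epoch is tens of optimizer steps; on a few hundred
    bridge cells that schedule performs almost no updates.  This profile
    keeps the number of gradient steps in the hundreds: batch 64, lr 1e-3,
    30 alignment epochs and 10 specific-model epochs.
    """
    return (
        TrainConfig(lr=1e-3, batch_size=64, epochs=30, seed=seed),
        TrainConfig(lr=1e-3, batch_size=64, epochs=10, seed=seed),
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def preprocess_dataset(ds: MosaicDataset, cfg: RunConfig) -> dict[str, ModalityInput]:
    """Reduce + batch-correct every modality according to the config."""
    inputs: dict[str, ModalityInput] = {}
    seed = cfg.stage_seed("preprocess")
    for mod in ds.modalities:
        mcfg = cfg.modalities.get(mod)
        if mcfg is None:
            method = "tfidf_lsi" if mod == "ATAC" else "pca"
            p = min(100, min(ds.modality_matrix(mod).shape) - 1)
            drop_first = mod == "ATAC"
            corr = "center"
        else:
            method = mcfg.reduction.method
            p = mcfg.reduction.p
            drop_first = mcfg.reduction.drop_first
            corr = mcfg.correction.method
        mi = reduce_modality(ds, mod, method=method, p=p, seed=seed, drop_first=drop_first)
        inputs[mod] = correct_batches(mi, method=corr, seed=seed)
    return inputs


def encoder_specs(inputs: Mapping[str, ModalityInput], cfg: RunConfig) -> dict[str, EncoderSpec]:
    specs = {}
    for mod, mi in inputs.items():
        mcfg = cfg.modalities.get(mod)
        if mcfg is not None and mcfg.layer_dims:
            specs[mod] = EncoderSpec(modality=mod, input_dim=mi.p, layer_dims=list(mcfg.layer_dims))
        else:
            specs[mod] = default_encoder_spec(mod, mi.p)
    return specs


def run_pipeline(cfg: RunConfig, out_dir, ds: MosaicDataset | None = None,
                 truth=None) -> Path:
    """Execute the requested stages in order, writing artifacts under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    stage = "setup"

    def finish_stage(name: str, t0: float, **extra) -> None:
        log["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3), **extra}

    try:
        # ---- data ---------------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        if ds is None:
            if cfg.simulate.enabled:
                ds, truth = easy_mosaic(seed=cfg.simulate.data_seed)
                write_mosaic(ds, out / "mosaic")
            elif cfg.input_dir:
                ds = load_mosaic_dir(cfg.input_dir)
            else:
                raise ValueError("no input mosaic: enable simulate or set input_dir")
        require_connected(build_bridge_graph(ds))
        finish_stage(stage, t0, n_cells=ds.n_cells, modalities=list(ds.modalities))

        # ---- preprocess ----------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        inputs = preprocess_dataset(ds, cfg)
        finish_stage(stage, t0, dims={m: mi.p for m, mi in inputs.items()})

        # ---- align ---------------------------------------------------------
        stage = "align"
        t0 = time.perf_counter()
        specs = encoder_specs(inputs, cfg)
        loss_cfg = LossConfig(tau=cfg.loss.tau,
                              include_intra_negatives=cfg.loss.include_intra_negatives)
        align_cfg = TrainConfig(lr=cfg.train.lr, batch_size=cfg.train.batch_size,
                                epochs=cfg.train.epochs, seed=cfg.stage_seed("align"))
        model = train_align(inputs, ds, specs, align_cfg, loss_cfg)
        shared = encode_shared(model.encoders, inputs)
        consensus, rows = consensus_align(shared, ds, cfg.consensus.weights)
        for mod, se in shared.items():
            write_embeddings(se.values, se.rows, out / f"shared_{mod}.csv")
        write_embeddings(consensus, rows, out / "consensus_align.csv")
        pd.DataFrame({"step": range(len(model.loss_trace)),
                      "loss": model.loss_trace,
                      "bridge_batch": model.step_batches}).to_csv(
            out / "align_loss_trace.csv", index=False)
        finish_stage(stage, t0, steps=len(model.loss_trace),
                     final_loss=model.loss_trace[-1] if model.loss_trace else None)

        # ---- spec ----------------------------------------------------------
        stage = "spec"
        t0 = time.perf_counter()
        spec_cfg = TrainConfig(lr=cfg.spec_train.lr, batch_size=cfg.spec_train.batch_size,
                               epochs=cfg.spec_train.epochs, seed=cfg.stage_seed("spec"))
        spec_encoders, spec_traces = train_spec(inputs, specs, spec_cfg, loss_cfg)
        specific = encode_specific(spec_encoders, inputs)
        completed = impute_missing_embeddings(
            shared, specific, ds, ImputationConfig(k=cfg.impute.k, metric=cfg.impute.metric))
        spec_consensus, spec_rows = consensus_spec(completed, ds)
        for mod, se in completed.items():
            df = pd.DataFrame(se.values, columns=[f"e{j}" for j in range(se.values.shape[1])])
            df.insert(0, "imputed", se.imputed_mask.astype(int))
            df.insert(0, "cell_id", [c for _, c in se.rows])
            df.insert(0, "batch_id", [b for b, _ in se.rows])
            df.to_csv(out / f"specific_{mod}.csv", index=False, float_format="%.17g")
        write_embeddings(spec_consensus, spec_rows, out / "consensus_spec.csv")
        finish_stage(stage, t0, steps={m: len(t) for m, t in spec_traces.items()})

        # ---- evaluate ------------------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        report = evaluate_run(ds, truth, shared, consensus, spec_consensus, rows, cfg)
        if report is not None:
            report.to_csv(out / "report.csv")
        finish_stage(stage, t0)
    except BaseException as exc:
        log["stages"][stage] = {"error": str(exc)}
        (out / "FAILED").write_text(f"stage: {stage}\n{traceback.format_exc()}")
        (out / "run.json").write_text(json.dumps(log, indent=2, default=str))
        raise StageFailure(stage, exc) from exc

    (out / "run.json").write_text(json.dumps(log, indent=2, default=str))
    return out


def evaluate_run(ds, truth, shared: Mapping[str, SharedEmbedding],
                 consensus_a: np.ndarray, consensus_s: np.ndarray,
                 rows, cfg: RunConfig) -> pd.DataFrame | None:
    """Metric table for the two consensus embeddings (needs cell-type labels)."""
    if ds.cell_type_labels is None:
        return None
    cell_types = ds.types_for(rows)
    batch_labels = np.asarray([b for b, _ in rows])
    mod_combo = {b.batch_id: "+".join(sorted(b.matrices)) for b in ds.batches}
    modality_labels = np.asarray([mod_combo[b] for b, _ in rows])
    pairs = None
    if truth is not None and len(shared) == 2 and truth.pairing:
        ma, mb = sorted(shared)
        pos = {rc: i for i, rc in enumerate(shared[ma].rows)}
        posb = {rc: i for i, rc in enumerate(shared[mb].rows)}
        bridge = [rc for rc in truth.pairing if rc in pos and rc in posb]
        pairs = (shared[ma].values[[pos[rc] for rc in bridge]],
                 shared[mb].values[[posb[rc] for rc in bridge]])
    table = {}
    seed = cfg.stage_seed("evaluate")
    table["ACE-align"] = evaluate_embedding(
        consensus_a, cell_types, batch_labels, modality_labels, pairs,
        cfg.evaluate.n_neighbors_ilisi, clustering_seed=seed)
    table["ACE-spec"] = evaluate_embedding(
        consensus_s, cell_types, batch_labels, modality_labels, None,
        cfg.evaluate.n_neighbors_ilisi, clustering_seed=seed)
    st = pd.DataFrame(table).T
    # aggregation requires every column for every method; keep raw table +
    # aggregate only over the shared columns
    common = [c for c in st.columns if st[c].notna().all()]
    agg = aggregate_scores(st[common]) if {"nmi", "ari", "ilisi_batch", "ilisi_mod"} <= set(common) else None
    return pd.concat([st, agg], axis=1) if agg is not None else st
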