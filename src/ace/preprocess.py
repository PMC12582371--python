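"""Per-modality dimensionality reduction and within-modality batch correction.

Encoders are trained on low-dimensional, batch-corrected per-modality
representations, not raw features.  RNA/protein use standardized PCA on
(optionally) library-size-normalized, log1p counts; ATAC uses TF-IDF + LSI
with the first component optionally dropped (it typically tracks sequencing
depth).  Batch correction within a modality is horizontal: Harmony through a
narrow adapter when available, or per-batch mean-centring (``center``) as a
lightweight fallback that exactly removes additive shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA, TruncatedSVD

from ace.data_model import MosaicDataset, MosaicError, canonical_modality


@dataclass
class ModalityInput:
    """Low-dimensional representation of one modality across all its batches."""

    modality: str
    rows: list[tuple[str, str]]  # global (batch_id, cell_id) index
    values: np.ndarray  # cells x p
    batch_labels: np.ndarray  # aligned to rows
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.rows):
            raise MosaicError("ModalityInput: values row count does not match rows index")
        if not np.all(np.isfinite(self.values)):
            raise MosaicError("ModalityInput: non-finite values")

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def block_slices(self) -> dict[str, slice]:
        """Contiguous row slice per batch (rows are grouped by batch)."""
        out: dict[str, slice] = {}
        start = 0
        current = None
        for i, b in enumerate(list(self.batch_labels) + [None]):
            if b != current:
                if current is not None:
                    out[current] = slice(start, i)
                current, start = b, i
        return out


def _tfidf(X: np.ndarray) -> np.ndarray:
    """Classic TF-IDF: term frequency times log(n_cells / document frequency).

    A feature observed in every cell gets IDF 0 and thus contributes nothing
    to the LSI decomposition; features observed nowhere likewise.
    """
    row_tot = X.sum(axis=1, keepdims=True)
    row_tot[row_tot == 0] = 1.0
    tf = X / row_tot
    df = (X > 0).sum(axis=0).astype(np.float64)
    idf = np.zeros_like(df)
    nz = df > 0
    idf[nz] = np.log(X.shape[0] / df[nz])
    return tf * idf


def reduce_modality(
    ds: MosaicDataset,
    modality: str,
    method: str = "pca",
    p: int = 100,
    seed: int = 0,
    normalize: str | bool = "auto",
    drop_first: bool = False,
) -> ModalityInput:
    """Reduce one modality's features to ``p`` dimensions over all its cells.

    Parameters
    ----------
    method
        ``pca``: library-size normalization to the median total + log1p
        (only when the data are non-negative counts, or ``normalize=True``),
        feature standardization, then top-``p`` principal components.
        ``tfidf_lsi``: TF-IDF transform then top singular vectors, with the
        first component dropped when ``drop_first`` (depth-correlated).
        ``passthrough``: identity, for pre-reduced inputs.
    """
    modality = canonical_modality(modality)
    X = ds.modality_matrix(modality)
    rows = ds.modality_rows(modality)
    batch_labels = ds.modality_batch_labels(modality)
    prov = {"reduction": method, "p": p, "seed": seed}

    zero_rows = np.where(np.abs(X).sum(axis=1) == 0)[0]
    if zero_rows.size:
        warnings.warn(
            f"{modality}: {zero_rows.size} all-zero rows kept as zero vectors", stacklevel=2
        )

    if method == "passthrough":
        return ModalityInput(modality, rows, X.copy(), batch_labels, prov)

    max_p = min(X.shape)
    if p > max_p:
        raise MosaicError(
            f"{modality}: requested p={p} exceeds min(cells, features)={max_p}"
        )

    if method == "pca":
        do_norm = bool(normalize) if normalize != "auto" else bool(np.all(X >= 0))
        Y = X
        if do_norm:
            totals = Y.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            Y = np.log1p(Y / totals * np.median(Y.sum(axis=1)))
        mu = Y.mean(axis=0)
        sd = Y.std(axis=0)
        sd[sd == 0] = 1.0
        Y = (Y - mu) / sd
        comps = PCA(n_components=p, random_state=seed).fit_transform(Y)
        prov["normalized"] = do_norm
        return ModalityInput(modality, rows, comps, batch_labels, prov)

    if method == "tfidf_lsi":
        if np.any(X < 0):
            raise MosaicError(f"{modality}: tfidf_lsi requires non-negative counts")
        Y = _tfidf(X)
        n_comp = p + 1 if drop_first else p
        if n_comp >= min(Y.shape):
            raise MosaicError(f"{modality}: p={p} too large for tfidf_lsi on shape {Y.shape}")
        svd = TruncatedSVD(n_components=n_comp, random_state=seed)
        comps = svd.fit_transform(Y)
        if drop_first:
            comps = comps[:, 1:]
        prov["drop_first"] = drop_first
        return ModalityInput(modality, rows, comps, batch_labels, prov)

    raise MosaicError(f"unknown reduction method {method!r}")


def correct_batches(
    mi: ModalityInput,
    batch_labels: Sequence | None = None,
    method: str = "center",
    seed: int = 0,
) -> ModalityInput:
    """Horizontal batch correction within one modality.

    ``harmony`` delegates to an external Harmony implementation through a
    narrow adapter (matrix + labels in, matrix out); ``center`` subtracts the
    per-batch mean and adds back the global mean, which exactly removes
    purely additive shifts; ``none`` is the identity.
    """
    labels = np.asarray(batch_labels if batch_labels is not None else mi.batch_labels)
    if len(labels) != mi.values.shape[0]:
        raise MosaicError("batch labels not aligned to ModalityInput rows")
    prov = dict(mi.provenance, correction=method)

    if method == "none":
        return ModalityInput(mi.modality, mi.rows, mi.values.copy(), mi.batch_labels, prov)

    uniq = np.unique(labels)
    if method == "center":
        if len(uniq) == 1:
            return ModalityInput(mi.modality, mi.rows, mi.values.copy(), mi.batch_labels, prov)
        out = mi.values.copy()
        global_mean = out.mean(axis=0)
        for b in uniq:
            mask = labels == b
            out[mask] += global_mean - out[mask].mean(axis=0)
        return ModalityInput(mi.modality, mi.rows, out, mi.batch_labels, prov)

    if method == "harmony":
        if len(uniq) == 1:
            warnings.warn(
                f"{mi.modality}: single batch, harmony is a no-op", stacklevel=2
            )
            return ModalityInput(mi.modality, mi.rows, mi.values.copy(), mi.batch_labels, prov)
        try:
            import harmonypy
        except ImportError as exc:
            raise MosaicError(
                "harmony correction requires the 'harmonypy' package, which is not "
                "installed; use method='center' or method='none' instead"
            ) from exc
        import pandas as pd

        meta = pd.DataFrame({"batch": labels})
        ho = harmonypy.run_harmony(mi.values, meta, ["batch"], random_state=seed)
        return ModalityInput(mi.modality, mi.rows, ho.Z_corr.T, mi.batch_labels, prov)

    raise MosaicError(f"unknown correction method {method!r}")
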