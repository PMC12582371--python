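"""Contrastive objectives for modality alignment and modality-specific training.

Three losses, all built on temperature-scaled cosine similarities over a
mini-batch of n cells:

* :func:`infonce_loss` — the plain bimodal InfoNCE objective: for each cell,
  its other-modality embedding is the positive and the other cells'
  other-modality embeddings are the negatives.  The denominator ranges over
  cross-modal similarities only, which leaves intra-modality geometry
  unconstrained and produces the *modality gap*.
* :func:`ace_align_loss` — the alignment objective: per anchor (cell i,
  modality j) the positives are cell i's embeddings in every other modality,
  and the denominator additionally includes intra-modality similarities to
  the other n-1 cells of modality j.  One shared denominator per anchor
  (i, j).  With intra-modality negatives disabled and M = 2 this reduces
  exactly to InfoNCE.
* :func:`specificity_loss` — the modality-specific objective: each cell is
  its own positive (similarity fixed at exactly 1), all other cells in the
  same modality are negatives, so the encoder learns to spread cells apart
  while owing nothing to other modalities.

Each loss has a ``*_with_grad`` variant returning analytic gradients with
respect to the embedding matrices; the training loops chain these through
the encoders.  All log-sum-exp denominators use max-subtraction (at the
default temperature 0.1 the exponents reach 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp


@dataclass
class LossConfig:
    """Temperature and loss-variant switches.

    ``tau`` is a fixed positive constant (default 0.1);
    ``include_intra_negatives`` selects the proposed alignment loss over
    plain InfoNCE.
    """

    tau: float = 0.1
    include_intra_negatives: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


class MiniBatchEmbeddings:
    """Per-modality n x d embeddings of the same n cells in the same order."""

    def __init__(self, embeddings: Mapping[str, np.ndarray]):
        if not embeddings:
            raise ValueError("empty mini-batch")
        self.modalities = list(embeddings)
        self.arrays = [np.asarray(embeddings[m], dtype=np.float64) for m in self.modalities]
        shape = self.arrays[0].shape
        if len(shape) != 2:
            raise ValueError("embeddings must be 2-D")
        for m, a in zip(self.modalities, self.arrays):
            if a.shape != shape:
                raise ValueError(
                    f"modality {m!r} has shape {a.shape}, expected {shape} (same n and d "
                    "for all modalities)"
                )
        self.n, self.d = shape

    @property
    def M(self) -> int:
        return len(self.arrays)


def _coerce(mb) -> list[np.ndarray]:
    if isinstance(mb, MiniBatchEmbeddings):
        return mb.arrays
    if isinstance(mb, Mapping):
        return MiniBatchEmbeddings(mb).arrays
    arrays = [np.asarray(a, dtype=np.float64) for a in mb]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("all modalities must share the same (n, d) shape")
    return arrays


def _normalize_rows(Z: np.ndarray, name: str = "embeddings") -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{name}: zero-norm row(s) at {np.where(norms == 0)[0].tolist()}")
    return Z / norms[:, None], norms


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities: entry (i, l) = cos(A_i, B_l), in [-1, 1]."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    Ua, _ = _normalize_rows(A, "A")
    Ub, _ = _normalize_rows(B, "B")
    return Ua @ Ub.T


def _grad_through_normalization(Z: np.ndarray, U: np.ndarray, norms: np.ndarray,
                                dU: np.ndarray) -> np.ndarray:
    # d(z/|z|)/dz applied to the upstream gradient: (g - (g.u) u) / |z|
    proj = np.einsum("ij,ij->i", dU, U)
    return (dU - proj[:, None] * U) / norms[:, None]


def _alignment_core(arrays: Sequence[np.ndarray], tau: float, include_intra: bool,
                    want_grad: bool):
    """Shared evaluator for InfoNCE and the generalized alignment loss.

    Loss = -(1/(M n)) sum_{i,j} l(i,j) with
    l(i,j) = sum_{p != j} [ s_{ii}^{jp}/tau ] - (M-1) log D_{ij},
    D_{ij} = sum_{v != j} sum_l exp(s_{il}^{jv}/tau)
             [+ sum_{l != i} exp(s_{il}^{jj}/tau) when intra negatives are on].
    """
    M = len(arrays)
    n, _ = arrays[0].shape
    units, norms = [], []
    for j, Z in enumerate(arrays):
        U, nr = _normalize_rows(Z, f"modality {j}")
        units.append(U)
        norms.append(nr)

    # similarity blocks; S[j][v] = U_j U_v^T
    S = [[units[j] @ units[v].T for v in range(M)] for j in range(M)]

    total = 0.0
    dU = [np.zeros_like(U) for U in units] if want_grad else None
    for j in range(M):
        blocks = []
        for v in range(M):
            if v == j:
                if include_intra:
                    blk = S[j][j] / tau
                    np.fill_diagonal(blk, -np.inf)  # anchor's own self-similarity excluded
                    blocks.append((v, blk))
            else:
                blocks.append((v, S[j][v] / tau))
        concat = np.concatenate([blk for _, blk in blocks], axis=1)
        logD = logsumexp(concat, axis=1)  # max-subtracted internally
        pos = sum(np.diag(S[j][p]) / tau for p in range(M) if p != j)
        total += float(np.sum(pos - (M - 1) * logD))

        if want_grad:
            P = np.exp(concat - logD[:, None])  # softmax over the shared denominator
            col = 0
            scale = 1.0 / (M * n * tau)
            for v, blk in blocks:
                Pv = P[:, col:col + n]
                col += n
                G = scale * (M - 1) * Pv
                if v == j:
                    np.fill_diagonal(G, 0.0)
                    dU[j] += (G + G.T) @ units[j]
                else:
                    G = G.copy()
                    G[np.arange(n), np.arange(n)] -= scale  # positive-pair term
                    dU[j] += G @ units[v]
                    dU[v] += G.T @ units[j]

    loss = -total / (M * n)
    if not want_grad:
        return loss, None
    dZ = [
        _grad_through_normalization(Z, U, nr, g)
        for Z, U, nr, g in zip(arrays, units, norms, dU)
    ]
    return loss, dZ


def infonce_loss(mb, cfg: LossConfig | None = None) -> float:
    """Bimodal InfoNCE loss (cross-modal negatives only); requires M = 2."""
    cfg = cfg or LossConfig()
    arrays = _coerce(mb)
    if len(arrays) != 2:
        raise ValueError(f"InfoNCE is defined for exactly 2 modalities, got {len(arrays)}")
    loss, _ = _alignment_core(arrays, cfg.tau, include_intra=False, want_grad=False)
    return loss


def ace_align_loss(mb, cfg: LossConfig | None = None) -> float:
    """Generalized alignment loss over M >= 2 modalities.

    With ``cfg.include_intra_negatives=False`` and M = 2 this is identical
    to :func:`infonce_loss` (same code path).
    """
    cfg = cfg or LossConfig()
    arrays = _coerce(mb)
    if len(arrays) < 2:
        raise ValueError("alignment loss needs at least 2 modalities")
    loss, _ = _alignment_core(arrays, cfg.tau, cfg.include_intra_negatives, want_grad=False)
    return loss


def ace_align_loss_with_grad(mb, cfg: LossConfig | None = None):
    """Alignment loss and its gradients w.r.t. each modality's embeddings."""
    cfg = cfg or LossConfig()
    arrays = _coerce(mb)
    if len(arrays) < 2:
        raise ValueError("alignment loss needs at least 2 modalities")
    return _alignment_core(arrays, cfg.tau, cfg.include_intra_negatives, want_grad=True)


def specificity_loss(zhat: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Modality-specific loss: self-positive (similarity exactly 1), all other
    cells in the mini-batch as negatives."""
    loss, _ = _specificity_core(zhat, (cfg or LossConfig()).tau, want_grad=False)
    return loss


def specificity_loss_with_grad(zhat: np.ndarray, cfg: LossConfig | None = None):
    return _specificity_core(zhat, (cfg or LossConfig()).tau, want_grad=True)


def _specificity_core(zhat: np.ndarray, tau: float, want_grad: bool):
    Z = np.asarray(zhat, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("expected a non-empty n x d embedding matrix")
    n = Z.shape[0]
    U, norms = _normalize_rows(Z)
    S = U @ U.T
    np.fill_diagonal(S, 1.0)  # the self-similarity is 1 by definition, not recomputed
    logD = logsumexp(S / tau, axis=1)
    loss = -float(np.sum(1.0 / tau - logD)) / n
    if not want_grad:
        return loss, None
    P = np.exp(S / tau - logD[:, None])
    G = P / (n * tau)
    np.fill_diagonal(G, 0.0)  # diagonal carries no gradient (identically 1)
    dU = (G + G.T) @ U
    return loss, _grad_through_normalization(Z, U, norms, dU)
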