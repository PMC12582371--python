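"""Integration-quality metrics and scIB-style score aggregation.

Three families of metrics:

* **Biological conservation** — NMI and ARI between a clustering of the
  embedding and reference cell-type labels (both 1 for a perfect match).
* **Batch correction** — graph iLISI computed with batch labels and, at a
  coarser resolution, with modality-combination labels; per cell the inverse
  Simpson's index of label proportions in a Gaussian-weighted neighbourhood,
  rescaled so 0 = fully separated and 1 = perfectly mixed.
* **Modality alignment** — FOSCTTM (reported on the 1-is-perfect scale, i.e.
  one minus the classical fraction-closer-than-the-true-match) and the
  matching score (mean probability mass a cross-modal kNN matching places on
  the true paired cell), both averaged over the two matching directions.

Per-metric values are min-max scaled across the compared methods, averaged
within each family, and combined into an overall score with weights
(bio, batch) = (0.6, 0.4) when modality alignment cannot be evaluated and
(0.4, 0.3, 0.3) when it can.
"""

from __future__ import annotations

import random
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors


def _check_labels(labels_a, labels_b):
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty label vectors")
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return a, b


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    A single-cluster partition carries zero entropy, so any comparison with
    one returns 0 by convention.
    """
    a, b = _check_labels(labels_a, labels_b)
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index; 1 = identical partitions, 0 = random."""
    a, b = _check_labels(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def _simpson_per_cell(distances: np.ndarray, neighbor_labels: np.ndarray,
                      n_categories: int, perplexity: float,
                      tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Inverse Simpson's index per cell over Gaussian-kernel neighbourhoods.

    Per-cell bandwidth is tuned by binary search so the kernel entropy equals
    log(perplexity), the convention of LISI-style batch-mixing scores.
    """
    n, k = distances.shape
    target = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        beta, lo, hi = 1.0, -np.inf, np.inf
        D = distances[i]
        for _ in range(max_iter):
            P = np.exp(-beta * D)
            sumP = P.sum()
            if sumP == 0:
                H, P = 0.0, np.zeros_like(D)
            else:
                H = np.log(sumP) + beta * (D * P).sum() / sumP
                P = P / sumP
            diff = H - target
            if abs(diff) < tol:
                break
            if diff > 0:
                lo = beta
                beta = beta * 2 if np.isinf(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if np.isinf(lo) else (beta + lo) / 2
        probs = np.zeros(n_categories)
        np.add.at(probs, neighbor_labels[i], P)
        out[i] = 1.0 / max(np.sum(probs**2), 1e-12)
    return out


def graph_ilisi(emb: np.ndarray, labels, n_neighbors: int = 90) -> float:
    """Graph iLISI of ``labels`` in the embedding, rescaled to [0, 1].

    Mean inverse Simpson's index of label proportions over each cell's
    ``n_neighbors`` nearest neighbours (Gaussian kernel, perplexity
    ``n_neighbors / 3``), rescaled by (mean - 1)/(B - 1) for B categories:
    0 = complete separation, 1 = perfect mixing.
    """
    emb = np.asarray(emb, dtype=np.float64)
    labels = np.asarray(labels)
    cats, codes = np.unique(labels, return_inverse=True)
    B = len(cats)
    if B < 2:
        raise ValueError("iLISI needs at least two label categories")
    n = emb.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    lisi = _simpson_per_cell(dist, codes[idx], B, perplexity=max(k / 3, 1.01))
    score = (float(np.mean(lisi)) - 1.0) / (B - 1.0)
    return float(np.clip(score, 0.0, 1.0))


def foscttm(za: np.ndarray, zb: np.ndarray) -> float:
    """FOSCTTM on the 1-is-perfect scale, averaged over both directions.

    Row i of ``za`` and ``zb`` are true cross-modal matches.  For each cell
    the fraction of the other modality's n-1 remaining cells strictly closer
    (Euclidean) than the true match is averaged over cells and directions;
    1 minus that mean is returned, so 1 = perfect alignment.
    """
    za = np.asarray(za, dtype=np.float64)
    zb = np.asarray(zb, dtype=np.float64)
    if za.shape != zb.shape:
        raise ValueError("paired embeddings must have identical shapes")
    n = za.shape[0]
    if n < 2:
        raise ValueError("FOSCTTM needs at least 2 paired cells")
    D = cdist(za, zb)
    true = np.diag(D)
    frac_a = (D < true[:, None]).sum(axis=1) / (n - 1)  # za_i vs all zb
    frac_b = (D < true[None, :]).sum(axis=0) / (n - 1)  # zb_l vs all za
    return float(1.0 - (frac_a.mean() + frac_b.mean()) / 2.0)


def matching_score(za: np.ndarray, zb: np.ndarray, k: int = 10) -> float:
    """Mean probability mass a cross-modal kNN matching puts on the true match.

    The k nearest opposite-modality cells of each cell receive probability
    1/k each; the score is the mean probability of the true match, averaged
    over both directions.  1 = the true match is the sole neighbour (k = 1).
    """
    za = np.asarray(za, dtype=np.float64)
    zb = np.asarray(zb, dtype=np.float64)
    if za.shape != zb.shape:
        raise ValueError("paired embeddings must have identical shapes")
    n = za.shape[0]
    if n < 2:
        raise ValueError("matching score needs at least 2 paired cells")
    k = min(k, n - 1)
    D = cdist(za, zb)

    def direction(dmat: np.ndarray) -> float:
        nbrs = np.argsort(dmat, axis=1, kind="stable")[:, :k]
        hit = (nbrs == np.arange(n)[:, None]).any(axis=1)
        return float(hit.mean() / k)

    return (direction(D) + direction(D.T)) / 2.0


# ---------------------------------------------------------------------------
# Clustering label producer for NMI/ARI on embeddings
# ---------------------------------------------------------------------------

def cluster_embedding(
    emb: np.ndarray,
    method: str = "louvain",
    n_neighbors: int = 15,
    resolution: float = 1.0,
    n_clusters: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Cluster an embedding: SNN-graph Louvain (default) or K-means fallback.

    The SNN graph uses Jaccard overlap of k-nearest-neighbour sets as edge
    weights (edges with zero overlap dropped), clustered with multilevel
    Louvain at the given resolution.
    """
    emb = np.asarray(emb, dtype=np.float64)
    n = emb.shape[0]
    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        return km.fit_predict(emb)
    if method != "louvain":
        raise ValueError(f"unknown clustering method {method!r}")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[int(j)])
            jac = inter / len(neigh[i] | neigh[int(j)])
            if jac > 0:
                edges.append((i, int(j)))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership)


def cluster_optimal_resolution(
    emb: np.ndarray,
    reference_labels,
    resolutions: Sequence[float] | None = None,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Louvain labels at the resolution maximizing NMI with a reference.

    The scIB convention for scoring embeddings against annotations: sweep
    Louvain resolutions (default 0.1 .. 2.0) and keep the clustering with
    the highest NMI versus ``reference_labels``.
    """
    if resolutions is None:
        resolutions = [round(0.1 * r, 1) for r in range(1, 21)]
    best_labels, best_nmi = None, -1.0
    for res in resolutions:
        labels = cluster_embedding(
            emb, n_neighbors=n_neighbors, resolution=float(res), seed=seed
        )
        score = nmi(labels, reference_labels)
        if score > best_nmi:
            best_nmi, best_labels = score, labels
    return best_labels


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

BIO_METRICS = ("nmi", "ari")
BATCH_METRICS = ("ilisi_batch", "ilisi_mod")
MODALIGN_METRICS = ("foscttm_score", "matching_score")

#: Default family weights with and without modality-alignment metrics.
WEIGHTS_WITH_MODALIGN = {"bio": 0.4, "batch": 0.3, "modAlign": 0.3}
WEIGHTS_WITHOUT_MODALIGN = {"bio": 0.6, "batch": 0.4}


def minmax_scale_columns(st: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each metric column across methods; constant columns -> 0.5."""
    out = st.astype(float).copy()
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        out[col] = 0.5 if hi == lo else (out[col] - lo) / (hi - lo)
    return out


def aggregate_scores(
    st: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """scIB-style aggregation of a methods x metrics table.

    Columns must use the canonical metric names (``nmi``, ``ari``,
    ``ilisi_batch``, ``ilisi_mod``, ``foscttm_score``, ``matching_score``).
    Each column is min-max scaled across methods, families are averaged
    (S_bio, S_batch, S_modAlign), and the overall score is their weighted
    sum.  ``weights`` maps family -> weight and must sum to 1; by default
    (0.4, 0.3, 0.3) when the modality-alignment columns are present, else
    (0.6, 0.4).
    """
    if not np.all(np.isfinite(st.to_numpy(dtype=float))):
        raise ValueError("score table contains non-finite values")
    has_modalign = all(c in st.columns for c in MODALIGN_METRICS)
    if weights is None:
        weights = WEIGHTS_WITH_MODALIGN if has_modalign else WEIGHTS_WITHOUT_MODALIGN
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"aggregation weights must sum to 1, got {total}")

    scaled = minmax_scale_columns(st)
    out = pd.DataFrame(index=st.index)
    families = {"bio": BIO_METRICS, "batch": BATCH_METRICS, "modAlign": MODALIGN_METRICS}
    overall = pd.Series(0.0, index=st.index)
    for fam, cols in families.items():
        w = float(weights.get(fam, 0.0))
        if w == 0.0 and not all(c in scaled.columns for c in cols):
            continue
        missing = [c for c in cols if c not in scaled.columns]
        if missing:
            raise ValueError(f"family {fam!r} requested but columns missing: {missing}")
        fam_score = scaled[list(cols)].mean(axis=1)
        out[f"S_{fam}"] = fam_score
        overall += w * fam_score
    out["S_overall"] = overall
    return out


def evaluate_embedding(
    emb: np.ndarray,
    cell_types: Sequence | None = None,
    batch_labels: Sequence | None = None,
    modality_labels: Sequence | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    n_neighbors_ilisi: int = 90,
    clustering_seed: int = 0,
) -> dict[str, float]:
    """Convenience: compute every applicable raw metric for one embedding."""
    res: dict[str, float] = {}
    if cell_types is not None:
        clusters = cluster_optimal_resolution(emb, cell_types, seed=clustering_seed)
        res["nmi"] = nmi(clusters, cell_types)
        res["ari"] = ari(clusters, cell_types)
    if batch_labels is not None:
        res["ilisi_batch"] = graph_ilisi(emb, batch_labels, n_neighbors_ilisi)
    if modality_labels is not None:
        res["ilisi_mod"] = graph_ilisi(emb, modality_labels, n_neighbors_ilisi)
    if pairs is not None:
        za, zb = pairs
        res["foscttm_score"] = foscttm(za, zb)
        res["matching_score"] = matching_score(za, zb)
    return res
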