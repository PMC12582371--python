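# Methods

## Problem setting

A *mosaic* single-cell dataset is a collection of batches in which each batch
measures only a subset of the modalities of interest (RNA expression, ATAC
accessibility, surface protein/ADT abundance, histone marks).  Batch $b_i$
supplies, for each measured modality $m_j$, a cells-by-features matrix
$X_{b_i}^{m_j} \in \mathbb{R}^{N_{b_i} \times D_{m_j}}$; $T_{b_i}$ denotes
the measured modality set and $\bar T_{b_i}$ the missing one.  The goal is a
per-cell consensus embedding $z_{b,i}$ in which biological state, not batch
or modality of origin, drives proximity.

Integration is only possible if every modality is linked to the rest through
*bridge* batches — batches measuring two or more modalities, whose rows are
physically paired cells.  Viewing modalities as nodes and each multimodal
batch as a clique over its measured set, the package requires this bridge
graph to be connected (`ace.data_model.require_connected`) and reports the
disconnected components otherwise.

## Preprocessing

Encoders are trained on low-dimensional per-modality representations rather
than raw features:

* RNA and protein: library-size normalization to the median total followed by
  `log1p` (applied only when the input is a non-negative count matrix),
  feature standardization, and PCA.  Protein panels skip feature selection.
* ATAC: TF-IDF (term frequency times $\log(n/\mathrm{df})$, so ubiquitous
  peaks receive weight zero) followed by truncated SVD, with the first
  component optionally dropped since it typically tracks sequencing depth.
* `passthrough` accepts pre-reduced inputs unchanged.

The default reduced dimension is $p = 100$ (clamped to the matrix rank for
narrow panels); all choices are per-modality configurable.

Within each modality, horizontal batch effects are removed before training.
Harmony is the intended correction and is wrapped behind a narrow adapter
(matrix + labels in, matrix out) rather than reimplemented; when the adapter
is unavailable, `center` subtracts the per-batch mean and restores the global
mean.  `center` exactly removes any purely additive shift, which is also
exactly the batch-effect model of the synthetic generator — this pairing
gives an end-to-end test in which correction provably succeeds.

## Alignment model

One encoder per modality maps its reduced input to a shared
$d$-dimensional space ($d = 256$): three dense layers (1024/512/256 for RNA
and ATAC, 512/2048/256 for protein), ELU and dropout $P = 0.2$ after the
first two.  Training samples mini-batches of $n$ paired cells from a bridge
batch (the batch chosen with probability proportional to its cell count,
cells without replacement) and minimizes a contrastive loss over
temperature-scaled cosine similarities $s^{j,v}_{i,l} =
\cos(z_i^{m_j}, z_l^{m_v})$ with fixed $\tau = 0.1$.

Plain InfoNCE treats only cross-modal pairs: for each cell, its own
other-modality embedding is the positive and other cells' other-modality
embeddings are negatives.  Because intra-modality geometry is never
penalized, embeddings of different modalities can remain linearly separable
after training — the *modality gap*.  The alignment loss used here adds
intra-modality pairs between different cells to the denominator: for anchor
(cell $i$, modality $j$) with $M$ modalities,

$$
\ell(i,j) = \sum_{p \ne j} \log
\frac{\exp(s^{j,p}_{i,i}/\tau)}
{\sum_{v \ne j}\sum_{l=1}^{n} \exp(s^{j,v}_{i,l}/\tau)
 + \sum_{l \ne i} \exp(s^{j,j}_{i,l}/\tau)},
\qquad
\mathcal{L} = -\frac{1}{Mn}\sum_{i}\sum_{j} \ell(i,j),
$$

with one shared denominator per anchor $(i,j)$.  With intra-modality
negatives disabled and $M = 2$ this reduces bit-for-bit to InfoNCE (the test
suite asserts this on random mini-batches).  If a sampled bridge batch
measures only $M' < M$ modalities, the loss is computed over those $M'$.

After training, every cell of every batch is encoded, and the consensus is a
weighted average over the cell's measured modalities.  Defaults are one-hot:
weight 1 on RNA for multimodal batches (protein when RNA is absent,
otherwise the alphabetically first measured modality), and weight 1 on the
single modality otherwise; custom weights are renormalized over each batch's
measured set.  Embeddings are stored un-normalized — cosine similarity in
the loss makes scale irrelevant, and the one-hot default means consensus
rows are single encoder outputs.

## Modality-specific model and imputation

Alignment can sacrifice information unique to one modality.  The specific
model therefore trains a second, fully independent encoder per modality
(same architecture, $\tau$, and in full-scale runs lr $1.75\times10^{-4}$
for 10 epochs) with a self-supervised separation objective: each cell is its
own positive with similarity fixed at exactly 1, and all other cells of the
same modality in the mini-batch are negatives.  Mini-batches are drawn from
*all* cells measuring the modality, not just bridges, and training one
modality never touches another's data.

Missing modalities are then imputed by cross-modality matching.  For batch
$b$, missing modality $m_j$, and each measured source modality $m_t$: each
cell's shared-space embedding $z^{m_t}$ is matched to its $k$ nearest
neighbours (default $k = 2$, cosine similarity; Euclidean available) among
the shared-space embeddings of all cells measuring $m_j$, and the
neighbours' *specific* embeddings $\hat z^{m_j}$ are averaged.  The
per-source imputations are averaged with equal weight $1/|T_b|$.  Measured
rows are never overwritten.  Ties in the neighbour search break
deterministically by (similarity descending, candidate row index ascending);
the search is exact (all pairs), and the test suite checks neighbour sets
against a brute-force oracle, ties included.  The same matching transfers
raw feature profiles instead of embeddings, in which case imputed rows are
convex combinations of observed profiles (hence non-negative for count
inputs).  The final consensus is the unweighted mean over all modalities'
completed specific embeddings.

## Evaluation metrics

* **NMI / ARI** between a clustering of the embedding and reference cell
  types.  The label producer is Louvain on a shared-nearest-neighbour graph
  (Jaccard weights over 15-NN sets); following the scIB benchmarking
  convention, the evaluation path sweeps resolutions 0.1–2.0 and keeps the
  clustering with the highest NMI against the reference
  (`cluster_optimal_resolution`).  A fixed resolution systematically
  over-partitions small, clean datasets — at resolution 1.0 the 700-cell
  fixture's four types split into ~9 communities — so the sweep measures
  embedding quality rather than graph granularity.  K-means is available as
  a fallback.  NMI uses arithmetic-mean normalization, with the convention
  that a zero-entropy (single-cluster) partition scores 0.
* **Graph iLISI** with batch labels and, coarser, with modality-combination
  labels: per cell, the inverse Simpson's index of label proportions over
  its 90 nearest neighbours under a Gaussian kernel whose bandwidth is tuned
  per cell to perplexity $n_\text{neighbors}/3$; the mean is rescaled by
  $(\overline{\mathrm{LISI}}-1)/(B-1)$ so 0 = full separation, 1 = perfect
  mixing.  Note the kernel's effective sample size is roughly the
  perplexity, so even perfectly mixed random labels score slightly below 1
  at finite neighbourhood sizes.
* **FOSCTTM**, reported on the 1-is-perfect scale: one minus the mean
  fraction of opposite-modality cells strictly closer (Euclidean) than the
  true match, averaged over both directions.
* **Matching score**: the cross-modal $k$-NN indicator ($k = 10$ by
  default), row-normalized to a matching-probability matrix; the score is
  the mean probability mass on the true match, averaged over both
  directions (so the ceiling is $1/k$ for $k > 1$, and 1 when $k = 1$).
* **Aggregation**: each metric column is min-max scaled across the compared
  methods (a constant column maps to 0.5 for every method, avoiding 0/0);
  families are averaged into $S_\text{bio}$ (NMI, ARI), $S_\text{batch}$
  (iLISI batch, iLISI modality) and $S_\text{modAlign}$ (FOSCTTM, MS), then
  combined as $S_\text{overall} = w_\text{bio} S_\text{bio} + w_\text{batch}
  S_\text{batch} + w_\text{modAlign} S_\text{modAlign}$ with weights
  (0.6, 0.4) when modality alignment cannot be scored and (0.4, 0.3, 0.3)
  when it can.

## Synthetic data

The generator draws per-type centroids in a latent space (default dimension
8), per-cell latents as centroid plus Gaussian jitter, and per-modality
features as a fixed random linear map of the latent plus Gaussian noise and
an additive per-(batch, modality) shift.  Missingness deletes matrices;
`shared_type_proportion` restricts which cell types appear in which batches
(shared types in every batch, private types in exactly one);
`bridge_downsample` subsamples bridge cells.  Type assignment is balanced by
default.  A count-like variant (exponentiate-and-Poisson) exists for
feature-imputation tests.  Everything is reproducible from one seed.

The canonical fixture (`easy_mosaic`) has 700 cells in three batches — a
300-cell RNA+protein bridge, 200 RNA-only and 200 protein-only cells — four
cell types, 300 RNA features, 40 protein features, noise sd 0.3 and batch
shift sd 0.5.

What passing tests on this generator do and do not show: the generator
matches the model's structural assumptions (shared latent state behind
modalities, linear feature maps, additive batch effects), so success here
demonstrates algorithmic correctness and internal consistency, not
robustness to the count noise, nonlinear batch effects, zero inflation, or
unbalanced compositions of real assays.

## Numerical and implementation choices

* No deep-learning framework is used: the encoders are small, so forward,
  backward (hand-derived), and Adam are implemented directly on numpy.
  Every analytic gradient — the three losses with respect to embeddings, and
  the MLP parameter gradients — is checked against central finite
  differences in the test suite.
* All log-sum-exp denominators use max-subtraction; at $\tau = 0.1$ the
  exponents reach 10, which overflows quickly without it.
* The pure loss functions reject zero-norm embedding rows rather than
  epsilon-stabilizing them, keeping tests honest; training code paths never
  produce exact zero rows in practice (dense linear output layers).
* Determinism: a single `numpy.random.Generator` seeded per run drives
  initialization, mini-batch sampling, and dropout; same seed + same inputs
  gives identical loss traces in single-threaded use.  The run
  configuration fans one global seed out to per-stage seeds via CRC32 of
  the stage name.
* Degenerate mini-batches: at $n = 1$, $M = 2$ the alignment loss is exactly
  0 (the positive term equals the whole denominator), as is the specificity
  loss; at $n = 1$, $M = 3$ the shared denominator contains both positives,
  leaving $2\log 2$ even for identical embeddings — asserted in the tests
  rather than rounded away.

## Small-data training profile

The published schedule (batch 512, lr $2\times10^{-4}$, 100 alignment
epochs) targets datasets of $10^4$–$10^5$ cells, where an epoch is tens of
optimizer steps.  On the 700-cell fixture the bridge holds 300 cells, an
epoch is a single clamped step, and that schedule barely moves the weights.
Test and acceptance runs therefore use the package's small-data profile
(`ace.pipeline.small_data_train_configs`): batch 64, lr $10^{-3}$, 30
alignment epochs and 10 specific-model epochs (~150 and ~80 steps).  Package
defaults remain the published values.

## Known limitations

* Harmony is wrapped, not bundled; without it, `center` handles only the
  additive component of batch effects.
* Bridge batches must be fully paired: every cell of a multimodal batch must
  be present in all of that batch's modalities.
* The imputation is a deterministic neighbour average with no uncertainty
  estimate; cells of types absent from every bridge batch are imputed from
  their nearest (wrong-type) neighbours without warning.
* The exact-kNN search is $O(n_\text{query} \cdot n_\text{candidate})$ per
  modality pair, appropriate up to ~$10^5$ cells but not beyond.
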