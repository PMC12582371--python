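"""ACE-spec: specific-model training, kNN imputation, and consensus."""

import numpy as np
import pytest

from ace.align import SharedEmbedding, TrainConfig
from ace.data_model import BatchRecord, MosaicDataset, MosaicError
from ace.losses import LossConfig
from ace.nn import EncoderSpec
from ace.preprocess import reduce_modality
from ace.spec import (
    ImputationConfig,
    SpecificEmbedding,
    consensus_spec,
    default_spec_train_config,
    encode_specific,
    impute_missing_embeddings,
    impute_missing_features,
    knn_match,
    train_spec,
)


def brute_force_neighbors(queries, candidates, k, metric="cosine"):
    """Independent O(n^2) exact-kNN with the documented tie-break."""
    out = []
    for q in queries:
        scored = []
        for idx, c in enumerate(candidates):
            if metric == "cosine":
                s = float(np.dot(q, c) / ((np.linalg.norm(q) or 1.0) * (np.linalg.norm(c) or 1.0)))
            else:
                s = -float(np.sum((q - c) ** 2))
            scored.append((-s, idx))
        scored.sort()  # similarity desc, then index asc
        out.append([idx for _, idx in scored[:k]])
    return np.asarray(out)


def mosaic_with_missing(seed=0, n_bridge=12, n_rna=6, n_adt=5):
    rng = np.random.default_rng(seed)
    mk = lambda n, d: rng.normal(size=(n, d))
    ids = lambda p, n: [f"{p}{i:02d}" for i in range(n)]
    return MosaicDataset([
        BatchRecord("br", {"RNA": mk(n_bridge, 7), "Protein": mk(n_bridge, 4)}, ids("b", n_bridge)),
        BatchRecord("r", {"RNA": mk(n_rna, 7)}, ids("r", n_rna)),
        BatchRecord("p", {"Protein": mk(n_adt, 4)}, ids("p", n_adt)),
    ])


def synthetic_embeddings(ds, d=3, seed=1):
    """Shared + specific embeddings keyed off a deterministic per-cell code."""
    rng = np.random.default_rng(seed)
    shared, specific = {}, {}
    codes = {rc: rng.normal(size=d) for rc in ds.all_rows()}
    for m in ds.modalities:
        rows = ds.modality_rows(m)
        shared[m] = SharedEmbedding(m, rows, np.array([codes[rc] for rc in rows]))
        specific[m] = SpecificEmbedding(m, rows, rng.normal(size=(len(rows), d)))
    return shared, specific


class TestTrainSpec:
    def test_modalities_trained_independently(self, easy_inputs):
        """Training one modality never reads (or depends on) another's data."""
        cfg = TrainConfig(lr=1e-3, batch_size=64, epochs=1, seed=4)
        specs = {m: EncoderSpec(m, mi.p, [16, 8], dropout_p=0.2)
                 for m, mi in easy_inputs.items()}
        both, traces_both = train_spec(easy_inputs, specs, cfg, LossConfig())
        only_rna, traces_rna = train_spec({"RNA": easy_inputs["RNA"]},
                                          {"RNA": specs["RNA"]}, cfg, LossConfig())
        np.testing.assert_array_equal(traces_both["RNA"], traces_rna["RNA"])
        X = easy_inputs["RNA"].values[:5]
        np.testing.assert_array_equal(both["RNA"].encode(X), only_rna["RNA"].encode(X))

    def test_loss_decreases(self, easy_inputs):
        cfg = TrainConfig(lr=1e-3, batch_size=64, epochs=4, seed=0)
        specs = {"RNA": EncoderSpec("RNA", easy_inputs["RNA"].p, [32, 16], dropout_p=0.2)}
        _, traces = train_spec({"RNA": easy_inputs["RNA"]}, specs, cfg, LossConfig())
        t = traces["RNA"]
        per_epoch = len(t) // 4
        assert np.mean(t[-per_epoch:]) < np.mean(t[:per_epoch])

    def test_same_seed_identical_traces(self, easy_inputs):
        cfg = TrainConfig(lr=1e-3, batch_size=64, epochs=1, seed=9)
        specs = {"RNA": EncoderSpec("RNA", easy_inputs["RNA"].p, [16, 8], dropout_p=0.2)}
        _, t1 = train_spec({"RNA": easy_inputs["RNA"]}, specs, cfg, LossConfig())
        _, t2 = train_spec({"RNA": easy_inputs["RNA"]}, specs, cfg, LossConfig())
        np.testing.assert_allclose(t1["RNA"], t2["RNA"], atol=1e-12)

    def test_defaults_match_published_schedule(self):
        cfg = default_spec_train_config()
        assert (cfg.lr, cfg.batch_size, cfg.epochs) == (1.75e-4, 512, 10)

    def test_fewer_than_two_cells_rejected(self):
        from ace.preprocess import ModalityInput

        mi = ModalityInput("RNA", [("b", "c0")], np.ones((1, 3)), np.array(["b"]))
        with pytest.raises(MosaicError, match="fewer than 2"):
            train_spec({"RNA": mi}, None, TrainConfig(epochs=1), LossConfig())


class TestKnnMatch:
    def test_matches_brute_force_with_ties(self, rng):
        """20 random instances, duplicated candidates to force similarity ties."""
        for trial in range(20):
            n = int(rng.integers(5, 201))
            d = int(rng.integers(2, 17))
            k = int(rng.integers(1, 5))
            cands = rng.normal(size=(n, d))
            cands[n // 2] = cands[0]  # exact duplicate -> tie on similarity
            queries = rng.normal(size=(min(20, n), d))
            for metric in ("cosine", "euclidean"):
                ours = knn_match(queries, cands, k, metric)
                oracle = brute_force_neighbors(queries, cands, k, metric)
                np.testing.assert_array_equal(ours, oracle)

    def test_exact_match_is_nearest(self, rng):
        cands = rng.normal(size=(10, 4))
        q = cands[[3]]
        assert knn_match(q, cands, 1)[0, 0] == 3


class TestImputeEmbeddings:
    def test_measured_rows_untouched_and_mask_correct(self):
        ds = mosaic_with_missing()
        shared, specific = synthetic_embeddings(ds)
        completed = impute_missing_embeddings(shared, specific, ds, ImputationConfig(k=2))
        for m in ds.modalities:
            se = completed[m]
            assert se.rows == ds.all_rows()
            pos = {rc: i for i, rc in enumerate(se.rows)}
            for i, rc in enumerate(ds.modality_rows(m)):
                np.testing.assert_array_equal(se.values[pos[rc]], specific[m].values[i])
                assert not se.imputed_mask[pos[rc]]
            measured = set(ds.modality_rows(m))
            for rc in se.rows:
                assert se.imputed_mask[pos[rc]] == (rc not in measured)

    def test_k1_exact_shared_match_copies_specific_row(self):
        ds = mosaic_with_missing()
        shared, specific = synthetic_embeddings(ds)
        # make the first RNA-only cell's shared embedding equal a bridge cell's
        rna_rows = ds.modality_rows("RNA")
        target = rna_rows.index(("br", "b03"))
        query = rna_rows.index(("r", "r00"))
        shared["RNA"].values[query] = 2.0 * shared["RNA"].values[target]  # cosine-equal
        completed = impute_missing_embeddings(shared, specific, ds, ImputationConfig(k=1))
        prot_rows = ds.modality_rows("Protein")
        donor = specific["Protein"].values[prot_rows.index(("br", "b03"))]
        pos = {rc: i for i, rc in enumerate(completed["Protein"].rows)}
        np.testing.assert_allclose(
            completed["Protein"].values[pos[("r", "r00")]], donor, atol=1e-12
        )

    def test_k2_equidistant_candidates_average(self):
        """Two candidates tied in shared space -> imputed row is their mean."""
        rng = np.random.default_rng(3)
        br = BatchRecord("br", {"RNA": rng.normal(size=(2, 3)),
                                "Protein": rng.normal(size=(2, 2))}, ["a", "b"])
        solo = BatchRecord("r", {"RNA": rng.normal(size=(1, 3))}, ["q"])
        ds = MosaicDataset([br, solo])
        d = 2
        shared = {
            "RNA": SharedEmbedding("RNA", ds.modality_rows("RNA"),
                                   np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])),
            "Protein": SharedEmbedding("Protein", ds.modality_rows("Protein"),
                                       np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        u = np.array([10.0, 0.0])
        v = np.array([0.0, 6.0])
        specific = {
            "RNA": SpecificEmbedding("RNA", ds.modality_rows("RNA"), rng.normal(size=(3, d))),
            "Protein": SpecificEmbedding("Protein", ds.modality_rows("Protein"),
                                         np.vstack([u, v])),
        }
        completed = impute_missing_embeddings(shared, specific, ds, ImputationConfig(k=2))
        pos = {rc: i for i, rc in enumerate(completed["Protein"].rows)}
        np.testing.assert_allclose(completed["Protein"].values[pos[("r", "q")]],
                                   (u + v) / 2, atol=1e-12)

    def test_multi_source_average_matches_brute_force(self, rng):
        """|T_b| = 2 imputation equals the mean of per-source oracle imputations."""
        for trial in range(5):
            n = int(rng.integers(10, 40))
            mk = lambda nn, dd: rng.normal(size=(nn, dd))
            ds = MosaicDataset([
                BatchRecord("br", {"RNA": mk(n, 5), "Protein": mk(n, 3), "ATAC": mk(n, 4)},
                            [f"b{i:02d}" for i in range(n)]),
                BatchRecord("ra", {"RNA": mk(6, 5), "ATAC": mk(6, 4)},
                            [f"x{i:02d}" for i in range(6)]),
            ], modalities=["RNA", "Protein", "ATAC"])
            shared, specific = synthetic_embeddings(ds, d=4, seed=trial)
            k = 3
            completed = impute_missing_embeddings(shared, specific, ds,
                                                  ImputationConfig(k=k))
            # oracle for Protein rows of batch 'ra' (measured: RNA + ATAC)
            prot_rows = ds.modality_rows("Protein")
            cand = shared["Protein"].values
            acc = np.zeros((6, 4))
            for src in ("RNA", "ATAC"):
                src_rows = ds.modality_rows(src)
                q = np.array([
                    shared[src].values[src_rows.index(("ra", f"x{i:02d}"))]
                    for i in range(6)
                ])
                nbrs = brute_force_neighbors(q, cand, k)
                acc += specific["Protein"].values[nbrs].mean(axis=1)
            oracle = acc / 2
            pos = {rc: i for i, rc in enumerate(completed["Protein"].rows)}
            ours = np.array([completed["Protein"].values[pos[("ra", f"x{i:02d}")]]
                             for i in range(6)])
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_k_clamped_with_warning(self):
        ds = mosaic_with_missing(n_bridge=3)
        shared, specific = synthetic_embeddings(ds)
        with pytest.warns(UserWarning, match="clamping"):
            impute_missing_embeddings(shared, specific, ds, ImputationConfig(k=50))

    def test_decoupling_other_modalities_unaffected(self):
        """Perturbing one modality's specific encoder output changes nothing
        about other modalities' completed measured rows."""
        ds = mosaic_with_missing()
        shared, specific = synthetic_embeddings(ds)
        completed = impute_missing_embeddings(shared, specific, ds, ImputationConfig())
        specific2 = dict(specific)
        specific2["RNA"] = SpecificEmbedding(
            "RNA", specific["RNA"].rows, specific["RNA"].values + 100.0
        )
        completed2 = impute_missing_embeddings(shared, specific2, ds, ImputationConfig())
        meas = ~completed["Protein"].imputed_mask
        np.testing.assert_array_equal(
            completed2["Protein"].values[meas], completed["Protein"].values[meas]
        )


class TestImputeFeatures:
    def test_non_negative_inputs_stay_non_negative(self, rng):
        ds = mosaic_with_missing(seed=2)
        # overwrite matrices with counts
        for b in ds.batches:
            for m in list(b.matrices):
                b.matrices[m] = rng.poisson(2.0, size=b.matrices[m].shape).astype(float)
        shared, _ = synthetic_embeddings(ds)
        out = impute_missing_features(shared, ds, ImputationConfig(k=2), modality="Protein")
        assert np.all(out.values >= 0)
        assert out.values.shape == (ds.n_cells, 4)

    def test_k1_copies_donor_profile(self):
        ds = mosaic_with_missing()
        shared, _ = synthetic_embeddings(ds)
        rna_rows = ds.modality_rows("RNA")
        q = rna_rows.index(("r", "r01"))
        t = rna_rows.index(("br", "b05"))
        shared["RNA"].values[q] = shared["RNA"].values[t]
        out = impute_missing_features(shared, ds, ImputationConfig(k=1), modality="Protein")
        pos = {rc: i for i, rc in enumerate(out.rows)}
        donor = ds.modality_matrix("Protein")[ds.modality_rows("Protein").index(("br", "b05"))]
        np.testing.assert_allclose(out.values[pos[("r", "r01")]], donor, atol=1e-12)

    def test_agrees_with_brute_force_oracle(self, rng):
        ds = mosaic_with_missing(seed=5, n_bridge=30, n_rna=20)
        shared, _ = synthetic_embeddings(ds, seed=6)
        k = 2
        out = impute_missing_features(shared, ds, ImputationConfig(k=k), modality="Protein")
        cand = shared["Protein"].values
        feats = ds.modality_matrix("Protein")
        rna_rows = ds.modality_rows("RNA")
        pos = {rc: i for i, rc in enumerate(out.rows)}
        for i in range(20):
            rc = ("r", f"r{i:02d}")
            q = shared["RNA"].values[[rna_rows.index(rc)]]
            nbrs = brute_force_neighbors(q, cand, k)[0]
            np.testing.assert_allclose(out.values[pos[rc]], feats[nbrs].mean(axis=0),
                                       atol=1e-10)


class TestConsensusSpec:
    def test_equal_weight_mean(self):
        ds = mosaic_with_missing()
        rows = ds.all_rows()
        a = SpecificEmbedding("RNA", rows, np.tile([1.0, 0.0], (len(rows), 1)))
        b = SpecificEmbedding("Protein", rows, np.tile([0.0, 1.0], (len(rows), 1)))
        cons, crows = consensus_spec({"RNA": a, "Protein": b}, ds)
        np.testing.assert_allclose(cons, np.tile([0.5, 0.5], (len(rows), 1)))
        assert crows == rows

    def test_three_modalities_match_loop_oracle(self, rng):
        ds = mosaic_with_missing()
        rows = ds.all_rows()
        mats = {m: rng.normal(size=(len(rows), 3)) for m in ("RNA", "Protein")}
        ds.modalities = ["RNA", "Protein"]
        cons, _ = consensus_spec(
            {m: SpecificEmbedding(m, rows, v) for m, v in mats.items()}, ds
        )
        for i in range(len(rows)):
            expected = (mats["RNA"][i] + mats["Protein"][i]) / 2
            np.testing.assert_allclose(cons[i], expected, atol=1e-12)

    def test_incomplete_modality_rejected(self):
        ds = mosaic_with_missing()
        partial = SpecificEmbedding("RNA", ds.modality_rows("RNA"),
                                    np.zeros((len(ds.modality_rows("RNA")), 2)))
        full = SpecificEmbedding("Protein", ds.all_rows(), np.zeros((ds.n_cells, 2)))
        with pytest.raises(MosaicError, match="incomplete"):
            consensus_spec({"RNA": partial, "Protein": full}, ds)


class TestRecovery:
    def test_imputed_cells_land_in_correct_type_cluster(self):
        """With perfect alignment and type-determined specific embeddings,
        imputed rows classify to the right type by nearest centroid."""
        rng = np.random.default_rng(12)
        n_types, d = 4, 6
        type_codes = rng.normal(size=(n_types, d)) * 4
        spec_codes = rng.normal(size=(n_types, d)) * 4  # Protein-specific map

        def batch(bid, mods, n, offset):
            types = np.arange(n) % n_types
            mats = {m: rng.normal(size=(n, 5)) for m in mods}
            return BatchRecord(bid, mats, [f"{bid}{i:03d}" for i in range(n)]), types

        br, t_br = batch("b", ("RNA", "Protein"), 60, 0)
        solo, t_solo = batch("r", ("RNA",), 40, 60)
        ds = MosaicDataset([br, solo])
        shared, specific = {}, {}
        types_by_row = {}
        for (b, t) in ((br, t_br), (solo, t_solo)):
            for i, c in enumerate(b.cell_ids):
                types_by_row[(b.batch_id, c)] = t[i]
        for m in ds.modalities:
            rows = ds.modality_rows(m)
            tvec = np.array([types_by_row[rc] for rc in rows])
            noise = rng.normal(scale=0.2, size=(len(rows), d))
            shared[m] = SharedEmbedding(m, rows, type_codes[tvec] + noise)
            specific[m] = SpecificEmbedding(m, rows, spec_codes[tvec]
                                            + rng.normal(scale=0.2, size=(len(rows), d)))
        completed = impute_missing_embeddings(shared, specific, ds, ImputationConfig(k=2))
        pos = {rc: i for i, rc in enumerate(completed["Protein"].rows)}
        correct = 0
        for i, c in enumerate(solo.cell_ids):
            v = completed["Protein"].values[pos[("r", c)]]
            pred = np.argmin(np.linalg.norm(spec_codes - v, axis=1))
            correct += pred == t_solo[i]
        assert correct / len(solo.cell_ids) >= 0.9
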