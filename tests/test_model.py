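"""Predictor behaviour: embeddings, encoder/decoder contracts, loss, training."""

import math

import numpy as np
import pytest

from gvpgo.geometry import featurize
from gvpgo.model import (FEATURE_NAMES, GvpGoClassifier, ModelConfig, _decode,
                         _encode, embed_and_sum, load_checkpoint,
                         permute_feature, save_checkpoint, weighted_bce_loss)
from gvpgo.structure_io import ProteinStructure, Residue
from gvpgo.synthetic import make_stub_embedding, make_toy_structure

from .conftest import random_rotation

TINY = dict(d_model=32, n_heads=4, n_gvp_layers=2, n_encoder_layers=1,
            n_decoder_layers=1, n_vector_channels=4, n_rbf=8, k_neighbors=4,
            learning_rate=1e-3, batch_size=4, max_epochs=2, seed=0)

TERMS = [f"GO:X{j}" for j in range(5)]


def tiny_bundle(seed=0, length=12, conformation="mixed", d_emb=6):
    s = make_toy_structure(length, conformation, seed=seed, low_conf_prob=0.0)
    return featurize(s, make_stub_embedding(s.sequence, d_emb, seed), k=4), s


def tiny_estimator(**overrides):
    est = GvpGoClassifier(**{**TINY, **overrides})
    est.initialize(d_emb=6, terms=TERMS)
    return est


class TestEmbedAndSum:
    def test_output_dimension_matches_d_model(self):
        est = GvpGoClassifier(**{**TINY, "d_model": 128, "n_heads": 8})
        est.initialize(d_emb=6, terms=TERMS)
        b, _ = tiny_bundle()
        out = embed_and_sum(b, est.params_)
        assert out.shape == (12, 128)

    def test_additivity_in_esm_stream(self):
        """Doubling the sequence embedding shifts the sum by exactly its delta."""
        est = tiny_estimator()
        b, _ = tiny_bundle()
        base = embed_and_sum(b, est.params_).data
        import copy
        b2 = copy.deepcopy(b)
        b2.seq_embedding = 2.0 * b.seq_embedding
        doubled = embed_and_sum(b2, est.params_).data
        esm_delta = b.seq_embedding @ est.params_.esm_W.data
        assert np.allclose(doubled - base, esm_delta, atol=1e-10)

    def test_wrong_embedding_dimension_named(self):
        est = tiny_estimator()
        b, _ = tiny_bundle(d_emb=9)
        with pytest.raises(ValueError, match="embedding dimension"):
            embed_and_sum(b, est.params_)


class TestEncodeDecode:
    def test_encoder_output_shape(self):
        est = tiny_estimator()
        b, _ = tiny_bundle(length=15)
        out = _encode(b, est.params_, est.config())
        assert out.shape == (15, TINY["d_model"])

    def test_decoder_outputs_in_unit_interval(self):
        est = tiny_estimator()
        b, _ = tiny_bundle()
        probs = _decode(_encode(b, est.params_, est.config()), est.params_, est.config())
        assert probs.shape == (len(TERMS),)
        assert ((probs.data > 0) & (probs.data < 1)).all()

    def test_query_permutation_permutes_outputs(self):
        est = tiny_estimator()
        b, _ = tiny_bundle()
        ctx = _encode(b, est.params_, est.config())
        out0 = _decode(ctx, est.params_, est.config()).data
        perm = np.random.default_rng(0).permutation(len(TERMS))
        est.params_.query_table.data = est.params_.query_table.data[perm]
        out1 = _decode(ctx, est.params_, est.config()).data
        assert np.allclose(out1, out0[perm], atol=1e-10)

    def test_zeroed_cross_attention_makes_predictions_protein_independent(self):
        est = tiny_estimator()
        for layer in est.params_.decoder:
            layer.cross_attn.Wo.data[:] = 0.0
        b1, _ = tiny_bundle(seed=1, conformation="helix")
        b2, _ = tiny_bundle(seed=2, conformation="extended")
        p1, p2 = est.predict_proba([b1, b2])
        assert np.allclose(p1, p2, atol=1e-12)

    def test_identical_proteins_identical_outputs(self):
        est = tiny_estimator()
        b, _ = tiny_bundle(seed=3)
        out = est.predict_proba([b, b])
        assert np.allclose(out[0], out[1], atol=0)


class TestLoss:
    def test_positive_half_is_three_ln_two(self):
        loss = weighted_bce_loss(np.array([0.5]), np.array([1.0]), pos_weight=3.0)
        assert float(loss.data) == pytest.approx(3 * math.log(2), abs=1e-9)

    def test_negative_half_is_ln_two(self):
        loss = weighted_bce_loss(np.array([0.5]), np.array([0.0]), pos_weight=3.0)
        assert float(loss.data) == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_predictions_vanishing_loss(self):
        loss = weighted_bce_loss(np.array([1 - 1e-6, 1e-6]), np.array([1.0, 0.0]))
        assert float(loss.data) < 1e-5

    def test_boundary_predictions_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = weighted_bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert np.isfinite(loss.data)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce_loss(np.zeros(3) + 0.5, np.zeros(4))


def _training_set(n=8, seed=0):
    rng = np.random.default_rng(seed)
    bundles, ys = [], []
    for i in range(n):
        conformation = "helix" if i % 2 == 0 else "extended"
        b, _ = tiny_bundle(seed=100 + i, conformation=conformation)
        bundles.append(b)
        y = np.zeros(len(TERMS))
        y[0] = 1.0 if conformation == "helix" else 0.0
        y[1] = 1.0 - y[0]
        ys.append(y)
    return bundles, np.array(ys)


class TestTraining:
    def test_one_epoch_reduces_training_loss(self):
        X, y = _training_set()
        est = GvpGoClassifier(**{**TINY, "max_epochs": 2})
        est.fit(X, y, terms=TERMS)
        assert est.loss_history_[1] < est.loss_history_[0]

    def test_identical_seeds_identical_histories(self):
        X, y = _training_set()
        runs = []
        for _ in range(2):
            est = GvpGoClassifier(**{**TINY, "max_epochs": 2})
            est.fit(X, y, terms=TERMS, validation=(X[:2], y[:2]))
            runs.append((est.loss_history_, est.val_loss_history_))
        assert np.allclose(runs[0][0], runs[1][0], atol=1e-6)
        assert np.allclose(runs[0][1], runs[1][1], atol=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_loss_decreases_over_first_epochs(self, seed):
        X, y = _training_set(seed=seed)
        est = GvpGoClassifier(**{**TINY, "max_epochs": 5, "seed": seed})
        est.fit(X, y, terms=TERMS)
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_divergence_aborts_with_diagnostic(self):
        X, y = _training_set(n=4)
        est = GvpGoClassifier(**{**TINY, "warm_start": True})
        est.initialize(d_emb=6, terms=TERMS)
        est.params_.out_w.data[0] = np.nan  # poisoned weights -> non-finite loss
        with pytest.raises(RuntimeError, match="diverged"):
            est.fit(X, y, terms=TERMS)


class TestPredict:
    def test_output_covers_candidate_terms(self):
        est = tiny_estimator()
        b, s = tiny_bundle(seed=5)
        scores = est.predict_structure(s, b.seq_embedding)
        assert set(scores) == set(TERMS)
        assert all(0.0 <= v <= 1.0 for v in scores.values())

    def test_rigid_motion_invariance(self):
        """Predictions on a rotated + translated copy agree to 1e-4 per term."""
        est = tiny_estimator()
        rng = np.random.default_rng(31)
        b, s = tiny_bundle(seed=6)
        base = est.predict_proba([b])[0]
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            s2 = s.transformed(R, t)
            b2 = featurize(s2, b.seq_embedding, k=est.k_neighbors)
            moved = est.predict_proba([b2])[0]
            assert np.max(np.abs(moved - base)) < 1e-4

    def test_fully_unconfident_protein_rejected(self):
        est = tiny_estimator()
        s = make_toy_structure(8, "helix", seed=7, plddt=np.full(8, 0.3))
        b = featurize(s, make_stub_embedding(s.sequence, 6, 0), k=4)
        with pytest.raises(ValueError, match="no confident"):
            est.predict_proba([b])


class TestPermuteFeature:
    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            permute_feature([], "wibble", seed=0)

    @pytest.mark.parametrize("feature", FEATURE_NAMES)
    def test_preserves_marginal_values(self, feature):
        bundles = [tiny_bundle(seed=i)[0] for i in range(3)]
        permuted = permute_feature(bundles, feature, seed=1)
        if feature == "plddt":
            before = np.sort(np.concatenate([b.plddt for b in bundles]))
            after = np.sort(np.concatenate([b.plddt for b in permuted]))
            assert np.allclose(before, after)
        elif feature == "token":
            before = np.sort(np.concatenate([b.tokens for b in bundles]))
            after = np.sort(np.concatenate([b.tokens for b in permuted]))
            assert (before == after).all()

    def test_deterministic_given_seed(self):
        bundles = [tiny_bundle(seed=i)[0] for i in range(3)]
        a = permute_feature(bundles, "dihedral", seed=9)
        b = permute_feature(bundles, "dihedral", seed=9)
        for x, y in zip(a, b):
            assert np.allclose(x.dihedrals, y.dihedrals)


class TestParameterCount:
    def test_matches_analytic_formula(self):
        """Total learned-tensor size equals the count implied by the config."""
        cfg = ModelConfig(**TINY)
        est = tiny_estimator()
        d, dff, nv, es = cfg.d_model, cfg.d_ff, cfg.n_vector_channels, cfg.n_rbf
        d_emb, T, vin = 6, len(TERMS), 8

        def gvp(n_in, v_in, n_out, v_out):
            h = max(v_in, n_in, 1)
            return h * v_in + v_out * h + n_out * (h + n_in) + n_out

        expected = 21 * d                       # token table
        expected += 9 * d + d                   # dihedral embedding
        expected += 1 * d + d                   # pLDDT embedding
        expected += d_emb * d + d               # sequence-embedding projection
        expected += gvp(d, vin, d, nv)          # input GVP
        per_conv = gvp(d + es, nv + 1, d, nv) + gvp(d, nv, d, nv) + 4 * d
        expected += cfg.n_gvp_layers * per_conv
        per_enc = 4 * d * d + 2 * d + (d * dff + dff) + (dff * d + d) + 2 * d
        expected += cfg.n_encoder_layers * per_enc
        expected += T * d                       # GO-query table
        per_dec = 8 * d * d + 4 * d + (d * dff + dff) + (dff * d + d) + 2 * d
        expected += cfg.n_decoder_layers * per_dec
        expected += d + 1                       # output head
        assert est.n_parameters() == expected


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, y = _training_set(n=4)
        est = GvpGoClassifier(**{**TINY, "max_epochs": 1})
        est.fit(X, y, terms=TERMS)
        path = tmp_path / "model.npz"
        save_checkpoint(est, path)
        loaded = load_checkpoint(path)
        assert loaded.classes_ == est.classes_
        assert loaded.config() == est.config()
        assert np.allclose(loaded.predict_proba(X[:2]), est.predict_proba(X[:2]), atol=1e-12)
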