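"""Encoders, bidirectional head, label mixing, and predictor training."""

import numpy as np
import pytest

from espred import chemdata, predictors, synthetic_data
from espred.chemdata import InstrumentSetting
from espred.predictors import (LatentCode, MixingStack, PredictorConfig,
                               PredictorModel, apply_label_mixing,
                               encode_fingerprint, encode_graph,
                               predict_spectrum)

SETTING = InstrumentSetting.make("[M+H]+", 0.5)


def _model(encoder="fingerprint", **kw) -> PredictorModel:
    defaults = dict(encoder=encoder, n_bins=200, fp_bits=64, enc_hidden=16,
                    is_hidden=4, latent_dim=16, head_hidden=16, n_mixing=2,
                    mixing_rank=8, aux_hidden=8, seed=3)
    defaults.update(kw)
    return PredictorModel(PredictorConfig(**defaults))


class TestFingerprintEncoder:
    def test_deterministic_and_pure(self):
        model = _model()
        rec = chemdata.parse_molecule("CCO", fp_bits=64)
        z1 = encode_fingerprint(rec, SETTING, model)
        z2 = encode_fingerprint(rec, SETTING, model)
        np.testing.assert_array_equal(z1.vector, z2.vector)
        # a different molecule with an identical fingerprint would give the
        # same latent: the encoder sees only (fingerprint, setting)
        twin = chemdata.MoleculeRecord(id="twin", smiles=rec.smiles,
                                       formula=rec.formula,
                                       fingerprint=rec.fingerprint.copy(),
                                       graph=rec.graph, maccs=rec.maccs)
        np.testing.assert_array_equal(
            encode_fingerprint(twin, SETTING, model).vector, z1.vector)

    def test_zero_input_zero_bias_gives_zero_latent(self):
        model = _model()
        for name in ("fp_b", "is_b", "z_b"):
            model.params[name].data[:] = 0.0
        rec = chemdata.parse_molecule("CCO", fp_bits=64)
        zero_rec = chemdata.MoleculeRecord(
            id="z", smiles=rec.smiles, formula=rec.formula,
            fingerprint=np.zeros(64, dtype=np.uint8), graph=rec.graph,
            maccs=rec.maccs)
        zero_setting = InstrumentSetting(np.array([1.0]), 0.0)
        # zero the precursor one-hot contribution by zeroing its weight row
        model.params["is_W"].data[:] = 0.0
        z = encode_fingerprint(zero_rec, zero_setting, model)
        np.testing.assert_allclose(z.vector, 0.0)

    def test_width_mismatch(self):
        model = _model()
        rec = chemdata.parse_molecule("CCO", fp_bits=128)
        with pytest.raises(ValueError, match="width"):
            encode_fingerprint(rec, SETTING, model)

    def test_wrong_encoder_kind(self):
        model = _model("graph")
        rec = chemdata.parse_molecule("CCO", fp_bits=64)
        with pytest.raises(ValueError):
            encode_fingerprint(rec, SETTING, model)


class TestGraphEncoder:
    def test_single_node_graph(self):
        model = _model("graph")
        rec = chemdata.parse_molecule("C", fp_bits=64)
        z = encode_graph(rec, SETTING, model)
        assert z.vector.shape == (16,)
        assert np.all(np.isfinite(z.vector))

    def test_permutation_invariance(self):
        """Relabeling graph nodes must not change the latent code."""
        model = _model("graph")
        rec = chemdata.parse_molecule("CC(O)CN", fp_bits=64)  # 5 heavy atoms
        g = rec.graph
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(g.n_nodes)
            inv = np.argsort(perm)
            permuted = chemdata.MolecularGraph(
                atom_types=g.atom_types[perm],
                atom_masses=g.atom_masses[perm],
                edge_index=np.array([[inv[u], inv[v]] for u, v in g.edge_index]),
                edge_types=g.edge_types.copy(),
            )
            prec = chemdata.MoleculeRecord(id="p", smiles=rec.smiles,
                                           formula=rec.formula,
                                           fingerprint=rec.fingerprint,
                                           graph=permuted, maccs=rec.maccs)
            np.testing.assert_allclose(encode_graph(prec, SETTING, model).vector,
                                       encode_graph(rec, SETTING, model).vector,
                                       atol=1e-10)

    def test_disconnected_duplicate_equals_single(self):
        """Mean pooling over two copies of the same graph = one copy."""
        model = _model("graph")
        one = chemdata.parse_molecule("CCO", fp_bits=64)
        two = chemdata.parse_molecule("CCO.CCO", fp_bits=64)
        z1 = encode_graph(one, SETTING, model)
        z2 = encode_graph(two, SETTING, model)
        np.testing.assert_allclose(z1.vector, z2.vector, atol=1e-10)


class TestBidirectionalHead:
    def test_mask_above_precursor_bin(self):
        model = _model()
        rng = np.random.default_rng(1)
        z = LatentCode(rng.normal(size=16))
        y = predict_spectrum(z, 120.7, model)
        assert y.shape == (200,)
        assert np.all(y[121:] == 0.0)
        assert np.all(y >= 0.0)

    def test_precursor_bin_out_of_range(self):
        model = _model()
        z = LatentCode(np.zeros(16))
        with pytest.raises(ValueError, match="precursor bin"):
            predict_spectrum(z, 1e6, model)

    def test_gate_saturation_forward_only(self):
        """Saturating the gate toward the forward branch makes the output
        equal the (masked, mixed) forward vector alone."""
        model = _model(theta=1.0)   # disable mixing contribution
        P = model.config.n_bins
        # huge positive gate logits -> sigmoid ~ 1 -> forward branch
        model.params["head_b2"].data[2 * P:] = 50.0
        rng = np.random.default_rng(2)
        z = LatentCode(rng.normal(size=16))
        y = predict_spectrum(z, 150.0, model)
        h = np.maximum(z.vector @ model.params["head_W1"].data
                       + model.params["head_b1"].data, 0)
        out = h @ model.params["head_W2"].data + model.params["head_b2"].data
        fwd = np.maximum(out[:P], 0)
        fwd[151:] = 0.0
        np.testing.assert_allclose(y, fwd, atol=1e-8)

    def test_determinism(self):
        model = _model()
        z = LatentCode(np.random.default_rng(3).normal(size=16))
        np.testing.assert_array_equal(predict_spectrum(z, 90.0, model),
                                      predict_spectrum(z, 90.0, model))


class TestLabelMixing:
    def test_zero_factors_give_theta_y(self):
        P, M = 32, 4
        mix = MixingStack(factors=[np.zeros((P, M))] * 2,
                          weights=np.array([0.5, 0.5]), theta=0.4)
        y = np.abs(np.random.default_rng(0).normal(size=P))
        np.testing.assert_allclose(apply_label_mixing(y, mix), 0.4 * y)

    def test_theta_one_is_identity(self):
        P, M = 16, 4
        rng = np.random.default_rng(1)
        mix = MixingStack(factors=[rng.normal(size=(P, M))],
                          weights=np.array([1.0]), theta=1.0)
        y = np.abs(rng.normal(size=P))
        np.testing.assert_allclose(apply_label_mixing(y, mix), y)

    def test_indicator_factor_spreads_mass(self):
        """D with a single column e5+e9 maps a one-hot at bin 5 to equal
        mass at bins 5 and 9 (hand-computed y D D^T)."""
        P = 16
        D = np.zeros((P, 1))
        D[5, 0] = D[9, 0] = 1.0
        mix = MixingStack(factors=[D], weights=np.array([1.0]), theta=0.0)
        y = np.zeros(P)
        y[5] = 1.0
        out = apply_label_mixing(y, mix)
        expected = np.zeros(P)
        expected[5] = expected[9] = 1.0
        np.testing.assert_allclose(out, expected)

    def test_positive_homogeneity(self):
        P, M = 24, 6
        rng = np.random.default_rng(4)
        mix = MixingStack(factors=[rng.normal(size=(P, M)) for _ in range(3)],
                          weights=np.array([0.2, 0.3, 0.5]), theta=0.5)
        y = np.abs(rng.normal(size=P))
        np.testing.assert_allclose(apply_label_mixing(3.0 * y, mix),
                                   3.0 * apply_label_mixing(y, mix), atol=1e-9)

    def test_factored_matches_explicit(self):
        """Factored computation equals materializing Q_l = D_l D_l^T."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            P = int(rng.integers(8, 33))
            M = int(rng.integers(1, P))
            L = int(rng.integers(1, 4))
            w = rng.dirichlet(np.ones(L))
            factors = [rng.normal(size=(P, M)) for _ in range(L)]
            theta = float(rng.uniform(0, 1))
            mix = MixingStack(factors=factors, weights=w, theta=theta)
            y = np.abs(rng.normal(size=P))
            y_co = sum((y @ (D @ D.T)) * t for D, t in zip(factors, w))
            expected = np.maximum(theta * y + (1 - theta) * y_co, 0.0)
            np.testing.assert_allclose(apply_label_mixing(y, mix), expected, atol=1e-9)

    def test_rank_bound(self):
        P = 8
        with pytest.raises(ValueError, match="rank"):
            MixingStack(factors=[np.zeros((P, P))], weights=np.array([1.0]), theta=0.5)

    def test_simplex_weights_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixingStack(factors=[np.zeros((8, 2))], weights=np.array([0.7]), theta=0.5)


@pytest.fixture(scope="module")
def tiny_corpus():
    cfg = synthetic_data.SyntheticConfig(
        families={"C5H12O": 5, "C5H13N": 5, "C6H14O": 5},
        energies=(10.0, 40.0), sigma=0.0, seed=1, fp_bits=256)
    return synthetic_data.generate_corpus(cfg)


def _tiny_config(**kw):
    defaults = dict(encoder="fingerprint", fp_bits=256, enc_hidden=32,
                    latent_dim=32, head_hidden=32, mixing_rank=16, n_mixing=2,
                    epochs=8, eval_every=4, batch_size=32, seed=0)
    defaults.update(kw)
    return PredictorConfig(**defaults)


class TestTraining:
    def test_seeded_determinism(self, tiny_corpus):
        cfg = _tiny_config(epochs=4)
        m1 = predictors.train_predictor(tiny_corpus, None, cfg)
        m2 = predictors.train_predictor(tiny_corpus, None, _tiny_config(epochs=4))
        log1 = [e for e in m1.training_log if "train_loss" in e]
        log2 = [e for e in m2.training_log if "train_loss" in e]
        assert log1[-1]["train_loss"] == log2[-1]["train_loss"]
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_loss_decreases_from_initialization(self, tiny_corpus):
        cfg = _tiny_config(epochs=8)
        model = predictors.train_predictor(tiny_corpus, None, cfg)
        losses = [e["train_loss"] for e in model.training_log if "train_loss" in e]
        assert losses[-1] < losses[0]
        val = predictors.evaluate_on_split(model, tiny_corpus, "val")
        init = predictors.evaluate_on_split(
            PredictorModel(_tiny_config()), tiny_corpus, "val")
        assert val["mean_cosine"] > init["mean_cosine"]

    def test_lambda_aux_zero_matches_no_topics(self, tiny_corpus):
        """With lambda_aux = 0 the topic model must not affect training."""
        from espred import spectra_topics

        Y = np.array([s.intensities for _, s in tiny_corpus.pairs_in_split("train")])
        topics = spectra_topics.fit_lda(Y, n_topics=4, seed=0, max_iter=5)
        cfg_a = _tiny_config(epochs=3, lambda_aux=0.0, n_topics=4)
        cfg_b = _tiny_config(epochs=3, lambda_aux=0.0, n_topics=0)
        m_a = predictors.train_predictor(tiny_corpus, topics, cfg_a)
        m_b = predictors.train_predictor(tiny_corpus, None, cfg_b)
        shared = [k for k in m_a.params if not k.startswith("aux_")]
        for k in shared:
            np.testing.assert_array_equal(m_a.params[k].data, m_b.params[k].data)

    def test_empty_training_split(self, tiny_corpus):
        import dataclasses

        empty = dataclasses.replace(tiny_corpus,
                                    splits={m: "test" for m in tiny_corpus.molecules})
        with pytest.raises(ValueError, match="empty training split"):
            predictors.train_predictor(empty, None, _tiny_config())

    def test_save_load_bit_exact(self, tiny_corpus, tmp_path):
        model = predictors.train_predictor(tiny_corpus, None, _tiny_config(epochs=2))
        model.save(tmp_path / "ckpt")
        back = PredictorModel.load(tmp_path / "ckpt")
        pairs = tiny_corpus.pairs_in_split("test")[:5]
        recs = [tiny_corpus.molecules[m] for m, _ in pairs]
        sets = [s.setting for _, s in pairs]
        mzs = [s.precursor_mz for _, s in pairs]
        np.testing.assert_array_equal(model.predict_spectra(recs, sets, mzs),
                                      back.predict_spectra(recs, sets, mzs))
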