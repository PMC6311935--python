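import dataclasses
import math

import numpy as np
import pytest

import mampep as mp
from mampep.network import build_model, train

from conftest import random_peptide
from _brute import brute_probability


def params_equal(a, b):
    return all(np.array_equal(p, q) for p, q in zip(a.parameters(), b.parameters()))


class TestBuildModel:
    def test_seeded_build_is_deterministic(self):
        assert params_equal(build_model(seed=0), build_model(seed=0))
        assert not params_equal(build_model(seed=0), build_model(seed=1))

    def test_default_head_shapes(self):
        m = build_model(seed=0)
        assert [len(w) for w in m.gap_w] == [16, 32]
        assert m.fusion_w.shape == (2,)
        assert m.embedding.shape == (20, 15)
        assert m.conv_w[0].shape == (16, 15, 7)
        assert m.conv_w[1].shape == (32, 16, 7)

    @pytest.mark.parametrize("bad", [
        dict(conv_filters=(0, 32)), dict(conv_filters=()),
        dict(embed_dim=0), dict(kernel_size=0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            mp.ArchSpec(**bad)


class TestForward:
    def test_zero_fusion_gives_half(self):
        m = build_model(seed=0)
        m.fusion_w[:] = 0.0
        for pep in ["LLFGYPVYV", "NLVPMVAT", "SLYNTVATLYC"]:
            assert m.forward(pep).probability == pytest.approx(0.5)

    def test_zero_conv_gives_zero_features_and_half(self):
        m = build_model(seed=0)
        for w, b in zip(m.conv_w, m.conv_b):
            w[:] = 0.0
            b[:] = 0.0
        tr = m.forward("LLFGYPVYV")
        for f in tr.features:
            assert np.all(f == 0.0)
        assert np.all(tr.level_contribs == 0.0)
        assert tr.probability == pytest.approx(0.5)

    def test_hand_built_single_filter_kernel_one(self):
        # one level, one filter, kernel 1, 2-dim embedding: the probability
        # reduces to sigmoid(m * w_gap * mean_k leaky(conv . emb[k] + b))
        arch = mp.ArchSpec(embed_dim=2, conv_filters=(1,), kernel_size=1,
                           dropout_rates=(0.0,))
        m = build_model(arch, seed=0)
        m.embedding[:] = 0.0
        m.embedding[mp.AA_INDEX["A"]] = [1.0, 2.0]
        m.embedding[mp.AA_INDEX["C"]] = [-1.0, 0.5]
        m.conv_w[0][0, :, 0] = [0.5, -0.25]
        m.conv_b[0][:] = 0.1
        m.gap_w[0][:] = 2.0
        m.fusion_w[:] = 1.5

        def leaky(z):
            return z if z >= 0 else 0.3 * z

        acts = {"A": leaky(0.5 * 1.0 - 0.25 * 2.0 + 0.1),
                "C": leaky(0.5 * -1.0 - 0.25 * 0.5 + 0.1)}
        seq = "AACCAACC"
        expected = 1.0 / (1.0 + math.exp(
            -1.5 * 2.0 * sum(acts[c] for c in seq) / len(seq)))
        assert m.forward(seq).probability == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_probability(self):
        rng = np.random.default_rng(5)
        m = build_model(seed=3)
        for L in (8, 9, 10, 11):
            pep = random_peptide(rng, L)
            assert m.forward(pep).probability == pytest.approx(
                brute_probability(m, pep), abs=1e-9)

    def test_feature_rows_equal_length(self):
        m = build_model(seed=0)
        for L in (8, 9, 10, 11):
            tr = m.forward(random_peptide(np.random.default_rng(L), L))
            assert [f.shape[0] for f in tr.features] == [L, L]
            assert 0.0 < tr.probability < 1.0


def separable_toy(n_per_class=20, seed=0):
    """Binders carry fixed residues at sites 2 and 9; non-binders are random
    peptides re-labeled by that planted rule (the oracle is the rule itself)."""
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_per_class):
        s = list(random_peptide(rng, 9))
        s[1], s[8] = "L", "V"
        recs.append(mp.PeptideRecord("".join(s), label=1))
    while sum(r.label == 0 for r in recs) < n_per_class:
        s = random_peptide(rng, 9)
        label = 1 if (s[1] == "L" and s[8] == "V") else 0
        if label == 0:
            recs.append(mp.PeptideRecord(s, label=0))
    return mp.Dataset(records=recs)


class TestTrain:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        data = separable_toy()
        cfg = mp.TrainConfig(max_epochs=150, patience=30, batch_size=8,
                             n_models=1, seed=0)
        model, _ = train(build_model(seed=0), data, cfg)
        preds = (model.predict_proba(data.sequences()) > 0.5).astype(int)
        assert np.array_equal(preds, data.labels())

    def test_early_stopping_contract(self):
        # zero learning rate and no dropout: the monitored loss is constant
        # from epoch 1, so training stops after exactly `patience` flat epochs
        arch = mp.ArchSpec(dropout_rates=(0.0, 0.0))
        data = separable_toy()
        cfg = mp.TrainConfig(max_epochs=100, patience=5, learning_rate=0.0,
                             n_models=1, seed=0)
        _, hist = train(build_model(arch, seed=0), data, cfg)
        assert hist["best_epoch"] == 1
        assert hist["stopped_epoch"] == 1 + cfg.patience
        assert len(hist["loss"]) == 1 + cfg.patience

    def test_training_is_deterministic(self):
        data = separable_toy()
        cfg = mp.TrainConfig(max_epochs=12, patience=5, n_models=1, seed=4)
        a, _ = train(build_model(seed=4), data, cfg)
        b, _ = train(build_model(seed=4), data, cfg)
        assert params_equal(a, b)

    def test_single_class_rejected(self):
        recs = [mp.PeptideRecord(random_peptide(np.random.default_rng(i), 9), label=1)
                for i in range(8)]
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(seed=0), mp.Dataset(records=recs),
                  mp.TrainConfig(max_epochs=5, patience=2, n_models=1))

    def test_unlabeled_rejected(self):
        recs = [mp.PeptideRecord(random_peptide(np.random.default_rng(i), 9))
                for i in range(8)]
        with pytest.raises(ValueError, match="unlabeled"):
            train(build_model(seed=0), mp.Dataset(records=recs),
                  mp.TrainConfig(max_epochs=5, patience=2, n_models=1))


class TestEnsemble:
    def test_members_differ_and_runs_reproduce(self, tiny_ensemble, small_split,
                                               tiny_config):
        a, b = tiny_ensemble.members
        assert not params_equal(a, b)
        again = mp.train_ensemble(small_split[0], tiny_config)
        for m1, m2 in zip(tiny_ensemble.members, again.members):
            assert params_equal(m1, m2)

    def test_prediction_is_member_mean_and_bounded(self, tiny_ensemble, small_split):
        seqs = small_split[1].sequences()
        member_probs = np.stack([m.predict_proba(seqs)
                                 for m in tiny_ensemble.members])
        ens_probs = mp.predict_ensemble(tiny_ensemble, small_split[1])
        np.testing.assert_allclose(ens_probs, member_probs.mean(axis=0), rtol=1e-12)
        assert np.all(ens_probs >= member_probs.min(axis=0))
        assert np.all(ens_probs <= member_probs.max(axis=0))

    def test_singleton_ensemble_equals_member(self, small_split):
        cfg = mp.TrainConfig(max_epochs=10, patience=4, n_models=1, seed=9)
        ens = mp.train_ensemble(small_split[0], cfg)
        seqs = small_split[1].sequences()
        np.testing.assert_array_equal(mp.predict_ensemble(ens, seqs),
                                      ens.members[0].predict_proba(seqs))

    def test_mixed_length_probes_accepted(self, tiny_ensemble):
        rng = np.random.default_rng(0)
        probes = [random_peptide(rng, L) for L in (8, 9, 10, 11)]
        probs = mp.predict_ensemble(tiny_ensemble, probes)
        assert probs.shape == (4,)
        assert np.all((probs > 0.0) & (probs < 1.0))


class TestFineTune:
    def test_zero_epochs_is_zero_shot_identity(self, tiny_ensemble, small_split):
        cfg = dataclasses.replace(tiny_ensemble.config, max_epochs=0)
        same = mp.fine_tune(tiny_ensemble, small_split[0], config=cfg)
        for m1, m2 in zip(tiny_ensemble.members, same.members):
            assert params_equal(m1, m2)

    def test_original_ensemble_untouched(self, tiny_ensemble, small_split):
        before = [m.copy() for m in tiny_ensemble.members]
        cfg = dataclasses.replace(tiny_ensemble.config, max_epochs=5, patience=2)
        tuned = mp.fine_tune(tiny_ensemble, small_split[0], config=cfg)
        for m1, m2 in zip(before, tiny_ensemble.members):
            assert params_equal(m1, m2)
        assert not params_equal(tuned.members[0], tiny_ensemble.members[0])


class TestBundle:
    def test_round_trip_predictions(self, tiny_ensemble, small_split, tmp_path):
        mp.save_bundle(tiny_ensemble, tmp_path / "b")
        back = mp.load_bundle(tmp_path / "b")
        seqs = small_split[1].sequences()
        np.testing.assert_array_equal(mp.predict_ensemble(back, seqs),
                                      mp.predict_ensemble(tiny_ensemble, seqs))

    def test_manifest_records_size(self, tiny_ensemble, tmp_path):
        import json
        mp.save_bundle(tiny_ensemble, tmp_path / "b")
        manifest = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert manifest["n_models"] == len(tiny_ensemble)

    def test_truncated_member_errors(self, tiny_ensemble, tmp_path):
        mp.save_bundle(tiny_ensemble, tmp_path / "b")
        f = tmp_path / "b" / "member_0.npz"
        f.write_bytes(f.read_bytes()[:100])
        with pytest.raises(mp.BundleError):
            mp.load_bundle(tmp_path / "b")

    def test_missing_manifest_errors(self, tmp_path):
        with pytest.raises(mp.BundleError):
            mp.load_bundle(tmp_path)
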