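"""Forward-pass contracts of the two-branch network: shapes, masking,
permutation invariance, ablation semantics, loss semantics and the
end-to-end gradient check."""

import datetime as dt

import numpy as np
import pytest

from hvat import (
    ClinicalToken,
    HvatConfig,
    HvatModel,
    TokenSequence,
    batch_loss,
    make_batch,
)
from hvat.autodiff import Tensor
from hvat.network import logit_loss, predict_sequences

D = dt.date


def _seq(pid, triples, interval=30.5):
    toks = [ClinicalToken(0, 0, 0.0)] + [ClinicalToken(t, c, v) for t, c, v in triples]
    return TokenSequence(pid, toks, D(2012, 1, 1), D(2012, 12, 31), interval)


@pytest.fixture
def small_model():
    return HvatModel(HvatConfig(d=8, n_blocks=2, n_heads=2, dropout=0.1, ffnn_hidden=8), 6, seed=3)


@pytest.fixture
def mixed_batch():
    rng = np.random.default_rng(0)
    seqs = [
        _seq("a", [(1, 1, 0.0), (3, 2, 1.5), (7, 3, -0.5)]),
        _seq("b", [(2, 4, 0.0)]),
        _seq("c", []),  # special token only
    ]
    statics = rng.normal(size=(3, 7))
    labels = np.array([1, 0, 1])
    return make_batch(seqs, statics, labels)


class TestConfig:
    def test_defaults_are_prototype_settings(self):
        cfg = HvatConfig()
        assert (cfg.d, cfg.n_blocks, cfg.n_heads, cfg.dropout) == (32, 2, 2, 0.1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HvatConfig(d=33)
        with pytest.raises(ValueError):
            HvatConfig(d=32, n_heads=3)
        with pytest.raises(ValueError):
            HvatConfig(variant="nope")


class TestVatForward:
    def test_output_shape_fixed_regardless_of_lengths(self, small_model, mixed_batch):
        out = small_model.vat_forward(mixed_batch)
        assert out.shape == (3, 8)

    def test_special_token_only_sequence_is_finite(self, small_model):
        batch = make_batch([_seq("c", [])], np.zeros((1, 7)), np.array([0]))
        out = small_model.vat_forward(batch)
        assert np.all(np.isfinite(out.data))

    def test_padding_invariance(self, small_model):
        seqs = [_seq("a", [(1, 1, 0.0), (3, 2, 1.5)])]
        statics = np.zeros((1, 7))
        labels = np.array([1])
        alone = small_model.forward(make_batch(seqs, statics, labels)).data
        padded = make_batch(
            seqs + [_seq("b", [(t, 1, 0.0) for t in range(1, 9)])],
            np.zeros((2, 7)),
            np.array([1, 0]),
        )
        together = small_model.forward(padded).data
        assert together[0] == pytest.approx(alone[0], abs=1e-12)

    def test_token_permutation_invariance(self, small_model):
        triples = [(1, 1, 0.0), (3, 2, 1.5), (7, 3, -0.5), (2, 4, 2.0)]
        statics = np.zeros((1, 7))
        labels = np.array([1])
        base = small_model.forward(make_batch([_seq("a", triples)], statics, labels)).data
        toks = [ClinicalToken(t, c, v) for t, c, v in triples[::-1]]
        permuted = TokenSequence("a", [ClinicalToken(0, 0, 0.0)] + toks,
                                 D(2012, 1, 1), D(2012, 12, 31), 30.5)
        out = small_model.forward(make_batch([permuted], statics, labels)).data
        assert out == pytest.approx(base, abs=1e-10)

    def test_empty_batch_rejected(self, small_model):
        with pytest.raises(ValueError):
            make_batch([], np.zeros((0, 7)), np.array([]))

    def test_missing_special_token_rejected(self):
        bad = TokenSequence("x", [ClinicalToken(1, 1, 0.0)], D(2012, 1, 1), D(2012, 12, 31), 30.5)
        with pytest.raises(ValueError):
            make_batch([bad], np.zeros((1, 7)), np.array([0]))


class TestStaticBranch:
    def test_output_width_is_d(self, small_model):
        out = small_model.static_branch_forward(np.random.default_rng(1).normal(size=(4, 7)))
        assert out.shape == (4, 8)

    def test_zeroed_hidden_block_reduces_to_projection(self, small_model):
        small_model.params["static.w2"].data[:] = 0.0
        x = np.random.default_rng(2).normal(size=(3, 7))
        out = small_model.static_branch_forward(x)
        proj = x @ small_model.params["static.win"].data + small_model.params["static.win_b"].data
        assert out.data == pytest.approx(proj)

    def test_wrong_input_width_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.static_branch_forward(np.zeros((2, 5)))

    def test_eval_mode_deterministic(self, small_model):
        x = np.random.default_rng(3).normal(size=(2, 7))
        a = small_model.static_branch_forward(x, training=False).data
        b = small_model.static_branch_forward(x, training=False).data
        assert np.array_equal(a, b)


class TestHvatForward:
    def test_probabilities_strictly_inside_unit_interval(self, small_model, mixed_batch):
        p = small_model.forward(mixed_batch).data
        assert np.all((p > 0) & (p < 1))

    def test_zero_logit_gives_half(self, small_model, mixed_batch):
        small_model.params["head.w"].data[:] = 0.0
        small_model.params["head.w_b"].data[:] = 0.0
        p = small_model.forward(mixed_batch).data
        assert p == pytest.approx([0.5, 0.5, 0.5])

    def test_without_vat_ignores_token_sequence(self, mixed_batch):
        model = HvatModel(HvatConfig(d=8, n_heads=2, ffnn_hidden=8, variant="without_vat"), 6, seed=3)
        p1 = model.forward(mixed_batch).data
        shuffled = make_batch(
            [_seq("a", [(5, 5, 3.0)]), _seq("b", []), _seq("c", [(1, 1, 0.0)])],
            mixed_batch.static,
            mixed_batch.labels,
        )
        p2 = model.forward(shuffled).data
        assert np.array_equal(p1, p2)

    def test_without_ffnn_matches_full_with_zeroed_static_contribution(self, mixed_batch):
        full = HvatModel(HvatConfig(d=8, n_heads=2, ffnn_hidden=8), 6, seed=3)
        ablated = HvatModel(HvatConfig(d=8, n_heads=2, ffnn_hidden=8, variant="without_ffnn"), 6, seed=3)
        ablated.load_state_dict(full.state_dict())
        # zero the static branch end to end: projection and residual output
        for name in ("static.win", "static.win_b", "static.w2", "static.w2_b"):
            full.params[name].data[:] = 0.0
            ablated.params[name].data[:] = 0.0
        assert full.forward(mixed_batch).data == pytest.approx(
            ablated.forward(mixed_batch).data, abs=1e-12
        )


class TestLoss:
    def test_half_probabilities_give_k_log_two(self):
        k = 5
        probs = Tensor(np.full(k, 0.5))
        loss = batch_loss(probs, np.ones(k))
        assert loss.data == pytest.approx(k * np.log(2.0))

    def test_perfect_predictions_approach_zero(self):
        probs = Tensor(np.array([1 - 1e-9, 1e-9]))
        assert batch_loss(probs, np.array([1, 0])).data == pytest.approx(0.0, abs=1e-5)

    def test_duplicating_batch_doubles_loss(self):
        probs = np.array([0.3, 0.8])
        labels = np.array([0, 1])
        single = batch_loss(Tensor(probs), labels).data
        double = batch_loss(Tensor(np.tile(probs, 2)), np.tile(labels, 2)).data
        assert double == pytest.approx(2 * single)

    def test_logit_loss_matches_probability_loss(self):
        logits = np.array([-2.0, 0.0, 3.0])
        labels = np.array([0, 1, 1])
        from scipy.special import expit

        a = logit_loss(Tensor(logits), labels).data
        b = batch_loss(Tensor(expit(logits)), labels).data
        assert a == pytest.approx(b, rel=1e-9)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            batch_loss(Tensor(np.array([0.5])), np.array([2]))


class TestGradientCheck:
    def test_backprop_matches_finite_differences(self, mixed_batch):
        """End-to-end check on a 3-patient batch: relative error < 1e-4 for
        sampled coordinates of every parameter tensor."""
        model = HvatModel(HvatConfig(d=8, n_blocks=1, n_heads=2, dropout=0.0, ffnn_hidden=8), 6, seed=5)
        labels = mixed_batch.labels

        def loss_value():
            return batch_loss(model.forward(mixed_batch), labels).data.item()

        model.zero_grad()
        loss = batch_loss(model.forward(mixed_batch), labels)
        loss.backward()
        rng = np.random.default_rng(0)
        for name, par in model.params.items():
            flat = par.data.reshape(-1)
            gflat = (par.grad if par.grad is not None else np.zeros_like(par.data)).reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                hi = loss_value()
                flat[idx] = orig - eps
                lo = loss_value()
                flat[idx] = orig
                fd = (hi - lo) / (2 * eps)
                diff = abs(fd - gflat[idx])
                if diff < 1e-8:  # below central-difference noise
                    continue
                scale = max(abs(fd), abs(gflat[idx]))
                assert diff / scale < 1e-4, f"{name}[{idx}]: {fd} vs {gflat[idx]}"


class TestCheckpoint:
    def test_save_load_reproduces_outputs_bit_exactly(self, small_model, mixed_batch, tmp_path):
        path = tmp_path / "model.npz"
        small_model.save(path, extra={"note": "test"})
        loaded, extra = HvatModel.load(path)
        assert extra == {"note": "test"}
        assert np.array_equal(
            small_model.forward(mixed_batch).data, loaded.forward(mixed_batch).data
        )

    def test_predict_sequences_batches_preserve_order(self, small_model):
        seqs = [_seq(f"p{i}", [(1 + i % 3, 1 + i % 5, 0.0)]) for i in range(7)]
        statics = np.random.default_rng(4).normal(size=(7, 7))
        labels = np.zeros(7, dtype=int)
        all_at_once = predict_sequences(small_model, seqs, statics, labels, batch_size=7)
        chunked = predict_sequences(small_model, seqs, statics, labels, batch_size=2)
        assert all_at_once == pytest.approx(chunked, abs=1e-12)
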