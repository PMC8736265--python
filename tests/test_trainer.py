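import math

import numpy as np
import pytest

from cxreport.corpus import Vocabulary, encode_report
from cxreport.model import CaptionModel, ModelConfig
from cxreport.trainer import (
    EpochTrace,
    TrainConfig,
    evaluate_loss,
    sequence_loss,
    teacher_forcing_batch,
    train,
)


def make_toy_setup(rng, n_images=6, width=12, dropout=0.0, seed=0,
                   texts=None, image_size=16):
    vocab_texts = texts or ["the lungs are clear", "opacity in the left zone"]
    vocab = Vocabulary.from_reports(vocab_texts)
    cfg = ModelConfig(embed_dim=width, hidden_dim=width, attn_dim=width,
                      feat_dim=width, dropout_p=dropout, toy_channels=(4, 8),
                      image_size=image_size, seed=seed)
    model = CaptionModel(cfg, vocab)
    images = [rng.random((image_size, image_size, 1)) for _ in range(n_images)]
    l_max = max(len(t.split()) for t in vocab_texts) + 2
    tokens = np.stack([
        encode_report(vocab_texts[i % len(vocab_texts)], vocab, l_max)
        for i in range(n_images)
    ])
    spatial, penult = model.extract_features(images)
    return model, spatial, penult, tokens


class TestSequenceLoss:
    def test_uniform_closed_form(self):
        p = np.full((3, 4), 0.25)
        targets = np.array([1, 2, 3])
        assert math.isclose(sequence_loss(p, targets), 3 * math.log(4), rel_tol=1e-12)

    def test_perfect_prediction_zero_loss(self):
        p = np.zeros((2, 3))
        p[0, 0] = 1.0
        p[1, 2] = 1.0
        assert sequence_loss(p, np.array([1, 3])) == 0.0

    def test_half_quarter_ln8(self):
        p = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25]])
        assert math.isclose(sequence_loss(p, np.array([1, 1])), math.log(8),
                            rel_tol=1e-12)

    def test_pad_positions_excluded(self):
        p = np.full((4, 5), 0.2)
        targets = np.array([1, 2, 0, 0])
        assert math.isclose(sequence_loss(p, targets), 2 * math.log(5), rel_tol=1e-12)

    def test_zero_probability_clamped(self, caplog):
        p = np.zeros((1, 2))
        p[0, 1] = 1.0
        loss = sequence_loss(p, np.array([1]))
        assert np.isfinite(loss) and loss > 20  # -ln(1e-12) ~ 27.6

    def test_matches_direct_per_token_oracle(self, rng):
        """Trainer loss equals the per-token -log p sum written out longhand."""
        model, sp, pen, toks = make_toy_setup(rng)
        probs = teacher_forcing_batch(model, sp, pen, toks)
        total = 0.0
        for b in range(toks.shape[0]):
            for t in range(toks.shape[1] - 1):
                tgt = toks[b, t + 1]
                if tgt != 0:
                    total += -math.log(probs[b, t, tgt - 1])
        oracle = total / toks.shape[0]
        assert math.isclose(sequence_loss(probs, toks[:, 1:]), oracle, rel_tol=1e-8)
        fwd = model.forward_batch(sp, pen, toks)
        assert math.isclose(fwd["loss"], oracle, rel_tol=1e-8)


class TestTeacherForcing:
    def test_one_distribution_per_transition(self, rng):
        model, sp, pen, toks = make_toy_setup(rng)
        probs = teacher_forcing_batch(model, sp, pen, toks)
        assert probs.shape == (toks.shape[0], toks.shape[1] - 1, len(model.vocab))

    def test_pad_tail_contributes_no_loss(self, rng):
        model, sp, pen, toks = make_toy_setup(
            rng, texts=["the lungs are clear", "opacity seen here now"])
        # extend padding: loss must be unchanged
        wide = np.concatenate([toks, np.zeros((len(toks), 4), dtype=toks.dtype)], axis=1)
        a = model.forward_batch(sp, pen, toks)["loss"]
        b = model.forward_batch(sp, pen, wide)["loss"]
        assert math.isclose(a, b, rel_tol=1e-12)

    def test_batch_equals_single_sequence(self, rng):
        """Batched teacher forcing matches per-sequence processing."""
        model, sp, pen, toks = make_toy_setup(rng, n_images=4)
        batched = teacher_forcing_batch(model, sp, pen, toks)
        for i in range(4):
            single = teacher_forcing_batch(model, sp[i:i+1], pen[i:i+1], toks[i:i+1])
            assert np.allclose(batched[i], single[0], atol=1e-12)


class TestTrain:
    def _train(self, rng, seed=0, max_epochs=6, dropout=0.0, n_images=6):
        model, sp, pen, toks = make_toy_setup(rng, seed=seed, dropout=dropout,
                                              n_images=n_images)
        tr = (sp[:4], pen[:4], toks[:4])
        val = (sp[4:], pen[4:], toks[4:])
        cfg = TrainConfig(batch_size=2, max_epochs=max_epochs, dropout_p=dropout,
                          seed=seed)
        best, traces = train(model, tr, val, cfg)
        return model, best, traces, (tr, val)

    def test_selected_epoch_is_val_loss_argmin(self, rng):
        model, best, traces, (tr, val) = self._train(rng)
        model.set_params_dict(best)
        best_loss, _ = evaluate_loss(model, *val)
        argmin = min(t.val_loss for t in traces)
        assert math.isclose(best_loss, argmin, rel_tol=1e-9)
        assert best_loss <= traces[0].val_loss

    def test_seed_determinism(self):
        a = self._train(np.random.default_rng(5), seed=3, dropout=0.5)[2]
        b = self._train(np.random.default_rng(5), seed=3, dropout=0.5)[2]
        assert [t.__dict__ for t in a] == [t.__dict__ for t in b]

    def test_training_loss_trends_down(self, rng):
        _, _, traces, _ = self._train(rng, max_epochs=8)
        losses = [t.train_loss for t in traces]
        upticks = sum(1 for i in range(1, len(losses)) if losses[i] > losses[i - 1])
        assert upticks <= 1
        assert losses[-1] < losses[0]

    def test_single_pair_memorisation(self):
        """One training pair is memorised: loss < 0.05 within 200 steps."""
        rng = np.random.default_rng(0)
        model, sp, pen, toks = make_toy_setup(rng, n_images=1, width=16)
        data = (sp, pen, toks)
        cfg = TrainConfig(learning_rate=0.01, batch_size=1, max_epochs=200,
                          dropout_p=0.0, seed=0)
        best, traces = train(model, data, data, cfg)
        assert min(t.train_loss for t in traces) < 0.05

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="sgd")
        with pytest.raises(ValueError):
            EpochTrace(0, -1.0, 0.0, 0.0, 0.0)
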