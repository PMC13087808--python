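"""Autodiff gradients, vocabulary, checkpointing, and training behavior."""

import numpy as np
import pytest

from leadtuner.augmentation import TrainingExample
from leadtuner.model import autodiff as ad
from leadtuner.model.autodiff import Tensor
from leadtuner.model.training import (
    Adam,
    NoamSchedule,
    build_vocabulary,
    perplexity,
    train,
)
from leadtuner.model.transformer import (
    DecodeCache,
    ModelConfig,
    ModelState,
    decode_step,
    encode_source,
    forward_logits,
    init_params,
)
from leadtuner.model.vocab import SPECIALS, Vocabulary


class TestVocabulary:
    def test_from_corpus_contains_tokens_and_specials(self):
        v = Vocabulary.from_corpora([["[C]", "[C]"], ["[C]"]])
        assert v.itos[:4] == list(SPECIALS)
        assert "[C]" in v and len(v) == 5

    def test_unknown_maps_to_unk(self):
        v = Vocabulary.from_corpora([["[C]"]])
        assert v.encode(["[Zz]"]) == [v.unk_id]

    def test_deterministic_frequency_order(self):
        corpus = [["[O]", "[C]", "[C]"], ["[N]", "[O]", "[C]"]]
        a = Vocabulary.from_corpora(corpus)
        b = Vocabulary.from_corpora(corpus)
        assert a.itos == b.itos
        assert a.itos[4] == "[C]"  # most frequent first

    def test_json_roundtrip(self):
        v = Vocabulary.from_corpora([["[C]", "[O]"]])
        assert Vocabulary.from_json(v.to_json()).itos == v.itos


class TestAutodiffGradients:
    def _finite_diff(self, fn, arrays, analytic, places=5):
        rng = np.random.default_rng(0)
        for name, arr in arrays.items():
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in arr.shape)
                eps = 1e-6
                arr[idx] += eps
                up = fn()
                arr[idx] -= 2 * eps
                down = fn()
                arr[idx] += eps
                num = (up - down) / (2 * eps)
                ana = analytic[name][idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), name

    def test_transformer_loss_gradients(self):
        cfg = ModelConfig(n_layers=1, d_model=8, n_heads=2, d_ff=16,
                          dropout=0.0, seed=1)
        params = {k: v.astype(np.float64) for k, v in init_params(cfg, 11).items()}
        src = np.array([[4, 5, 6, 0], [7, 8, 0, 0]])
        tgt_in = np.array([[1, 4, 5], [1, 9, 0]])
        tgt_out = np.array([[4, 5, 2], [9, 2, 0]])
        mask = (tgt_out != 0).astype(float)

        def loss_of(p):
            tp = {k: Tensor(v) for k, v in p.items()}
            out = ad.cross_entropy(
                forward_logits(tp, src, tgt_in, cfg, train=False), tgt_out, mask)
            return out, tp

        loss, tp = loss_of(params)
        loss.backward()
        probe = {k: params[k] for k in
                 ["embed", "enc0.self_Wq", "dec0.cross_Wv", "out_W",
                  "dec0.ln2_g", "enc0.ff_b1"]}
        analytic = {k: tp[k].grad for k in probe}
        self._finite_diff(lambda: float(loss_of(params)[0].data), probe, analytic)


class TestForwardConsistency:
    def test_cached_decoding_matches_training_forward(self):
        cfg = ModelConfig(n_layers=2, d_model=32, n_heads=4, d_ff=64,
                          dropout=0.0, seed=2)
        params = init_params(cfg, 13)
        tp = {k: Tensor(v) for k, v in params.items()}
        src = np.array([[4, 5, 6, 7, 0], [8, 9, 10, 0, 0]])
        tgt_in = np.array([[1, 4, 5, 6], [1, 7, 8, 9]])
        ref = forward_logits(tp, src, tgt_in, cfg, train=False).data
        memory, bias = encode_source(params, src, cfg)
        cache = DecodeCache(params, cfg, memory, bias)
        steps = [decode_step(cache, tgt_in[:, t]) for t in range(tgt_in.shape[1])]
        assert np.allclose(ref, np.stack(steps, axis=1), atol=1e-5)


def toy_examples(n=30):
    rng = np.random.default_rng(5)
    out = []
    for i in range(n):
        a = "".join(rng.choice(["[C]", "[O]", "[N]"]) for _ in range(6))
        b = "".join(rng.choice(["[C]", "[O]"]) for _ in range(5))
        out.append(TrainingExample(a, b, str(i)))
    return out


class TestTraining:
    def test_empty_examples_raise(self):
        with pytest.raises(ValueError):
            train([], ModelConfig())

    def test_uniform_output_layer_perplexity_equals_vocab_size(self):
        # zeroing the output projection makes the next-token distribution
        # uniform, whose perplexity is exactly the vocabulary size
        ex = toy_examples(8)
        vocab = build_vocabulary([e.source_selfies for e in ex]
                                 + [e.target_selfies for e in ex])
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, d_ff=32,
                          dropout=0.0, seed=0)
        params = init_params(cfg, len(vocab))
        params["out_W"][:] = 0.0
        params["out_b"][:] = 0.0
        state = ModelState(params, vocab, cfg, 0, "pretrain")
        assert perplexity(state, ex) == pytest.approx(len(vocab), rel=1e-4)

    def test_one_checkpoint_per_epoch_and_determinism(self):
        ex = toy_examples(20)
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, d_ff=32,
                          dropout=0.1, batch_size=10, epochs=3,
                          warmup_steps=10, seed=3)
        r1 = train(ex, cfg, phase="finetune")
        r2 = train(ex, cfg, phase="finetune")
        assert len(r1.states) == 3
        assert [s.epoch for s in r1.states] == [1, 2, 3]
        assert r1.perplexities == r2.perplexities
        for k in r1.states[-1].params:
            assert np.array_equal(r1.states[-1].params[k], r2.states[-1].params[k])

    def test_patience_stops_pretraining(self):
        # perplexity cannot keep improving on random targets forever
        ex = toy_examples(12)
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, d_ff=32,
                          dropout=0.0, batch_size=12, epochs=30,
                          warmup_steps=10, seed=1)
        res = train(ex, cfg, phase="pretrain", max_epochs=30, patience=1)
        assert len(res.states) < 30

    def test_checkpoint_roundtrip_identical_likelihoods(self, tmp_path):
        ex = toy_examples(15)
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, d_ff=32,
                          dropout=0.0, batch_size=8, epochs=2,
                          warmup_steps=10, seed=2)
        res = train(ex, cfg, phase="finetune", checkpoint_dir=tmp_path)
        path = tmp_path / "finetune_epoch02.npz"
        assert path.exists()
        loaded = ModelState.load(path)
        assert loaded.epoch == 2 and loaded.phase == "finetune"
        assert perplexity(loaded, ex) == perplexity(res.states[-1], ex)

    def test_noam_schedule_peak_at_warmup(self):
        s = NoamSchedule(64, 100, 1.0)
        lrs = [s.lr(t) for t in range(1, 300)]
        assert int(np.argmax(lrs)) + 1 == 100
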