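"""Training loop: Adam with the Noam schedule, per-epoch checkpoints,
held-out perplexity, and perplexity-patience stopping for pretraining."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .. import selfies
from ..augmentation import TrainingExample
from . import autodiff as ad
from .autodiff import Tensor
from .transformer import ModelConfig, ModelState, forward_logits, init_params
from .vocab import Vocabulary

log = logging.getLogger(__name__)


def build_vocabulary(corpora: Sequence[Sequence[str]]) -> Vocabulary:
    """Vocabulary over token strings (each corpus entry is a token string)."""
    return Vocabulary.from_corpora([selfies.tokenize(s) for s in corpora])


def encode_example(vocab: Vocabulary, ex: TrainingExample) -> tuple[list[int], list[int]]:
    src = vocab.encode(selfies.tokenize(ex.source_selfies))
    tgt = vocab.encode(selfies.tokenize(ex.target_selfies))
    return src, tgt


def pad_batch(seqs: list[list[int]], pad: int = 0) -> np.ndarray:
    width = max(len(s) for s in seqs)
    out = np.full((len(seqs), width), pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


class NoamSchedule:
    def __init__(self, d_model: int, warmup: int, scale: float):
        self.d_model, self.warmup, self.scale = d_model, warmup, scale

    def lr(self, step: int) -> float:
        step = max(step, 1)
        return (self.scale * self.d_model ** -0.5
                * min(step ** -0.5, step * self.warmup ** -1.5))


class Adam:
    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.98, eps=1e-9):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _batch_arrays(vocab: Vocabulary, batch: list[tuple[list[int], list[int]]]):
    src = pad_batch([s for s, _ in batch])
    tgt_in = pad_batch([[vocab.bos_id] + t for _, t in batch])
    tgt_out = pad_batch([t + [vocab.eos_id] for _, t in batch])
    mask = (tgt_out != vocab.pad_id).astype(float)
    return src, tgt_in, tgt_out, mask


def _nll(params: dict[str, np.ndarray], vocab: Vocabulary,
         encoded: list[tuple[list[int], list[int]]], config: ModelConfig,
         batch_size: int = 256) -> float:
    """Mean per-token negative log-likelihood (no dropout, no gradients)."""
    tensor_params = {k: Tensor(v) for k, v in params.items()}
    total, count = 0.0, 0.0
    for i in range(0, len(encoded), batch_size):
        src, tgt_in, tgt_out, mask = _batch_arrays(vocab, encoded[i : i + batch_size])
        logits = forward_logits(tensor_params, src, tgt_in, config, train=False)
        loss = ad.cross_entropy(logits, tgt_out, mask)
        n = mask.sum()
        total += float(loss.data) * n
        count += n
    return total / count


def perplexity(state: ModelState, examples: Sequence[TrainingExample]) -> float:
    """exp(mean per-token NLL); 1 = perfect next-token prediction."""
    encoded = [encode_example(state.vocab, ex) for ex in examples]
    return float(np.exp(_nll(state.params, state.vocab, encoded, state.config)))


@dataclass
class TrainResult:
    states: list[ModelState]      # one checkpoint per completed epoch
    perplexities: list[float]     # held-out perplexity per epoch
    best_epoch: int               # 1-based epoch with the best perplexity


def train(examples: Sequence[TrainingExample], config: ModelConfig,
          vocab: Vocabulary | None = None, init: ModelState | None = None,
          phase: str = "finetune", val_examples: Sequence[TrainingExample] | None = None,
          max_epochs: int | None = None, patience: int | None = None,
          checkpoint_dir=None) -> TrainResult:
    """Token-level cross-entropy training with one checkpoint per epoch.

    Fine-tuning passes ``init`` (a pretraining checkpoint) and inherits its
    vocabulary.  Held-out perplexity comes from ``val_examples`` when given,
    else from a ``config.val_fraction`` tail slice (the training slice itself
    when that would be empty).  ``patience`` stops after that many epochs
    without improvement — the pretraining convention; fine-tuning runs all
    epochs unconditionally.
    """
    if not examples:
        raise ValueError("empty example set")
    if init is not None:
        vocab = init.vocab
        params = {k: v.copy() for k, v in init.params.items()}
    else:
        if vocab is None:
            vocab = build_vocabulary(
                [ex.source_selfies for ex in examples]
                + [ex.target_selfies for ex in examples]
            )
        params = init_params(config, len(vocab))

    examples = list(examples)
    if val_examples is None:
        n_val = int(len(examples) * config.val_fraction)
        if n_val >= 1:
            val_slice = examples[-n_val:]
            train_slice = examples[:-n_val]
        else:
            val_slice = examples
            train_slice = examples
    else:
        val_slice = list(val_examples)
        train_slice = examples

    enc_train = [encode_example(vocab, ex) for ex in train_slice]
    enc_val = [encode_example(vocab, ex) for ex in val_slice]

    tensor_params = {k: Tensor(v) for k, v in params.items()}
    opt = Adam(tensor_params)
    sched = NoamSchedule(config.d_model, config.warmup_steps, config.lr_scale)
    n_epochs = config.epochs if max_epochs is None else max_epochs
    rng = np.random.default_rng(config.seed + 7919)

    states: list[ModelState] = []
    ppls: list[float] = []
    best_ppl, best_epoch, since_best = np.inf, 0, 0
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(len(enc_train))
        for start in range(0, len(order), config.batch_size):
            batch = [enc_train[i] for i in order[start : start + config.batch_size]]
            src, tgt_in, tgt_out, mask = _batch_arrays(vocab, batch)
            opt.zero_grad()
            logits = forward_logits(tensor_params, src, tgt_in, config,
                                    rng=rng, train=True)
            loss = ad.cross_entropy(logits, tgt_out, mask)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {opt.t}: {loss.data!r}"
                )
            loss.backward()
            opt.step(sched.lr(opt.t + 1))
        snapshot = {k: v.data.copy() for k, v in tensor_params.items()}
        ppl = float(np.exp(_nll(snapshot, vocab, enc_val, config)))
        state = ModelState(snapshot, vocab, config, epoch, phase)
        states.append(state)
        ppls.append(ppl)
        if checkpoint_dir is not None:
            state.save(f"{checkpoint_dir}/{phase}_epoch{epoch:02d}.npz")
        log.info("%s epoch %d: val perplexity %.4f", phase, epoch, ppl)
        if ppl < best_ppl:
            best_ppl, best_epoch, since_best = ppl, epoch, 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                log.info("%s: perplexity has not improved for %d epoch(s); stopping",
                         phase, since_best)
                break
    return TrainResult(states, ppls, best_epoch)
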