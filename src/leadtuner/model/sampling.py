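"""Nucleus (top-p) generation from trained checkpoints.

At each step the next token is drawn only from the smallest prefix of the
probability-sorted vocabulary whose cumulative probability strictly exceeds
``p``, with probabilities renormalized inside that set.  ``p -> 0`` reduces
to greedy decoding; ``p = 1`` is unrestricted sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .. import selfies
from ..chem import canonicalize
from .transformer import DecodeCache, ModelState, encode_source

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionRecord:
    """One sampled molecule: source id, checkpoint epoch, canonical form."""

    input_id: str
    epoch: int
    canonical_smiles: str  # "" when the generation derived no atoms
    raw_selfies: str

    @property
    def is_empty(self) -> bool:
        return self.canonical_smiles == ""


def nucleus_candidates(probs: np.ndarray, p: float) -> np.ndarray:
    """Indices of the smallest probability-sorted prefix with cumulative
    probability strictly greater than ``p`` (1-D input)."""
    order = np.argsort(-probs, kind="stable")
    csum = np.cumsum(probs[order])
    k = int(np.searchsorted(csum, p, side="right")) + 1
    return order[: min(k, probs.size)]


def _sample_rows(probs: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized nucleus sampling, one token per row of ``probs`` (B, V)."""
    order = np.argsort(-probs, axis=-1, kind="stable")
    sorted_p = np.take_along_axis(probs, order, axis=-1)
    csum = np.cumsum(sorted_p, axis=-1)
    # keep position j iff the cumulative mass *before* j is <= p
    before = csum - sorted_p
    keep = before <= p
    keep[:, 0] = True
    trimmed = np.where(keep, sorted_p, 0.0)
    trimmed /= trimmed.sum(axis=-1, keepdims=True)
    u = rng.random((probs.shape[0], 1))
    pick = (np.cumsum(trimmed, axis=-1) < u).sum(axis=-1)
    pick = np.minimum(pick, probs.shape[1] - 1)
    return np.take_along_axis(order, pick[:, None], axis=-1)[:, 0]


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _generate_batch(state: ModelState, src_ids: np.ndarray, p: float,
                    rng: np.random.Generator, max_len: int) -> list[list[int]]:
    vocab = state.vocab
    memory, src_bias = encode_source(state.params, src_ids, state.config)
    cache = DecodeCache(state.params, state.config, memory, src_bias)
    n = src_ids.shape[0]
    tokens = np.full(n, vocab.bos_id, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    outputs: list[list[int]] = [[] for _ in range(n)]
    forbidden = [vocab.pad_id, vocab.bos_id, vocab.unk_id]
    for _ in range(max_len):
        logits = decode_step_masked(cache, tokens, forbidden)
        probs = _softmax(logits)
        nxt = _sample_rows(probs, p, rng)
        for i in range(n):
            if done[i]:
                continue
            if nxt[i] == vocab.eos_id:
                done[i] = True
            else:
                outputs[i].append(int(nxt[i]))
        if done.all():
            break
        tokens = np.where(done, vocab.eos_id, nxt)
    return outputs


def decode_step_masked(cache: DecodeCache, tokens: np.ndarray,
                       forbidden: Sequence[int]) -> np.ndarray:
    from .transformer import decode_step

    logits = decode_step(cache, tokens)
    logits[:, list(forbidden)] = -1e9
    return logits


def nucleus_sample(state: ModelState, source: Sequence[str] | str, p: float,
                   seed: int, max_len: int | None = None) -> list[str]:
    """Sample one token sequence for one source token string; deterministic
    per seed."""
    if isinstance(source, str):
        source = selfies.tokenize(source)
    max_len = max_len if max_len is not None else state.config.max_len
    src = np.asarray([state.vocab.encode(list(source))], dtype=np.int64)
    rng = np.random.default_rng(int(seed))
    out = _generate_batch(state, src, p, rng, max_len)[0]
    return state.vocab.decode(out)


def predict_batch(checkpoints: Sequence[ModelState],
                  inputs: Sequence[tuple[str, str]], seed: int,
                  p: float | None = None, max_len: int | None = None,
                  batch_size: int = 256) -> list[PredictionRecord]:
    """One sampled molecule per (checkpoint, input representation).

    ``inputs`` are (molecule id, source token string) pairs.  Outputs are
    decoded to canonical SMILES; generations deriving no atoms are recorded
    with an empty canonical form and counted in a log message.
    """
    if not checkpoints or not inputs:
        raise ValueError("need at least one checkpoint and one input")
    records: list[PredictionRecord] = []
    n_empty = 0
    encoded = [(mid, selfies.tokenize(sf)) for mid, sf in inputs]
    for ci, state in enumerate(checkpoints):
        cfg_p = p if p is not None else state.config.nucleus_p
        ml = max_len if max_len is not None else state.config.max_len
        rng = np.random.default_rng((int(seed) * 100003 + ci) % (2**31 - 1))
        vocab = state.vocab
        for start in range(0, len(encoded), batch_size):
            chunk = encoded[start : start + batch_size]
            width = max(len(t) for _, t in chunk)
            src = np.zeros((len(chunk), width), dtype=np.int64)
            for i, (_, toks) in enumerate(chunk):
                src[i, : len(toks)] = vocab.encode(toks)
            outs = _generate_batch(state, src, cfg_p, rng, ml)
            for (mid, _), ids in zip(chunk, outs):
                toks = vocab.decode(ids)
                raw = selfies.detokenize(toks)
                smi = selfies.decode(raw) if toks else None
                if smi is None:
                    n_empty += 1
                    records.append(PredictionRecord(mid, state.epoch, "", raw))
                else:
                    records.append(PredictionRecord(mid, state.epoch,
                                                    canonicalize(smi), raw))
    if n_empty:
        log.info("%d of %d generations derived no molecule", n_empty, len(records))
    return records
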