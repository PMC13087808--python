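"""Token vocabulary with reserved sentinels."""

from __future__ import annotations

import json
from collections import Counter
from typing import Iterable, Sequence

PAD, BOS, EOS, UNK = "<pad>", "<s>", "</s>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)


class Vocabulary:
    """token -> contiguous index mapping; indices 0..3 are the sentinels.

    Ordering of regular tokens is frequency-descending with lexicographic
    tie-break, so the same corpus always yields the same vocabulary.
    """

    def __init__(self, tokens: Sequence[str]):
        ordered = list(SPECIALS) + [t for t in tokens if t not in SPECIALS]
        if len(set(ordered)) != len(ordered):
            raise ValueError("duplicate tokens in vocabulary")
        self.itos: list[str] = ordered
        self.stoi: dict[str, int] = {t: i for i, t in enumerate(ordered)}

    @classmethod
    def from_corpora(cls, corpora: Iterable[Sequence[str]]) -> "Vocabulary":
        counts: Counter[str] = Counter()
        n = 0
        for token_seq in corpora:
            counts.update(token_seq)
            n += 1
        if n == 0:
            raise ValueError("empty corpora")
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        return cls(ordered)

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, token: str) -> bool:
        return token in self.stoi

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    @property
    def unk_id(self) -> int:
        return 3

    def encode(self, tokens: Sequence[str]) -> list[int]:
        unk = self.unk_id
        return [self.stoi.get(t, unk) for t in tokens]

    def decode(self, ids: Sequence[int], strip_specials: bool = True) -> list[str]:
        toks = [self.itos[i] for i in ids]
        if strip_specials:
            toks = [t for t in toks if t not in SPECIALS]
        return toks

    def to_json(self) -> str:
        return json.dumps(self.itos)

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        itos = json.loads(payload)
        if list(itos[:4]) != list(SPECIALS):
            raise ValueError("vocabulary payload missing sentinel prefix")
        return cls(itos[4:])
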