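"""Training-set expansion by randomized SMILES enumeration.

One molecule has many valid SMILES spellings; writing each directed pair
with fresh random spellings of its source and target multiplies the
training data without changing its chemistry.  Expansion can be uniform
(every pair k times) or weighted by score difference:

    n_i = floor((d_i - d_min) / (d_max - d_min) * n)

so the most property-improving pair is seen ``n`` times and the least
improving pair is dropped (its floor is 0).  When every score difference
is equal the formula is undefined; each pair then gets one example and a
warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import MoleculeRecord, random_smiles, to_selfies
from .scoring_ordering import DirectedPair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingExample:
    source_selfies: str
    target_selfies: str
    pair_id: str  # "sourceid>targetid"


def weighted_counts(score_diffs: Sequence[float], n: int) -> np.ndarray:
    """Per-pair augmentation counts from the score-difference weighting rule."""
    d = np.asarray(score_diffs, dtype=float)
    if d.size == 0:
        return np.zeros(0, dtype=int)
    if (d < 0).any():
        raise ValueError("score differences must be non-negative")
    dmin, dmax = d.min(), d.max()
    if dmax == dmin:
        log.warning("all %d score differences equal (%.3g); falling back to one "
                    "augmentation per pair", d.size, dmin)
        return np.ones(d.size, dtype=int)
    return np.floor((d - dmin) / (dmax - dmin) * n).astype(int)


def uniform_counts(n_pairs: int, k: int) -> np.ndarray:
    """Every pair augmented ``k`` times (the unweighted scheme)."""
    return np.full(n_pairs, k, dtype=int)


def _pair_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def augment(pairs: Sequence[DirectedPair], counts: Sequence[int],
            records_by_id: dict[str, MoleculeRecord], seed: int) -> list[TrainingExample]:
    """Expand each directed pair into ``counts[i]`` training examples.

    Source and target spellings are drawn independently; molecules admitting
    fewer distinct spellings than requested contribute their maximum (the
    shortfall is logged by the enumeration layer).  Deterministic per seed.
    """
    if len(pairs) != len(counts):
        raise ValueError("counts must align with pairs")
    seeds = _pair_seeds(seed, 2 * len(pairs))
    out: list[TrainingExample] = []
    for i, (dp, c) in enumerate(zip(pairs, counts)):
        c = int(c)
        if c <= 0:
            continue
        src_rec = records_by_id[dp.source_id]
        tgt_rec = records_by_id[dp.target_id]
        src_smis = random_smiles(src_rec, c, seeds[2 * i])
        tgt_smis = random_smiles(tgt_rec, c, seeds[2 * i + 1])
        k = min(len(src_smis), len(tgt_smis))
        pid = f"{dp.source_id}>{dp.target_id}"
        for s, t in zip(src_smis[:k], tgt_smis[:k]):
            out.append(TrainingExample(to_selfies(s), to_selfies(t), pid))
    return out


def shuffle_examples(examples: Sequence[TrainingExample], seed: int) -> list[TrainingExample]:
    """Seeded permutation so each training batch mixes many different pairs."""
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def inference_representations(records: Sequence[MoleculeRecord], k: int,
                              seed: int) -> list[tuple[str, str]]:
    """Model inputs for generation: per molecule, its canonical SMILES plus
    ``k`` randomized spellings (k+1 representations in total), all encoded as
    token strings.  Unbiased: no score weighting at inference time."""
    seeds = _pair_seeds(seed, len(records))
    reps: list[tuple[str, str]] = []
    for rec, s in zip(records, seeds):
        reps.append((rec.id, to_selfies(rec.smiles_canonical)))
        for smi in random_smiles(rec, k, s):
            reps.append((rec.id, to_selfies(smi)))
    return reps


# ---------------------------------------------------------------------------
# parallel-corpus I/O (one example per line, aligned source/target files)

def write_parallel(examples: Sequence[TrainingExample], src_path, tgt_path) -> None:
    with open(src_path, "w") as fs, open(tgt_path, "w") as ft:
        for ex in examples:
            fs.write(ex.source_selfies + "\n")
            ft.write(ex.target_selfies + "\n")


def read_parallel(src_path, tgt_path) -> list[TrainingExample]:
    with open(src_path) as fs, open(tgt_path) as ft:
        src = [line.strip() for line in fs if line.strip()]
        tgt = [line.strip() for line in ft if line.strip()]
    if len(src) != len(tgt):
        raise ValueError("source and target files are not aligned")
    return [TrainingExample(s, t, str(i)) for i, (s, t) in enumerate(zip(src, tgt))]
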