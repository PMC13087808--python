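# leadtuner

Directed matched-molecular-pair fine-tuning of a SELFIES sequence-to-sequence
transformer for multiobjective lead optimization.

## The problem

In the lead-optimization phase of a drug-discovery campaign, chemists iterate
on a single congeneric series — compounds sharing one scaffold, differing in
substituents — trying to improve potency and ADMET properties at the same
time.  The data are far too scarce (a few hundred compounds) to train a
generative chemical language model from scratch, but they are enough to
*fine-tune* one that has already learned common medicinal-chemistry edits
from a large corpus of matched molecular pairs.

`leadtuner` implements that workflow end to end:

1. **Matched molecular pairs (MMPs).** Molecules are fragmented at acyclic
   single bonds; two molecules producing an identical constant part form a
   pair, and their differing fragments define a SMIRKS-like transformation
   `lhs >> rhs`.
2. **Directed ordering.** Molecules are ranked per property (best = rank N).
   With two objectives the score is the unweighted rank sum,
   s(m) = rank_IC50(m) + rank_t½(m).  Each pair is oriented worse → better,
   so the model only sees property-improving transformations; ties are kept
   in both orders.
3. **Weighted augmentation.** One molecule has many SMILES spellings.  Each
   directed pair is written n_i times with fresh random spellings,

       n_i = ⌊ (d_i − d_min) / (d_max − d_min) · n ⌋,

   where d_i is the pair's score difference — the most-improving pair is
   seen n times, the least-improving pair is dropped.
4. **SELFIES transformer.** Examples are encoded in a robust SELFIES-style
   token grammar (every token string decodes to a valid molecule) and train
   a small encoder–decoder transformer (NumPy, in-package autodiff) with the
   Noam learning-rate schedule.  Generation uses nucleus (top-p) sampling:
   tokens are drawn from the smallest probability-sorted vocabulary prefix
   whose cumulative probability exceeds p (default 0.9).
5. **Evaluation.** A retrospective protocol (top-k holdout recovery and
   similarity-based potency transfer via Tanimoto/Morgan fingerprints) and a
   prospective protocol (deduplication, PAINS and novelty filtering,
   one-step SMIRKS reachability, pooled rank-sum re-ranking).

Because real lead-optimization tables are proprietary, the package ships a
first-class synthetic-data module: congeneric series whose log-scale IC50
and microsomal half-life follow additive per-substituent contributions plus
noise, with a fixed quota of "inactives" pinned at 1 mM.

## Worked example

```python
from leadtuner.synthetic_data import SeriesSpec, generate_series
from leadtuner.mmp_pairs import build_pairs, extract_transformation
from leadtuner.scoring_ordering import build_score_table, orient_pairs
from leadtuner.augmentation import weighted_counts

records = generate_series(SeriesSpec(n_molecules=160, n_inactive=20, seed=5))
pairs = build_pairs(records)
table = build_score_table(records, multiobjective=True)
directed = orient_pairs(pairs, table)
counts = weighted_counts([d.score_diff for d in directed], n=200)
print(len(records), len(pairs), len(directed), counts.max(), counts.min())
```

prints

```
160 1292 1295 200 0
```

— 160 molecules yield 1292 matched pairs (1295 directed pairs: three score
ties are kept in both orders); with scale n = 200 the most-improving pair is
augmented 200 times and the least-improving pair is dropped.

A complete study runs from the command line:

```bash
leadtuner run --design retrospective --outdir run1 --seed 7
```

writes `records.csv`, `pairs.csv`, `directed.csv`, the parallel training
corpus, per-epoch checkpoints, `predictions.csv`, the evaluation reports and
a `manifest.json` with per-stage seeds and artifact checksums.  Every stage
is also its own subcommand (`gen-data`, `pairs`, `orient`, `augment`,
`pretrain`, `finetune`, `predict`, `evaluate`, `filter`, `reachability`).

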