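# Methods

This note documents the models and procedures implemented in `leadtuner`,
the defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical conventions that affect results.

## Synthetic congeneric series

Real lead-optimization tables are proprietary, so all experiments run on
generated series with the statistical structure the method assumes.

**Structure.** A series is a scaffold with enumerated attachment points,
decorated combinatorially from per-site substituent pools.  The default
scaffold is a spiro[3.4] azetidine–pyrrolidine benzamide with two sites
(28 amine-compatible substituents at R1, 24 aryl substituents at R2, 672
combinations); molecules are sampled without replacement, so all records are
distinct canonical SMILES containing the scaffold.

**Properties.** Log-scale properties are additive:

    log10 IC50  = b_p + c_p(R1) + c_p(R2) + N(0, σ_p),   σ_p = 0.3
    log10 t½    = b_s + c_s(R1) + c_s(R2) + N(0, σ_s),   σ_s = 0.15

with b_p = −6.5, b_s = 1.5 (≈30 min) and per-substituent contributions drawn
once per series seed from N(0, 0.7) and N(0, 0.3) respectively.  These
spreads put active IC50s roughly in the 1 nM – 100 µM range and half-lives
in 3–500 min — a typical assay-panel spread with a learnable but noisy
structure–activity relationship (noise σ = 0.3 log units is an ordinary
inter-replicate spread for biochemical IC50s).  Active IC50s are clipped to
(10⁻¹⁰ M, 1 mM).

**Inactives.** A stated number of compounds are flagged inactive and pinned
at IC50 = 1 mM (above any measurable value).  They are the molecules with
the *worst model-implied* (noiseless) potency, not a random subset — an SAR
cliff — so that "worst stratum" draws in the evaluation protocols contain
genuine structure, and they tie at the bottom potency rank as a block.

**What this does not emulate.** No real chemotypes or assay values; no
activity cliffs orthogonal to the additive model; no assay floor/ceiling
artifacts other than the inactive pin; no inter-assay batch effects.
Passing tests therefore demonstrate that the machinery behaves as specified
under a well-posed additive SAR, not that the method improves real series.

**Pretraining corpus.** A fragment grammar (15 ring cores × 52 substituents
at two sites) generates diverse, valid, distinct molecules as a desk-scale
stand-in for a large public bioactive corpus.  Pretraining pairs are the
matched pairs of this corpus used in both orders (undirected), teaching the
model copy-with-small-edit behavior before any property direction.

**Demonstration series.** For fast directed-learning studies a 32-molecule
benzamide–piperazine series is provided (`directed_demo_spec`) whose R1
contributions concentrate the potency reward on the N-acetyl substituent
(−2.2 log units vs +0.1…+0.8 for the others).  Directed pairs then point
overwhelmingly toward acetylated analogues, giving a clean signal for the
enrichment analysis.

## String layer

Molecules are handled as canonical, stereochemistry-free SMILES (stereo
information is deliberately discarded; enantiomers collapse).  Multi-fragment
inputs keep the largest fragment (logged).

The model operates on a robust SELFIES-style token grammar implemented in
the package: atom tokens with bond-order prefixes, `[BranchL]`/`[RingL]`
instructions with overloaded base-16 index tokens, and a decoder that
enforces per-element valence caps during derivation.  Any token string over
the alphabet decodes to a valid molecule (or to nothing when it contains no
atom token), so sampled generations never fail syntactically.  The grammar
covers the neutral organic subset (B, C, N, O, P, S, halogens; no charges,
isotopes or radicals) — enough for typical congeneric series; encoding a
molecule outside the subset raises an explicit error.  This is an
independent implementation of the SELFIES idea; token strings are not
interchangeable with other codecs.

## Matched molecular pairs

Fragmentation cuts acyclic single bonds between heavy atoms (single cut by
default; a serial double cut treats the middle piece as a variable linker).
The constant part is the larger side and must contain ≥ 2/3 of the heavy
atoms — a standard MMP constraint that keeps pairs congeneric.  Attachment
points carry atom-map label 1 (and 2); canonical fragment SMILES are the
grouping keys, and two molecules pair once per shared constant part.
Transformations are fragment swaps `lhs >> rhs`; application enumerates all
symmetry-equivalent cut sites and deduplicates products by canonical form.

## Scoring and pair orientation

Ranks run 1 (worst) to N (best); ties share the minimum rank of their block
("competition" ranking).  Integer ranks keep rank-sum score differences
integral, which in turn keeps the augmentation weights exact.  The
multiobjective score is the unweighted rank sum — parameter-free, at the
cost of implicitly weighting objectives by their rank spread.  Pairs are
oriented worse → better; exact ties are emitted in both directions
(score difference 0), reproducing undirected training for uninformative
pairs.  In single-objective mode the score is the potency rank alone;
ordering by rank or by raw IC50 is observationally equivalent.

## Augmentation

Each directed pair i is expanded into

    n_i = ⌊ (d_i − d_min) / (d_max − d_min) · n ⌋

training examples (default scale n = 200 at full size), each with freshly
and independently randomized SMILES spellings for source and target,
re-encoded as tokens.  Consequences of taking the floor literally: the
least-improving pair receives 0 examples and is dropped.  When all score
differences are equal the formula is undefined; every pair then gets one
example and a warning is logged.  Molecules admitting fewer distinct
spellings than requested contribute their maximum (logged).  Examples are
shuffled (seeded) so batches mix many pairs.

At inference time augmentation is unbiased: each input molecule contributes
its canonical spelling plus k randomized ones (k+1 representations; k = 5
in the prospective protocol, so 160 molecules give 960 inputs).

## Model and training

A pre-layer-norm encoder–decoder transformer over the token vocabulary
(sentinels `<pad> <s> </s> <unk>` at indices 0–3, then tokens by corpus
frequency).  Desk-scale default: 2+2 layers, width 64, 4 heads,
feed-forward 256, dropout 0.1 — small enough for single-CPU training while
retaining enough capacity to memorize desk-scale corpora (the capacity test
drives training perplexity below 1.1).  The implementation is NumPy with an
in-package reverse-mode autodiff whose gradients are pinned by
finite-difference tests; generation uses a separate cached inference path
verified to produce identical logits.

Optimization is Adam (β = 0.9/0.98) under the Noam schedule
lr = scale · d_model^−1/2 · min(step^−1/2, step · warmup^−3/2); "learning
rate 1" means scale = 1, the convention of the translation toolkits this
schedule comes from.  Fine-tuning runs a fixed 30 epochs at batch size 128
(defaults), checkpointing every epoch.  Pretraining stops when held-out
perplexity fails to improve (patience 1) with an epoch cap of 10, and
fine-tuning starts from the best pretraining checkpoint.  Perplexity is
exp(mean per-token NLL) on a held-out 5% slice unless an explicit validation
set is given.

Generation is nucleus sampling: at each step the candidate set is the
smallest probability-sorted vocabulary prefix whose cumulative probability
strictly exceeds p (default 0.9), renormalized.  p→0 reduces to greedy
decoding; p = 1 is the full vocabulary.  Sentinels other than `</s>` are
masked out.  One sample per (input representation, checkpoint); generation
ends at `</s>` or max_len (96 tokens).  Generations deriving no atoms are
recorded with an empty canonical form and flagged rather than dropped, so
prediction accounting stays exact.

## Evaluation protocols

**Retrospective split.** The n_holdout (default 20) most potent molecules
are withheld; ties at the boundary raise an error rather than silently
including a tied molecule.  The inference set is a seeded stratified draw
from the ⌊0.4 N⌋ worst molecules: exactly 10 inactives and 20 weak actives
by default.  The remainder trains the model (554 → 504/20/30).

**Similarity transfer.** Each prediction inherits the IC50 of its most
similar reference molecule (Tanimoto on Morgan fingerprints, radius 2,
2048 bits, binary — the ECFP4-equivalent convention) when the similarity
reaches the threshold (default 0.8).  Similarity ties resolve to the most
potent reference (documented choice; the alternative changes assignments
only on exact fingerprint ties).  The enrichment summary reports log-decade
histograms (inactives pinned to the terminal 10⁻³ bin), the difference in
median log10 IC50 between assigned and measured distributions (negative =
enrichment toward potency), and a one-sided Mann–Whitney p-value.

**Prospective triage.** Predictions are deduplicated, PAINS-filtered
(packaged pattern families A/B/C; user SMARTS lists supported), and passed
through a novelty window: Tanimoto similarity to the lead inside
[0.5, 0.95] and not identical to a training molecule.  The window is the
programmatic proxy for the manual "novel groups, small scaffold changes"
selection, which is out of scope.  One-step reachability asks whether a
candidate equals some transformation applied to some training molecule,
using a precomputed cut index; on small instances it provably agrees with
exhaustive product enumeration.  Shortlisted candidates are "assayed" by the
synthetic property oracle (noiseless model-implied values) and re-ranked
pooled with the training set.  Ligand efficiency uses
LE = 1.37 · pIC50 / heavy atoms (2.303 RT at 298 K, kcal/mol).

## Reference studies and problem sizes

The packaged studies (used by the test suite and `scripts/acceptance.py`)
run at deliberately reduced sizes chosen as the smallest that exercise every
code path with stable statistics on one CPU:

* *Prediction accounting*: full-size inputs (160 molecules × 6
  representations × 30 checkpoints = 28,800 samples) with a reduced model
  (width 48) and a capped training set (400 examples) — the accounting is
  exact regardless of model quality.
* *Enrichment*: the 32-molecule demo series, augmentation scale 10,
  45 epochs, predictions from the last 5 checkpoints with 3 spellings per
  molecule.  At this size the fine-tuned model reaches per-token perplexity
  ≈ 1.5–1.7 and the assigned-potency median lands 0.1–0.4 log units below
  the measured median across seeds.
* *Memorization*: 50 fixed examples, 200 epochs, width 64.

## Known limitations

* The transformer is deliberately small; nothing here probes scaling
  behavior, and pretraining is a desk-scale stand-in, not a large-corpus
  base model.
* The token grammar excludes charged/isotopic chemistry; series containing
  such compounds must be neutralized upstream.
* Single-cut MMPs capture substituent swaps, not ring-system rewrites;
  double cuts cover linker replacements only.
* Rank-sum scoring ignores objective scale; strongly unbalanced objective
  spreads may need the (unimplemented) weighted variant.
* The property oracle "assays" only molecules inside the generator's
  combinatorial space; out-of-space predictions can be filtered and ranked
  by similarity but not scored.
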