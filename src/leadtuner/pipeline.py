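"""End-to-end orchestration of the two study designs.

``run_pipeline`` chains the stages

    gen-data -> pairs -> orient -> augment -> pretrain -> finetune
             -> predict -> evaluate -> filter/reachability

writing one artifact per stage plus a JSON manifest with per-stage seeds,
record counts and artifact checksums, so a run can be audited stage by
stage and reproduced bit for bit.  Every stage is also callable on its own
with the previous stage's files (see ``cli``).

Study designs:

* ``retrospective`` — single objective (potency).  The best molecules are
  withheld, the model is fine-tuned on the rest, inference runs from a
  weak/inactive stratum, and predictions are scored by holdout recovery and
  similarity-based potency transfer.
* ``prospective`` — multiobjective (potency + microsomal stability rank
  sum).  The whole set trains the model; predictions are deduplicated,
  PAINS- and novelty-filtered, checked for one-step reachability, and
  re-ranked against the training set with oracle-assayed properties.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augmentation, evaluation, filtering_reachability, mmp_pairs
from . import scoring_ordering as scoring
from . import synthetic_data
from .chem import MoleculeRecord, to_selfies
from .errors import StageError
from .model.sampling import PredictionRecord, predict_batch
from .model.training import build_vocabulary, train
from .model.transformer import ModelConfig, ModelState

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    outdir: str = "run"
    input_csv: str | None = None  # use an existing molecule table instead of gen-data

    # synthetic data
    n_molecules: int = 554
    n_inactive: int = 66
    corpus_size: int = 400

    # pairing
    max_cuts: int = 1
    min_constant_frac: float = 2.0 / 3.0

    # retrospective split
    n_holdout: int = 20
    n_inference: int = 30
    n_inference_inactive: int = 10
    bottom_fraction: float = 0.4

    # augmentation
    augment_n: int = 200          # weighted-scheme scale (prospective)
    augment_uniform: int = 30     # uniform scheme (retrospective)
    inference_aug: int = 5        # randomized spellings added to the canonical input
    max_examples: int | None = None  # training-set cap after shuffling
    pretrain_pair_spellings: int = 1

    # model + schedule
    model: ModelConfig = field(default_factory=ModelConfig)
    pretrain_epoch_cap: int = 10
    pretrain_patience: int = 1

    # evaluation
    sim_threshold: float = 0.8
    sim_window: tuple[float, float] = (0.5, 0.95)
    reachability_top: int = 5

    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        model = payload.pop("model", {})
        cfg = cls(**{k: v for k, v in payload.items() if k != "model"})
        cfg.model = ModelConfig(**model)
        if isinstance(cfg.sim_window, list):
            cfg.sim_window = tuple(cfg.sim_window)
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed: independent streams, reproducible manifest."""
    return (zlib.crc32(stage.encode()) ^ (int(master) * 2654435761)) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, config: RunConfig, design: str):
        self.data = {
            "design": design,
            "config": dataclasses.asdict(config),
            "stage_seeds": {},
            "counts": {},
            "artifacts": {},
            "notes": {
                "base_model": "desk-scale stand-in architecture; see config.model"
            },
        }

    def seed(self, stage: str, value: int) -> None:
        self.data["stage_seeds"][stage] = value

    def count(self, name: str, value) -> None:
        self.data["counts"][name] = value
        log.info("count %s = %s", name, value)

    def artifact(self, path: Path) -> None:
        self.data["artifacts"][path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def _records_by_id(records):
    return {r.id: r for r in records}


def load_or_generate_records(config: RunConfig, manifest: Manifest,
                             outdir: Path, multiobjective: bool):
    if config.input_csv:
        records = synthetic_data.read_csv(config.input_csv)
    else:
        seed = stage_seed(config.seed, "gen-data")
        manifest.seed("gen-data", seed)
        spec = synthetic_data.SeriesSpec(
            n_molecules=config.n_molecules, n_inactive=config.n_inactive,
            with_stability=multiobjective, seed=seed,
        )
        records = synthetic_data.generate_series(spec)
    path = outdir / "records.csv"
    synthetic_data.write_csv(records, path)
    manifest.count("records", len(records))
    manifest.artifact(path)
    return records


def build_training_examples(train_records, config: RunConfig, manifest: Manifest,
                            outdir: Path, multiobjective: bool):
    """pairs -> orient -> augment -> shuffle, with per-stage artifacts."""
    pairs = mmp_pairs.build_pairs(train_records, max_cuts=config.max_cuts,
                                  min_constant_frac=config.min_constant_frac)
    if not pairs:
        raise StageError("pairs", "no matched pairs found among training molecules")
    ppath = outdir / "pairs.csv"
    mmp_pairs.pairs_to_frame(pairs).to_csv(ppath, index=False)
    manifest.count("matched_pairs", len(pairs))
    manifest.artifact(ppath)

    table = scoring.build_score_table(train_records, multiobjective=multiobjective)
    spath = outdir / "scores.csv"
    scoring.score_table_to_csv(table, spath)
    manifest.artifact(spath)

    directed = scoring.orient_pairs(pairs, table)
    manifest.count("directed_pairs", len(directed))

    if multiobjective:
        counts = augmentation.weighted_counts([d.score_diff for d in directed],
                                              config.augment_n)
    else:
        counts = augmentation.uniform_counts(len(directed), config.augment_uniform)
    import pandas as pd

    dpath = outdir / "directed.csv"
    pd.DataFrame({
        "source_id": [d.source_id for d in directed],
        "target_id": [d.target_id for d in directed],
        "score_diff": [d.score_diff for d in directed],
        "n_augment": counts,
    }).to_csv(dpath, index=False)
    manifest.artifact(dpath)

    aug_seed = stage_seed(config.seed, "augment")
    manifest.seed("augment", aug_seed)
    examples = augmentation.augment(directed, counts,
                                    _records_by_id(train_records), aug_seed)
    examples = augmentation.shuffle_examples(examples, aug_seed + 1)
    manifest.count("augmented_examples", len(examples))
    if config.max_examples is not None and len(examples) > config.max_examples:
        examples = examples[: config.max_examples]
        manifest.count("training_examples_after_cap", len(examples))
    augmentation.write_parallel(examples, outdir / "train_src.txt",
                                outdir / "train_tgt.txt")
    manifest.artifact(outdir / "train_src.txt")
    manifest.artifact(outdir / "train_tgt.txt")
    return examples


def pretrain_base_model(config: RunConfig, manifest: Manifest, outdir: Path,
                        extra_corpus: list[str]):
    """Pretrain on matched pairs from a diverse corpus (both pair orders),
    stopping by the perplexity-patience rule."""
    seed = stage_seed(config.seed, "pretrain-corpus")
    manifest.seed("pretrain-corpus", seed)
    corpus = synthetic_data.generate_pretrain_corpus(config.corpus_size, seed)
    corpus_records = [MoleculeRecord(f"C{i:05d}", smi) for i, smi in enumerate(corpus)]
    with open(outdir / "corpus.smi", "w") as fh:
        for r in corpus_records:
            fh.write(f"{r.smiles_canonical}\t{r.id}\n")
    manifest.count("pretrain_corpus", len(corpus))
    manifest.artifact(outdir / "corpus.smi")

    pairs = mmp_pairs.build_pairs(corpus_records,
                                  min_constant_frac=config.min_constant_frac)
    manifest.count("pretrain_pairs", len(pairs))
    # undirected: both orders, as in base-model training
    directed = []
    for p in pairs:
        directed.append(scoring.DirectedPair(p.id_a, p.id_b, 0.0, p))
        directed.append(scoring.DirectedPair(p.id_b, p.id_a, 0.0, p))
    aug_seed = stage_seed(config.seed, "pretrain-augment")
    manifest.seed("pretrain-augment", aug_seed)
    examples = augmentation.augment(
        directed,
        augmentation.uniform_counts(len(directed), config.pretrain_pair_spellings),
        _records_by_id(corpus_records), aug_seed,
    )
    examples = augmentation.shuffle_examples(examples, aug_seed + 1)
    manifest.count("pretrain_examples", len(examples))

    # the vocabulary must cover both the corpus and the series chemistry
    vocab = build_vocabulary(
        [to_selfies(s) for s in corpus] + extra_corpus
    )
    manifest.count("vocab_size", len(vocab))
    manifest.count("vocab_sha256",
                   hashlib.sha256(vocab.to_json().encode()).hexdigest()[:16])

    ckdir = outdir / "checkpoints"
    ckdir.mkdir(exist_ok=True)
    result = train(examples, config.model, vocab=vocab, phase="pretrain",
                   max_epochs=config.pretrain_epoch_cap,
                   patience=config.pretrain_patience, checkpoint_dir=ckdir)
    manifest.count("pretrain_epochs_run", len(result.states))
    manifest.count("pretrain_best_epoch", result.best_epoch)
    base = result.states[result.best_epoch - 1]
    return base, result


def run_pipeline(config: RunConfig, design: str) -> dict:
    """Execute one study design end to end; returns the manifest dict."""
    if design not in ("retrospective", "prospective"):
        raise ValueError(f"unknown design {design!r}")
    multiobjective = design == "prospective"
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config, design)
    config.to_yaml(outdir / "config.yaml")

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrap

    records = stage("gen-data")(load_or_generate_records, config, manifest,
                                outdir, multiobjective)
    by_id = _records_by_id(records)

    if design == "retrospective":
        split_seed = stage_seed(config.seed, "split")
        manifest.seed("split", split_seed)
        split = stage("split")(
            evaluation.make_retrospective_split, records, split_seed,
            config.n_holdout, config.n_inference, config.n_inference_inactive,
            config.bottom_fraction,
        )
        with open(outdir / "split.json", "w") as fh:
            json.dump(dataclasses.asdict(split), fh, indent=2)
        manifest.artifact(outdir / "split.json")
        manifest.count("train", len(split.train_ids))
        manifest.count("holdout", len(split.holdout_ids))
        manifest.count("inference", len(split.inference_ids))
        train_records = [by_id[i] for i in split.train_ids]
        inference_records = [by_id[i] for i in split.inference_ids]
    else:
        train_records = records
        inference_records = records

    examples = stage("augment")(build_training_examples, train_records, config,
                                manifest, outdir, multiobjective)

    extra = [to_selfies(r.smiles_canonical) for r in records]
    base, _ = stage("pretrain")(pretrain_base_model, config, manifest, outdir, extra)

    ckdir = outdir / "checkpoints"
    ft = stage("finetune")(train, examples, config.model, init=base,
                           phase="finetune", checkpoint_dir=ckdir)
    manifest.count("finetune_epochs", len(ft.states))

    pred_seed = stage_seed(config.seed, "predict")
    manifest.seed("predict", pred_seed)
    reps = stage("predict")(augmentation.inference_representations,
                            inference_records, config.inference_aug, pred_seed)
    manifest.count("inference_representations", len(reps))
    predictions = stage("predict")(predict_batch, ft.states, reps, pred_seed)
    manifest.count("predictions", len(predictions))
    import pandas as pd

    ppath = outdir / "predictions.csv"
    pd.DataFrame({
        "input_id": [p.input_id for p in predictions],
        "epoch": [p.epoch for p in predictions],
        "canonical_smiles": [p.canonical_smiles for p in predictions],
        "raw_selfies": [p.raw_selfies for p in predictions],
    }).to_csv(ppath, index=False)
    manifest.artifact(ppath)

    unique = evaluation.dedup_predictions(predictions)
    manifest.count("unique_predictions", len(unique))

    if design == "retrospective":
        stage("evaluate")(evaluate_retrospective, config, manifest, outdir,
                          unique, by_id, split, train_records)
    else:
        stage("evaluate")(evaluate_prospective, config, manifest, outdir,
                          unique, train_records)

    manifest.write(outdir / "manifest.json")
    return manifest.data


def evaluate_retrospective(config, manifest, outdir: Path, unique: dict,
                           by_id: dict, split, train_records) -> None:
    import pandas as pd

    holdout_records = [by_id[i] for i in split.holdout_ids]
    recovery = evaluation.holdout_recovery(unique, holdout_records)
    pd.Series(recovery, name="times_predicted").rename_axis("id").to_csv(
        outdir / "recovery.csv")
    manifest.artifact(outdir / "recovery.csv")
    manifest.count("holdout_recovered", sum(v > 0 for v in recovery.values()))

    novel = [s for s in unique
             if s not in {r.smiles_canonical for r in train_records}]
    assignments = evaluation.similarity_transfer(novel, train_records,
                                                 threshold=config.sim_threshold)
    pd.DataFrame({
        "smiles": [a.smiles for a in assignments],
        "nearest_id": [a.nearest_id for a in assignments],
        "similarity": [a.similarity for a in assignments],
        "assigned_ic50": [a.assigned_ic50 for a in assignments],
    }).to_csv(outdir / "assignments.csv", index=False)
    manifest.artifact(outdir / "assignments.csv")
    manifest.count("assigned_predictions", len(assignments))

    summary = evaluation.enrichment_summary(
        [a.assigned_ic50 for a in assignments],
        [r.ic50_molar for r in train_records],
    )
    pd.DataFrame({
        "bin_log10_ic50": summary.bins,
        "predicted": summary.predicted_hist,
        "training": summary.training_hist,
    }).to_csv(outdir / "enrichment.csv", index=False)
    manifest.artifact(outdir / "enrichment.csv")
    manifest.count("median_shift", summary.median_shift)
    manifest.count("shift_p_value", summary.p_value)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write("retrospective evaluation\n")
        fh.write(f"holdout recovered: {sum(v > 0 for v in recovery.values())} "
                 f"of {len(recovery)}\n")
        fh.write(f"recovery counts: {sorted(recovery.values(), reverse=True)}\n")
        fh.write(f"assigned predictions: {len(assignments)}\n")
        fh.write(f"median log10(IC50) shift: {summary.median_shift}\n")
        fh.write(f"one-sided rank-test p: {summary.p_value}\n")
    manifest.artifact(outdir / "summary.txt")


def evaluate_prospective(config, manifest, outdir: Path, unique: dict,
                         train_records) -> None:
    import pandas as pd

    train_smiles = {r.smiles_canonical for r in train_records}
    candidates = [s for s in unique if s not in train_smiles]
    manifest.count("novel_unique_predictions", len(candidates))

    table = scoring.build_score_table(train_records, multiobjective=True)
    lead_id = table["score"].idxmax()
    lead = next(r for r in train_records if r.id == lead_id)
    manifest.count("lead_id", lead_id)

    report = filtering_reachability.filter_report(
        candidates, train_records, lead, sim_window=config.sim_window)
    pd.DataFrame({
        "smiles": [e.smiles for e in report],
        "pains_flags": [";".join(e.pains_flags) for e in report],
        "similarity_to_lead": [e.similarity_to_lead for e in report],
        "in_training_set": [e.in_training_set for e in report],
        "passed": [e.passed for e in report],
    }).to_csv(outdir / "filter_report.csv", index=False)
    manifest.artifact(outdir / "filter_report.csv")
    pains_clean = [e for e in report if not e.pains_flags]
    manifest.count("pains_pass", len(pains_clean))
    shortlist = [e.smiles for e in report if e.passed]
    manifest.count("novelty_pass", len(shortlist))

    # most frequently predicted shortlisted molecules, as synthesis candidates
    ranked = sorted(shortlist, key=lambda s: (-unique[s], s))
    top = ranked[: config.reachability_top]

    transformations = [
        mmp_pairs.extract_transformation(p)
        for p in mmp_pairs.build_pairs(train_records,
                                       min_constant_frac=config.min_constant_frac)
    ]
    index = filtering_reachability.CutIndex(train_records)
    reach_rows = []
    for smi in top:
        ok, wit = filtering_reachability.one_step_reachable(
            smi, train_records, transformations, index=index)
        reach_rows.append({"smiles": smi, "one_step_reachable": ok,
                           "witness": wit[0][1] if wit else ""})
    pd.DataFrame(reach_rows).to_csv(outdir / "reachability.csv", index=False)
    manifest.artifact(outdir / "reachability.csv")
    manifest.count("top_one_step_reachable",
                   sum(r["one_step_reachable"] for r in reach_rows))

    # oracle "assay" of the top candidates, then pooled re-ranking
    oracle = synthetic_data.property_oracle(
        synthetic_data.SeriesSpec(
            n_molecules=config.n_molecules, n_inactive=config.n_inactive,
            seed=stage_seed(config.seed, "gen-data"))
    ) if not config.input_csv else {}
    measured = []
    for i, smi in enumerate(top):
        if smi in oracle:
            ic50, th = oracle[smi]
            measured.append(MoleculeRecord(f"P{i + 1}", smi, ic50, th))
    manifest.count("top_assayable", len(measured))
    if measured:
        combined = evaluation.rank_predictions(measured, train_records)
        combined.to_csv(outdir / "ranks.csv")
        manifest.artifact(outdir / "ranks.csv")
        pred_rows = combined[combined["is_prediction"]]
        manifest.count("prediction_rank_positions",
                       pred_rows["rank_position"].tolist())
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("prospective evaluation\n")
        fh.write(f"unique predictions: {len(unique)}\n")
        fh.write(f"novel unique predictions: {len(candidates)}\n")
        fh.write(f"PAINS pass: {len(pains_clean)}\n")
        fh.write(f"novelty-window pass: {len(shortlist)}\n")
        fh.write(f"top candidates: {top}\n")
        fh.write(f"one-step reachable among top: "
                 f"{sum(r['one_step_reachable'] for r in reach_rows)}\n")
        if measured:
            fh.write(f"prediction rank positions (1=best) of "
                     f"{len(train_records) + len(measured)}: "
                     f"{pred_rows['rank_position'].tolist()}\n")
    manifest.artifact(outdir / "summary.txt")
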