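"""Retrospective and prospective evaluation protocols.

Retrospective: hold out the top molecules by potency, fine-tune on the rest,
run inference from a weak/inactive stratum, then ask (a) how often held-out
actives are regenerated (holdout recovery) and (b) whether predictions sit in
potent chemical neighborhoods, by transferring the IC50 of the most similar
known molecule (Tanimoto on Morgan fingerprints) when similarity clears a
threshold and comparing the assigned distribution with the measured one.

Prospective: deduplicate predictions, pool measured predictions with the
training set, and re-rank everything by the multiobjective rank-sum score.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import mannwhitneyu

from .chem import MoleculeRecord, mol_from_smiles
from .model.sampling import PredictionRecord
from .scoring_ordering import build_score_table

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class RetroSplit:
    """Partition for the retrospective study: the best ``holdout`` molecules
    by IC50 are withheld, ``inference`` molecules (with a fixed inactive
    quota) are drawn from the worst stratum, the rest train the model."""

    train_ids: list[str]
    holdout_ids: list[str]
    inference_ids: list[str]


def make_retrospective_split(records: Sequence[MoleculeRecord], seed: int,
                             n_holdout: int = 20, n_inference: int = 30,
                             n_inference_inactive: int = 10,
                             bottom_fraction: float = 0.4) -> RetroSplit:
    """Deterministic seeded split; see RetroSplit.

    The inference set is a stratified uniform draw from the ``bottom_fraction``
    worst molecules: exactly ``n_inference_inactive`` inactives, the rest
    actives.  Raises when the stratum lacks enough of either.
    """
    if any(r.ic50_molar is None for r in records):
        missing = [r.id for r in records if r.ic50_molar is None]
        raise ValueError(f"records lacking potency: {', '.join(missing)}")
    n = len(records)
    if n < n_holdout + n_inference + 1:
        raise ValueError("too few records to split")
    by_potency = sorted(records, key=lambda r: (r.ic50_molar, r.id))
    if by_potency[n_holdout - 1].ic50_molar >= by_potency[n_holdout].ic50_molar:
        raise ValueError("potency tie at the holdout boundary; holdout not unique")
    holdout = by_potency[:n_holdout]
    rest = by_potency[n_holdout:]

    n_bottom = int(bottom_fraction * n)  # worst 40% of the full set
    bottom = rest[-n_bottom:]
    bottom_inactive = [r for r in bottom if r.is_inactive]
    bottom_active = [r for r in bottom if not r.is_inactive]
    n_active_draw = n_inference - n_inference_inactive
    if len(bottom_inactive) < n_inference_inactive:
        raise ValueError(
            f"worst stratum has {len(bottom_inactive)} inactives; "
            f"{n_inference_inactive} required"
        )
    if len(bottom_active) < n_active_draw:
        raise ValueError("worst stratum has too few active molecules")
    rng = np.random.default_rng(int(seed))
    inf_inactive = [bottom_inactive[i] for i in
                    rng.choice(len(bottom_inactive), n_inference_inactive, replace=False)]
    inf_active = [bottom_active[i] for i in
                  rng.choice(len(bottom_active), n_active_draw, replace=False)]
    inference_ids = {r.id for r in inf_inactive} | {r.id for r in inf_active}
    train_ids = [r.id for r in rest if r.id not in inference_ids]
    return RetroSplit(
        train_ids=train_ids,
        holdout_ids=[r.id for r in holdout],
        inference_ids=sorted(inference_ids),
    )


def dedup_predictions(records: Sequence[PredictionRecord]) -> dict[str, int]:
    """canonical SMILES -> prediction count (empty generations excluded;
    counts over non-empty records sum to their total)."""
    return dict(Counter(r.canonical_smiles for r in records if not r.is_empty))


def holdout_recovery(unique_predictions: Mapping[str, int],
                     holdout_records: Sequence[MoleculeRecord]) -> dict[str, int]:
    """Per holdout molecule: how often it was predicted (0 when never)."""
    return {r.id: int(unique_predictions.get(r.smiles_canonical, 0))
            for r in holdout_records}


def _fingerprints(smiles: Sequence[str]):
    return [_MORGAN.GetFingerprint(mol_from_smiles(s)) for s in smiles]


@dataclass
class SimilarityAssignment:
    smiles: str
    nearest_id: str
    similarity: float
    assigned_ic50: float


def similarity_transfer(predictions: Sequence[str],
                        reference_records: Sequence[MoleculeRecord],
                        threshold: float = 0.8,
                        fp_radius: int = 2) -> list[SimilarityAssignment]:
    """Assign each prediction the IC50 of its most similar reference molecule
    when the Tanimoto similarity (Morgan fingerprints, radius ``fp_radius``,
    2048 bits) reaches ``threshold``; otherwise no assignment.  Ties on
    similarity go to the most potent (lowest-IC50) reference.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    gen = (_MORGAN if fp_radius == 2
           else rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=2048))
    ref_fps = [gen.GetFingerprint(mol_from_smiles(r.smiles_canonical))
               for r in reference_records]
    out: list[SimilarityAssignment] = []
    for smi in predictions:
        fp = gen.GetFingerprint(mol_from_smiles(smi))
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(fp, ref_fps))
        best_sim = sims.max()
        if best_sim < threshold:
            continue
        tied = np.flatnonzero(sims == best_sim)
        best = min(tied, key=lambda i: (reference_records[i].ic50_molar,
                                        reference_records[i].id))
        out.append(SimilarityAssignment(smi, reference_records[best].id,
                                        float(best_sim),
                                        float(reference_records[best].ic50_molar)))
    return out


@dataclass
class EnrichmentSummary:
    bins: list[float]                  # left edges, log10 molar; last = inactive bin
    predicted_hist: list[int]
    training_hist: list[int]
    median_shift: float | None        # median log10 assigned - median log10 training
    p_value: float | None              # rank-based one-sided test (assigned < training)
    n_assigned: int = 0
    message: str = ""


def enrichment_summary(assigned_potencies: Sequence[float],
                       training_potencies: Sequence[float],
                       inactive_ic50_molar: float = 1e-3) -> EnrichmentSummary:
    """Log-binned histograms plus a distribution-shift statistic.

    One bin per log10 decade from 1e-9.5 up, with the inactive ceiling pinned
    to its own terminal bin.  Negative shift = predictions concentrate at
    better (lower) IC50 than the measured set.
    """
    edges = list(np.arange(-9.5, -3.4, 1.0))  # -9.5 .. -3.5
    inactive_edge = np.log10(inactive_ic50_molar)
    bins = edges + [inactive_edge]

    def hist(values):
        counts = [0] * len(bins)
        for v in values:
            lv = np.log10(v)
            if v >= inactive_ic50_molar:
                counts[-1] += 1
                continue
            idx = int(np.clip(np.floor(lv - edges[0]), 0, len(edges) - 1))
            counts[idx] += 1
        return counts

    if len(assigned_potencies) == 0:
        return EnrichmentSummary(bins, [0] * len(bins), hist(training_potencies),
                                 None, None, 0, "no assignable predictions")
    a = np.log10(np.asarray(assigned_potencies, dtype=float))
    t = np.log10(np.asarray(training_potencies, dtype=float))
    shift = float(np.median(a) - np.median(t))
    p = float(mannwhitneyu(a, t, alternative="less").pvalue)
    return EnrichmentSummary(bins, hist(assigned_potencies), hist(training_potencies),
                             shift, p, len(assigned_potencies))


def rank_predictions(predicted_records: Sequence[MoleculeRecord],
                     training_records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Pool measured predictions with the training set and re-rank by the
    multiobjective rank-sum score.

    Returns the combined score table with a ``rank_position`` column
    (1 = best; ties share the best position of their block) and an
    ``is_prediction`` flag.
    """
    missing = [r.id for r in predicted_records
               if r.ic50_molar is None or r.t_half_min is None]
    if missing:
        raise ValueError(f"predictions lacking measured properties: {', '.join(missing)}")
    pooled = list(training_records) + list(predicted_records)
    table = build_score_table(pooled, multiobjective=True)
    scores = table["score"].to_numpy()
    position = 1 + (scores[:, None] < scores[None, :]).sum(axis=1)
    table["rank_position"] = position
    pred_ids = {r.id for r in predicted_records}
    table["is_prediction"] = [i in pred_ids for i in table.index]
    return table


def ligand_efficiency(ic50_molar: float, heavy_atoms: int) -> float:
    """LE = 1.37 * pIC50 / heavy atoms (kcal/mol per heavy atom at 298 K).

    The constant is 2.303*R*T in kcal/mol at T = 298 K, converting a log10
    potency into a binding free energy.
    """
    if ic50_molar <= 0:
        raise ValueError("ic50 must be positive")
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return 1.37 * (-np.log10(ic50_molar)) / heavy_atoms
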