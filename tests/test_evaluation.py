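"""Retrospective/prospective evaluation protocol mechanics."""

import numpy as np
import pytest

from leadtuner.chem import MoleculeRecord, canonicalize, heavy_atom_count
from leadtuner.evaluation import (
    dedup_predictions,
    enrichment_summary,
    holdout_recovery,
    ligand_efficiency,
    make_retrospective_split,
    rank_predictions,
    similarity_transfer,
)
from leadtuner.model.sampling import PredictionRecord
from leadtuner.synthetic_data import SeriesSpec, generate_series


class TestRetrospectiveSplit:
    def test_partition_law(self, series_160):
        split = make_retrospective_split(series_160, seed=1, n_holdout=10,
                                         n_inference=20, n_inference_inactive=8)
        all_ids = (set(split.train_ids) | set(split.holdout_ids)
                   | set(split.inference_ids))
        assert len(all_ids) == len(series_160)
        assert len(split.train_ids) + len(split.holdout_ids) + \
            len(split.inference_ids) == len(series_160)

    def test_holdout_strictly_best(self, series_160):
        split = make_retrospective_split(series_160, seed=1, n_holdout=10,
                                         n_inference=20, n_inference_inactive=8)
        by_id = {r.id: r for r in series_160}
        worst_holdout = max(by_id[i].ic50_molar for i in split.holdout_ids)
        others = [by_id[i].ic50_molar for i in
                  split.train_ids + split.inference_ids]
        assert worst_holdout < min(others)

    def test_inference_inactive_quota(self, series_160):
        split = make_retrospective_split(series_160, seed=3, n_holdout=10,
                                         n_inference=20, n_inference_inactive=8)
        by_id = {r.id: r for r in series_160}
        inactives = sum(by_id[i].is_inactive for i in split.inference_ids)
        assert inactives == 8

    def test_deterministic(self, series_160):
        a = make_retrospective_split(series_160, seed=5, n_holdout=10,
                                     n_inference=20, n_inference_inactive=8)
        b = make_retrospective_split(series_160, seed=5, n_holdout=10,
                                     n_inference=20, n_inference_inactive=8)
        assert a == b

    def test_insufficient_inactives_raise(self):
        recs = generate_series(SeriesSpec(n_molecules=60, n_inactive=2, seed=1))
        with pytest.raises(ValueError, match="inactives"):
            make_retrospective_split(recs, seed=0, n_holdout=5,
                                     n_inference=10, n_inference_inactive=5)


class TestDedupAndRecovery:
    def _pred(self, smi, i=0):
        return PredictionRecord("x", i, canonicalize(smi), "")

    def test_triplicate_collapses(self):
        out = dedup_predictions([self._pred("CCO", i) for i in range(3)])
        assert out == {canonicalize("CCO"): 3}

    def test_empty_input(self):
        assert dedup_predictions([]) == {}

    def test_counts_conserved(self, small_series):
        preds = [self._pred(r.smiles_canonical, i)
                 for i, r in enumerate(small_series)] * 2
        out = dedup_predictions(preds)
        assert sum(out.values()) == len(preds)

    def test_recovery_counts(self):
        hold = [MoleculeRecord("h1", canonicalize("CCO")),
                MoleculeRecord("h2", canonicalize("CCN"))]
        unique = {canonicalize("CCO"): 6, canonicalize("CCCC"): 2}
        assert holdout_recovery(unique, hold) == {"h1": 6, "h2": 0}

    def test_recovery_order_invariant(self):
        hold = [MoleculeRecord("h1", canonicalize("CCO")),
                MoleculeRecord("h2", canonicalize("CCN"))]
        unique = {canonicalize("CCN"): 1}
        assert holdout_recovery(unique, hold) == \
            holdout_recovery(unique, list(reversed(hold)))
        assert holdout_recovery(unique, hold) == {"h1": 0, "h2": 1}


class TestSimilarityTransfer:
    def test_identity_assignment(self, small_series):
        ref = small_series[0]
        out = similarity_transfer([ref.smiles_canonical], small_series, 0.8)
        assert len(out) == 1
        assert out[0].similarity == 1.0
        assert out[0].assigned_ic50 == ref.ic50_molar

    def test_disjoint_molecule_unassigned(self, small_series):
        assert similarity_transfer(["C"], small_series, 0.8) == []

    def test_threshold_zero_assigns_everything(self, small_series):
        preds = ["C", "CCO", small_series[0].smiles_canonical]
        assert len(similarity_transfer(preds, small_series, 0.0)) == 3

    def test_threshold_one_only_exact(self, small_series):
        preds = ["CCO", small_series[3].smiles_canonical]
        out = similarity_transfer(preds, small_series, 1.0)
        assert [a.smiles for a in out] == [small_series[3].smiles_canonical]

    def test_monotone_in_threshold(self, small_series, series_160):
        preds = [r.smiles_canonical for r in series_160[:40]]
        counts = [len(similarity_transfer(preds, small_series, t))
                  for t in (0.75, 0.8, 0.85, 0.9)]
        assert counts == sorted(counts, reverse=True)


class TestEnrichment:
    def test_identical_distributions_zero_shift(self):
        vals = [1e-8, 1e-7, 1e-6, 1e-5]
        s = enrichment_summary(vals, vals)
        assert s.median_shift == 0.0

    def test_all_at_best_training_value(self):
        train = [1e-8, 1e-7, 1e-6, 1e-5]
        s = enrichment_summary([1e-8] * 4, train)
        assert s.median_shift == pytest.approx(np.log10(1e-8) - np.log10(np.sqrt(1e-7 * 1e-6)))
        assert s.median_shift < 0

    def test_empty_assignments_reported(self):
        s = enrichment_summary([], [1e-8])
        assert s.median_shift is None and "no assignable" in s.message

    def test_inactives_pinned_to_terminal_bin(self):
        s = enrichment_summary([1e-3, 1e-8], [1e-3])
        assert s.predicted_hist[-1] == 1
        assert s.training_hist[-1] == 1


class TestRankPredictions:
    def test_pool_and_best_rank(self, series_160):
        best = MoleculeRecord("pred", "C", ic50_molar=1e-12, t_half_min=1e5)
        table = rank_predictions([best], series_160)
        assert len(table) == 161
        assert table.loc["pred", "rank_position"] == 1

    def test_tie_shares_block(self, series_160):
        twin_src = series_160[0]
        twin = MoleculeRecord("pred", "C", ic50_molar=twin_src.ic50_molar,
                              t_half_min=twin_src.t_half_min)
        table = rank_predictions([twin], series_160)
        assert table.loc["pred", "rank_position"] == \
            table.loc[twin_src.id, "rank_position"]

    def test_missing_property_raises(self, series_160):
        bad = MoleculeRecord("pred", "C", ic50_molar=1e-9, t_half_min=None)
        with pytest.raises(ValueError, match="pred"):
            rank_predictions([bad], series_160)


class TestLigandEfficiency:
    def test_closed_form(self):
        assert ligand_efficiency(1e-9, 30) == pytest.approx(1.37 * 9 / 30)
        assert ligand_efficiency(1e-9, 30) == pytest.approx(0.411)

    def test_proportionality(self):
        assert ligand_efficiency(1e-8, 60) == pytest.approx(
            ligand_efficiency(1e-8, 30) / 2)

    def test_monotone_in_size(self):
        vals = [ligand_efficiency(1e-8, n) for n in (10, 20, 40, 80)]
        assert vals == sorted(vals, reverse=True)
        assert all(v > 0 for v in vals)
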