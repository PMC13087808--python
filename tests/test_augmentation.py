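"""Score-difference-weighted augmentation and example bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leadtuner.augmentation import (
    augment,
    inference_representations,
    read_parallel,
    shuffle_examples,
    uniform_counts,
    weighted_counts,
    write_parallel,
)
from leadtuner.chem import from_selfies
from leadtuner.mmp_pairs import build_pairs
from leadtuner.scoring_ordering import build_score_table, orient_pairs


def one_line_oracle(diffs, n):
    """Independent evaluation of the weighting formula."""
    lo, hi = min(diffs), max(diffs)
    return [math.floor((d - lo) / (hi - lo) * n) for d in diffs]


class TestWeightedCounts:
    def test_endpoints_forced(self):
        assert weighted_counts([0.0, 5.0, 10.0], 200).tolist() == [0, 100, 200]

    def test_floor_applied_exactly(self):
        # (d - dmin)/(dmax - dmin) = 0.499 -> floor(99.8) = 99
        assert weighted_counts([0.0, 0.499, 1.0], 200).tolist()[1] == 99

    def test_degenerate_all_equal_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            out = weighted_counts([2.0, 2.0, 2.0], 200)
        assert out.tolist() == [1, 1, 1]
        assert any("equal" in r.message for r in caplog.records)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e3, allow_nan=False),
                    min_size=2, max_size=30).filter(lambda d: max(d) > min(d)),
           st.integers(min_value=1, max_value=500))
    def test_matches_one_line_oracle(self, diffs, n):
        assert weighted_counts(diffs, n).tolist() == one_line_oracle(diffs, n)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False),
                    min_size=2, max_size=20).filter(lambda d: max(d) > min(d)))
    def test_monotone_in_diff(self, diffs):
        counts = weighted_counts(diffs, 100)
        order = np.argsort(diffs)
        assert (np.diff(counts[order]) >= 0).all()


@pytest.fixture(scope="module")
def directed(small_series):
    table = build_score_table(small_series)
    return orient_pairs(build_pairs(small_series), table)


class TestAugment:
    def test_single_pair_thirty_examples(self, directed, records_by_id):
        dp = [d for d in directed if d.score_diff > 0][0]
        out = augment([dp], [30], records_by_id, seed=1)
        assert len(out) == 30
        src = records_by_id[dp.source_id].smiles_canonical
        tgt = records_by_id[dp.target_id].smiles_canonical
        for ex in out:
            assert from_selfies(ex.source_selfies) == src
            assert from_selfies(ex.target_selfies) == tgt

    def test_zero_count_contributes_nothing(self, directed, records_by_id):
        assert augment(directed[:3], [0, 0, 0], records_by_id, seed=1) == []

    def test_total_conservation(self, directed, records_by_id):
        counts = weighted_counts([d.score_diff for d in directed], 5)
        out = augment(directed, counts, records_by_id, seed=2)
        assert len(out) == int(counts.sum())

    def test_deterministic(self, directed, records_by_id):
        a = augment(directed[:5], [3] * 5, records_by_id, seed=7)
        b = augment(directed[:5], [3] * 5, records_by_id, seed=7)
        assert a == b

    def test_source_never_equals_target_molecule(self, directed, records_by_id):
        out = augment(directed[:10], [2] * 10, records_by_id, seed=3)
        for ex in out:
            assert from_selfies(ex.source_selfies) != from_selfies(ex.target_selfies)


class TestShuffleAndIO:
    def test_multiset_equality_and_determinism(self, small_series, records_by_id):
        directed = orient_pairs(build_pairs(small_series),
                                build_score_table(small_series))
        ex = augment(directed[:8], uniform_counts(8, 2), records_by_id, seed=4)
        shuffled = shuffle_examples(ex, seed=9)
        assert sorted(map(repr, shuffled)) == sorted(map(repr, ex))
        assert shuffle_examples(ex, seed=9) == shuffled
        assert shuffle_examples(ex[:1], seed=0) == ex[:1]

    def test_parallel_roundtrip(self, tmp_path, small_series, records_by_id):
        directed = orient_pairs(build_pairs(small_series),
                                build_score_table(small_series))
        ex = augment(directed[:4], uniform_counts(4, 2), records_by_id, seed=4)
        write_parallel(ex, tmp_path / "s.txt", tmp_path / "t.txt")
        back = read_parallel(tmp_path / "s.txt", tmp_path / "t.txt")
        assert [(e.source_selfies, e.target_selfies) for e in back] == \
            [(e.source_selfies, e.target_selfies) for e in ex]


class TestInferenceRepresentations:
    def test_canonical_plus_k(self, small_series):
        reps = inference_representations(small_series[:4], k=5, seed=1)
        assert len(reps) == 4 * 6  # canonical + 5 randomized each
        for rec in small_series[:4]:
            mine = [sf for mid, sf in reps if mid == rec.id]
            assert from_selfies(mine[0]) == rec.smiles_canonical
            assert all(from_selfies(s) == rec.smiles_canonical for s in mine)
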