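"""Series generator: counts, determinism, additive-model recovery."""

import io

import numpy as np
import pytest
from rdkit import Chem

from leadtuner.errors import SeriesExhaustedError
from leadtuner.synthetic_data import (
    DEFAULT_SCAFFOLD,
    SeriesSpec,
    generate_pretrain_corpus,
    generate_series,
    property_oracle,
    records_to_frame,
    resolve_contributions,
)

SCAFFOLD_QUERY = Chem.MolFromSmiles(DEFAULT_SCAFFOLD.replace("[*:1]", "[H]")
                                    .replace("[*:2]", "[H]"), sanitize=True)


def _scaffold_core():
    # scaffold with attachment points stripped, as a substructure query
    core = Chem.MolFromSmiles("O=C(c1ccccc1)N1CCC2(C1)CNC2")
    assert core is not None
    return core


class TestGenerateSeries:
    def test_counts_and_inactive_constant(self):
        recs = generate_series(SeriesSpec(n_molecules=554, n_inactive=66, seed=3))
        assert len(recs) == 554
        inactive = [r for r in recs if r.is_inactive]
        assert len(inactive) == 66
        assert all(r.ic50_molar == 1e-3 for r in inactive)
        actives = [r for r in recs if not r.is_inactive]
        assert all(1e-10 < r.ic50_molar < 1e-3 for r in actives)
        assert all(r.t_half_min > 0 for r in recs)

    def test_single_molecule_contains_scaffold(self):
        recs = generate_series(SeriesSpec(n_molecules=1, n_inactive=0, seed=0))
        assert len(recs) == 1
        mol = Chem.MolFromSmiles(recs[0].smiles_canonical)
        assert mol.HasSubstructMatch(_scaffold_core())

    def test_all_contain_scaffold_and_distinct(self, small_series):
        core = _scaffold_core()
        smiles = [r.smiles_canonical for r in small_series]
        assert len(set(smiles)) == len(smiles)
        for s in smiles:
            assert Chem.MolFromSmiles(s).HasSubstructMatch(core)

    def test_deterministic_byte_identical(self):
        spec = SeriesSpec(n_molecules=40, n_inactive=5, seed=9)
        a, b = io.StringIO(), io.StringIO()
        records_to_frame(generate_series(spec)).to_csv(a, index=False)
        records_to_frame(generate_series(spec)).to_csv(b, index=False)
        assert a.getvalue() == b.getvalue()

    def test_pool_exhaustion_names_shortfall(self):
        with pytest.raises(SeriesExhaustedError, match="shortfall"):
            generate_series(SeriesSpec(n_molecules=10_000, n_inactive=0, seed=0))

    def test_inactives_are_worst_by_model(self):
        spec = SeriesSpec(n_molecules=60, n_inactive=10, seed=2)
        recs = generate_series(spec)
        pot, _ = resolve_contributions(spec)
        det = {r.id: sum(c[i] for c, i in zip(pot, r.extra["combo"])) for r in recs}
        worst = sorted(det, key=lambda i: -det[i])[:10]
        assert {r.id for r in recs if r.is_inactive} == set(worst)

    def test_parameter_recovery(self):
        # regressing log10(IC50) on substituent indicators recovers the
        # additive contributions to well within 3 noise s.d.
        spec = SeriesSpec(n_molecules=250, n_inactive=0, seed=13)
        recs = generate_series(spec)
        pot, _ = resolve_contributions(spec)
        n1, n2 = len(spec.substituent_pools[0]), len(spec.substituent_pools[1])
        X = np.zeros((len(recs), 1 + (n1 - 1) + (n2 - 1)))
        X[:, 0] = 1.0
        y = np.empty(len(recs))
        for k, r in enumerate(recs):
            i, j = r.extra["combo"]
            if i > 0:
                X[k, i] = 1.0
            if j > 0:
                X[k, n1 - 1 + j] = 1.0
            y[k] = np.log10(r.ic50_molar)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        tol = 3 * spec.potency_model.noise_sd
        # recovered contrasts vs reference substituent 0 at each site
        for i in range(1, n1):
            assert abs(beta[i] - (pot[0][i] - pot[0][0])) < tol
        for j in range(1, n2):
            assert abs(beta[n1 - 1 + j] - (pot[1][j] - pot[1][0])) < tol


class TestPropertyOracle:
    def test_oracle_covers_series_and_caps_at_ceiling(self):
        spec = SeriesSpec(n_molecules=20, n_inactive=0, seed=4)
        oracle = property_oracle(spec)
        for r in generate_series(spec):
            ic50, th = oracle[r.smiles_canonical]
            assert 0 < ic50 <= spec.inactive_ic50_molar
            assert th > 0


class TestPretrainCorpus:
    def test_count_validity_distinct(self):
        corpus = generate_pretrain_corpus(300, seed=7)
        assert len(corpus) == 300 == len(set(corpus))
        for s in corpus[:50]:
            assert Chem.MolFromSmiles(s) is not None

    def test_single_and_determinism(self):
        assert len(generate_pretrain_corpus(1, seed=0)) == 1
        assert generate_pretrain_corpus(50, seed=5) == generate_pretrain_corpus(50, seed=5)

    def test_diverse_scaffolds(self):
        corpus = generate_pretrain_corpus(200, seed=1)
        core = _scaffold_core()
        without = sum(1 for s in corpus
                      if not Chem.MolFromSmiles(s).HasSubstructMatch(core))
        assert without > 150  # not dominated by the series scaffold
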