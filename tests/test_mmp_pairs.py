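"""Matched-pair fragmentation, pairing, and transformation round trips."""

import random

import pytest
from rdkit import Chem

from leadtuner.chem import MoleculeRecord, canonicalize
from leadtuner.mmp_pairs import (
    Transformation,
    apply_transformation,
    build_pairs,
    extract_transformation,
    fragment,
)


def rec(name, smiles):
    return MoleculeRecord(name, canonicalize(smiles))


def brute_force_cuts(smiles):
    """Independent oracle: every acyclic single bond split, constant = the
    side with more heavy atoms (canonical-SMILES tie-break)."""
    mol = Chem.MolFromSmiles(smiles)
    out = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        cut = Chem.FragmentOnBonds(mol, [bond.GetIdx()], dummyLabels=[(1, 1)])
        frags = Chem.GetMolFrags(cut, asMols=True)
        for f in frags:
            for a in f.GetAtoms():
                if a.GetAtomicNum() == 0:
                    a.SetAtomMapNum(1)
                    a.SetIsotope(0)
        fa, fb = (Chem.MolToSmiles(f) for f in frags)
        ha, hb = (f.GetNumHeavyAtoms() for f in frags)
        const, var = ((fa, fb) if (ha, fa) >= (hb, fb) else (fb, fa))
        out.add((const, var))
    return out


class TestFragment:
    def test_ethanol_both_cuts(self):
        frs = fragment(rec("eth", "CCO"), min_constant_frac=0.0)
        got = {(f.constant_part, f.variable_part) for f in frs}
        assert got == brute_force_cuts("CCO")
        assert len(frs) == 2  # C-C and C-O

    def test_methane_no_cuttable_bond(self):
        assert fragment(rec("m", "C")) == []

    def test_toluene_single_cut_excludes_ring_bonds(self):
        frs = fragment(rec("tol", "Cc1ccccc1"))
        assert len(frs) == 1
        assert frs[0].variable_part == "C[*:1]"
        assert frs[0].constant_part == "c1ccc([*:1])cc1"

    @pytest.mark.parametrize("smiles", ["CCO", "CCCC", "CC(C)CO", "c1ccccc1C",
                                        "CC(=O)NC", "C1CC1CC", "OCCN"])
    def test_brute_force_oracle_small_molecules(self, smiles):
        frs = fragment(rec("x", canonicalize(smiles)), min_constant_frac=0.0)
        got = {(f.constant_part, f.variable_part) for f in frs}
        assert got == brute_force_cuts(canonicalize(smiles))

    def test_constant_at_least_as_large(self, small_series):
        from leadtuner.chem import heavy_atom_count as hac

        for r in small_series[:8]:
            for f in fragment(r, min_constant_frac=0.0):
                assert (hac(f.constant_part) >= hac(f.variable_part))

    def test_double_cut_linker(self):
        frs = fragment(rec("x", "c1ccccc1CCNC(C)=O"), max_cuts=2,
                       min_constant_frac=0.0)
        two = [f for f in frs if f.n_cuts == 2]
        assert two, "serial double cuts should yield linker fragmentations"
        for f in two:
            assert "[*:1]" in f.constant_part and "[*:2]" in f.constant_part


class TestBuildPairs:
    def test_toluene_ethylbenzene(self):
        pairs = build_pairs([rec("tol", "Cc1ccccc1"), rec("eb", "CCc1ccccc1")])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.constant_part == "c1ccc([*:1])cc1"
        assert {p.variable_a, p.variable_b} == {"C[*:1]", "CC[*:1]"}

    def test_no_shared_constant(self):
        assert build_pairs([rec("m", "C"), rec("e", "CC")]) == []

    def test_permutation_invariance(self, small_series):
        a = build_pairs(small_series)
        b = build_pairs(list(reversed(small_series)))
        key = lambda p: (p.id_a, p.id_b, p.constant_part, p.variable_a, p.variable_b)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_series_pairs_share_scaffold(self, small_series):
        pairs = build_pairs(small_series)
        assert len(pairs) > 0
        by_id = {r.id: r for r in small_series}
        for p in pairs[:25]:
            const = Chem.MolFromSmiles(p.constant_part.replace("[*:1]", "[H]"))
            for mid in (p.id_a, p.id_b):
                mol = Chem.MolFromSmiles(by_id[mid].smiles_canonical)
                assert mol.HasSubstructMatch(const)


class TestTransformations:
    def test_extract_apply_reproduces_partner(self):
        pairs = build_pairs([rec("tol", "Cc1ccccc1"), rec("eb", "CCc1ccccc1")])
        t = extract_transformation(pairs[0])
        by_id = {"tol": rec("tol", "Cc1ccccc1"), "eb": rec("eb", "CCc1ccccc1")}
        products = apply_transformation(t, by_id[pairs[0].id_a])
        assert by_id[pairs[0].id_b].smiles_canonical in products

    def test_apply_no_match_is_empty(self):
        t = Transformation("C[*:1]", "CC[*:1]")
        assert apply_transformation(t, rec("b", "c1ccccc1")) == []

    def test_symmetric_sites_collapse(self):
        t = Transformation("C[*:1]", "CC[*:1]")
        prods = apply_transformation(t, rec("oxyl", "Cc1ccccc1C"))
        assert prods == [canonicalize("CCc1ccccc1C")]

    def test_para_distinct_sites_two_products(self):
        t = Transformation("C[*:1]", "OC[*:1]")
        prods = apply_transformation(t, rec("x", "Cc1ccc(CC)cc1"))
        # methyl site and the methyl of the ethyl both match
        assert len(prods) == 2

    def test_extraction_idempotent(self):
        pairs = build_pairs([rec("tol", "Cc1ccccc1"), rec("eb", "CCc1ccccc1")])
        assert extract_transformation(pairs[0]) == extract_transformation(pairs[0])

    def test_roundtrip_on_series_sample(self, small_series, records_by_id):
        pairs = build_pairs(small_series)
        rng = random.Random(3)
        for p in rng.sample(pairs, min(30, len(pairs))):
            t = extract_transformation(p)
            assert records_by_id[p.id_b].smiles_canonical in \
                apply_transformation(t, records_by_id[p.id_a])
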