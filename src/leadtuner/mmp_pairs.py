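"""Matched molecular pairs: fragmentation, pairing, transformations.

A matched molecular pair (MMP) is two molecules that differ only by a small
fragment swap at a shared constant substructure.  Molecules are fragmented by
cutting acyclic single bonds; two molecules that produce an identical
constant part form a pair, and the two variable parts define a SMIRKS-like
transformation (lhs ``>>`` rhs) that can be re-applied to other molecules.

Conventions (standard MMP practice):

* single-cut fragmentation by default (``max_cuts=1``); a double cut treats
  the middle piece as the variable linker;
* the constant part is the larger side and must hold at least
  ``min_constant_frac`` (default 2/3) of the parent's heavy atoms, which
  keeps pairs congeneric;
* attachment points carry atom-map label 1 (and 2 for double cuts); canonical
  fragment SMILES are the grouping keys;
* symmetry-equivalent application sites are all enumerated and products
  deduplicated by canonical form.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from rdkit import Chem

from .chem import MoleculeRecord, canonicalize, mol_from_smiles

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragmentation:
    molecule_id: str
    constant_part: str  # canonical SMILES with [*:1] (and [*:2] for 2 cuts)
    variable_part: str
    n_cuts: int = 1


@dataclass(frozen=True)
class MatchedPair:
    id_a: str
    id_b: str
    constant_part: str
    variable_a: str
    variable_b: str


@dataclass(frozen=True)
class Transformation:
    """A variable-fragment swap; ``lhs``/``rhs`` carry the attachment marker."""

    lhs: str
    rhs: str
    provenance: tuple[str, str] = ("", "")

    @property
    def smirks(self) -> str:
        return f"{self.lhs}>>{self.rhs}"


def _canon_fragment(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _cut_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of cuttable bonds: acyclic single bonds between heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() > 1 and b.GetAtomicNum() > 1:
            out.append(bond.GetIdx())
    return out


def _isotopes_to_maps(mol: Chem.Mol) -> Chem.Mol:
    # FragmentOnBonds labels dummies by isotope; molzip joins on atom maps.
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() > 0:
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    return mol


def _single_cut_fragments(mol: Chem.Mol, bond_idx: int) -> tuple[Chem.Mol, Chem.Mol]:
    cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True,
                               dummyLabels=[(1, 1)])
    frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    assert len(frags) == 2
    return _isotopes_to_maps(frags[0]), _isotopes_to_maps(frags[1])


def fragment(record: MoleculeRecord, max_cuts: int = 1,
             min_constant_frac: float = 2.0 / 3.0) -> list[Fragmentation]:
    """Enumerate fragmentations of one molecule.

    One result per acyclic single bond (or bond pair for ``max_cuts=2``)
    whose constant side is at least as large as the variable side and holds
    ``min_constant_frac`` of the heavy atoms.  Molecules with no cuttable
    bond return an empty list.
    """
    if max_cuts not in (1, 2):
        raise ValueError("max_cuts must be 1 or 2")
    mol = mol_from_smiles(record.smiles_canonical)
    n_heavy = mol.GetNumHeavyAtoms()
    out: list[Fragmentation] = []
    bonds = _cut_bonds(mol)
    for bidx in bonds:
        fa, fb = _single_cut_fragments(mol, bidx)
        ha, hb = fa.GetNumHeavyAtoms(), fb.GetNumHeavyAtoms()
        const, var = (fa, fb) if (ha, _canon_fragment(fa)) >= (hb, _canon_fragment(fb)) else (fb, fa)
        if const.GetNumHeavyAtoms() < min_constant_frac * n_heavy:
            continue
        out.append(
            Fragmentation(record.id, _canon_fragment(const), _canon_fragment(var), 1)
        )
    if max_cuts == 2:
        for b1, b2 in itertools.combinations(bonds, 2):
            cut = Chem.FragmentOnBonds(mol, [b1, b2], addDummies=True,
                                       dummyLabels=[(1, 1), (2, 2)])
            frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
            if len(frags) != 3:
                continue
            frags = [_isotopes_to_maps(f) for f in frags]
            def labels(m):
                return sorted(a.GetAtomMapNum() for a in m.GetAtoms()
                              if a.GetAtomicNum() == 0)
            middle = [f for f in frags if labels(f) == [1, 2]]
            ends = [f for f in frags if len(labels(f)) == 1]
            if len(middle) != 1 or len(ends) != 2:
                continue  # cuts not in series
            var = middle[0]
            const_smi = ".".join(sorted(_canon_fragment(f) for f in ends))
            n_const = sum(f.GetNumHeavyAtoms() for f in ends)
            if n_const < var.GetNumHeavyAtoms() or n_const < min_constant_frac * n_heavy:
                continue
            out.append(Fragmentation(record.id, const_smi, _canon_fragment(var), 2))
    return out


def build_pairs(records: list[MoleculeRecord], max_cuts: int = 1,
                min_constant_frac: float = 2.0 / 3.0) -> list[MatchedPair]:
    """All matched pairs among ``records`` sharing an identical constant part.

    Each unordered molecule pair is reported once per shared constant part
    (with distinct variable parts); no self-pairs.  Output order is
    deterministic and invariant (up to ordering) under input permutation.
    """
    by_constant: dict[str, list[tuple[str, str]]] = {}
    for rec in records:
        seen_frag = set()
        for fr in fragment(rec, max_cuts=max_cuts, min_constant_frac=min_constant_frac):
            key = (fr.constant_part, fr.variable_part)
            if key in seen_frag:
                continue
            seen_frag.add(key)
            by_constant.setdefault(fr.constant_part, []).append((rec.id, fr.variable_part))
    pairs: list[MatchedPair] = []
    seen: set[tuple] = set()
    for constant in sorted(by_constant):
        entries = by_constant[constant]
        for (ida, va), (idb, vb) in itertools.combinations(entries, 2):
            if ida == idb or va == vb:
                continue
            if ida > idb:
                ida, idb, va, vb = idb, ida, vb, va
            key = (ida, idb, constant, va, vb)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(MatchedPair(ida, idb, constant, va, vb))
    return pairs


def extract_transformation(pair: MatchedPair) -> Transformation:
    """The variable-fragment swap turning molecule a into molecule b."""
    if pair.variable_a == pair.variable_b:
        raise ValueError("pair has identical variable parts")
    return Transformation(pair.variable_a, pair.variable_b, (pair.id_a, pair.id_b))


def attach(constant: str, variable: str) -> str:
    """Reassemble constant and variable fragments at their attachment points."""
    mol = Chem.molzip(mol_from_smiles(constant), mol_from_smiles(variable))
    return canonicalize(Chem.MolToSmiles(mol))


def apply_transformation(t: Transformation, record: MoleculeRecord,
                         min_constant_frac: float = 0.0) -> list[str]:
    """Products of applying ``t`` at every matching cut site of a molecule.

    The molecule is fragmented at every acyclic single bond; wherever one
    side equals the lhs fragment, the other side is rejoined with the rhs.
    Products are canonical, valid and deduplicated; empty when lhs never
    matches.
    """
    lhs = canonicalize_fragment(t.lhs)
    mol = mol_from_smiles(record.smiles_canonical)
    products: list[str] = []
    seen: set[str] = set()
    for bidx in _cut_bonds(mol):
        fa, fb = _single_cut_fragments(mol, bidx)
        for var, const in ((fa, fb), (fb, fa)):
            if const.GetNumHeavyAtoms() < min_constant_frac * mol.GetNumHeavyAtoms():
                continue
            if _canon_fragment(var) != lhs:
                continue
            prod = attach(_canon_fragment(const), t.rhs)
            if prod not in seen:
                seen.add(prod)
                products.append(prod)
    return products


def canonicalize_fragment(frag_smiles: str) -> str:
    """Canonical form of a fragment SMILES with attachment markers."""
    mol = mol_from_smiles(frag_smiles)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# serialization

PAIR_COLUMNS = ["id_a", "id_b", "constant", "variable_a", "variable_b", "transformation"]


def pairs_to_frame(pairs: list[MatchedPair]):
    import pandas as pd

    return pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "constant": [p.constant_part for p in pairs],
            "variable_a": [p.variable_a for p in pairs],
            "variable_b": [p.variable_b for p in pairs],
            "transformation": [extract_transformation(p).smirks for p in pairs],
        }
    )


def frame_to_pairs(df) -> list[MatchedPair]:
    return [
        MatchedPair(r.id_a, r.id_b, r.constant, r.variable_a, r.variable_b)
        for r in df.itertuples(index=False)
    ]
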