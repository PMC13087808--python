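"""Post-generation triage and one-step transformation reachability.

Generated molecules pass through (1) a PAINS substructure filter — pan-assay
interference motifs that tend to light up biochemical assays artifactually —
and (2) a novelty window: predictions must be similar enough to the lead to
stay in the series but not identical to it or to any training molecule.

The reachability analysis asks whether a prediction could have been produced
by a *single* known matched-pair transformation applied to some training
molecule; predictions more than one step away are evidence the generator
composes or invents transformations rather than replaying the catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import FilterCatalog, rdFingerprintGenerator

from .chem import MoleculeRecord, mol_from_smiles
from .mmp_pairs import Transformation, apply_transformation, attach, fragment

log = logging.getLogger(__name__)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class FilterEntry:
    smiles: str
    pains_flags: list[str] = field(default_factory=list)
    similarity_to_lead: float | None = None
    in_training_set: bool = False
    passed: bool = True


def default_pains_catalog() -> FilterCatalog.FilterCatalog:
    """RDKit's packaged PAINS pattern families A, B and C."""
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog.FilterCatalog(params)


def load_pattern_file(path) -> list[tuple[str, str]]:
    """Read a two-column (name, SMARTS) pattern list; validates each SMARTS
    and raises naming the offending pattern."""
    patterns: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split(None, 1)
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"malformed SMARTS pattern {name!r}: {smarts}")
            patterns.append((name, smarts))
    return patterns


def pains_filter(molecules: Sequence[str],
                 pattern_set: Sequence[tuple[str, str]] | None = None) -> list[FilterEntry]:
    """Flag molecules matching any PAINS pattern.

    ``pattern_set`` is an optional user list of (name, SMARTS) tuples; by
    default the packaged catalog is used.  A molecule fails iff it matches at
    least one pattern; matched pattern names are recorded.
    """
    if pattern_set is None:
        catalog = default_pains_catalog()

        def flags(mol):
            return [m.filterMatch.GetName() for m in catalog.GetFilterMatches(mol)]
    else:
        compiled = []
        for name, smarts in pattern_set:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS pattern {name!r}: {smarts}")
            compiled.append((name, patt))

        def flags(mol):
            return [name for name, patt in compiled if mol.HasSubstructMatch(patt)]

    entries = []
    for smi in molecules:
        mol = mol_from_smiles(smi)
        hit = flags(mol)
        entries.append(FilterEntry(smi, pains_flags=hit, passed=not hit))
    return entries


def novelty_filter(predictions: Sequence[str],
                   training_records: Sequence[MoleculeRecord],
                   lead: MoleculeRecord,
                   sim_window: tuple[float, float] = (0.5, 0.95)) -> list[str]:
    """Keep predictions whose similarity to the lead lies inside the window
    and that are not identical to any training molecule.

    The lower edge discards early-epoch generations that wandered out of the
    series; the upper edge discards trivial copies of the lead.
    """
    low, high = sim_window
    if not 0.0 <= low < high <= 1.0:
        raise ValueError("similarity window must satisfy 0 <= low < high <= 1")
    training = {r.smiles_canonical for r in training_records}
    lead_fp = _MORGAN.GetFingerprint(mol_from_smiles(lead.smiles_canonical))
    kept = []
    for smi in predictions:
        if smi in training:
            continue
        sim = DataStructs.TanimotoSimilarity(
            lead_fp, _MORGAN.GetFingerprint(mol_from_smiles(smi)))
        if low <= sim <= high:
            kept.append(smi)
    return kept


def filter_report(predictions: Sequence[str],
                  training_records: Sequence[MoleculeRecord],
                  lead: MoleculeRecord,
                  sim_window: tuple[float, float] = (0.5, 0.95),
                  pattern_set: Sequence[tuple[str, str]] | None = None) -> list[FilterEntry]:
    """Full triage report: PAINS flags, lead similarity, training membership;
    ``passed`` iff clean of PAINS, inside the novelty window and unseen."""
    entries = pains_filter(predictions, pattern_set)
    low, high = sim_window
    training = {r.smiles_canonical for r in training_records}
    lead_fp = _MORGAN.GetFingerprint(mol_from_smiles(lead.smiles_canonical))
    for e in entries:
        e.in_training_set = e.smiles in training
        e.similarity_to_lead = float(DataStructs.TanimotoSimilarity(
            lead_fp, _MORGAN.GetFingerprint(mol_from_smiles(e.smiles))))
        e.passed = (not e.pains_flags and not e.in_training_set
                    and low <= e.similarity_to_lead <= high)
    return entries


class CutIndex:
    """Precomputed single-cut fragmentations of a molecule set, keyed by the
    variable fragment, so a transformation catalogue can be applied in bulk
    without re-fragmenting for every (molecule, transformation) pair."""

    def __init__(self, records: Sequence[MoleculeRecord]):
        # lhs fragment -> [(molecule id, constant fragment), ...]
        self.by_variable: dict[str, list[tuple[str, str]]] = {}
        for rec in records:
            for fr in fragment(rec, max_cuts=1, min_constant_frac=0.0):
                self.by_variable.setdefault(fr.variable_part, []).append(
                    (rec.id, fr.constant_part))

    def products_of(self, t: Transformation) -> list[tuple[str, str]]:
        """(molecule id, product canonical SMILES) for every application site."""
        out = []
        for mid, const in self.by_variable.get(t.lhs, []):
            out.append((mid, attach(const, t.rhs)))
        return out


def one_step_reachable(prediction: str,
                       training_records: Sequence[MoleculeRecord],
                       transformations: Sequence[Transformation],
                       find_all: bool = False,
                       index: CutIndex | None = None) -> tuple[bool, list[tuple[str, str]]]:
    """Is ``prediction`` one catalogued transformation away from training?

    Returns (reachable, witnesses) where each witness is a (molecule id,
    transformation SMIRKS) pair producing the prediction's canonical form.
    ``find_all=False`` stops at the first witness.  Pass a prebuilt
    ``CutIndex`` when checking many predictions against one molecule set.
    """
    index = index if index is not None else CutIndex(training_records)
    witnesses: list[tuple[str, str]] = []
    for t in transformations:
        for mid, prod in index.products_of(t):
            if prod == prediction:
                witnesses.append((mid, t.smirks))
                if not find_all:
                    return True, witnesses
    return bool(witnesses), witnesses


def enumerate_products(training_records: Sequence[MoleculeRecord],
                       transformations: Sequence[Transformation],
                       cap: int = 100_000) -> set[str]:
    """All canonical products of applying every transformation to every
    training molecule; stops with a warning once ``cap`` distinct products
    are collected."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    index = CutIndex(training_records)
    products: set[str] = set()
    for t in transformations:
        for _, prod in index.products_of(t):
            products.add(prod)
            if len(products) >= cap:
                log.warning("product enumeration stopped at cap %d", cap)
                return products
    return products
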