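"""Canonicalization, randomized SMILES enumeration, and SELFIES bridging.

Every other module goes through this string layer.  Molecules are handled as
canonical, stereochemistry-free SMILES: congeneric series modeling here
deliberately discards stereo information, so two enantiomers collapse to the
same record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

from . import selfies
from .errors import SmilesParseError

RDLogger.DisableLog("rdApp.*")
log = logging.getLogger(__name__)


@dataclass
class MoleculeRecord:
    """One compound: identifier, canonical stereo-free SMILES, measurements.

    ``ic50_molar`` is the half-maximal inhibitory concentration in mol/l
    (lower = more potent); ``t_half_min`` the microsomal half-life in minutes
    (higher = more stable).  ``is_inactive`` marks compounds whose IC50 was
    pinned to the assay-ceiling constant rather than measured.
    """

    id: str
    smiles_canonical: str
    ic50_molar: float | None = None
    t_half_min: float | None = None
    is_inactive: bool = False
    extra: dict = field(default_factory=dict, repr=False, compare=False)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising SmilesParseError with the offending input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical stereo-free SMILES.

    Multi-fragment inputs (salts) keep the largest fragment; the event is
    logged.  Idempotent: the output is its own canonicalization fixed point.
    """
    mol = mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        log.info("kept largest of %d fragments for %r", len(frags), smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def random_smiles(record: "MoleculeRecord | str", k: int, seed: int) -> list[str]:
    """Up to ``k`` distinct randomized SMILES for one molecule.

    Each returned string canonicalizes back to the molecule's canonical form.
    Molecules admitting fewer than ``k`` distinct encodings return all that
    were found and log the shortfall (small or highly symmetric molecules).
    Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    smi = record.smiles_canonical if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smi)
    seed = int(seed) % (2**31 - 1) + 1  # RDKit treats <=0 as "nondeterministic"
    out: list[str] = []
    seen: set[str] = set()
    for attempt_n in (k, 4 * k, 16 * k):
        for s in Chem.MolToRandomSmilesVect(mol, attempt_n, randomSeed=seed):
            if s not in seen:
                seen.add(s)
                out.append(s)
            if len(out) == k:
                return out
    log.warning(
        "molecule %s admits only %d distinct encodings (%d requested)",
        smi, len(out), k,
    )
    return out


def to_selfies(smiles: str) -> str:
    """Encode a SMILES string in the robust token grammar (see ``selfies``)."""
    return selfies.encode(smiles)


def from_selfies(sf: str) -> str | None:
    """Decode a token string to canonical SMILES (None when it derives no atoms)."""
    return selfies.decode(sf)


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()
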