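"""Robust SELFIES-style molecular string encoding.

This module implements a derivation-rule token grammar in the spirit of
SELFIES (self-referencing embedded strings): molecules are written as a
sequence of bracketed tokens such as ``[C]``, ``[=O]``, ``[Branch1]`` or
``[Ring1]``, and the decoder enforces valence caps during derivation so that
*every* token sequence over the alphabet decodes to a chemically valid
molecule (or to nothing, when the sequence contains no atom token).  That
robustness is what makes the representation attractive for generative
models: sampled token streams never have to be discarded as syntax errors.

This is an independent implementation of the idea, not a reimplementation of
the published SELFIES grammar; token strings produced here are not
interchangeable with other SELFIES codecs.  The supported chemistry is the
neutral organic subset (B, C, N, O, P, S, F, Cl, Br, I; no formal charges,
isotopes or radicals), which covers typical congeneric inhibitor series.

Grammar
-------
* Atom tokens ``[X]``, ``[=X]``, ``[#X]`` append atom X bonded to the current
  chain head with the given bond order (capped by remaining valence; a bare
  first atom starts the molecule).
* ``[BranchL]`` (L in 1..3) reads L index tokens giving Q, then derives the
  next Q+1 tokens as a branch rooted at the current atom.
* ``[RingL]`` / ``[=RingL]`` (L in 1..2) reads L index tokens giving Q and
  bonds the current atom to the atom Q+1 positions earlier in derivation
  order.
* Index tokens reuse ordinary tokens as base-16 digits via ``INDEX_ORDER``.

Decoding never fails: oversubscribed valence stops or skips the offending
instruction, out-of-range ring targets are clipped, and unknown tokens are
ignored.
"""

from __future__ import annotations

import re

from rdkit import Chem, RDLogger

from .errors import SmilesParseError, UnsupportedMoleculeError

RDLogger.DisableLog("rdApp.*")

# Maximum total bond order to heavy neighbors per element. Intermediate
# valences (e.g. S with 3 explicit bonds) are completed with implicit H by
# RDKit, so every cap-respecting bond multiset sanitizes.
VALENCE: dict[str, int] = {
    "B": 3,
    "C": 4,
    "N": 3,
    "O": 2,
    "P": 5,
    "S": 6,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}

BRANCH_TOKENS = ("[Branch1]", "[Branch2]", "[Branch3]")
RING_TOKENS = ("[Ring1]", "[Ring2]", "[=Ring1]", "[=Ring2]")

#: Tokens usable as base-16 digits, in digit order 0..15.
INDEX_ORDER = (
    "[C]",
    "[Ring1]",
    "[Ring2]",
    "[Branch1]",
    "[Branch2]",
    "[Branch3]",
    "[=C]",
    "[#C]",
    "[O]",
    "[N]",
    "[=N]",
    "[=O]",
    "[S]",
    "[F]",
    "[Cl]",
    "[Br]",
)
_TOKEN_DIGIT = {t: i for i, t in enumerate(INDEX_ORDER)}

_ATOM_TOKEN_RE = re.compile(r"\[(=|#)?([A-Z][a-z]?)\]")
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


def atom_tokens() -> list[str]:
    """All atom tokens of the alphabet (bond-order prefix within valence cap)."""
    out = []
    for sym, cap in VALENCE.items():
        for order in (1, 2, 3):
            if order <= cap:
                out.append(f"[{_BOND_PREFIX[order]}{sym}]")
    return out


def alphabet() -> list[str]:
    """The full token alphabet (atoms, branches, rings)."""
    return atom_tokens() + list(BRANCH_TOKENS) + list(RING_TOKENS)


def tokenize(selfies: str) -> list[str]:
    """Split a token string into its bracketed tokens.

    Raises ValueError when the string is not a concatenation of tokens.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise ValueError(f"not a valid token string: {selfies!r}")
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


def _parse_atom_token(token: str) -> tuple[int, str] | None:
    m = _ATOM_TOKEN_RE.fullmatch(token)
    if m is None:
        return None
    order = _PREFIX_BOND[m.group(1) or ""]
    sym = m.group(2)
    if sym not in VALENCE or order > VALENCE[sym]:
        return None
    return order, sym


def _digits_for(q: int) -> list[str]:
    digits = []
    while True:
        digits.append(INDEX_ORDER[q % 16])
        q //= 16
        if q == 0:
            break
    return digits[::-1]


def _prepare_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in VALENCE:
            raise UnsupportedMoleculeError(f"element {sym} has no token ({smiles})")
        if atom.GetFormalCharge() != 0:
            raise UnsupportedMoleculeError(f"charged atom {sym} in {smiles}")
        if atom.GetIsotope() != 0:
            raise UnsupportedMoleculeError(f"isotope label in {smiles}")
        if atom.GetNumRadicalElectrons() != 0:
            raise UnsupportedMoleculeError(f"radical atom in {smiles}")
        bond_sum = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if bond_sum > VALENCE[sym]:
            raise UnsupportedMoleculeError(
                f"{sym} exceeds valence cap {VALENCE[sym]} in {smiles}"
            )
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles, "no atoms")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise UnsupportedMoleculeError(
            f"multi-fragment input not encodable: {smiles} (keep largest fragment first)"
        )
    return mol


def encode(smiles: str) -> str:
    """Encode a SMILES string as a robust token string.

    Raises SmilesParseError on unparseable input and UnsupportedMoleculeError
    for chemistry outside the supported subset.
    """
    mol = _prepare_mol(smiles)
    visited: set[int] = set()
    pos: dict[int, int] = {}
    used_bonds: set[int] = set()
    counter = [0]

    def bond_order(a: int, b: int) -> int:
        return int(mol.GetBondBetweenAtoms(a, b).GetBondTypeAsDouble())

    def subtree(u: int, parent: int | None, order_in: int) -> list[str]:
        visited.add(u)
        pos[u] = counter[0]
        counter[0] += 1
        sym = mol.GetAtomWithIdx(u).GetSymbol()
        toks = [f"[{_BOND_PREFIX[order_in]}{sym}]"]
        nbrs = sorted(n.GetIdx() for n in mol.GetAtomWithIdx(u).GetNeighbors())
        # ring closures: this atom is the later endpoint
        for v in nbrs:
            if v == parent or v not in visited:
                continue
            bond = mol.GetBondBetweenAtoms(u, v)
            if bond.GetIdx() in used_bonds:
                continue
            used_bonds.add(bond.GetIdx())
            o = int(bond.GetBondTypeAsDouble())
            if o > 2:
                raise UnsupportedMoleculeError(
                    f"triple-bond ring closure not encodable in {smiles}"
                )
            q = pos[u] - pos[v] - 1
            digits = _digits_for(q)
            if len(digits) > 2:
                raise UnsupportedMoleculeError(f"ring span too large in {smiles}")
            prefix = "=" if o == 2 else ""
            toks.append(f"[{prefix}Ring{len(digits)}]")
            toks.extend(digits)
        child_toks: list[list[str]] = []
        for v in nbrs:
            if v in visited:
                continue
            bond = mol.GetBondBetweenAtoms(u, v)
            used_bonds.add(bond.GetIdx())
            child_toks.append(subtree(v, u, bond_order(u, v)))
        for ct in child_toks[:-1]:
            digits = _digits_for(len(ct) - 1)
            if len(digits) > 3:
                raise UnsupportedMoleculeError(f"branch too long in {smiles}")
            toks.append(f"[Branch{len(digits)}]")
            toks.extend(digits)
            toks.extend(ct)
        if child_toks:
            toks.extend(child_toks[-1])
        return toks

    tokens = subtree(0, None, 1)
    return detokenize(tokens)


class _DecodeState:
    __slots__ = ("rw", "caps", "order")

    def __init__(self) -> None:
        self.rw = Chem.RWMol()
        self.caps: list[int] = []  # remaining valence per atom index
        self.order: dict[int, int] = {}  # atom index -> derivation position

    def add_atom(self, sym: str) -> int:
        idx = self.rw.AddAtom(Chem.Atom(sym))
        self.caps.append(VALENCE[sym])
        self.order[idx] = len(self.order)
        return idx

    def add_bond(self, a: int, b: int, order: int) -> None:
        bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        self.rw.AddBond(a, b, bt[order])
        self.caps[a] -= order
        self.caps[b] -= order


_BRANCH_RE = re.compile(r"\[Branch([123])\]")
_RING_RE = re.compile(r"\[(=)?Ring([12])\]")


def _derive(state: _DecodeState, tokens: list[str], start: int, end: int,
            prev: int | None) -> None:
    """Derive tokens[start:end] with chain head ``prev``; robust to any input."""
    cur = prev
    i = start
    while i < end:
        tok = tokens[i]
        atom = _parse_atom_token(tok)
        if atom is not None:
            order, sym = atom
            if cur is None:
                cur = state.add_atom(sym)
                i += 1
                continue
            if state.caps[cur] <= 0:
                return  # chain head saturated: derivation of this level stops
            o = min(order, state.caps[cur], VALENCE[sym])
            new = state.add_atom(sym)
            state.add_bond(cur, new, o)
            cur = new
            i += 1
            continue
        m = _BRANCH_RE.fullmatch(tok)
        if m is not None:
            L = int(m.group(1))
            if i + L >= end:
                return
            q = 0
            for d in tokens[i + 1 : i + 1 + L]:
                q = q * 16 + _TOKEN_DIGIT.get(d, 0)
            blen = min(q + 1, end - (i + 1 + L))
            body_start = i + 1 + L
            if cur is not None and state.caps[cur] >= 2:
                _derive(state, tokens, body_start, body_start + blen, cur)
            i = body_start + blen
            continue
        m = _RING_RE.fullmatch(tok)
        if m is not None:
            o = 2 if m.group(1) else 1
            L = int(m.group(2))
            if i + L >= end:
                return
            q = 0
            for d in tokens[i + 1 : i + 1 + L]:
                q = q * 16 + _TOKEN_DIGIT.get(d, 0)
            i += 1 + L
            if cur is None:
                continue
            tpos = state.order[cur] - (q + 1)
            if tpos < 0:
                tpos = 0
            target = next(a for a, p in state.order.items() if p == tpos)
            if target == cur or state.rw.GetBondBetweenAtoms(target, cur) is not None:
                continue
            c = min(o, state.caps[cur], state.caps[target])
            if c >= 1:
                state.add_bond(cur, target, c)
            continue
        i += 1  # unknown/special token: ignored


def decode(selfies: str) -> str | None:
    """Decode a token string to canonical SMILES.

    Returns None when the string derives no atoms.  Never raises on token
    strings drawn from the alphabet: valence caps are enforced during
    derivation, so the result always sanitizes.
    """
    tokens = tokenize(selfies) if isinstance(selfies, str) else list(selfies)
    state = _DecodeState()
    _derive(state, tokens, 0, len(tokens), None)
    if state.rw.GetNumAtoms() == 0:
        return None
    mol = state.rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
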