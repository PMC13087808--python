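"""Synthetic congeneric inhibitor series and a desk-scale pretraining corpus.

Real lead-optimization data sets are proprietary, so this module generates
series with the statistical structure the pipeline assumes: one shared
scaffold decorated combinatorially at enumerated attachment points, with
log-scale potency (IC50, molar) and microsomal half-life (minutes) driven by
additive per-substituent contributions plus Gaussian noise.  A stated number
of compounds are "inactive": their IC50 is pinned to an assay-ceiling
constant (default 1 mM) and flagged, mirroring how screening campaigns
report non-binders.  Inactives are chosen as the molecules with the worst
model-implied potency — an SAR cliff, not a random subset — so that
"worst stratum" sampling in the evaluation protocols is meaningful.

The default scaffold is a spiro-bicyclic amide core with two attachment
points, echoing the shape of advanced inhibitor series without reproducing
any real chemotype.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord, canonicalize
from .errors import SeriesExhaustedError

log = logging.getLogger(__name__)

#: Spiro[3.4] azetidine–pyrrolidine benzamide with substituent sites R1
#: (azetidine nitrogen) and R2 (para-aryl position).
DEFAULT_SCAFFOLD = "[*:2]c1ccc(cc1)C(=O)N2CCC3(C2)CN([*:1])C3"

#: Amine-compatible substituents for R1.
POOL_R1 = (
    "*C", "*CC", "*CCC", "*C(C)C", "*CCCC", "*C(C)CC", "*CC(C)C",
    "*C1CC1", "*CC1CC1", "*C1CCC1", "*CC(F)(F)F", "*CCF", "*CCO", "*CCOC",
    "*C(=O)C", "*C(=O)CC", "*C(=O)C(C)C", "*C(=O)C1CC1", "*C(=O)OC",
    "*C(=O)OCC", "*CC#N", "*CCC#N", "*Cc1ccccc1", "*CCc1ccccc1",
    "*Cc1ccncc1", "*C(=O)c1ccccc1", "*CC(=O)N(C)C", "*S(=O)(=O)C",
)

#: Aryl substituents for R2.
POOL_R2 = (
    "*F", "*Cl", "*Br", "*C", "*CC", "*C(C)C", "*OC", "*OCC", "*OC(C)C",
    "*C#N", "*C(F)(F)F", "*OC(F)(F)F", "*N(C)C", "*NC", "*NC(=O)C",
    "*C(=O)N(C)C", "*C(=O)NC", "*S(=O)(=O)N(C)C", "*SC", "*CO", "*CCO",
    "*OCCOC", "*C1CC1", "*c1ccccc1",
)


@dataclass
class PropertyModel:
    """Additive log-scale property model: base + sum of per-substituent
    contributions + Normal(0, noise_sd), all in log10 units."""

    base: float
    noise_sd: float
    #: one contribution array per attachment point, aligned with the pools;
    #: None means "draw deterministically from the series seed".
    contributions: tuple[tuple[float, ...], ...] | None = None
    contrib_sd: float = 0.55


@dataclass
class SeriesSpec:
    """Recipe for one congeneric series."""

    scaffold: str = DEFAULT_SCAFFOLD
    substituent_pools: tuple[tuple[str, ...], ...] = (POOL_R1, POOL_R2)
    n_molecules: int = 160
    n_inactive: int = 0
    potency_model: PropertyModel = field(
        default_factory=lambda: PropertyModel(base=-6.5, noise_sd=0.3, contrib_sd=0.7)
    )
    stability_model: PropertyModel = field(
        default_factory=lambda: PropertyModel(base=1.5, noise_sd=0.15, contrib_sd=0.3)
    )
    inactive_ic50_molar: float = 1e-3
    with_stability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        if not 0 <= self.n_inactive <= self.n_molecules:
            raise ValueError("n_inactive must be in [0, n_molecules]")


def resolve_contributions(spec: SeriesSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-substituent contribution arrays (potency, stability) for a spec.

    Drawn deterministically from the spec seed when not given explicitly, so
    tests can regress generated properties against the true parameters.
    """
    rng = np.random.default_rng(int(spec.seed) + 101)
    out = []
    for model in (spec.potency_model, spec.stability_model):
        if model.contributions is not None:
            out.append([np.asarray(c, dtype=float) for c in model.contributions])
        else:
            out.append(
                [rng.normal(0.0, model.contrib_sd, size=len(pool))
                 for pool in spec.substituent_pools]
            )
    return out[0], out[1]


def assemble(scaffold: str, substituents: tuple[str, ...]) -> str:
    """Attach one substituent per labeled site of the scaffold; canonical SMILES."""
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise ValueError(f"bad scaffold {scaffold!r}")
    for site, sub in enumerate(substituents, start=1):
        frag = Chem.MolFromSmiles(sub.replace("*", f"[*:{site}]", 1))
        if frag is None:
            raise ValueError(f"bad substituent {sub!r}")
        mol = Chem.molzip(mol, frag)
    return canonicalize(Chem.MolToSmiles(mol))


def generate_series(spec: SeriesSpec) -> list[MoleculeRecord]:
    """Generate the series; deterministic for a fixed seed.

    Raises SeriesExhaustedError when the combinatorial pool is smaller than
    ``n_molecules``.
    """
    pool_sizes = [len(p) for p in spec.substituent_pools]
    total = math.prod(pool_sizes)
    if total < spec.n_molecules:
        raise SeriesExhaustedError(spec.n_molecules, total)
    rng = np.random.default_rng(int(spec.seed))
    combo_ids = rng.choice(total, size=spec.n_molecules, replace=False)
    combos = []
    for cid in combo_ids:
        idxs = []
        rest = int(cid)
        for size in reversed(pool_sizes):
            idxs.append(rest % size)
            rest //= size
        combos.append(tuple(reversed(idxs)))

    pot_contribs, stab_contribs = resolve_contributions(spec)
    pot_det = np.array(
        [sum(c[i] for c, i in zip(pot_contribs, combo)) for combo in combos]
    )
    stab_det = np.array(
        [sum(c[i] for c, i in zip(stab_contribs, combo)) for combo in combos]
    )
    log_ic50 = spec.potency_model.base + pot_det + rng.normal(
        0.0, spec.potency_model.noise_sd, size=spec.n_molecules
    )
    log_thalf = spec.stability_model.base + stab_det + rng.normal(
        0.0, spec.stability_model.noise_sd, size=spec.n_molecules
    )
    # actives stay strictly inside (1e-10, inactive ceiling)
    hi = math.log10(spec.inactive_ic50_molar) - 1e-3
    log_ic50 = np.clip(log_ic50, -10.0 + 1e-3, hi)

    # inactives: worst model-implied potency (deterministic part of the model)
    inactive_idx = set(np.argsort(-pot_det, kind="stable")[: spec.n_inactive].tolist())

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    width = max(4, len(str(spec.n_molecules)))
    for i, combo in enumerate(combos):
        smi = assemble(spec.scaffold, tuple(
            spec.substituent_pools[k][j] for k, j in enumerate(combo)
        ))
        if smi in seen:  # distinct combos should give distinct molecules
            raise RuntimeError(f"duplicate molecule from combo {combo}: {smi}")
        seen.add(smi)
        inactive = i in inactive_idx
        records.append(
            MoleculeRecord(
                id=f"M{i:0{width}d}",
                smiles_canonical=smi,
                ic50_molar=spec.inactive_ic50_molar if inactive else float(10.0 ** log_ic50[i]),
                t_half_min=float(10.0 ** log_thalf[i]) if spec.with_stability else None,
                is_inactive=inactive,
                extra={"combo": combo},
            )
        )
    return records


#: Small benzamide-piperazine scaffold for quick directed-learning studies.
DEMO_SCAFFOLD = "[*:1]N1CCN(CC1)C(=O)c1ccc([*:2])cc1"
DEMO_POOL_R1 = ("*C", "*CC", "*CCC", "*C(C)C", "*CCO", "*C(=O)C", "*CC#N", "*C1CC1")
DEMO_POOL_R2 = ("*F", "*Cl", "*C", "*OC")


def directed_demo_spec(seed: int = 0) -> SeriesSpec:
    """A 32-molecule series whose potency strongly rewards one substituent
    (the N-acetyl at R1), so that property-directed training has a clean,
    checkable signal: pairs point toward acetylated analogues and a model
    that has learned the direction generates them preferentially."""
    r1_contrib = (0.8, 0.5, 0.3, 0.4, 0.1, -2.2, 0.6, 0.0)
    r2_contrib = (0.1, -0.1, 0.05, -0.05)
    return SeriesSpec(
        scaffold=DEMO_SCAFFOLD,
        substituent_pools=(DEMO_POOL_R1, DEMO_POOL_R2),
        n_molecules=32,
        n_inactive=0,
        potency_model=PropertyModel(base=-7.0, noise_sd=0.3,
                                    contributions=(r1_contrib, r2_contrib)),
        with_stability=False,
        seed=seed,
    )


def property_oracle(spec: SeriesSpec) -> dict[str, tuple[float, float]]:
    """Expected (ic50_molar, t_half_min) for *every* molecule the spec's
    combinatorial space can produce, keyed by canonical SMILES.

    This is the synthetic stand-in for "synthesize and assay the predicted
    molecule": predictions that fall inside the series chemistry get the
    noiseless model-implied property values.  Molecules outside the space are
    simply absent.
    """
    pot_contribs, stab_contribs = resolve_contributions(spec)
    out: dict[str, tuple[float, float]] = {}
    pools = spec.substituent_pools
    sizes = [len(p) for p in pools]
    total = math.prod(sizes)
    for cid in range(total):
        idxs = []
        rest = cid
        for size in reversed(sizes):
            idxs.append(rest % size)
            rest //= size
        combo = tuple(reversed(idxs))
        smi = assemble(spec.scaffold, tuple(pools[k][j] for k, j in enumerate(combo)))
        log_ic50 = spec.potency_model.base + sum(
            c[i] for c, i in zip(pot_contribs, combo))
        log_th = spec.stability_model.base + sum(
            c[i] for c, i in zip(stab_contribs, combo))
        ic50 = min(10.0 ** log_ic50, spec.inactive_ic50_molar)
        out[smi] = (float(ic50), float(10.0 ** log_th))
    return out


# ---------------------------------------------------------------------------
# pretraining corpus

_CORPUS_CORES = (
    "[*:1]c1ccc([*:2])cc1",
    "[*:1]c1ccc([*:2])cn1",
    "[*:1]c1ncc([*:2])cn1",
    "[*:1]c1ccc([*:2])o1",
    "[*:1]c1ccc([*:2])s1",
    "[*:1]c1cc([*:2])n(C)n1",
    "[*:1]N1CCC([*:2])CC1",
    "[*:1]N1CCN([*:2])CC1",
    "[*:1]C1CCC([*:2])CC1",
    "[*:1]C1CCN([*:2])C1",
    "[*:1]N1CCOC([*:2])C1",
    "[*:1]c1ccc2ccc([*:2])cc2c1",
    "[*:1]c1nc2ccccc2n1[*:2]",
    "[*:1]C1CC1[*:2]",
    "[*:1]CC([*:2])CO",
)

_CORPUS_SUBS = POOL_R1 + POOL_R2


def generate_pretrain_corpus(n: int, seed: int) -> list[str]:
    """``n`` distinct, valid, canonical, stereo-free SMILES over diverse cores.

    A desk-scale stand-in for a large public bioactive-molecule corpus: random
    (core, substituent, substituent) combinations, deduplicated by canonical
    form.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = len(_CORPUS_CORES) * len(_CORPUS_SUBS) ** 2
    if n > total // 2:
        raise ValueError(f"corpus request {n} too large for the fragment grammar")
    rng = np.random.default_rng(int(seed))
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        core = _CORPUS_CORES[rng.integers(len(_CORPUS_CORES))]
        s1 = _CORPUS_SUBS[rng.integers(len(_CORPUS_SUBS))]
        s2 = _CORPUS_SUBS[rng.integers(len(_CORPUS_SUBS))]
        smi = assemble(core, (s1, s2))
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    if len(out) < n:  # pragma: no cover - grammar is large enough in practice
        raise RuntimeError(f"could only generate {len(out)} of {n} corpus molecules")
    return out


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = ["id", "smiles", "ic50_molar", "t_half_min", "is_inactive"]


def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_canonical for r in records],
            "ic50_molar": [r.ic50_molar for r in records],
            "t_half_min": [r.t_half_min for r in records],
            "is_inactive": [r.is_inactive for r in records],
        }
    )


def write_csv(records: list[MoleculeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_csv(path) -> list[MoleculeRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MoleculeRecord(
                id=str(row.id),
                smiles_canonical=canonicalize(row.smiles),
                ic50_molar=None if pd.isna(row.ic50_molar) else float(row.ic50_molar),
                t_half_min=None if pd.isna(row.t_half_min) else float(row.t_half_min),
                is_inactive=bool(row.is_inactive),
            )
        )
    return records


def write_smi(records: list[MoleculeRecord], path) -> None:
    """Two-column SMI format: SMILES<tab>id."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles_canonical}\t{r.id}\n")


def read_smi(path) -> list[MoleculeRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smi = parts[0]
            mid = parts[1] if len(parts) > 1 else f"S{len(records):04d}"
            records.append(MoleculeRecord(id=mid, smiles_canonical=canonicalize(smi)))
    return records
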