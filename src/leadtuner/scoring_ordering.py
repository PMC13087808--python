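"""Property ranking, multiobjective rank-sum scores, and pair orientation.

Molecules are ranked per property (best value gets rank N, worst rank 1;
ties share the minimum rank of their block, "competition" style).  The
multiobjective score is the unweighted sum of the potency and stability
ranks — a parameter-free way to combine objectives.  Matched pairs are
then oriented worse molecule -> better molecule so that a generative model
trained on them only sees property-improving transformations; tied pairs
are emitted in both orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chem import MoleculeRecord
from .mmp_pairs import MatchedPair

Direction = Literal["higher_is_better", "lower_is_better"]


@dataclass(frozen=True)
class DirectedPair:
    """An ordered matched pair: applying the underlying transformation to
    ``source_id`` yields ``target_id``, which scores at least as well."""

    source_id: str
    target_id: str
    score_diff: float
    pair: MatchedPair


def rank_property(values: Sequence[float], direction: Direction,
                  ids: Sequence[str] | None = None) -> np.ndarray:
    """Integer ranks with best = N, worst = 1; ties share the minimum rank.

    Raises ValueError naming the offending id on non-finite values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value to rank")
    bad = ~np.isfinite(arr)
    if bad.any():
        which = [ids[i] if ids is not None else str(i) for i in np.flatnonzero(bad)]
        raise ValueError(f"non-finite property value for: {', '.join(which)}")
    if direction == "higher_is_better":
        oriented = arr
    elif direction == "lower_is_better":
        oriented = -arr
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return rankdata(oriented, method="min").astype(int)


def build_score_table(records: list[MoleculeRecord],
                      multiobjective: bool = False) -> pd.DataFrame:
    """ScoreTable indexed by molecule id.

    Single-objective: score = potency rank.  Multiobjective: score =
    potency rank + stability rank (range [2, 2N]); raises listing ids that
    lack a property.
    """
    ids = [r.id for r in records]
    missing_pot = [r.id for r in records if r.ic50_molar is None]
    if missing_pot:
        raise ValueError(f"records lacking ic50_molar: {', '.join(missing_pot)}")
    pot = rank_property([r.ic50_molar for r in records], "lower_is_better", ids)
    table = pd.DataFrame({"potency_rank": pot}, index=pd.Index(ids, name="id"))
    if multiobjective:
        missing = [r.id for r in records if r.t_half_min is None]
        if missing:
            raise ValueError(f"records lacking t_half_min: {', '.join(missing)}")
        stab = rank_property([r.t_half_min for r in records], "higher_is_better", ids)
        table["stability_rank"] = stab
        table["score"] = table["potency_rank"] + table["stability_rank"]
    else:
        table["stability_rank"] = pd.NA
        table["score"] = table["potency_rank"].astype(float)
    table["score"] = table["score"].astype(float)
    return table


def multiobjective_score(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute score = potency_rank + stability_rank on an existing table."""
    if table["stability_rank"].isna().any():
        missing = table.index[table["stability_rank"].isna()].tolist()
        raise ValueError(f"records lacking stability rank: {', '.join(map(str, missing))}")
    out = table.copy()
    out["score"] = (out["potency_rank"] + out["stability_rank"]).astype(float)
    return out


def orient_pairs(pairs: Sequence[MatchedPair], table: pd.DataFrame) -> list[DirectedPair]:
    """Orient each matched pair worse -> better by score.

    Pairs with unequal scores give one directed pair; exact ties are kept in
    both orders (score_diff 0), mirroring undirected base-model training for
    uninformative pairs.
    """
    scores = table["score"]
    out: list[DirectedPair] = []
    for p in pairs:
        sa, sb = float(scores[p.id_a]), float(scores[p.id_b])
        if sa < sb:
            out.append(DirectedPair(p.id_a, p.id_b, sb - sa, p))
        elif sb < sa:
            out.append(DirectedPair(p.id_b, p.id_a, sa - sb, p))
        else:
            out.append(DirectedPair(p.id_a, p.id_b, 0.0, p))
            out.append(DirectedPair(p.id_b, p.id_a, 0.0, p))
    return out


def score_table_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def score_table_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
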