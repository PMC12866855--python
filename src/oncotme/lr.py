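"""Ligand-receptor interaction scores between cluster pairs.

The score of a (ligand, receptor) pair for an ordered (sender, receiver)
cluster pair in one condition is the product of the ligand's mean CPM in
the sender cluster and the receptor's mean CPM in the receiver cluster.
Both means must exceed the detection threshold (default 0.1 CPM, a dropout
guard) or the score is reported as 0; pairs whose unscaled score exceeds 20
in at least one condition are prioritized; a x10 scaled copy of the score is
carried for visualization only.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import pandas as pd

from .preprocess import ClusterProfile

DETECT_CPM = 0.1
MIN_PRIORITY_SCORE = 20.0
TRIPLE = ["ligand", "receptor", "sender", "receiver"]


class LRPair(NamedTuple):
    ligand: str
    receptor: str

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


#: Small curated mouse ligand-receptor table used when no user table is
#: given.  Covers the IL-15 axis plus common chemokine / cytokine / growth
#: factor interactions.
DEFAULT_PAIRS: list[LRPair] = [
    LRPair("Il15", "Il2rb"),
    LRPair("Il15", "Il15ra"),
    LRPair("Il2", "Il2rb"),
    LRPair("Ccl17", "Ccr4"),
    LRPair("Ccl2", "Ccr2"),
    LRPair("Cxcl12", "Cxcr4"),
    LRPair("Cxcl9", "Cxcr3"),
    LRPair("Tgfb1", "Tgfbr2"),
    LRPair("Tnf", "Tnfrsf1a"),
    LRPair("Ifng", "Ifngr1"),
    LRPair("Il6", "Il6ra"),
    LRPair("Il10", "Il10ra"),
    LRPair("Il18", "Il18r1"),
    LRPair("Csf1", "Csf1r"),
    LRPair("Kitl", "Kit"),
    LRPair("Vegfa", "Flt1"),
    LRPair("Pdgfb", "Pdgfrb"),
    LRPair("Dll4", "Notch1"),
    LRPair("Jag1", "Notch2"),
]


def _as_pairs(pairs) -> list[LRPair]:
    if isinstance(pairs, pd.DataFrame):
        return [LRPair(str(r.ligand), str(r.receptor)) for r in pairs.itertuples()]
    return [p if isinstance(p, LRPair) else LRPair(*p) for p in pairs]


def score_pairs(
    profiles: dict[str, ClusterProfile],
    pairs,
    detect_cpm: float = DETECT_CPM,
) -> pd.DataFrame:
    """Score every pair over all ordered (sender, receiver) cluster pairs.

    ``profiles`` maps condition -> :class:`ClusterProfile` of mean CPM.
    Self-pairs (autocrine, sender == receiver) are included.  A pair with a
    gene missing from the shared universe is skipped with a warning.
    Detection requires mean ligand CPM > ``detect_cpm`` AND mean receptor
    CPM > ``detect_cpm`` (strict); undetected records keep their means but
    report score 0.  Returns a long DataFrame, one row per
    (pair, sender, receiver, condition).
    """
    pair_list = _as_pairs(pairs)
    if not pair_list:
        raise ValueError("empty ligand-receptor pair list")
    if not profiles:
        raise ValueError("no cluster profiles given")
    rows = []
    for condition in profiles:
        prof = profiles[condition]
        genes = set(prof.means.index)
        clusters = prof.clusters
        for pair in pair_list:
            if pair.ligand not in genes or pair.receptor not in genes:
                warnings.warn(
                    f"pair {pair.name}: gene missing from matrix; skipped",
                    stacklevel=2,
                )
                continue
            lig = prof.means.loc[pair.ligand]
            rec = prof.means.loc[pair.receptor]
            for sender in clusters:
                for receiver in clusters:
                    ml, mr = float(lig[sender]), float(rec[receiver])
                    detected = (ml > detect_cpm) and (mr > detect_cpm)
                    score = ml * mr if detected else 0.0
                    rows.append(
                        (
                            pair.name, pair.ligand, pair.receptor,
                            sender, receiver, condition,
                            ml, mr, detected, score, 10.0 * score,
                        )
                    )
    if not rows:
        raise ValueError("no scorable pair: all pair genes missing from matrix")
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "ligand", "receptor", "sender", "receiver", "condition",
            "mean_cpm_ligand", "mean_cpm_receptor", "detected",
            "score", "viz_score",
        ],
    )


def prioritize(records: pd.DataFrame, min_score: float = MIN_PRIORITY_SCORE) -> pd.DataFrame:
    """Keep triples whose unscaled score exceeds ``min_score`` somewhere.

    A (pair, sender, receiver) triple is kept iff its score is strictly
    greater than ``min_score`` in at least one condition (the threshold is
    applied before any visualization scaling); all condition rows of kept
    triples are retained and flagged ``prioritized``.
    """
    if len(records) == 0:
        return records.assign(prioritized=pd.Series(dtype=bool))
    best = records.groupby(TRIPLE, sort=False)["score"].transform("max")
    out = records[best > min_score].copy()
    out["prioritized"] = True
    return out.reset_index(drop=True)


def condition_delta(
    records: pd.DataFrame,
    cond_hi: str = "OFF",
    cond_lo: str = "ON",
    eps: float = 1.0,
) -> pd.DataFrame:
    """Per-triple score difference and pseudocount ratio between conditions.

    delta = score(cond_hi) - score(cond_lo);
    ratio = (score(cond_hi) + eps) / (score(cond_lo) + eps).
    Triples seen in only one condition get missing delta/ratio.
    """
    wide = records.pivot_table(
        index=TRIPLE, columns="condition", values="score", aggfunc="first"
    )
    for c in (cond_hi, cond_lo):
        if c not in wide.columns:
            wide[c] = float("nan")
    out = wide.reset_index()
    out["delta"] = out[cond_hi] - out[cond_lo]
    out["ratio"] = (out[cond_hi] + eps) / (out[cond_lo] + eps)
    out = out.rename(columns={cond_hi: f"score_{cond_hi}", cond_lo: f"score_{cond_lo}"})
    return out.sort_values("delta", ascending=False, kind="stable").reset_index(
        drop=True
    )
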