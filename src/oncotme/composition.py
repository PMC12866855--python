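"""Condition-dependent composition shifts tested with Fisher's exact test.

Cell counts per cell type (or T/NK subpopulation) are cross-tabulated by
condition and each row is tested type-vs-rest x OFF-vs-ON with a two-sided
Fisher exact test (point-probability method), BH-adjusted across rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


def build_composition(
    meta: pd.DataFrame,
    type_key: str = "cell_type",
    condition_key: str = "condition",
    conditions: tuple[str, str] = ("OFF", "ON"),
) -> pd.DataFrame:
    """Exact cross-tabulation of cell types by condition.

    Returns a types x conditions integer DataFrame (columns ordered as
    ``conditions``).  Unknown condition labels are an error.
    """
    if len(meta) == 0:
        return pd.DataFrame(columns=list(conditions), dtype=int)
    unknown = set(meta[condition_key].astype(str).unique()) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    table = pd.crosstab(meta[type_key], meta[condition_key].astype(str))
    for c in conditions:
        if c not in table.columns:
            table[c] = 0
    table = table[list(conditions)].astype(int)
    table.index.name = "cell_type"
    return table


def fet_enrichment(
    table: pd.DataFrame,
    totals: pd.Series | None = None,
    adjust: str | None = "fdr_bh",
) -> pd.DataFrame:
    """Per-row 2x2 Fisher exact tests against the rest of the population.

    For each row the 2x2 table is
    ``[[in-type & cond1, in-type & cond2], [rest & cond1, rest & cond2]]``
    where the rest is ``totals - row`` (``totals`` defaults to the column
    sums; pass parent-population totals when rows overlap, as with
    subpopulations).  p is the two-sided exact p (sum of all fixed-margin
    tables with point probability <= observed); the odds ratio is the
    sample OR with a Haldane-Anscombe 0.5 correction when any cell is zero.
    Zero-margin rows get p = 1 and a missing OR.  q is BH across rows
    (``adjust=None`` disables the correction).
    """
    if table.shape[1] != 2:
        raise ValueError("composition table must have exactly two conditions")
    if totals is None:
        totals = table.sum(axis=0)
    totals = totals[table.columns]
    if (totals <= 0).any():
        raise ValueError("condition totals must be positive")
    rows = []
    for name, row in table.iterrows():
        a, b = int(row.iloc[0]), int(row.iloc[1])
        c, d = int(totals.iloc[0] - a), int(totals.iloc[1] - b)
        if min(c, d) < 0:
            raise ValueError(f"row {name!r} exceeds its condition total")
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            p, oddsr = 1.0, np.nan
        else:
            p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            if min(a, b, c, d) == 0:
                oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                oddsr = (a * d) / (b * c)
        rows.append((name, a, b, c, d, oddsr, p))
    out = pd.DataFrame(
        rows, columns=["cell_type", "a", "b", "c", "d", "odds_ratio", "p_value"]
    )
    if adjust is None:
        out["q_value"] = out["p_value"]
    else:
        out["q_value"] = multipletests(out["p_value"], method=adjust)[1]
    return out


@dataclass
class SubpopDefinition:
    """Marker-positivity subpopulations within a parent population.

    ``predicates`` maps a subpopulation name to a list of (gene, min raw
    count) conjunctions, e.g. CD8+CD69+ double positives require both
    Cd8a >= 1 and Cd69 >= 1.
    """

    parent_key: str                     # obs column holding the parent label
    parent_value: object                # e.g. "T cells" or a cluster id
    predicates: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def t_cell_subpops(
    parent_key: str = "cell_type",
    parent_value: object = "T cells",
    min_count: int = 1,
) -> SubpopDefinition:
    """CD8+, CD69+, CD8+CD69+ and NK (Ncr1+) subsets of the T-cell cluster."""
    return SubpopDefinition(
        parent_key=parent_key,
        parent_value=parent_value,
        predicates={
            "CD8+ T cells": [("Cd8a", min_count)],
            "CD69+ T cells": [("Cd69", min_count)],
            "CD8+CD69+ T cells": [("Cd8a", min_count), ("Cd69", min_count)],
            "NK cells (Ncr1+)": [("Ncr1", min_count)],
        },
    )


def subpop_counts(
    adata: AnnData,
    definition: SubpopDefinition,
    condition_key: str = "condition",
    conditions: tuple[str, str] = ("OFF", "ON"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Count predicate-satisfying cells per condition within the parent.

    Returns the subpopulation x condition count table (rows may overlap)
    and the parent-population totals per condition, which must be passed to
    :func:`fet_enrichment` as ``totals``.
    """
    parent = (adata.obs[definition.parent_key] == definition.parent_value).to_numpy()
    if parent.sum() == 0:
        raise ValueError(
            f"parent population {definition.parent_value!r} is empty"
        )
    cond = adata.obs[condition_key].astype(str).to_numpy()
    X = adata.X
    counts = {}
    for name, preds in definition.predicates.items():
        mask = parent.copy()
        for gene, thr in preds:
            if gene not in adata.var_names:
                raise KeyError(f"predicate gene {gene!r} absent from matrix")
            col = adata[:, gene].X
            vals = np.asarray(col.todense()).ravel() if sp.issparse(col) \
                else np.asarray(col).ravel()
            mask &= vals >= thr
        counts[name] = {c: int((mask & (cond == c)).sum()) for c in conditions}
    table = pd.DataFrame(counts).T[list(conditions)].astype(int)
    table.index.name = "subpopulation"
    totals = pd.Series(
        {c: int((parent & (cond == c)).sum()) for c in conditions}
    )[list(conditions)]
    if (totals == 0).all():
        raise ValueError("parent population empty in every condition")
    return table, totals
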