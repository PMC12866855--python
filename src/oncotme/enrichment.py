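"""Hypergeometric over-representation of cluster markers in gene sets.

For a background universe of N genes, a pathway of K genes, n cluster
marker genes and an overlap of k, the enrichment p-value is the upper tail

    p = P(X >= k) = 1 - sum_{i=0}^{k-1} C(K,i) C(N-K,n-i) / C(N,n),

computed in log-space (scipy's survival function) so that N ~ 20000 is
stable.  Clusters below a size threshold are pooled before testing to
recover statistical power, and p-values are BH-adjusted within each
(pooled) cluster across pathways.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

BACKGROUND_N = 20_000  # ~ protein-coding mouse genes
MIN_CLUSTER_N = 50


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Arguments follow the over-representation convention: ``N`` universe
    size, ``K`` pathway size, ``n`` number of markers, ``k`` overlap.
    ``k = 0`` returns exactly 1 (empty lower sum).
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0 or v != int(v):
            raise ValueError(f"argument {name}={v} must be a non-negative integer")
    if K > N:
        raise ValueError(f"argument K={K} exceeds N={N}")
    if n > N:
        raise ValueError(f"argument n={n} exceeds N={N}")
    if k > min(K, n):
        raise ValueError(f"argument k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def pool_small_clusters(
    marker_sets: dict,
    cluster_sizes: dict,
    min_n: int = MIN_CLUSTER_N,
    pooling: dict | None = None,
) -> tuple[dict, dict, dict]:
    """Merge small clusters' marker sets before enrichment testing.

    Clusters with size strictly below ``min_n`` are merged: by default all
    of them into one group named by joining their ids with '+'; a user
    ``pooling`` map (cluster -> group name) overrides the default and may
    only reference known clusters.  Marker sets are unioned (sorted for
    determinism) and group sizes summed.  Returns
    (pooled marker sets, pooled sizes, cluster -> group mapping).
    """
    unknown = set(marker_sets) - set(cluster_sizes)
    if unknown:
        raise ValueError(f"marker sets for clusters without sizes: {sorted(unknown)}")

    def _key(cl):
        return (0, cl, "") if isinstance(cl, (int, np.integer)) else (1, 0, str(cl))

    small = sorted((cl for cl in marker_sets if cluster_sizes[cl] < min_n), key=_key)
    if pooling is not None:
        bad = set(pooling) - set(marker_sets)
        if bad:
            raise ValueError(f"pooling map references unknown clusters: {sorted(bad)}")
        mapping = {cl: pooling.get(cl, cl) for cl in marker_sets}
    else:
        group_name = "+".join(str(cl) for cl in small)
        mapping = {cl: (group_name if cl in small else cl) for cl in marker_sets}
    pooled_sets: dict = {}
    pooled_sizes: dict = {}
    for cl in sorted(marker_sets, key=_key):
        g = mapping[cl]
        pooled_sets.setdefault(g, set()).update(marker_sets[cl])
        pooled_sizes[g] = pooled_sizes.get(g, 0) + cluster_sizes[cl]
    return (
        {g: sorted(s) for g, s in pooled_sets.items()},
        pooled_sizes,
        mapping,
    )


def enrich(
    marker_sets: dict,
    collection: dict[str, list[str]],
    universe: list[str],
    background: int | str = BACKGROUND_N,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each marker set in each pathway.

    Marker and pathway genes are intersected with the declared ``universe``
    first, so (N, K, n, k) stay self-consistent; markers outside the
    universe are dropped with a warning.  ``background`` is the universe
    size N: the literal "observed" uses len(universe); an integer must be
    >= the observed universe.  Pathways empty after intersection are
    skipped with a warning.  BH adjustment is applied within each group
    across pathways; rows are sorted by q then p.
    """
    uni = set(universe)
    if background == "observed":
        N = len(uni)
    else:
        N = int(background)
        if N < len(uni):
            raise ValueError(
                f"background N={N} smaller than observed universe ({len(uni)})"
            )
    path_sets = {}
    for pw, genes in collection.items():
        inter = set(genes) & uni
        if not inter:
            warnings.warn(f"pathway {pw!r} empty after universe intersection",
                          stacklevel=2)
            continue
        path_sets[pw] = inter
    frames = []
    for group in sorted(marker_sets, key=str):
        markers = set(marker_sets[group])
        dropped = markers - uni
        if dropped:
            warnings.warn(
                f"group {group!r}: {len(dropped)} marker gene(s) outside the "
                "universe dropped",
                stacklevel=2,
            )
        markers &= uni
        n = len(markers)
        rows = []
        for pw in path_sets:
            K = len(path_sets[pw])
            k = len(markers & path_sets[pw])
            p = hypergeom_upper(N, K, n, k)
            rows.append((group, pw, N, K, n, k, p))
        if not rows:
            continue
        df = pd.DataFrame(
            rows, columns=["group", "pathway", "N", "K", "n", "k", "p_value"]
        )
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["group", "pathway", "N", "K", "n", "k", "p_value",
                     "q_value", "significant"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["q_value"] < alpha
    return out.sort_values(
        ["q_value", "p_value", "group", "pathway"], kind="stable"
    ).reset_index(drop=True)


def plot_enrichment_bars(results: pd.DataFrame, path, top: int = 10) -> None:
    """Horizontal-bar summary: bar length = overlap count k, color
    intensity = -log10(p), exact p labeled on each bar, group on the left.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.nsmallest(top, "p_value").iloc[::-1]
    if len(df) == 0:
        return
    neglogp = -np.log10(np.maximum(df["p_value"].to_numpy(), 1e-300))
    colors = plt.cm.Reds(0.25 + 0.75 * neglogp / max(neglogp.max(), 1.0))
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(df) + 1.5))
    labels = [f"{g} | {p}" for g, p in zip(df["group"], df["pathway"])]
    ax.barh(labels, df["k"], color=colors)
    for y, (k, p) in enumerate(zip(df["k"], df["p_value"])):
        ax.text(k, y, f" p={p:.2e}", va="center", fontsize=8)
    ax.set_xlabel("overlapping genes (k)")
    ax.set_title("pathway enrichment (color ~ -log10 p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
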