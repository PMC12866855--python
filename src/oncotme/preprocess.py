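"""Cell-level QC, CPM normalization, cluster profiles, annotation, markers.

Conventions: counts live in an :class:`anndata.AnnData` with cells as rows
(obs) and genes as columns (var), raw integer counts in ``X``.  Per-cell
metadata columns used throughout: ``condition`` (e.g. ON/OFF), ``cluster``
(precomputed cluster labels — clustering itself is out of scope here),
``n_genes_detected`` and ``mito_fraction`` (added by
:func:`add_qc_metrics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

#: Marker panel for cluster annotation: mouse genes characteristic of the
#: major cell types of a Kras-driven liver tumor microenvironment.  rtTA3 is
#: the transactivator transgene carried by the tumor cells.
MARKER_PANEL: dict[str, list[str]] = {
    "immune cells": ["Ptprc"],
    "macrophages": ["Csf1r", "C1qa", "Cd68", "Ccr2"],
    "neutrophils": ["S100a8", "Cxcr2"],
    "T cells": ["Cd3d", "Cd3e"],
    "vascular cells": ["Pecam1", "Flt1"],
    "dendritic cells": ["Xcr1", "Cd209a"],
    "tumor cells": ["Krt8", "Krt18", "rtTA3"],
    "CAFs": ["Dcn", "Col1a1", "Acta2"],
    "B cells": ["Cd79a", "Cd19", "Igkc"],
}

MITO_PREFIX = "mt-"
AMBIGUOUS = "ambiguous"


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


@dataclass
class QcReport:
    """Cells removed by each QC criterion (a cell can trip both)."""

    n_input: int
    n_retained: int
    n_low_genes: int
    n_high_mito: int
    min_genes: int
    max_mito: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input",
                    "n_retained",
                    "removed_low_genes",
                    "removed_high_mito",
                    "min_genes",
                    "max_mito",
                ],
                "value": [
                    self.n_input,
                    self.n_retained,
                    self.n_low_genes,
                    self.n_high_mito,
                    self.min_genes,
                    self.max_mito,
                ],
            }
        )


@dataclass
class ClusterProfile:
    """Per-cluster mean CPM profile with sizes and (optional) cell types.

    ``means`` is a genes x clusters DataFrame of arithmetic mean CPM
    (zeros included); ``n_cells`` counts cells per cluster; ``cell_type``
    holds the annotation result (``None`` before annotation).
    """

    means: pd.DataFrame
    n_cells: pd.Series
    cell_type: pd.Series | None = field(default=None)

    @property
    def clusters(self) -> list:
        return list(self.means.columns)


def add_qc_metrics(adata: AnnData, mito_prefix: str = MITO_PREFIX) -> AnnData:
    """Attach ``n_genes_detected`` and ``mito_fraction`` to ``adata.obs``.

    A gene is detected in a cell if its raw count is > 0.  The mitochondrial
    fraction is the share of a cell's total counts carried by genes whose
    name starts with ``mito_prefix`` (mouse nomenclature ``mt-``).
    """
    X = adata.X
    is_mito = adata.var_names.str.startswith(mito_prefix)
    if sp.issparse(X):
        n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
        total = np.asarray(X.sum(axis=1)).ravel()
        mito = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        n_detected = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
        mito = X[:, is_mito].sum(axis=1)
    adata.obs["n_genes_detected"] = n_detected.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    adata.obs["mito_fraction"] = frac
    adata.var["mt"] = is_mito
    return adata


def qc_filter(
    adata: AnnData, min_genes: int = 200, max_mito: float = 0.10
) -> tuple[AnnData, QcReport]:
    """Remove low-quality cells.

    Cells with fewer than ``min_genes`` detected genes or more than
    ``max_mito`` mitochondrial content are excluded; the boundaries
    (exactly ``min_genes`` genes, exactly ``max_mito`` fraction) are
    retained, reading the exclusion rules literally as strict inequalities.
    The gene axis is unchanged.  Idempotent.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    if not (0.0 <= max_mito <= 1.0):
        raise ValueError("max_mito must be in [0, 1]")
    if "n_genes_detected" not in adata.obs or "mito_fraction" not in adata.obs:
        add_qc_metrics(adata)
    genes_ok = adata.obs["n_genes_detected"].to_numpy() >= min_genes
    mito = adata.obs["mito_fraction"].to_numpy()
    if np.any(mito < 0) or np.any(mito > 1) or np.any(~np.isfinite(mito)):
        raise ValueError("malformed cell metadata: mito_fraction outside [0, 1]")
    mito_ok = mito <= max_mito
    keep = genes_ok & mito_ok
    report = QcReport(
        n_input=adata.n_obs,
        n_retained=int(keep.sum()),
        n_low_genes=int((~genes_ok).sum()),
        n_high_mito=int((~mito_ok).sum()),
        min_genes=min_genes,
        max_mito=max_mito,
    )
    if report.n_retained == 0:
        warnings.warn("QC filter removed every cell", stacklevel=2)
    return adata[keep].copy(), report


def cpm_normalize(adata: AnnData) -> AnnData:
    """Scale each cell to counts-per-million (column sum 1e6).

    value(g, c) = count(g, c) / total(c) * 1e6.  Cells with zero total
    counts are a hard error: run :func:`qc_filter` first.
    """
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total <= 0):
        raise ValueError(
            "cells with zero total counts present; apply qc_filter before "
            "CPM normalization"
        )
    out = adata.copy()
    if sp.issparse(X):
        scale = sp.diags(1e6 / total)
        out.X = (scale @ X.tocsr()).astype(np.float64)
    else:
        out.X = np.asarray(X, dtype=np.float64) * (1e6 / total)[:, None]
    return out


def cluster_means(adata_cpm: AnnData, cluster_key: str = "cluster") -> ClusterProfile:
    """Arithmetic mean CPM per cluster (zeros included) plus cluster sizes.

    Clusters with zero cells (possible with categorical labels) are omitted
    with a warning.
    """
    if cluster_key not in adata_cpm.obs:
        raise KeyError(f"missing cluster label column {cluster_key!r}")
    labels = adata_cpm.obs[cluster_key]
    X = _dense(adata_cpm.X)
    means = {}
    sizes = {}
    for cl in pd.unique(labels):
        mask = (labels == cl).to_numpy()
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"cluster {cl!r} has no cells; omitted", stacklevel=2)
            continue
        means[cl] = X[mask].mean(axis=0)
        sizes[cl] = n
    order = sorted(means, key=lambda c: str(c))
    mean_df = pd.DataFrame(
        {cl: means[cl] for cl in order}, index=adata_cpm.var_names
    )
    return ClusterProfile(means=mean_df, n_cells=pd.Series({c: sizes[c] for c in order}))


def annotate_clusters(
    profile: ClusterProfile,
    panel: dict[str, list[str]] = MARKER_PANEL,
    margin: float = 1.2,
) -> ClusterProfile:
    """Assign a cell type to each cluster from marker-panel expression.

    Per cluster, score(type) = mean over the panel's genes of
    log1p(mean CPM).  The top-scoring type is assigned only when it wins by
    the multiplicative ``margin`` over the runner-up (and is positive);
    otherwise the cluster is labeled ``"ambiguous"`` rather than silently
    guessed.  Panel genes missing from the profile are dropped with a
    warning; a type whose genes are all missing is skipped.
    """
    if not panel:
        raise ValueError("empty marker panel")
    scores = {}
    for cell_type, genes in panel.items():
        if not genes:
            raise ValueError(f"marker panel for {cell_type!r} is empty")
        present = [g for g in genes if g in profile.means.index]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(
                f"panel genes missing from matrix for {cell_type!r}: "
                f"{sorted(missing)}",
                stacklevel=2,
            )
        if not present:
            continue
        scores[cell_type] = np.log1p(profile.means.loc[present]).mean(axis=0)
    if not scores:
        raise ValueError("no panel gene present in the expression matrix")
    score_df = pd.DataFrame(scores)  # clusters x types
    assigned = {}
    for cl, row in score_df.iterrows():
        ranked = row.sort_values(ascending=False)
        top, second = ranked.iloc[0], (ranked.iloc[1] if len(ranked) > 1 else 0.0)
        if top > 0 and top >= margin * second:
            assigned[cl] = ranked.index[0]
        else:
            assigned[cl] = AMBIGUOUS
    cell_type = pd.Series(assigned).loc[profile.means.columns]
    return replace(profile, cell_type=cell_type)


def find_markers(
    adata_cpm: AnnData,
    cluster_key: str = "cluster",
    min_abs_log2fc: float = 0.25,
    alpha: float = 0.05,
) -> dict:
    """One-vs-rest Wilcoxon rank-sum marker genes per cluster.

    For each cluster, every gene is tested cluster-vs-rest with a two-sided
    Wilcoxon rank-sum (Mann-Whitney U, normal approximation with tie
    correction) on CPM values; p-values are BH-adjusted across genes within
    the cluster.  A gene is reported as a marker when q < ``alpha`` and it
    is up-regulated in the cluster with
    log2((mean_in + 1) / (mean_rest + 1)) >= ``min_abs_log2fc``.
    Constant genes get p = 1 and are never selected.  Deterministic.
    """
    labels = adata_cpm.obs[cluster_key]
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("find_markers requires at least 2 clusters")
    counts = labels.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"clusters with fewer than 3 cells: {small}")
    X = _dense(adata_cpm.X)
    results = {}
    for cl in sorted(clusters, key=str):
        mask = (labels == cl).to_numpy()
        x_in, x_out = X[mask], X[~mask]
        constant = np.all(X == X[0], axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = mannwhitneyu(
                x_in, x_out, axis=0, alternative="two-sided", method="asymptotic"
            )
        p = np.where(constant | ~np.isfinite(p), 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        mean_in = x_in.mean(axis=0)
        mean_out = x_out.mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        sel = (q < alpha) & (log2fc >= min_abs_log2fc)
        df = pd.DataFrame(
            {
                "gene": adata_cpm.var_names[sel],
                "log2fc": log2fc[sel],
                "p_value": p[sel],
                "q_value": q[sel],
            }
        ).sort_values(["q_value", "p_value", "gene"], kind="stable")
        results[cl] = df.reset_index(drop=True)
    return results
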