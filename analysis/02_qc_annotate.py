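#!/usr/bin/env python
"""QC-filter the dataset, annotate clusters from marker panels, find markers.

Reads results/data (from 01_simulate.py); writes the QC report, per-cluster
mean-CPM profile, cell-type annotation and one-vs-rest Wilcoxon marker lists
under results/tables/.
"""

from pathlib import Path

import pandas as pd

from oncotme import io as oio
from oncotme import preprocess as pp

DATA = Path("results/data")
TABLES = Path("results/tables")


def main() -> None:
    adata = oio.read_counts(DATA)
    pp.add_qc_metrics(adata)
    filtered, report = pp.qc_filter(adata, min_genes=200, max_mito=0.10)
    oio.write_tsv(report.to_frame(), TABLES / "qc_report.tsv")
    print(f"QC: retained {report.n_retained}/{report.n_input} cells "
          f"({report.n_low_genes} low-gene, {report.n_high_mito} high-mito)")

    cpm = pp.cpm_normalize(filtered)
    profile = pp.annotate_clusters(pp.cluster_means(cpm), pp.MARKER_PANEL)
    ann = pd.DataFrame(
        {"cluster": profile.clusters, "n_cells": profile.n_cells.to_numpy(),
         "cell_type": profile.cell_type.to_numpy()}
    )
    oio.write_tsv(profile.means, TABLES / "cluster_profile.tsv", index=True)
    oio.write_tsv(ann, TABLES / "annotation.tsv")
    print("cluster annotation:")
    print(ann.to_string(index=False))

    markers = pp.find_markers(cpm, min_abs_log2fc=0.25, alpha=0.05)
    long = pd.concat(
        [df.assign(cluster=cl) for cl, df in markers.items()], ignore_index=True
    )[["cluster", "gene", "log2fc", "p_value", "q_value"]]
    oio.write_tsv(long, TABLES / "markers.tsv")
    # QC-retained cells carry their filtered barcodes forward for stage 03
    oio.write_tsv(
        filtered.obs.rename_axis("barcode").reset_index()[
            ["barcode", "condition", "cluster"]
        ],
        TABLES / "cells_retained.tsv",
    )
    per_cluster = long.groupby("cluster").size()
    print(f"markers: {len(long)} genes selected "
          f"(median {per_cluster.median():.0f} per cluster)")


if __name__ == "__main__":
    main()
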