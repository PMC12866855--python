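#!/usr/bin/env python
"""Hypergeometric pathway enrichment of per-cluster marker genes.

Marker sets (from 02) are tested against the GMT collection with the exact
upper-tail hypergeometric test after pooling clusters below 50 cells; BH
adjustment within each (pooled) cluster.  The background universe is the
observed simulated gene universe.  Writes results/tables/enrichment.tsv and
a bar-plot summary under results/figures/.
"""

from pathlib import Path

from oncotme import enrichment as enr
from oncotme import io as oio

DATA = Path("results/data")
TABLES = Path("results/tables")
FIGURES = Path("results/figures")


def main() -> None:
    long = oio.read_tsv(TABLES / "markers.tsv")
    marker_sets = {
        cl: df["gene"].tolist() for cl, df in long.groupby("cluster", sort=True)
    }
    ann = oio.read_tsv(TABLES / "annotation.tsv")
    sizes = dict(zip(ann["cluster"], ann["n_cells"].astype(int)))
    pooled_sets, pooled_sizes, mapping = enr.pool_small_clusters(
        marker_sets, sizes, min_n=50
    )
    pooled = {cl: g for cl, g in mapping.items() if cl != g}
    print(f"pooled small clusters (n < 50): {pooled or 'none'}")

    universe = oio.read_tsv(DATA / "genes.tsv")["gene"].astype(str).tolist()
    collection = oio.read_gmt(DATA / "genesets.gmt")
    res = enr.enrich(pooled_sets, collection, universe, background="observed")
    oio.write_tsv(res, TABLES / "enrichment.tsv")
    FIGURES.mkdir(parents=True, exist_ok=True)
    enr.plot_enrichment_bars(res, FIGURES / "enrichment_bars.png", top=10)

    print(f"\n{len(res)} tests across {len(pooled_sets)} groups; top hits:")
    print(res.head(5).to_string(index=False))
    sig = res[res["significant"]]
    print(f"\nsignificant at q<0.05: {len(sig)} "
          f"({', '.join(sig['pathway'].unique())})")


if __name__ == "__main__":
    main()
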