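#!/usr/bin/env python
"""Fisher-exact composition shifts between conditions.

Cell types (from 02's annotation) and T-cell subpopulations (Cd8a+/Cd69+/
double-positive/Ncr1+) are cross-tabulated ON vs OFF and tested type-vs-rest
with two-sided Fisher exact tests, BH-adjusted.  Writes results/tables/
composition.tsv, fet_celltypes.tsv, subpop_composition.tsv, fet_subpops.tsv.
"""

from pathlib import Path

from oncotme import composition as comp
from oncotme import io as oio
from oncotme import preprocess as pp

DATA = Path("results/data")
TABLES = Path("results/tables")


def main() -> None:
    adata = oio.read_counts(DATA)
    retained = set(oio.read_tsv(TABLES / "cells_retained.tsv")["barcode"])
    adata = adata[[b in retained for b in adata.obs_names]].copy()
    ann = oio.read_tsv(TABLES / "annotation.tsv")
    type_of = dict(zip(ann["cluster"], ann["cell_type"]))
    adata.obs["cell_type"] = adata.obs["cluster"].map(type_of)

    table = comp.build_composition(adata.obs, conditions=("OFF", "ON"))
    fet = comp.fet_enrichment(table)
    oio.write_tsv(table.reset_index(), TABLES / "composition.tsv")
    oio.write_tsv(fet, TABLES / "fet_celltypes.tsv")
    print("cell-type enrichment (OFF vs ON):")
    print(fet.sort_values("q_value").to_string(index=False))
    hits = fet[(fet["q_value"] < 0.05) & (fet["odds_ratio"] > 1)]["cell_type"]
    print(f"\nenriched in OFF at q<0.05: {', '.join(hits)}")

    sub_table, sub_totals = comp.subpop_counts(
        adata, comp.t_cell_subpops(min_count=1), conditions=("OFF", "ON")
    )
    sub_fet = comp.fet_enrichment(sub_table, totals=sub_totals).rename(
        columns={"cell_type": "subpopulation"}
    )
    oio.write_tsv(sub_table.reset_index(), TABLES / "subpop_composition.tsv")
    oio.write_tsv(sub_fet, TABLES / "fet_subpops.tsv")
    print("\nT-cell subpopulations (within annotated T cells):")
    print(sub_fet.to_string(index=False))


if __name__ == "__main__":
    main()
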