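"""End-to-end pipeline: simulate -> QC -> annotate -> composition -> L-R -> enrich.

A single :class:`PipelineConfig` carries every stage threshold (defaults are
the study constants: 200 detected genes, 10% mitochondrial content, 0.1 CPM
detection, score > 20 prioritization, n < 50 pooling, N = 20000 background,
alpha = 0.05) and one seed.  :func:`run_all` executes the stages in order,
writes every intermediate table as TSV plus a run log and a SHA-256
manifest, and is byte-deterministic under (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import composition as comp
from . import enrichment as enr
from . import io as oio
from . import lr as lrmod
from . import preprocess as pp
from . import simulate as sim


@dataclass
class PipelineConfig:
    """All stage thresholds plus the seed; defaults are the study constants."""

    seed: int = 0
    n_cells_per_condition: int = 2000
    conditions: tuple[str, str] = ("ON", "OFF")
    min_genes: int = 200
    max_mito: float = 0.10
    detect_cpm: float = 0.1
    min_score: float = 20.0
    min_n_pool: int = 50
    background: int | str = enr.BACKGROUND_N
    alpha: float = 0.05
    min_log2fc: float = 0.25
    annotate_margin: float = 1.2
    subpop_min_count: int = 1
    n_pathways: int = 60
    pathway_size: int = 50
    overlap_fraction: float = 0.8
    delta_eps: float = 1.0
    dropout_rate: float = 0.1
    extra: dict = field(default_factory=dict)

    @classmethod
    def demo(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """The shipped demo configuration for the synthetic dataset.

        Identical to the defaults except that the enrichment background is
        the observed simulated gene universe, which is the analogue — for a
        2000-gene simulation — of using the ~20000 protein-coding genes as
        background on real data.
        """
        return cls(seed=seed, background="observed", **overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        defaults = cls()
        for k, v in asdict(defaults).items():
            if getattr(cfg, k) != v:
                warnings.warn(f"config override: {k} = {getattr(cfg, k)!r}",
                              stacklevel=2)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    """Wrap stage exceptions with the stage name; partial outputs remain."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_all(config: PipelineConfig, outdir) -> tuple[dict, dict]:
    """Run every stage on a freshly simulated dataset; write all reports.

    Returns ``(results, manifest)``: ``results`` holds the in-memory
    objects of each stage (adata, profiles, score tables, ...), ``manifest``
    maps every written file to its SHA-256.  Two runs with the same config
    produce byte-identical manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"config": config}

    def save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        written.append(oio.write_tsv(df, outdir / name, index=index))

    with _stage("simulate"):
        simcfg = sim.default_config(
            n_cells_per_condition=config.n_cells_per_condition,
            seed=config.seed,
            dropout_rate=config.dropout_rate,
        )
        adata, truth = sim.simulate_counts(simcfg)
        results["adata_raw"], results["truth"] = adata, truth
        counts_dir = outdir / "counts"
        oio.write_counts(adata, counts_dir)
        written += [counts_dir / f for f in
                    (oio.MATRIX_FILE, oio.GENES_FILE, oio.BARCODES_FILE)]
        written.append(
            oio.write_lr_pairs(truth.lr_pairs, outdir / "lr_pairs.tsv")
        )

    with _stage("qc"):
        pp.add_qc_metrics(adata)
        filtered, report = pp.qc_filter(
            adata, min_genes=config.min_genes, max_mito=config.max_mito
        )
        results["adata"], results["qc_report"] = filtered, report
        save(report.to_frame(), "qc_report.tsv")

    with _stage("normalize"):
        cpm = pp.cpm_normalize(filtered)
        results["cpm"] = cpm

    with _stage("annotate"):
        profile = pp.cluster_means(cpm, cluster_key="cluster")
        profile = pp.annotate_clusters(
            profile, pp.MARKER_PANEL, margin=config.annotate_margin
        )
        results["profile"] = profile
        save(profile.means, "cluster_profile.tsv", index=True)
        ann = pd.DataFrame(
            {
                "cluster": profile.clusters,
                "n_cells": profile.n_cells.to_numpy(),
                "cell_type": profile.cell_type.to_numpy(),
            }
        )
        save(ann, "annotation.tsv")
        type_of = dict(zip(ann["cluster"], ann["cell_type"]))
        for a in (filtered, cpm):
            a.obs["cell_type"] = a.obs["cluster"].map(type_of)

    with _stage("markers"):
        markers = pp.find_markers(
            cpm, cluster_key="cluster",
            min_abs_log2fc=config.min_log2fc, alpha=config.alpha,
        )
        results["markers"] = markers
        long = pd.concat(
            [df.assign(cluster=cl) for cl, df in markers.items()],
            ignore_index=True,
        )[["cluster", "gene", "log2fc", "p_value", "q_value"]]
        save(long, "markers.tsv")

    with _stage("composition"):
        cond_order = (config.conditions[1], config.conditions[0])  # OFF first
        table = comp.build_composition(
            filtered.obs, type_key="cell_type", conditions=cond_order
        )
        fet = comp.fet_enrichment(table)
        results["composition"], results["fet_celltypes"] = table, fet
        save(table.reset_index(), "composition.tsv")
        save(fet, "fet_celltypes.tsv")
        subdef = comp.t_cell_subpops(min_count=config.subpop_min_count)
        sub_table, sub_totals = comp.subpop_counts(
            filtered, subdef, conditions=cond_order
        )
        sub_fet = comp.fet_enrichment(sub_table, totals=sub_totals).rename(
            columns={"cell_type": "subpopulation"}
        )
        results["subpop_table"], results["fet_subpops"] = sub_table, sub_fet
        save(sub_table.reset_index(), "subpop_composition.tsv")
        save(sub_fet, "fet_subpops.tsv")

    with _stage("lr_scoring"):
        profiles = {}
        for cond in config.conditions:
            sub = cpm[cpm.obs["condition"] == cond]
            profiles[cond] = pp.cluster_means(sub, cluster_key="cluster")
        scores = lrmod.score_pairs(
            profiles, truth.lr_pairs, detect_cpm=config.detect_cpm
        )
        prioritized = lrmod.prioritize(scores, min_score=config.min_score)
        deltas = lrmod.condition_delta(
            prioritized,
            cond_hi=config.conditions[1], cond_lo=config.conditions[0],
            eps=config.delta_eps,
        )
        all_deltas = lrmod.condition_delta(
            scores,
            cond_hi=config.conditions[1], cond_lo=config.conditions[0],
            eps=config.delta_eps,
        )
        results.update(
            lr_scores=scores, lr_prioritized=prioritized,
            lr_deltas=deltas, lr_deltas_all=all_deltas,
        )
        save(scores, "lr_scores.tsv")
        save(prioritized, "lr_prioritized.tsv")
        save(deltas, "lr_deltas.tsv")

    with _stage("enrichment"):
        universe = list(cpm.var_names)
        genesets = sim.simulate_genesets(
            truth, universe,
            n_pathways=config.n_pathways, sizes=config.pathway_size,
            seed=config.seed + 1, overlap_fraction=config.overlap_fraction,
        )
        written.append(oio.write_gmt(genesets.sets, outdir / "genesets.gmt"))
        marker_sets = {cl: df["gene"].tolist() for cl, df in markers.items()}
        sizes = {cl: int(profile.n_cells[cl]) for cl in profile.clusters}
        pooled_sets, pooled_sizes, mapping = enr.pool_small_clusters(
            marker_sets, sizes, min_n=config.min_n_pool
        )
        enrich_df = enr.enrich(
            pooled_sets, genesets.sets, universe,
            background=config.background, alpha=config.alpha,
        )
        results.update(
            genesets=genesets, enrichment=enrich_df, pooling=mapping,
            pooled_sizes=pooled_sizes,
        )
        save(enrich_df, "enrichment.tsv")

    with _stage("report"):
        log_lines = ["# oncotme run log", "", "## configuration"]
        for k, v in sorted(config.to_dict().items()):
            log_lines.append(f"{k}: {v!r}")
        log_lines += [
            "",
            "## stage summary",
            f"cells simulated: {adata.n_obs}",
            f"cells retained after QC: {filtered.n_obs}",
            f"clusters: {len(profile.clusters)}",
            f"prioritized L-R triples: "
            f"{len(prioritized.drop_duplicates(lrmod.TRIPLE))}",
            f"enrichment tests: {len(enrich_df)}",
        ]
        log_path = outdir / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        written.append(log_path)
        manifest = {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    results["manifest"] = manifest
    return results, manifest
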