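"""Seeded two-condition scRNA-seq simulator with planted ground truth.

Counts are gene-wise negative binomial (mean/dispersion parameterization,
variance = mu + mu^2 * alpha) with cluster/condition fold-changes on top of a
per-gene baseline, followed by independent Bernoulli dropout.  The default
configuration emulates the structure of a conditional-oncogene (ON/OFF)
tumor dataset: 15 clusters covering tumor, immune, vascular and fibroblast
compartments; a T-cell abundance shift between conditions; condition-
dependent Cd8a/Cd69/Ncr1 positivity inside the T-cell cluster; a planted
Il15 (tumor cluster) -> Il2rb (T-cell cluster) ligand-receptor signal among
decoy pairs; mitochondrial-content and library-depth QC structure; and one
gene-set collection with a planted pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .preprocess import MARKER_PANEL, MITO_PREFIX

CONDITIONS = ("ON", "OFF")

#: 13 mouse mitochondrial protein-coding genes (name prefix keys QC).
MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Nd5", "mt-Nd6",
    "mt-Co1", "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Atp8", "mt-Cytb",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""

    def __init__(self, fieldname: str, message: str):
        super().__init__(f"{fieldname}: {message}")
        self.fieldname = fieldname


@dataclass(frozen=True)
class PlantedInteraction:
    """The planted ligand-receptor signal.

    ``ligand_fold``/``receptor_fold`` map condition -> fold-change applied
    to the ligand in the sender cluster / receptor in the receiver cluster.
    """

    ligand: str
    receptor: str
    sender: int
    receiver: int
    ligand_fold: dict[str, float]
    receptor_fold: dict[str, float]


@dataclass(frozen=True)
class PositivityEffect:
    """A per-cell bimodal ('positive fraction') gene inside one cluster.

    Within ``cluster``, a cell is positive with probability
    ``frac[condition]``; positive cells express the gene at NB mean
    ``mean_count`` (otherwise the gene keeps its baseline mean).
    """

    gene: str
    cluster: int
    frac: dict[str, float]
    mean_count: float


@dataclass
class SimulationConfig:
    """Everything :func:`simulate_counts` needs; validated before use."""

    n_cells_per_condition: int
    cluster_proportions: dict[str, np.ndarray]
    gene_names: list[str]
    baseline_mean: np.ndarray
    dispersion: np.ndarray
    marker_effects: dict[tuple[int, str], float]
    cluster_cell_types: dict[int, str]
    lr_effect: PlantedInteraction | None = None
    lr_pairs: pd.DataFrame | None = None
    positivity: list[PositivityEffect] = field(default_factory=list)
    dropout_rate: float = 0.1
    frac_low_depth: float = 0.03
    low_depth_factor: float = 0.08
    frac_high_mito: float = 0.06
    mito_boost: float = 4.0
    planted_markers: dict[int, list[str]] = field(default_factory=dict)
    enriched_types: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def mito_gene_indices(self) -> np.ndarray:
        return np.flatnonzero(
            pd.Index(self.gene_names).str.startswith(MITO_PREFIX)
        )

    @property
    def n_clusters(self) -> int:
        return len(next(iter(self.cluster_proportions.values())))

    def validate(self) -> None:
        if self.n_cells_per_condition <= 0:
            raise ConfigError("n_cells_per_condition", "must be positive")
        if self.n_genes <= 0:
            raise ConfigError("gene_names", "must be non-empty")
        if len(set(self.gene_names)) != self.n_genes:
            raise ConfigError("gene_names", "duplicate gene identifiers")
        for cond, p in self.cluster_proportions.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or not np.isfinite(p).all():
                raise ConfigError(
                    "cluster_proportions", f"negative/non-finite entry ({cond})"
                )
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    "cluster_proportions",
                    f"probabilities for condition {cond!r} sum to {p.sum()!r}, not 1",
                )
        for name, arr in (("baseline_mean", self.baseline_mean),
                          ("dispersion", self.dispersion)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_genes,):
                raise ConfigError(name, "length must equal n_genes")
            if not np.isfinite(arr).all() or np.any(arr < 0):
                raise ConfigError(name, "must be finite and non-negative")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ConfigError("dispersion", "must be strictly positive")
        for (cl, gene), fold in self.marker_effects.items():
            if not (np.isfinite(fold) and fold >= 0):
                raise ConfigError("marker_effects", f"fold for ({cl}, {gene}) invalid")
            if gene not in self.gene_names:
                raise ConfigError("marker_effects", f"unknown gene {gene!r}")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigError("dropout_rate", "must be in [0, 1]")


@dataclass
class GroundTruth:
    """Realized per-cell labels plus every planted effect."""

    cells: pd.DataFrame  # index: barcode; columns: condition, cluster, ...
    cluster_cell_types: dict[int, str]
    enriched_types: dict[str, list[str]]
    lr: PlantedInteraction | None
    lr_pairs: pd.DataFrame | None
    planted_markers: dict[int, list[str]]


@dataclass
class GeneSetCollection:
    """Pathway id -> member genes, with the planted pathway flagged."""

    sets: dict[str, list[str]]
    source: str = "synthetic"
    planted: str | None = None


# --------------------------------------------------------------------------
# default ("shipped") configuration

#: cluster -> cell type for the 15 default clusters.  Cluster 4 is the
#: T-cell cluster and cluster 13 a tumor subclone (the planted L-R sender);
#: cluster 9 is kept below 50 cells to exercise small-cluster pooling.
DEFAULT_CLUSTER_TYPES: dict[int, str] = {
    0: "tumor cells", 1: "tumor cells", 2: "tumor cells",
    3: "macrophages", 4: "T cells", 5: "macrophages",
    6: "neutrophils", 7: "vascular cells", 8: "CAFs",
    9: "B cells", 10: "dendritic cells", 11: "B cells",
    12: "neutrophils", 13: "tumor cells", 14: "vascular cells",
}

#: per-10000 cluster proportions; the T-cell cluster (4) moves 5% -> 20%
#: between conditions, B cells and CAFs also expand after oncogene loss.
DEFAULT_PROPORTIONS = {
    "ON": np.array(
        [1800, 1400, 1100, 1000, 500, 700, 700, 400, 400, 80,
         400, 300, 400, 300, 520], dtype=float) / 1e4,
    "OFF": np.array(
        [1000, 800, 600, 1000, 2000, 700, 500, 600, 700, 120,
         400, 500, 400, 300, 380], dtype=float) / 1e4,
}

_IMMUNE_TYPES = {"macrophages", "neutrophils", "T cells", "dendritic cells",
                 "B cells"}
_TYPE_ABBR = {
    "tumor cells": "Tum", "macrophages": "Mac", "neutrophils": "Neu",
    "T cells": "Tc", "vascular cells": "Vas", "dendritic cells": "Dc",
    "CAFs": "Caf", "B cells": "Bc",
}

_N_DECOY_PAIRS = 60
_N_PROGRAM = 25
_BASELINE_RNG_SEED = 916801  # fixed: the shipped gene universe is a constant


def default_config(
    n_cells_per_condition: int = 2000,
    n_genes: int = 2000,
    seed: int = 0,
    dropout_rate: float = 0.1,
) -> SimulationConfig:
    """The shipped study configuration (see the methods note for rationale)."""
    rng = np.random.default_rng(_BASELINE_RNG_SEED)
    panel_genes = [g for genes in MARKER_PANEL.values() for g in genes]
    subpop_genes = ["Cd8a", "Cd69", "Ncr1"]
    il_genes = ["Il15", "Il2rb", "Il15ra"]
    decoy_lig = [f"LigD{i:02d}" for i in range(1, _N_DECOY_PAIRS + 1)]
    decoy_rec = [f"RecD{i:02d}" for i in range(1, _N_DECOY_PAIRS + 1)]
    program_genes: dict[str, list[str]] = {
        t: [f"{abbr}prog{i:02d}" for i in range(1, _N_PROGRAM + 1)]
        for t, abbr in _TYPE_ABBR.items()
    }
    all_program = [g for genes in program_genes.values() for g in genes]
    named = panel_genes + subpop_genes + il_genes + decoy_lig + decoy_rec \
        + all_program + MITO_GENES
    n_filler = n_genes - len(named)
    if n_filler < 0:
        raise ConfigError("n_genes", f"must be >= {len(named)}")
    filler = [f"Gene{i:04d}" for i in range(1, n_filler + 1)]
    gene_names = named + filler
    gi = {g: i for i, g in enumerate(gene_names)}

    baseline = np.empty(n_genes)
    for g in panel_genes:
        baseline[gi[g]] = 0.02
    for g in subpop_genes:
        baseline[gi[g]] = 0.002
    baseline[gi["Il15"]] = 0.005
    baseline[gi["Il2rb"]] = 0.005
    baseline[gi["Il15ra"]] = 0.003
    for g in decoy_lig + decoy_rec:
        baseline[gi[g]] = rng.lognormal(mean=math.log(0.004), sigma=0.8)
    for g in all_program:
        baseline[gi[g]] = 0.05
    for g in MITO_GENES:
        baseline[gi[g]] = 4.0
    for g in filler:
        baseline[gi[g]] = min(rng.lognormal(mean=math.log(0.3), sigma=1.2), 30.0)
    dispersion = np.full(n_genes, 0.5)

    # fold-changes: strong panel markers in their clusters, moderate
    # cell-type programs, pan-immune Ptprc, constitutive Il2rb on T cells.
    marker_effects: dict[tuple[int, str], float] = {}
    for cl, ctype in DEFAULT_CLUSTER_TYPES.items():
        for g in MARKER_PANEL[ctype]:
            marker_effects[(cl, g)] = 25.0
        for g in program_genes[ctype]:
            marker_effects[(cl, g)] = 6.0
        if ctype in _IMMUNE_TYPES:
            marker_effects[(cl, "Ptprc")] = 4.0

    lr = PlantedInteraction(
        ligand="Il15", receptor="Il2rb", sender=13, receiver=4,
        ligand_fold={"ON": 3.0, "OFF": 40.0},
        receptor_fold={"ON": 30.0, "OFF": 30.0},
    )
    pairs = pd.DataFrame(
        {
            "ligand": ["Il15", "Il15"] + decoy_lig,
            "receptor": ["Il2rb", "Il15ra"] + decoy_rec,
        }
    )
    positivity = [
        PositivityEffect("Cd8a", 4, {"ON": 0.30, "OFF": 0.50}, 2.0),
        PositivityEffect("Cd69", 4, {"ON": 0.15, "OFF": 0.45}, 2.0),
        PositivityEffect("Ncr1", 4, {"ON": 0.05, "OFF": 0.10}, 2.0),
    ]
    planted_markers = {
        cl: list(program_genes[ctype]) + list(MARKER_PANEL[ctype])
        for cl, ctype in DEFAULT_CLUSTER_TYPES.items()
    }
    return SimulationConfig(
        n_cells_per_condition=n_cells_per_condition,
        cluster_proportions={c: DEFAULT_PROPORTIONS[c].copy() for c in CONDITIONS},
        gene_names=gene_names,
        baseline_mean=baseline,
        dispersion=dispersion,
        marker_effects=marker_effects,
        cluster_cell_types=dict(DEFAULT_CLUSTER_TYPES),
        lr_effect=lr,
        lr_pairs=pairs,
        positivity=positivity,
        dropout_rate=dropout_rate,
        planted_markers=planted_markers,
        enriched_types={"OFF": ["T cells", "CAFs", "B cells"]},
        seed=seed,
    )


# --------------------------------------------------------------------------
# simulation

def simulate_counts(config: SimulationConfig) -> tuple[AnnData, GroundTruth]:
    """Draw a two-condition count matrix and its ground truth.

    One RNG stream (``numpy.random.default_rng(config.seed)``) drives the
    whole draw in a fixed order, so identical (config, seed) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conditions = list(config.cluster_proportions)
    n_per = config.n_cells_per_condition
    n_total = n_per * len(conditions)
    G = config.n_genes
    gi = {g: i for i, g in enumerate(config.gene_names)}

    cond_arr = np.repeat(conditions, n_per)
    cluster_arr = np.concatenate(
        [
            rng.choice(config.n_clusters, size=n_per, p=config.cluster_proportions[c])
            for c in conditions
        ]
    )
    low_depth = rng.random(n_total) < config.frac_low_depth
    high_mito = rng.random(n_total) < config.frac_high_mito

    mean = np.tile(np.asarray(config.baseline_mean, dtype=float), (n_total, 1))
    for (cl, gene), fold in sorted(
        config.marker_effects.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        mean[cluster_arr == cl, gi[gene]] *= fold
    if config.lr_effect is not None:
        lr = config.lr_effect
        for cond in conditions:
            in_cond = cond_arr == cond
            mean[in_cond & (cluster_arr == lr.sender), gi[lr.ligand]] *= \
                lr.ligand_fold[cond]
            mean[in_cond & (cluster_arr == lr.receiver), gi[lr.receptor]] *= \
                lr.receptor_fold[cond]

    pos_states: dict[str, np.ndarray] = {}
    for eff in config.positivity:
        frac = np.array([eff.frac[c] for c in cond_arr])
        state = (cluster_arr == eff.cluster) & (rng.random(n_total) < frac)
        mean[state, gi[eff.gene]] = eff.mean_count
        pos_states[f"{eff.gene}_pos"] = state

    mito_idx = config.mito_gene_indices
    if mito_idx.size:
        mean[np.ix_(high_mito, mito_idx)] *= config.mito_boost
    mean[low_depth, :] *= config.low_depth_factor

    alpha = np.asarray(config.dispersion, dtype=float)
    lam = rng.gamma(np.broadcast_to(1.0 / alpha, (n_total, G)), alpha * mean)
    counts = rng.poisson(lam)
    if config.dropout_rate > 0:
        counts *= rng.random((n_total, G)) >= config.dropout_rate

    barcodes = [f"{c}-{i:05d}" for c in conditions for i in range(n_per)]
    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(cond_arr, categories=conditions),
            "cluster": cluster_arr.astype(int),
        },
        index=barcodes,
    )
    var = pd.DataFrame(index=pd.Index(config.gene_names, name="gene"))
    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)), obs=obs, var=var
    )
    truth_cells = obs.copy()
    truth_cells["low_depth"] = low_depth
    truth_cells["high_mito"] = high_mito
    for k, v in pos_states.items():
        truth_cells[k] = v
    truth = GroundTruth(
        cells=truth_cells,
        cluster_cell_types=dict(config.cluster_cell_types),
        enriched_types=dict(config.enriched_types),
        lr=config.lr_effect,
        lr_pairs=None if config.lr_pairs is None else config.lr_pairs.copy(),
        planted_markers={k: list(v) for k, v in config.planted_markers.items()},
    )
    return adata, truth


def simulate_genesets(
    truth: GroundTruth,
    gene_universe: list[str],
    n_pathways: int = 60,
    sizes: int = 50,
    seed: int = 0,
    overlap_fraction: float = 0.8,
    target_cluster: int | None = None,
) -> GeneSetCollection:
    """A GMT-style collection with one pathway planted on a cluster's markers.

    The planted pathway contains ``overlap_fraction`` of the target
    cluster's planted program genes (default target: the T-cell cluster),
    padded with random universe genes to ``sizes``; the remaining
    ``n_pathways - 1`` pathways are uniform random draws.  Deterministic
    under ``seed``.
    """
    if n_pathways == 0:
        return GeneSetCollection(sets={}, planted=None)
    if sizes <= 0:
        raise ValueError("sizes must be positive")
    if sizes > len(gene_universe):
        raise ValueError(
            f"requested pathway size {sizes} exceeds gene universe "
            f"({len(gene_universe)})"
        )
    rng = np.random.default_rng(seed)
    if target_cluster is None:
        target_cluster = next(
            cl for cl, t in sorted(truth.cluster_cell_types.items())
            if t == "T cells"
        )
    markers = [g for g in truth.planted_markers[target_cluster]
               if g in set(gene_universe)]
    n_overlap = min(math.ceil(overlap_fraction * len(markers)), sizes)
    chosen = list(rng.choice(markers, size=n_overlap, replace=False)) \
        if overlap_fraction < 1.0 else list(markers[:min(len(markers), sizes)])
    rest_pool = [g for g in gene_universe if g not in set(chosen)]
    filler = rng.choice(rest_pool, size=sizes - len(chosen), replace=False)
    sets = {"PLANTED_TCELL_PROGRAM": sorted(chosen) + sorted(filler.tolist())}
    for i in range(1, n_pathways):
        draw = rng.choice(gene_universe, size=sizes, replace=False)
        sets[f"DECOY_PW_{i:03d}"] = sorted(draw.tolist())
    return GeneSetCollection(sets=sets, planted="PLANTED_TCELL_PROGRAM")


@dataclass(frozen=True)
class TumorGrowthModel:
    """Piecewise log-linear burden: growth to ``switch_day``, then decay."""

    growth_rate: float = 0.35      # per day, log scale
    regression_rate: float = math.log(100.0) / 7.0  # 99% drop in 7 days
    switch_day: float = 0.0
    noise_sd: float = 0.0          # sd of multiplicative log-normal noise
    baseline: float = 1.0e5        # burden units at day 0
    seed: int = 0


def simulate_tumor_series(
    model: TumorGrowthModel,
    days,
    n_subjects: int = 3,
    group: str = "KrasOFF",
    mode: str = "radiance",
    aspect: float = 1.3,
) -> pd.DataFrame:
    """Per-subject tumor burden series (radiance or caliper length/width).

    log burden(t) = log baseline + growth*min(t, switch)
                    - regression*max(0, t - switch) + noise.
    In caliper mode the burden is treated as an ellipsoid volume
    V = pi*L*W^2/6 with fixed aspect ratio L/W; L and W are reported in mm.
    """
    days = np.asarray(days, dtype=float)
    if days.ndim != 1 or len(days) == 0 or np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    rng = np.random.default_rng(model.seed)
    records = []
    for s in range(n_subjects):
        log_b = (
            math.log(model.baseline)
            + model.growth_rate * np.minimum(days, model.switch_day)
            - model.regression_rate * np.maximum(0.0, days - model.switch_day)
        )
        if model.noise_sd > 0:
            log_b = log_b + rng.normal(0.0, model.noise_sd, size=len(days))
        burden = np.exp(log_b)
        for d, b in zip(days, burden):
            rec = {"subject": f"{group}-{s + 1}", "group": group, "day": d}
            if mode == "radiance":
                rec["radiance"] = b
            elif mode == "caliper":
                width = (6.0 * b / (aspect * math.pi)) ** (1.0 / 3.0)
                rec["length_mm"] = aspect * width
                rec["width_mm"] = width
            else:
                raise ValueError(f"unknown mode {mode!r}")
            records.append(rec)
    return pd.DataFrame.from_records(records)
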