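import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, nbinom

from oncotme import simulate as sim


def tiny_config(**overrides):
    """3 equal clusters, flat baseline, no planted effects."""
    n_genes = 30
    cfg = sim.SimulationConfig(
        n_cells_per_condition=overrides.pop("n_cells_per_condition", 200),
        cluster_proportions={
            "ON": np.full(3, 1 / 3),
            "OFF": np.full(3, 1 / 3),
        },
        gene_names=[f"g{i}" for i in range(n_genes)],
        baseline_mean=np.full(n_genes, 1.0),
        dispersion=np.full(n_genes, 0.5),
        marker_effects={},
        cluster_cell_types={0: "T cells", 1: "tumor cells", 2: "B cells"},
        dropout_rate=0.0,
        frac_low_depth=0.0,
        frac_high_mito=0.0,
        planted_markers={0: ["g0", "g1", "g2", "g3"]},
        seed=11,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def test_identical_seed_and_config_give_bit_identical_output():
    cfg = sim.default_config(n_cells_per_condition=150, seed=7)
    a1, t1 = sim.simulate_counts(cfg)
    a2, t2 = sim.simulate_counts(sim.default_config(n_cells_per_condition=150, seed=7))
    assert (a1.X != a2.X).nnz == 0
    pd.testing.assert_frame_equal(t1.cells, t2.cells)
    a3, _ = sim.simulate_counts(sim.default_config(n_cells_per_condition=150, seed=8))
    assert (a1.X != a3.X).nnz > 0


def test_dropout_one_zeroes_everything():
    adata, _ = sim.simulate_counts(tiny_config(dropout_rate=1.0))
    assert adata.X.nnz == 0


def test_labels_cover_every_cell_exactly_once():
    adata, truth = sim.simulate_counts(tiny_config())
    assert adata.n_obs == len(truth.cells)
    assert list(adata.obs_names) == list(truth.cells.index)


def test_equal_effects_give_equal_cluster_means():
    # no fold-changes, equal proportions: per-gene means agree across
    # clusters within sampling error (~5000 cells total)
    cfg = tiny_config(n_cells_per_condition=2500)
    adata, _ = sim.simulate_counts(cfg)
    X = adata.X.toarray()
    mu, alpha = 1.0, 0.5
    for cl in (0, 1, 2):
        mask = (adata.obs["cluster"] == cl).to_numpy()
        se = math.sqrt((mu + alpha * mu**2) / mask.sum())
        assert np.all(np.abs(X[mask].mean(axis=0) - mu) < 5 * se)


def test_planted_t_cell_shift_within_binomial_envelope():
    cfg = sim.default_config(n_cells_per_condition=2000, seed=5)
    adata, truth = sim.simulate_counts(cfg)
    t_cluster = 4
    for cond, p in (("ON", 0.05), ("OFF", 0.20)):
        obs = truth.cells.query("condition == @cond")
        k = int((obs["cluster"] == t_cluster).sum())
        lo, hi = binom.ppf([0.005, 0.995], 2000, p)
        assert lo <= k <= hi, (cond, k, lo, hi)


def test_negative_binomial_moments_match_parameterization():
    # dropout 0: sample mean/variance per gene track mu and mu + mu^2*alpha
    n = 3000
    means = np.array([0.5, 2.0, 5.0])
    cfg = tiny_config(n_cells_per_condition=n)
    cfg.gene_names = ["a", "b", "c"]
    cfg.baseline_mean = means
    cfg.dispersion = np.full(3, 0.5)
    cfg.cluster_proportions = {"ON": np.array([1.0]), "OFF": np.array([1.0])}
    cfg.cluster_cell_types = {0: "T cells"}
    cfg.planted_markers = {0: ["a"]}
    adata, _ = sim.simulate_counts(cfg)
    X = adata.X.toarray().astype(float)
    ntot = X.shape[0]
    for j, mu in enumerate(means):
        alpha = 0.5
        var = mu + alpha * mu**2
        se_mean = math.sqrt(var / ntot)
        assert abs(X[:, j].mean() - mu) < 3 * se_mean
        r, p = 1 / alpha, 1 / (1 + alpha * mu)
        kurt = nbinom.stats(r, p, moments="k")  # excess kurtosis
        se_var = var * math.sqrt(2 / (ntot - 1) + kurt / ntot)
        assert abs(X[:, j].var(ddof=1) - var) < 3 * se_var


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("n_cells_per_condition", 0, "n_cells_per_condition"),
        ("dropout_rate", 1.5, "dropout_rate"),
        ("dispersion", np.zeros(30), "dispersion"),
        ("baseline_mean", np.full(30, -1.0), "baseline_mean"),
        (
            "cluster_proportions",
            {"ON": np.array([0.5, 0.4, 0.2]), "OFF": np.full(3, 1 / 3)},
            "cluster_proportions",
        ),
    ],
)
def test_invalid_config_names_the_offending_field(field, value, match):
    cfg = tiny_config()
    setattr(cfg, field, value)
    with pytest.raises(sim.ConfigError, match=match):
        sim.simulate_counts(cfg)


def test_geneset_overlap_one_contains_all_markers():
    _, truth = sim.simulate_counts(tiny_config())
    universe = [f"g{i}" for i in range(30)]
    coll = sim.simulate_genesets(
        truth, universe, n_pathways=5, sizes=10, seed=3,
        overlap_fraction=1.0, target_cluster=0,
    )
    planted = set(coll.sets[coll.planted])
    assert planted >= set(truth.planted_markers[0])
    assert len(coll.sets) == 5


def test_geneset_edge_cases_and_determinism():
    _, truth = sim.simulate_counts(tiny_config())
    universe = [f"g{i}" for i in range(30)]
    assert sim.simulate_genesets(truth, universe, n_pathways=0).sets == {}
    with pytest.raises(ValueError, match="exceeds gene universe"):
        sim.simulate_genesets(truth, universe, n_pathways=2, sizes=31,
                              target_cluster=0)
    c1 = sim.simulate_genesets(truth, universe, n_pathways=4, sizes=8, seed=9,
                               target_cluster=0)
    c2 = sim.simulate_genesets(truth, universe, n_pathways=4, sizes=8, seed=9,
                               target_cluster=0)
    assert c1.sets == c2.sets


def test_tumor_series_noise_free_is_exact_exponential():
    days = np.arange(8)
    m = sim.TumorGrowthModel(growth_rate=0.3, regression_rate=0.0,
                             switch_day=100, noise_sd=0.0, baseline=10.0)
    df = sim.simulate_tumor_series(m, days, n_subjects=1)
    np.testing.assert_allclose(df["radiance"], 10.0 * np.exp(0.3 * days))


def test_tumor_series_regression_to_one_percent_by_day_seven():
    # rate chosen by inverting the model: exp(-r*7) = 0.01
    m = sim.TumorGrowthModel(growth_rate=0.0, switch_day=0.0, noise_sd=0.0,
                             regression_rate=math.log(100) / 7, baseline=100.0)
    df = sim.simulate_tumor_series(m, [0, 7], n_subjects=1)
    rel = df["radiance"].iloc[1] / df["radiance"].iloc[0]
    assert rel == pytest.approx(0.01)


def test_tumor_series_reproducible_and_validates_days():
    m = sim.TumorGrowthModel(noise_sd=0.2, seed=4)
    d1 = sim.simulate_tumor_series(m, [0, 1, 2])
    d2 = sim.simulate_tumor_series(m, [0, 1, 2])
    pd.testing.assert_frame_equal(d1, d2)
    with pytest.raises(ValueError, match="strictly increasing"):
        sim.simulate_tumor_series(m, [0, 2, 2])
    caliper = sim.simulate_tumor_series(m, [0, 1], mode="caliper")
    assert (caliper["length_mm"] > caliper["width_mm"]).all()
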