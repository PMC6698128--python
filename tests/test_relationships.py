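import numpy as np
import pytest

from standlab.relationships import (
    classify_diversity_productivity, run_regression_grid, treatment_summary,
)
from standlab.treedata import InventorySeries, PlotInventory, TreeRecord


def test_hump_recovery_with_vertex_location(rng):
    p = rng.uniform(0, 4, 36)
    s = 10 + 4 * p - p**2 + rng.normal(0, 0.05, 36)
    cls = classify_diversity_productivity(p, s)
    assert cls.verdict == "hump"
    assert cls.quadratic.vertex == pytest.approx(2.0, abs=0.05)


def test_u_shape_requires_negative_linear_term(rng):
    p = rng.uniform(0, 4, 36)
    s = 10 - 4 * p + p**2 + rng.normal(0, 0.05, 36)
    assert classify_diversity_productivity(p, s).verdict == "U"


def test_pure_line_classified_linear(rng):
    p = rng.uniform(0, 4, 36)
    s = 8 + 1.5 * p + rng.normal(0, 0.5, 36)
    cls = classify_diversity_productivity(p, s)
    assert cls.verdict == "linear_increasing"
    s2 = 8 - 1.5 * p + rng.normal(0, 0.5, 36)
    assert classify_diversity_productivity(p, s2).verdict == "linear_decreasing"


def test_flat_noise_is_none(rng):
    p = rng.uniform(0, 4, 36)
    s = 10 + rng.normal(0, 1.0, 36)
    assert classify_diversity_productivity(p, s).verdict == "none"


def test_constant_productivity_errors():
    with pytest.raises(ValueError):
        classify_diversity_productivity([1.0] * 10, np.arange(10))
    with pytest.raises(ValueError):
        classify_diversity_productivity([1, 2, 3], [1, 2, 3])  # too few


def test_grid_has_54_rows(default_experiment):
    grid = run_regression_grid(default_experiment)
    assert len(grid) == 54
    assert set(grid["component"]) == {"AGB", "BGB"}
    assert grid["index"].nunique() == 9
    assert grid["period"].nunique() == 3


def test_grid_single_period_has_18_rows(default_experiment):
    grid = run_regression_grid(default_experiment, periods=[(1982, 1993)])
    assert len(grid) == 18


def test_grid_deterministic_and_duplicate_index_rows_identical(default_experiment):
    g1 = run_regression_grid(default_experiment, periods=[(1982, 1993)],
                             indices=("SW", "SW"))
    a = g1.iloc[0].drop("index")
    b = g1.iloc[1].drop("index")
    assert a.equals(b)


def test_bgb_rows_match_agb_when_biomasses_proportional():
    """All trees share one diameter and one biomass equation, so plot BGB is
    exactly proportional to plot AGB and the two components must classify
    identically."""
    rng = np.random.default_rng(4)
    series = []
    species = [f"SP{i}" for i in range(6)]
    groups = dict(zip(species, ["pine", "other_conifer", "pine", "pine",
                                "other_conifer", "pine"]))
    for i in range(12):
        invs = []
        for year, n in [(1982, 20 + i), (1993, 30 + 3 * i)]:
            trees = []
            for j in range(n):
                sp = species[int(rng.integers(0, 3 + i % 4))]
                trees.append(TreeRecord(f"P{i}", year, sp, groups[sp], 20.0, 12.0))
            invs.append(PlotInventory(f"P{i}", year, 0.0, trees))
        series.append(InventorySeries(f"P{i}", 0.0, invs))
    grid = run_regression_grid(series, periods=[(1982, 1993)])
    agb = grid[grid["component"] == "AGB"].set_index("index")
    bgb = grid[grid["component"] == "BGB"].set_index("index")
    for idx in agb.index:
        assert agb.loc[idx, "verdict"] == bgb.loc[idx, "verdict"]
        if np.isfinite(agb.loc[idx, "quad_r2"]):
            assert agb.loc[idx, "quad_r2"] == pytest.approx(bgb.loc[idx, "quad_r2"], rel=1e-9)


def test_holm_option_only_demotes(default_experiment):
    plain = run_regression_grid(default_experiment)
    holm = run_regression_grid(default_experiment, holm=True)
    curved = plain["verdict"].isin(["hump", "U"]).sum()
    curved_holm = holm["verdict"].isin(["hump", "U"]).sum()
    assert curved_holm <= curved


def test_treatment_summary_structure(default_experiment):
    summ = treatment_summary(default_experiment)
    groups, regs = summ["groups"], summ["regressions"]
    # 3 periods x 2 components x 6 removal levels
    assert len(groups) == 36
    assert len(regs) == 6
    assert (groups["n"] == 6).all()
    assert groups["ci95_half"].notna().all()
    assert ((regs["r2"] >= 0) & (regs["r2"] <= 1)).all()


def test_treatment_summary_flat_world_zero_slope():
    # identical plots -> zero slope, r2 ~ 0
    series = []
    for i, removal in enumerate([0.0, 0.2, 0.4, 0.6]):
        invs = []
        for year, d in [(1982, 20.0), (1993, 25.0)]:
            trees = [TreeRecord(f"P{i}", year, "PICO", "pine", d, 12.0)] * 10
            invs.append(PlotInventory(f"P{i}", year, removal, trees))
        series.append(InventorySeries(f"P{i}", removal, invs))
    summ = treatment_summary(series, periods=[(1982, 1993)])
    regs = summ["regressions"]
    assert regs["slope"].abs().max() == pytest.approx(0.0, abs=1e-12)
    # singleton groups are flagged
    assert (summ["groups"]["note"] != "").all()


def test_ci_width_shrinks_with_replication(rng):
    """t-based CI half-width scales roughly as 1/sqrt(n) over replicated
    synthetic groups."""
    def half_width(n):
        series = []
        for i in range(n):
            invs = []
            for year, d in [(1982, 20.0), (1993, 25.0 + float(rng.normal(0, 0.5)))]:
                trees = [TreeRecord(f"P{i}", year, "PICO", "pine", d, 12.0)] * 10
                invs.append(PlotInventory(f"P{i}", year, 0.0, trees))
            series.append(InventorySeries(f"P{i}", 0.0, invs))
        summ = treatment_summary(series, periods=[(1982, 1993)])
        g = summ["groups"]
        return float(g[g["component"] == "AGB"]["ci95_half"].iloc[0])

    w8, w128 = half_width(8), half_width(128)
    ratio = w8 / w128
    assert 2.0 < ratio < 8.0  # ~ sqrt(16) = 4 up to sampling noise
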