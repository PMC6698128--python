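import numpy as np
import pytest

from standlab.allometry import (
    load_equations,
    DEFAULT_VOLUME_EQUATION, VolumeEquation, agb_tree, bgb_tree,
    crosscheck_physical, productivity, stand_biomass,
)
from standlab.treedata import InventorySeries, PlotInventory, TreeRecord


def _inv(dbhs, year=1982, groups=None, area=0.25, heights=None):
    groups = groups or ["pine"] * len(dbhs)
    heights = heights or [10.0] * len(dbhs)
    trees = [TreeRecord("P01", year, "PICO" if g == "pine" else "QUSI", g, d, h)
             for d, g, h in zip(dbhs, groups, heights)]
    return PlotInventory("P01", year, 0.0, trees, area)


def test_agb_power_law_values():
    assert agb_tree(20.0, "pine") == pytest.approx(0.0726 * 20**2.4459)
    assert agb_tree(20.0, "pine") == pytest.approx(110.4, abs=0.2)
    assert agb_tree(20.0, "oak") == pytest.approx(0.0768 * 20**2.4416)
    # conifers use the pine equation, broadleaves the oak equation
    assert agb_tree(20.0, "other_conifer") == agb_tree(20.0, "pine")
    assert agb_tree(20.0, "other_broadleaf") == agb_tree(20.0, "oak")
    with pytest.raises(ValueError):
        agb_tree(20.0, "shrub")
    with pytest.raises(ValueError):
        agb_tree(-1.0, "pine")


def test_agb_monotone_and_vanishing_at_zero():
    d = np.linspace(0.01, 100, 500)
    vals = [agb_tree(x, "pine") for x in d]
    assert np.all(np.diff(vals) > 0)
    assert agb_tree(1e-9, "pine") < 1e-12


def test_bgb_below_agb_over_size_range():
    assert bgb_tree(20.0) == pytest.approx(0.016 * 20**2.668)
    for d in np.linspace(5, 100, 200):
        assert bgb_tree(d) < agb_tree(d, "pine")
        assert bgb_tree(d) < agb_tree(d, "oak")


def test_stand_biomass_additivity_and_expansion():
    assert stand_biomass(_inv([]), "agb") == 0.0
    one = stand_biomass(_inv([20.0]), "agb")
    two = stand_biomass(_inv([20.0, 20.0]), "agb")
    assert two == pytest.approx(2 * one)
    assert one == pytest.approx(agb_tree(20.0, "pine") * 4 / 1000)
    # homogeneous degree 1 in the expansion factor
    half_area = stand_biomass(_inv([20.0], area=0.125), "agb")
    assert half_area == pytest.approx(2 * one)


def test_crosscheck_contrived_identity():
    # choose wsg so that V * wsg equals the allometric AGB exactly for one tree
    d, h = 20.0, 12.0
    v = DEFAULT_VOLUME_EQUATION(d, h)
    wsg = agb_tree(d, "pine") / 1000.0 / v
    eq = VolumeEquation(DEFAULT_VOLUME_EQUATION.a, DEFAULT_VOLUME_EQUATION.b,
                        DEFAULT_VOLUME_EQUATION.c, wsg={"pine": wsg, "oak": 0.6})
    res = crosscheck_physical(_inv([d], heights=[h]), eq)
    assert res["rel_difference"] == pytest.approx(0.0, abs=1e-12)


def test_crosscheck_invariant_to_subplot_area():
    a = crosscheck_physical(_inv([15, 22, 30], area=0.25))
    b = crosscheck_physical(_inv([15, 22, 30], area=1.0))
    assert a["rel_difference"] == pytest.approx(b["rel_difference"], rel=1e-12)
    assert np.isfinite(a["rel_difference"])
    assert a["plot_id"] == "P01"


def _series(dbhs_by_year):
    invs = [_inv(d, year=y) for y, d in sorted(dbhs_by_year.items())]
    return InventorySeries("P01", 0.0, invs)


def test_productivity_identical_censuses_is_zero():
    s = _series({1982: [20.0, 15.0], 1993: [20.0, 15.0]})
    rec = productivity(s, (1982, 1993))
    assert rec.agb == 0.0 and rec.bgb == 0.0


def test_productivity_single_growing_pine_hand_value():
    s = _series({1982: [20.0], 1993: [25.0]})
    rec = productivity(s, (1982, 1993))
    expect = (agb_tree(25.0, "pine") - agb_tree(20.0, "pine")) * 4 / 1000 / 11
    assert rec.agb == pytest.approx(expect, rel=1e-12)
    assert rec.interval == 11


def test_productivity_can_be_negative_and_missing_census_errors():
    s = _series({1982: [20.0, 30.0], 1993: [20.0]})
    assert productivity(s, (1982, 1993)).agb < 0
    with pytest.raises(Exception, match="2004"):
        productivity(s, (1982, 2004))


def test_full_period_is_interval_weighted_mean(default_experiment):
    """P(82-04) == (11 P(82-93) + 11 P(93-04)) / 22 exactly, per plot."""
    for s in default_experiment:
        p1 = productivity(s, (1982, 1993))
        p2 = productivity(s, (1993, 2004))
        pf = productivity(s, (1982, 2004))
        assert pf.agb == pytest.approx((11 * p1.agb + 11 * p2.agb) / 22, rel=1e-12, abs=1e-15)
        assert pf.bgb == pytest.approx((11 * p1.bgb + 11 * p2.bgb) / 22, rel=1e-12, abs=1e-15)


def test_load_equations_from_csv(tmp_path):
    path = tmp_path / "eq.csv"
    path.write_text(
        "group,a,b,c,wsg\n"
        "pine,0.08,2.4,,0.45\n"
        "bgb,0.02,2.6,,\n"
        "volume,0.0002,2.0,0.5,\n"
    )
    eqs = load_equations(path)
    assert eqs["agb"]["pine"](10.0) == pytest.approx(0.08 * 10**2.4)
    assert eqs["agb"]["oak"].a == pytest.approx(0.0768)  # default retained
    assert eqs["bgb"](10.0) == pytest.approx(0.02 * 10**2.6)
    assert eqs["volume"].wsg["pine"] == pytest.approx(0.45)
    assert eqs["volume"](10.0, 8.0) == pytest.approx(0.0002 * 100 * 8**0.5)
    bad = tmp_path / "bad.csv"
    bad.write_text("group,a,b\nshrub,1,1\n")
    with pytest.raises(ValueError, match="shrub"):
        load_equations(bad)
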