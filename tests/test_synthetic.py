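import numpy as np
import pytest

from standlab.stand_structure import weibull_moments_fit
from standlab.synthetic import SimConfig, default_experiment_config, generate_experiment
from standlab.treedata import density, write_tree_table


def test_same_seed_reproduces_exactly(tmp_path):
    a = generate_experiment(SimConfig(seed=42, n_treatments=2, reps_per_treatment=2,
                                      removal_levels=(0.0, 0.6)))
    b = generate_experiment(SimConfig(seed=42, n_treatments=2, reps_per_treatment=2,
                                      removal_levels=(0.0, 0.6)))
    for fa, fb in [(tmp_path / "a.csv", tmp_path / "b.csv")]:
        write_tree_table(a, fa, tmp_path / "ma.csv")
        write_tree_table(b, fb, tmp_path / "mb.csv")
        assert fa.read_bytes() == fb.read_bytes()
        assert (tmp_path / "ma.csv").read_bytes() == (tmp_path / "mb.csv").read_bytes()


def test_plot_substreams_stable_under_subsetting():
    full = generate_experiment(SimConfig(seed=5))
    # regenerating cannot change an individual plot's trees
    again = generate_experiment(SimConfig(seed=5))
    t1 = [(t.species, t.dbh) for t in full[17].inventories[2].trees]
    t2 = [(t.species, t.dbh) for t in again[17].inventories[2].trees]
    assert t1 == t2


def test_frozen_dynamics_keeps_tree_lists_identical():
    cfg = SimConfig(seed=2, n_treatments=1, reps_per_treatment=2, removal_levels=(0.0,),
                    mortality_rate=0.0, recruitment_rate=0.0)
    cfg.growth = {"base": 0.0, "removal_boost": 0.0, "cv": 0.3}
    for s in generate_experiment(cfg):
        lists = [[(t.species, t.dbh, t.height) for t in inv.trees] for inv in s.inventories]
        assert lists[0] == lists[1] == lists[2]


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        cfg = SimConfig(seed=0, recruitment_rate=0.0)
        cfg.regen["clearcut_density"] = 0.0
        cfg.regen["replace_fraction"] = 0.0
        cfg.validate()


def test_default_config_matches_reported_stand_conditions(default_experiment):
    """1982 means per plot: density ~1065/ha, D ~16 cm, H ~9 m, S 8-12,
    all within 25%."""
    dens, rich, mean_d, mean_h = [], [], [], []
    for s in default_experiment:
        inv = s.inventory(1982)
        dens.append(density(inv))
        rich.append(len(inv.counts_by_species()))
        mean_d.append(np.mean([t.dbh for t in inv.trees]))
        mean_h.append(np.mean([t.height for t in inv.trees]))
    assert np.mean(dens) == pytest.approx(1065, rel=0.25)
    assert 7 <= np.mean(rich) <= 12
    assert np.mean(mean_d) == pytest.approx(16.0, rel=0.25)
    assert np.mean(mean_h) == pytest.approx(9.0, rel=0.25)


def test_two_species_dominate(default_experiment):
    total = top = 0
    for s in default_experiment:
        c = s.inventory(1982).counts_by_species()
        total += sum(c.values())
        top += c.get("PICO", 0) + c.get("QUSI", 0)
    assert top / total >= 0.60


def test_clearcut_plots_denser_and_poorer_than_controls(default_experiment):
    ctrl = [s for s in default_experiment if s.treatment_removal == 0.0]
    cc = [s for s in default_experiment if s.treatment_removal == 1.0]
    d = lambda group: np.mean([density(s.inventory(1982)) for s in group])
    r = lambda group: np.mean([len(s.inventory(1982).counts_by_species()) for s in group])
    assert d(cc) > d(ctrl)
    assert r(cc) < r(ctrl)


def test_generated_diameters_recover_configured_weibull():
    """Moments fit on a large pooled pine sample recovers the configured
    law within 2% on the shape."""
    cfg = SimConfig(seed=11, n_treatments=1, reps_per_treatment=1, removal_levels=(0.0,),
                    base_density=400_000.0, subplot_area_ha=1.0,
                    census_years=(1982,))
    exp = generate_experiment(cfg)
    pines = np.array([t.dbh for t in exp[0].inventories[0].trees if t.group == "pine"])
    assert pines.size > 1e5
    fit, _ = weibull_moments_fit(pines)
    law = cfg.d_law["pine"]
    assert fit.alpha == pytest.approx(law.alpha, rel=0.02)
    assert fit.beta == pytest.approx(law.beta, rel=0.03)


def test_geometric_abundance_recovered():
    """Multinomial draws (N=10^4) from a geometric(k=0.4) pool refit the
    geometric series with k within 10%."""
    from standlab.abundance_models import fit_geometric
    from standlab.diversity import AbundanceVector

    cfg = SimConfig(seed=21, abundance_model=("geometric", {"k": 0.4}))
    rng = np.random.default_rng(21)
    p = cfg.pool_proportions()[:10]
    p = p / p.sum()
    counts = rng.multinomial(10_000, p)
    fit = fit_geometric(AbundanceVector([int(c) for c in counts if c > 0]))
    assert fit.params["k"] == pytest.approx(0.4, rel=0.10)


def test_oak_effect_raises_pine_productivity():
    """With oak_effect > 0, mean pine AGB productivity rises monotonically
    with the configured oak share (averaged over replicate seeds)."""
    from standlab.allometry import stand_biomass

    def pine_prod(oak_share, seeds=(0, 1, 2)):
        vals = []
        for seed in seeds:
            pool = (("PICO", "pine"), ("QUSI", "oak"))
            # two-species stand; geometric k chosen so the oak stem share is
            # oak_share, with total density scaled to hold pine density fixed
            k = (1 - 2 * oak_share) / (1 - oak_share)
            cfg = SimConfig(seed=seed, n_treatments=1, reps_per_treatment=2,
                            removal_levels=(0.0,), species_pool=pool,
                            abundance_model=("geometric", {"k": k}),
                            base_density=900.0 / (1 - oak_share),
                            recruitment_rate=0.0, mortality_rate=0.0,
                            oak_effect=1.5)
            for s in generate_experiment(cfg):
                agb = [stand_biomass(inv, "agb", "pine") for inv in s.inventories]
                vals.append((agb[-1] - agb[0]) / 22)
        return np.mean(vals)

    p = [pine_prod(x) for x in (0.05, 0.2, 0.4)]
    assert p[0] < p[1] < p[2]


def test_recruits_enter_at_measurable_threshold(default_experiment):
    for s in default_experiment[:6]:
        for inv in s.inventories:
            assert min(t.dbh for t in inv.trees) >= 5.0
            assert min(t.height for t in inv.trees) >= 1.4
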