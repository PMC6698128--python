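import math

import numpy as np
import pytest

from standlab.abundance_models import (
    broken_stick_expected, fit_all, fit_broken_stick, fit_geometric,
    fit_logseries, fit_preston_curve, fit_trunc_lognormal, octave_counts,
    preston_curve, solve_logseries_x,
)
from standlab.diversity import AbundanceVector


# ---------------------------------------------------------------------------
# broken stick


def test_broken_stick_hand_expectations():
    exp = broken_stick_expected(33, 3)
    # (N/S) * harmonic tails: 11*(1+1/2+1/3), 11*(1/2+1/3), 11*(1/3)
    assert exp == pytest.approx([20.1666667, 9.1666667, 3.6666667], abs=1e-6)
    assert exp.sum() == pytest.approx(33.0, rel=1e-12)
    assert np.all(np.diff(exp) < 0)


def test_broken_stick_perfect_fit():
    # with S=2, N=4 the expected ranks (3, 1) are integers
    fit = fit_broken_stick(AbundanceVector([3, 1]))
    assert fit.chi2 == pytest.approx(0.0, abs=1e-12)
    assert fit.p == pytest.approx(1.0)
    assert fit.accepted


def test_broken_stick_requires_two_species():
    with pytest.raises(ValueError):
        fit_broken_stick(AbundanceVector([5]))


# ---------------------------------------------------------------------------
# geometric series


def test_geometric_recovers_k_from_noise_free_ranks():
    k, s, n = 0.4, 8, 10**6
    i = np.arange(1, s + 1)
    ck = 1 / (1 - (1 - k) ** s)
    expected = n * ck * k * (1 - k) ** (i - 1)
    v = AbundanceVector([int(round(e)) for e in expected])
    fit = fit_geometric(v)
    assert fit.params["k"] == pytest.approx(k, abs=1e-3)
    assert fit.accepted


@pytest.mark.parametrize("k", [0.05, 0.3, 0.7, 0.95])
def test_geometric_expected_sums_to_n(k):
    from standlab.abundance_models import _geometric_expected

    exp = _geometric_expected(1234, 9, k)
    assert exp.sum() == pytest.approx(1234.0, rel=1e-12)


def test_geometric_near_equal_ranks_hits_boundary():
    fit = fit_geometric(AbundanceVector([50, 50, 50, 50]))
    assert fit.params["k"] < 1e-4
    assert "boundary" in fit.note


# ---------------------------------------------------------------------------
# log series


def test_logseries_root_satisfies_defining_relation():
    for s, n in [(5, 100), (10, 2000), (12, 250)]:
        x = solve_logseries_x(n, s)
        assert (1 - x) / x * (-math.log1p(-x)) == pytest.approx(s / n, abs=1e-10)


def test_logseries_alpha_identity():
    """Fitted (alpha, x) satisfy S = alpha ln(1 + N/alpha)."""
    v = AbundanceVector([120, 40, 18, 9, 4, 2, 1, 1])
    fit = fit_logseries(v)
    alpha = fit.params["alpha"]
    assert v.s == pytest.approx(alpha * math.log(1 + v.n / alpha), abs=1e-6)


def test_logseries_series_mass_equals_n():
    """sum_n phi(n) * n == N (checked by summing the series far out)."""
    v = AbundanceVector([120, 40, 18, 9, 4, 2, 1, 1])
    fit = fit_logseries(v)
    alpha, x = fit.params["alpha"], fit.params["x"]
    n_arr = np.arange(1, 10**6 + 1)
    total = (alpha * x**n_arr).sum()  # sum phi(n)*n = alpha * sum x^n
    assert total == pytest.approx(v.n, rel=1e-3)


def test_logseries_all_singletons_boundary():
    fit = fit_logseries(AbundanceVector([1, 1, 1, 1]))
    assert not fit.testable
    assert "singleton" in fit.note


# ---------------------------------------------------------------------------
# octaves and truncated lognormal


def test_octave_binning_boundary_split():
    # abundances 1,2,3,4: 1 -> octave 0; 2 -> half in 0, half in 1;
    # 3 -> octave 1; 4 -> half in 1, half in 2
    out = octave_counts(np.array([1, 2, 3, 4]))
    assert out == pytest.approx([1.5, 2.0, 0.5])
    assert out.sum() == pytest.approx(4.0)


def test_preston_recovery_from_exact_curve():
    s0, a, r0 = 12.0, 0.3, 3.0
    octaves = preston_curve(np.arange(8), s0, a, r0)
    f0, fa, fr = fit_preston_curve(octaves)
    assert f0 == pytest.approx(s0, abs=1e-6)
    assert fa == pytest.approx(a, abs=1e-6)
    assert fr == pytest.approx(r0, abs=1e-6)


def test_preston_symmetric_histogram_mode():
    octaves = [1.0, 4.0, 9.0, 4.0, 1.0]
    _, _, r0 = fit_preston_curve(octaves)
    assert r0 == pytest.approx(2.0, abs=1e-6)


def test_trunc_lognormal_fit_nonnegative_curve():
    v = AbundanceVector([64, 30, 28, 14, 12, 8, 6, 3, 2, 2, 1, 1])
    fit = fit_trunc_lognormal(v)
    assert fit.testable
    assert (preston_curve(np.linspace(-5, 15, 100), **{
        "s0": fit.params["S0"], "a": fit.params["a"], "r0": fit.params["R0"]}) >= 0).all()


# ---------------------------------------------------------------------------
# fit_all


def test_fit_all_degenerate_inputs_do_not_crash():
    res = fit_all(AbundanceVector([1, 1, 1, 1]))
    assert set(res["fits"]) == {"geometric", "logseries", "trunc_lognormal", "broken_stick"}
    assert 0.0 <= res["acceptance_fraction"] <= 1.0
    assert res["fits"]["broken_stick"].testable


def test_fit_all_acceptance_fraction_bounds(default_experiment):
    s = default_experiment[0]
    v = AbundanceVector(s.inventories[0].counts_by_species())
    res = fit_all(v)
    assert 0.0 <= res["acceptance_fraction"] <= 1.0


def test_expected_mass_conservation_after_pooling():
    """Every model's expected abundances/species sum to the observed total
    within 0.5% after octave pooling."""
    v = AbundanceVector([130, 55, 31, 14, 9, 6, 3, 2, 1, 1])
    bs = fit_broken_stick(v)
    assert bs.expected.sum() == pytest.approx(v.n, rel=5e-3)
    geo = fit_geometric(v)
    assert geo.expected.sum() == pytest.approx(v.n, rel=5e-3)
    ls = fit_logseries(v)
    # octave models conserve species count, not individuals
    assert ls.observed.sum() == pytest.approx(v.s, rel=5e-3)


def test_df_rule_floor():
    # tiny vector: pooling can leave very few classes, df never below 1
    fit = fit_geometric(AbundanceVector([3, 2, 1]))
    assert fit.df >= 1
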