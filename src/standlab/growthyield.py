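"""Growth-and-yield modeling with an oak-mixture diversity covariate.

Timber volume per hectare is modeled from basal area (BA), site index (SI),
mean pine age (t), and the oak ratio IQ = oak stems / total stems, either
multiplicatively,

    V = b0 * BA**b1 * SI**b2 * t**b3 * IQ**b4,

or linearly, V = b0 + b1*BA + b2*SI + b3*t + b4*IQ.  The b4 coefficient
carries the diversity effect; its t-test against zero is the null hypothesis
that the oak mixture does not influence yield.  Pure-pine stands (IQ = 0)
cannot enter the multiplicative fit and are handled by a separate pine-only
model; projections of the two models over stand age quantify the mixture
advantage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .allometry import VolumeEquation, stand_volume
from .treedata import InventorySeries, PlotInventory, basal_area, density

__all__ = [
    "GrowthYieldFit",
    "iq_index",
    "dominant_height",
    "fit_schumacher_guide",
    "site_index",
    "growth_yield_table",
    "fit_growth_yield",
    "project_yield",
]

_PREDICTORS = ("BA", "SI", "t", "IQ")


def iq_index(inv: PlotInventory) -> float:
    """Oak ratio: oak stem density over total stem density, in [0, 1]."""
    if not inv.trees:
        raise ValueError(f"plot {inv.plot_id} ({inv.year}) has no trees")
    return density(inv, "oak") / density(inv)


def dominant_height(inv: PlotInventory, group: str = "pine",
                    n_per_ha: float = 100.0) -> float:
    """Mean top height of the thickest `n_per_ha` trees per hectare."""
    trees = [t for t in inv.trees if t.group == group] or list(inv.trees)
    n = max(1, round(n_per_ha * inv.subplot_area_ha))
    top = sorted(trees, key=lambda t: t.dbh, reverse=True)[:n]
    return float(np.mean([t.height for t in top]))


def fit_schumacher_guide(heights, ages) -> tuple[float, float]:
    """Fit the Schumacher guide curve H = A exp(-B / t) to dominant-height /
    age pairs.  Nonlinear least squares, initialized from the log-linear
    regression ln H = ln A - B / t."""
    h = np.asarray(heights, dtype=float)
    t = np.asarray(ages, dtype=float)
    if (t <= 0).any():
        raise ValueError("ages must be positive")
    x = 1.0 / t
    slope, intercept = np.polyfit(x, np.log(h), 1)
    p0 = (math.exp(intercept), -slope)
    popt, _ = optimize.curve_fit(lambda tt, a, b: a * np.exp(-b / tt), t, h,
                                 p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def site_index(h_dom: float, t: float, base_age: float = 50.0,
               guide: tuple[float, float] = (30.0, 12.0)) -> float:
    """Anamorphic site index: the height the stand's guide curve predicts at
    the base age, anchored through (t, h_dom).  SI = H exp(B/t - B/base)."""
    if t <= 0:
        raise ValueError("stand age must be positive")
    _, b = guide
    return h_dom * math.exp(b / t - b / base_age)


def growth_yield_table(series: list[InventorySeries],
                       volume_eq: VolumeEquation | None = None,
                       base_age: float = 50.0) -> pd.DataFrame:
    """One observation per plot-census: V, BA, SI, t, IQ.

    The SI guide curve is fitted across all plot-census dominant-height/age
    pairs; plots lacking a stand age are dropped with a warning column.
    """
    rows = []
    for s in series:
        for inv in s.inventories:
            if not inv.trees or inv.stand_age is None:
                continue
            rows.append({
                "plot_id": s.plot_id,
                "year": inv.year,
                "removal": s.treatment_removal,
                "V": stand_volume(inv, volume_eq),
                "BA": basal_area(inv),
                "Hdom": dominant_height(inv),
                "t": float(inv.stand_age),
                "IQ": iq_index(inv),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no usable plot-census observations (missing stand ages?)")
    guide = fit_schumacher_guide(df["Hdom"], df["t"])
    df["SI"] = [site_index(h, t, base_age, guide) for h, t in zip(df["Hdom"], df["t"])]
    return df


@dataclass
class GrowthYieldFit:
    """Fitted volume model with coefficient inference."""

    form: str  # "multiplicative" | "linear"
    coef: dict[str, float]  # b0..b4
    se: dict[str, float]
    p: dict[str, float]
    r2: float
    n: int
    t_range: tuple[float, float]

    def predict(self, BA, SI, t, IQ):
        b = self.coef
        BA, SI, t, IQ = map(np.asarray, (BA, SI, t, IQ))
        if self.form == "multiplicative":
            out = b["b0"] * BA**b["b1"] * SI**b["b2"] * t**b["b3"]
            if "b4" in b:
                out = out * IQ**b["b4"]
            return out
        out = b["b0"] + b["b1"] * BA + b["b2"] * SI + b["b3"] * t
        if "b4" in b:
            out = out + b["b4"] * IQ
        return out


def _nls_inference(f, p0, xdata, y, sigma=None):
    popt, pcov = optimize.curve_fit(f, xdata, y, p0=p0, sigma=sigma, maxfev=40000)
    resid = y - f(xdata, *popt)
    dof = max(y.size - len(popt), 1)
    se = np.sqrt(np.diag(pcov))
    tvals = popt / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return popt, se, pvals, r2


def fit_growth_yield(obs: pd.DataFrame, form: str = "multiplicative",
                     include_iq: bool = True,
                     weights: str = "relative") -> GrowthYieldFit:
    """Fit the volume model to a table with columns V, BA, SI, t (and IQ).

    The multiplicative form is fitted by nonlinear least squares on the
    original volume scale, initialized from the log-linear OLS solution.
    Residuals are weighted by the observed volume by default
    (``weights="relative"``): volume errors scale with stand size
    (multiplicative error), and relative weighting keeps the coefficient
    t-tests calibrated under that regime.  ``weights="none"`` gives the
    unweighted fit.  Plots with IQ = 0 must be excluded from the mixed
    multiplicative fit beforehand (IQ**b4 forces V = 0 there).
    """
    cols = ["V", "BA", "SI", "t"] + (["IQ"] if include_iq else [])
    missing = [c for c in cols if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    df = obs.dropna(subset=cols)
    if len(df) < 10:
        raise ValueError(f"need at least 10 complete observations, have {len(df)}")
    y = df["V"].to_numpy(dtype=float)
    X = {c: df[c].to_numpy(dtype=float) for c in cols[1:]}
    names = ["b0"] + [f"b{i+1}" for i in range(len(cols) - 1)]

    if form == "linear":
        import statsmodels.api as sm

        design = sm.add_constant(np.column_stack([X[c] for c in cols[1:]]))
        res = sm.OLS(y, design).fit()
        coef = dict(zip(names, res.params))
        se = dict(zip(names, res.bse))
        p = dict(zip(names, res.pvalues))
        return GrowthYieldFit("linear", coef, se, p, float(res.rsquared), len(df),
                              (float(X["t"].min()), float(X["t"].max())))

    if form != "multiplicative":
        raise ValueError(f"unknown form {form!r}")
    if include_iq and (X["IQ"] <= 0).any():
        raise ValueError("multiplicative fit with IQ requires IQ > 0; fit the "
                         "pine-only model (include_iq=False) for IQ = 0 stands")

    # log-linear OLS start values
    logs = np.column_stack([np.log(X[c]) for c in cols[1:]])
    A = np.column_stack([np.ones(len(df)), logs])
    sol, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    p0 = [math.exp(sol[0]), *sol[1:]]

    xdata = np.vstack([X[c] for c in cols[1:]])

    def f(xd, *b):
        out = np.full(xd.shape[1], b[0])
        for i in range(xd.shape[0]):
            out = out * xd[i] ** b[i + 1]
        return out

    if weights == "relative":
        sigma = y
    elif weights == "none":
        sigma = None
    else:
        raise ValueError(f"unknown weights option {weights!r}")
    try:
        popt, se, pvals, r2 = _nls_inference(f, p0, xdata, y, sigma)
    except RuntimeError as exc:
        raise RuntimeError(
            f"nonlinear fit failed to converge (start values {p0}): {exc}") from exc
    return GrowthYieldFit("multiplicative", dict(zip(names, popt)),
                          dict(zip(names, se)), dict(zip(names, pvals)),
                          r2, len(df), (float(X["t"].min()), float(X["t"].max())))


def project_yield(fit_mixed: GrowthYieldFit, fit_pure: GrowthYieldFit,
                  ages, ba_of_t, si: float, iq: float) -> dict:
    """Project both models along a stand trajectory and locate the maximum
    mixture advantage and any crossover age.

    ``ba_of_t`` maps age to basal area (callable or array aligned with
    ``ages``); ``iq`` is the oak ratio assumed for the mixed stand.
    """
    ages = np.asarray(ages, dtype=float)
    ba = np.asarray([ba_of_t(a) for a in ages]) if callable(ba_of_t) \
        else np.asarray(ba_of_t, dtype=float)
    warn = ""
    lo = min(fit_mixed.t_range[0], fit_pure.t_range[0])
    hi = max(fit_mixed.t_range[1], fit_pure.t_range[1])
    if ages.min() < lo or ages.max() > hi:
        warn = (f"trajectory ages [{ages.min():g}, {ages.max():g}] extend beyond "
                f"the fitted range [{lo:g}, {hi:g}]; projections are extrapolations")
    v_mixed = fit_mixed.predict(ba, si, ages, np.full_like(ages, iq))
    v_pure = fit_pure.predict(ba, si, ages, np.zeros_like(ages))
    diff = v_mixed - v_pure
    i_max = int(np.argmax(np.abs(diff)))
    sign = np.sign(diff)
    crossings = ages[1:][np.diff(sign) != 0]
    return {
        "ages": ages,
        "v_mixed": v_mixed,
        "v_pure": v_pure,
        "difference": diff,
        "max_difference": float(diff[i_max]),
        "age_at_max": float(ages[i_max]),
        "crossover_ages": crossings.tolist(),
        "warning": warn,
    }
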