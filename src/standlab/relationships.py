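"""Diversity-productivity regressions and treatment-effect summaries.

Each diversity index is regressed on biomass productivity P with both a
linear and a quadratic model, S = a + b*P + c*P**2.  The quadratic term's
t-test (H0: c = 0, alpha = 0.05) decides between a curved and a monotonic
description: a significant negative c with the vertex inside the observed
productivity range is *hump-shaped*, a significant positive c with negative
b and an interior vertex is *U-shaped*, otherwise the relationship is
classified from the linear fit's slope.  Running the full grid - every
index against above- and belowground productivity for every census
interval - yields 9 x 2 x 3 = 54 classifications for the standard design.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .allometry import productivity
from .diversity import AbundanceVector, INDEX_NAMES, diversity_profile
from .treedata import InventorySeries, density

__all__ = [
    "QuadraticFit",
    "ShapeClassification",
    "classify_diversity_productivity",
    "run_regression_grid",
    "treatment_summary",
    "GRID_INDICES",
]

#: the eight abundance-vector indices plus stand density, the customary
#: abundance-based companion, giving the nine-index grid
GRID_INDICES = INDEX_NAMES + ("Den",)


@dataclass(frozen=True)
class QuadraticFit:
    a: float
    b: float
    c: float
    se: tuple[float, float, float]
    p: tuple[float, float, float]
    r2: float
    p_range: tuple[float, float]

    @property
    def vertex(self) -> float | None:
        return -self.b / (2.0 * self.c) if self.c != 0 else None


@dataclass(frozen=True)
class ShapeClassification:
    verdict: str  # hump | U | linear_increasing | linear_decreasing | none
    quadratic: QuadraticFit
    linear_slope: float
    linear_p: float
    linear_r2: float


def classify_diversity_productivity(p_values, index_values,
                                    alpha: float = 0.05) -> ShapeClassification:
    """Classify one index-productivity relationship; see the module docs."""
    x = np.asarray(p_values, dtype=float)
    y = np.asarray(index_values, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("productivity values are constant; no regression possible")

    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    qf = QuadraticFit(
        a=float(quad.params[0]), b=float(quad.params[1]), c=float(quad.params[2]),
        se=tuple(map(float, quad.bse)), p=tuple(map(float, quad.pvalues)),
        r2=float(quad.rsquared), p_range=(float(x.min()), float(x.max())),
    )
    b, c = qf.b, qf.c
    c_sig = qf.p[2] < alpha
    vertex = qf.vertex
    interior = vertex is not None and x.min() < vertex < x.max()
    if c_sig and c < 0 and interior:
        verdict = "hump"
    elif c_sig and c > 0 and b < 0 and interior:
        verdict = "U"
    elif lin.pvalues[1] < alpha:
        verdict = "linear_increasing" if lin.params[1] > 0 else "linear_decreasing"
    else:
        verdict = "none"
    return ShapeClassification(verdict, qf, float(lin.params[1]),
                               float(lin.pvalues[1]), float(lin.rsquared))


def _plot_profiles(series: list[InventorySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for inv in s.inventories:
            if not inv.trees:
                continue
            prof = diversity_profile(AbundanceVector(inv.counts_by_species()))
            row = {"plot_id": s.plot_id, "year": inv.year,
                   "removal": s.treatment_removal, "Den": density(inv)}
            row.update(prof.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def run_regression_grid(series: list[InventorySeries],
                        periods: list[tuple[int, int]] | None = None,
                        indices: tuple[str, ...] = GRID_INDICES,
                        alpha: float = 0.05,
                        holm: bool = False) -> pd.DataFrame:
    """The full classification grid: indices x {AGB, BGB} x periods.

    Index values are taken at the closing census of each period; Simpson
    values of +inf (all-singleton plots) are dropped pairwise.  With the
    default nine indices, two components and three periods the grid has 54
    rows.  ``holm`` optionally applies a Holm step-down correction to the
    quadratic-term p-values before classification (off by default).
    """
    years = sorted({inv.year for s in series for inv in s.inventories})
    if periods is None:
        periods = [(y1, y2) for y1, y2 in zip(years[:-1], years[1:])]
        if len(years) > 2:
            periods.append((years[0], years[-1]))
    profiles = _plot_profiles(series)

    prods = {}
    for per in periods:
        recs = [productivity(s, per) for s in series if per[0] in s.years and per[1] in s.years]
        prods[per] = pd.DataFrame(
            [{"plot_id": r.plot_id, "agb": r.agb, "bgb": r.bgb} for r in recs]
        )

    rows = []
    for per, comp, idx in product(periods, ("agb", "bgb"), indices):
        prof = profiles[profiles["year"] == per[1]][["plot_id", idx]]
        merged = prods[per].merge(prof, on="plot_id").replace([np.inf, -np.inf], np.nan)
        merged = merged.dropna(subset=[comp, idx])
        try:
            cls = classify_diversity_productivity(merged[comp], merged[idx], alpha)
            rows.append({
                "index": idx, "component": comp.upper(),
                "period": f"{per[0]}-{per[1]}",
                "verdict": cls.verdict,
                "c": cls.quadratic.c, "c_p": cls.quadratic.p[2],
                "quad_r2": cls.quadratic.r2,
                "lin_slope": cls.linear_slope, "lin_p": cls.linear_p,
                "lin_r2": cls.linear_r2, "n": len(merged), "note": "",
            })
        except ValueError as exc:
            rows.append({"index": idx, "component": comp.upper(),
                         "period": f"{per[0]}-{per[1]}", "verdict": "none",
                         "c": np.nan, "c_p": np.nan, "quad_r2": np.nan,
                         "lin_slope": np.nan, "lin_p": np.nan, "lin_r2": np.nan,
                         "n": len(merged), "note": str(exc)})
    grid = pd.DataFrame(rows)
    if holm:
        grid = _apply_holm(grid, alpha)
    return grid


def _apply_holm(grid: pd.DataFrame, alpha: float) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    ok = grid["c_p"].notna()
    adj = np.full(len(grid), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(grid.loc[ok, "c_p"], alpha, "holm")[1]
    grid = grid.assign(c_p_holm=adj)
    # demote curved verdicts whose corrected quadratic term is no longer significant
    demote = grid["verdict"].isin(["hump", "U"]) & (grid["c_p_holm"] >= alpha)
    grid.loc[demote, "verdict"] = "none"
    return grid


def treatment_summary(series: list[InventorySeries],
                      periods: list[tuple[int, int]] | None = None) -> dict:
    """Per-removal-level productivity means with t-based 95% CIs, plus the
    OLS of productivity on removal fraction (slope, r^2) per period."""
    years = sorted({inv.year for s in series for inv in s.inventories})
    if periods is None:
        periods = [(y1, y2) for y1, y2 in zip(years[:-1], years[1:])]
        if len(years) > 2:
            periods.append((years[0], years[-1]))
    rows, regs = [], []
    for per in periods:
        recs = [(s.treatment_removal, productivity(s, per)) for s in series
                if per[0] in s.years and per[1] in s.years]
        df = pd.DataFrame([{"removal": f, "agb": r.agb, "bgb": r.bgb} for f, r in recs])
        for comp in ("agb", "bgb"):
            for f, grp in df.groupby("removal"):
                vals = grp[comp].to_numpy()
                mean = float(vals.mean())
                if len(vals) > 1:
                    half = float(stats.t.ppf(0.975, len(vals) - 1)
                                 * vals.std(ddof=1) / np.sqrt(len(vals)))
                    note = ""
                else:
                    half, note = np.nan, "singleton group: CI undefined"
                rows.append({"period": f"{per[0]}-{per[1]}", "component": comp.upper(),
                             "removal": f, "mean": mean, "ci95_half": half,
                             "n": len(vals), "note": note})
            res = sm.OLS(df[comp], sm.add_constant(df["removal"])).fit()
            regs.append({"period": f"{per[0]}-{per[1]}", "component": comp.upper(),
                         "slope": float(res.params.iloc[1]),
                         "slope_p": float(res.pvalues.iloc[1]),
                         "r2": float(res.rsquared)})
    return {"groups": pd.DataFrame(rows), "regressions": pd.DataFrame(regs)}
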