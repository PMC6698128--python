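"""Orchestration: simulate -> analyze -> report.

Each stage is a plain function over files so runs are reproducible and
scriptable; the ``standlab`` console entry point is a thin wrapper.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance_models, allometry, diversity, relationships, stand_structure
from .growthyield import fit_growth_yield, growth_yield_table
from .synthetic import SimConfig, generate_experiment
from .treedata import InventorySeries, basal_area, density, read_tree_table, write_tree_table

log = logging.getLogger("standlab")

ANALYSIS_TABLES = (
    "stand_summary.csv",
    "treatment_productivity.csv",
    "diversity_summary.csv",
    "diversity_by_treatment.csv",
    "abundance_fits.csv",
    "weibull_fits.csv",
    "regression_grid.csv",
    "growth_yield_fits.csv",
)


def _config_to_jsonable(cfg: SimConfig) -> dict:
    def conv(obj):
        if hasattr(obj, "alpha") and hasattr(obj, "beta"):  # WeibullParams
            return {"alpha": obj.alpha, "beta": obj.beta, "epsilon": obj.epsilon}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    return conv(asdict(cfg))


def cmd_simulate(config: SimConfig | None, seed: int, out: str | Path) -> dict:
    """Generate an experiment and write the tree-list / metadata CSV pair
    plus a manifest recording the seed and a hash of the full config."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or SimConfig(seed=seed)
    cfg.seed = seed
    series = generate_experiment(cfg)
    write_tree_table(series, out / "trees.csv", out / "plots.csv")
    cfg_json = json.dumps(_config_to_jsonable(cfg), sort_keys=True)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_plots": len(series),
        "census_years": list(cfg.census_years),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "config.json").write_text(cfg_json + "\n")
    log.info("simulated %d plots -> %s", len(series), out)
    return manifest


def _stand_summary(series: list[InventorySeries]) -> pd.DataFrame:
    rows = []
    years = sorted({inv.year for s in series for inv in s.inventories})
    for year in years:
        for grp in ("pine", "oak"):
            per_plot = []
            for s in series:
                if year not in s.years:
                    continue
                inv = s.inventory(year)
                trees = [t for t in inv.trees if t.group == grp]
                if not trees:
                    continue
                per_plot.append({
                    "D": float(np.mean([t.dbh for t in trees])),
                    "H": float(np.mean([t.height for t in trees])),
                    "BA": basal_area(inv, grp),
                    "V": allometry.stand_volume(inv, group=grp),
                    "Den": density(inv, grp),
                    "AGB": allometry.stand_biomass(inv, "agb", grp),
                    "BGB": allometry.stand_biomass(inv, "bgb", grp),
                })
            df = pd.DataFrame(per_plot)
            row = {"year": year, "group": grp, "n_plots": len(df)}
            for c in df.columns:
                row[f"mean_{c}"] = float(df[c].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def _diversity_tables(series) -> tuple[pd.DataFrame, pd.DataFrame]:
    prof = relationships._plot_profiles(series)
    by_year = prof.drop(columns=["plot_id", "removal"]).groupby("year").mean().reset_index()
    by_treat = (prof.drop(columns=["plot_id"])
                .groupby(["year", "removal"]).mean().reset_index())
    return by_year, by_treat


def _abundance_table(series) -> pd.DataFrame:
    rows = []
    for s in series:
        for inv in s.inventories:
            if not inv.trees:
                continue
            v = diversity.AbundanceVector(inv.counts_by_species())
            if v.s < 2:
                continue
            res = abundance_models.fit_all(v)
            for name, fit in res["fits"].items():
                rows.append({
                    "plot_id": s.plot_id, "year": inv.year,
                    "removal": s.treatment_removal, "model": name,
                    "params": json.dumps({k: round(x, 6) for k, x in fit.params.items()}),
                    "chi2": fit.chi2, "df": fit.df, "p": fit.p,
                    "testable": fit.testable, "accepted": fit.accepted,
                    "note": fit.note,
                })
    return pd.DataFrame(rows)


def _weibull_table(series) -> pd.DataFrame:
    rows = []
    for s in series:
        for inv in s.inventories:
            for var, attr in (("D", "dbh"), ("H", "height")):
                vals = np.array([getattr(t, attr) for t in inv.trees])
                row = {"plot_id": s.plot_id, "year": inv.year, "variable": var,
                       "n": vals.size}
                try:
                    fit = stand_structure.ks_screen(vals, variable=var)
                    row.update(alpha=fit.params.alpha, beta=fit.params.beta,
                               epsilon=fit.params.epsilon, ks_p=fit.ks_p,
                               adequate=fit.adequate, note=fit.note)
                except ValueError as exc:
                    row.update(alpha=np.nan, beta=np.nan, epsilon=np.nan,
                               ks_p=np.nan, adequate=False, note=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)


def _growth_yield_table(series) -> pd.DataFrame:
    rows = []
    try:
        obs = growth_yield_table(series)
    except ValueError as exc:
        return pd.DataFrame([{"form": "unavailable", "note": str(exc)}])
    mixed = obs[obs["IQ"] > 0]
    pure = obs[obs["IQ"] == 0]
    fits = []
    try:
        fits.append(("mixed", fit_growth_yield(mixed, "multiplicative")))
    except (ValueError, RuntimeError) as exc:
        rows.append({"form": "multiplicative-mixed", "note": str(exc)})
    try:
        fits.append(("linear", fit_growth_yield(obs, "linear")))
    except (ValueError, RuntimeError) as exc:
        rows.append({"form": "linear", "note": str(exc)})
    if len(pure) >= 10:
        try:
            fits.append(("pure_pine",
                         fit_growth_yield(pure, "multiplicative", include_iq=False)))
        except (ValueError, RuntimeError) as exc:
            rows.append({"form": "multiplicative-pure", "note": str(exc)})
    for label, fit in fits:
        for name in fit.coef:
            rows.append({"form": f"{fit.form}-{label}", "coef": name,
                         "estimate": fit.coef[name], "se": fit.se[name],
                         "p": fit.p[name], "r2": fit.r2, "n": fit.n, "note": ""})
    return pd.DataFrame(rows)


def cmd_analyze(trees: str | Path, plots: str | Path, out: str | Path,
                species_table=None, alpha: float = 0.05,
                periods: list[tuple[int, int]] | None = None) -> dict[str, Path]:
    """Run every analysis stage on a tree-list/metadata pair; each stage
    failure is logged and the remaining independent stages still run."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    series = read_tree_table(trees, plots, species_table)
    written: dict[str, Path] = {}

    def emit(name: str, fn):
        try:
            df = fn()
            path = out / name
            df.to_csv(path, index=False, float_format="%.6g")
            written[name] = path
        except Exception:
            log.exception("analysis stage %s failed", name)

    def prods():
        summ = relationships.treatment_summary(series, periods)
        return summ["groups"].merge(summ["regressions"], on=["period", "component"],
                                    how="left", suffixes=("", "_reg"))

    emit("stand_summary.csv", lambda: _stand_summary(series))
    emit("treatment_productivity.csv", prods)
    by_year, by_treat = _diversity_tables(series)
    emit("diversity_summary.csv", lambda: by_year)
    emit("diversity_by_treatment.csv", lambda: by_treat)
    emit("abundance_fits.csv", lambda: _abundance_table(series))
    emit("weibull_fits.csv", lambda: _weibull_table(series))
    emit("regression_grid.csv",
         lambda: relationships.run_regression_grid(series, periods, alpha=alpha))
    emit("growth_yield_fits.csv", lambda: _growth_yield_table(series))
    return written


def cmd_report(results_dir: str | Path) -> str:
    """Render a plain-text summary of an analysis output directory."""
    results_dir = Path(results_dir)
    lines = [f"standlab report for {results_dir}", "=" * 40]
    for name in ANALYSIS_TABLES:
        path = results_dir / name
        if not path.exists():
            lines.append(f"[absent] {name}")
            continue
        df = pd.read_csv(path)
        lines.append(f"\n## {name} ({len(df)} rows)")
        if name == "regression_grid.csv" and "verdict" in df.columns:
            counts = df["verdict"].value_counts().to_dict()
            lines.append(f"verdicts: {counts}")
        elif name == "abundance_fits.csv" and "accepted" in df.columns:
            frac = df[df["testable"]].groupby("model")["accepted"].mean()
            lines.append("acceptance by model: " +
                         ", ".join(f"{m}={v:.2f}" for m, v in frac.items()))
        elif name == "weibull_fits.csv" and "adequate" in df.columns:
            lines.append(f"adequate fits: {100 * df['adequate'].mean():.1f}%")
        else:
            lines.append(df.head(3).to_string(index=False))
    return "\n".join(lines) + "\n"
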