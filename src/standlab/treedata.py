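"""Domain types and I/O for permanent-plot tree-list censuses.

A census record is one measured tree: plot, census year, species code,
diameter at breast height (cm) and top height (m).  Trees are measured on a
sub-quadrat of the 1-ha plot (0.25 ha by default), so per-hectare quantities
carry an expansion factor of ``1 / subplot_area_ha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TreeRecord",
    "PlotInventory",
    "InventorySeries",
    "DEFAULT_SPECIES_GROUPS",
    "TreeDataError",
    "read_tree_table",
    "write_tree_table",
    "basal_area",
    "density",
]

GROUPS = ("pine", "oak", "other_conifer", "other_broadleaf")

#: Default species -> functional-group table for the Sierra Madre Occidental
#: mixed pine-oak forests.  Conifers without their own biomass equation use
#: the pine equations downstream, broadleaves the oak equations.
DEFAULT_SPECIES_GROUPS: dict[str, str] = {
    "PICO": "pine",  # Pinus cooperi
    "PIDU": "pine",  # Pinus durangensis
    "PILE": "pine",  # Pinus leiophylla
    "PITE": "pine",  # Pinus teocote
    "PIAY": "pine",  # Pinus ayacahuite
    "QUSI": "oak",  # Quercus sideroxylla
    "ARXA": "other_broadleaf",  # Arbutus xalapensis
    "ALAC": "other_broadleaf",  # Alnus acuminata
    "JUSP": "other_conifer",  # Juniperus spp.
    "PSME": "other_conifer",  # Pseudotsuga menziesii
}


class TreeDataError(ValueError):
    """Raised for malformed tree-list or metadata input."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured tree."""

    plot_id: str
    year: int
    species: str
    group: str
    dbh: float  # diameter at breast height, cm
    height: float  # top height, m

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise TreeDataError(f"non-positive dbh {self.dbh} for tree in plot {self.plot_id}")
        if self.height <= 0:
            raise TreeDataError(f"non-positive height {self.height} for tree in plot {self.plot_id}")
        if self.group not in GROUPS:
            raise TreeDataError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class PlotInventory:
    """All trees measured in one plot at one census."""

    plot_id: str
    year: int
    treatment_removal: float  # fraction of basal area removed at treatment
    trees: list[TreeRecord]
    subplot_area_ha: float = 0.25
    stand_age: float | None = None  # mean age of pines at this census, yr

    def __post_init__(self) -> None:
        if self.subplot_area_ha <= 0:
            raise TreeDataError("subplot_area_ha must be positive")
        for t in self.trees:
            if t.plot_id != self.plot_id or t.year != self.year:
                raise TreeDataError(
                    f"tree ({t.plot_id}, {t.year}) does not belong to inventory "
                    f"({self.plot_id}, {self.year})"
                )

    @property
    def expansion(self) -> float:
        """Trees-to-hectare expansion factor."""
        return 1.0 / self.subplot_area_ha

    def counts_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trees:
            out[t.species] = out.get(t.species, 0) + 1
        return out


@dataclass
class InventorySeries:
    """One plot's inventories across census years, ordered by year."""

    plot_id: str
    treatment_removal: float
    inventories: list[PlotInventory] = field(default_factory=list)

    def __post_init__(self) -> None:
        years = [inv.year for inv in self.inventories]
        if years != sorted(set(years)):
            raise TreeDataError(f"census years {years} must be strictly increasing")
        for inv in self.inventories:
            if inv.plot_id != self.plot_id:
                raise TreeDataError("all inventories must share the series plot_id")

    @property
    def years(self) -> list[int]:
        return [inv.year for inv in self.inventories]

    def inventory(self, year: int) -> PlotInventory:
        for inv in self.inventories:
            if inv.year == year:
                return inv
        raise TreeDataError(f"plot {self.plot_id} has no census in {year}")


# ---------------------------------------------------------------------------
# Readers / writers

_TREE_COLUMNS = ["plot_id", "year", "species", "dbh_cm", "height_m"]
_META_COLUMNS = ["plot_id", "treatment_removal_pct", "subplot_area_ha"]


def read_tree_table(
    tree_path: str | Path,
    meta_path: str | Path,
    species_table: Mapping[str, str] | str | Path | None = None,
) -> list[InventorySeries]:
    """Read a tree-list CSV plus plot-metadata CSV into validated series.

    ``species_table`` maps species code to functional group; it may be a
    mapping or a CSV path with columns ``species, group``.  Defaults to the
    packaged Durango species table.
    """
    groups = _load_species_table(species_table)
    trees = pd.read_csv(tree_path)
    missing = [c for c in _TREE_COLUMNS if c not in trees.columns]
    if missing:
        raise TreeDataError(f"tree table missing columns: {missing}")
    meta = pd.read_csv(meta_path)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise TreeDataError(f"metadata table missing columns: {missing}")
    meta = meta.set_index(meta["plot_id"].astype(str))

    bad_rows = trees.index[(trees["dbh_cm"] <= 0) | (trees["height_m"] <= 0)]
    if len(bad_rows):
        # +2: header line plus 1-based numbering, matching what an editor shows
        rows = ", ".join(str(i + 2) for i in bad_rows[:10])
        raise TreeDataError(f"non-positive dbh/height on file row(s) {rows}")
    unknown = sorted(set(trees["species"].astype(str)) - set(groups))
    if unknown:
        raise TreeDataError(f"species code(s) not in species table: {unknown}")

    series: list[InventorySeries] = []
    for plot_id, plot_df in trees.groupby(trees["plot_id"].astype(str), sort=True):
        if plot_id not in meta.index:
            raise TreeDataError(f"plot {plot_id} present in tree table but absent from metadata")
        row = meta.loc[plot_id]
        removal = float(row["treatment_removal_pct"]) / 100.0
        area = float(row["subplot_area_ha"])
        age0 = float(row["stand_age_yr"]) if "stand_age_yr" in meta.columns else None
        invs = []
        years = sorted(plot_df["year"].unique())
        for year in years:
            ydf = plot_df[plot_df["year"] == year]
            recs = [
                TreeRecord(plot_id, int(year), str(r.species), groups[str(r.species)],
                           float(r.dbh_cm), float(r.height_m))
                for r in ydf.itertuples()
            ]
            age = None if age0 is None else age0 + (int(year) - int(years[0]))
            invs.append(PlotInventory(plot_id, int(year), removal, recs, area, age))
        series.append(InventorySeries(plot_id, removal, invs))
    return series


def write_tree_table(
    series: Iterable[InventorySeries],
    tree_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write series back to the tree-list + metadata CSV pair."""
    tree_rows, meta_rows = [], {}
    for s in series:
        for inv in s.inventories:
            for t in inv.trees:
                tree_rows.append((t.plot_id, t.year, t.species, t.dbh, t.height))
            first = s.inventories[0]
            meta_rows[s.plot_id] = (
                s.plot_id,
                100.0 * s.treatment_removal,
                inv.subplot_area_ha,
                first.stand_age,
            )
    pd.DataFrame(tree_rows, columns=_TREE_COLUMNS).to_csv(tree_path, index=False)
    meta = pd.DataFrame(
        meta_rows.values(),
        columns=_META_COLUMNS + ["stand_age_yr"],
    )
    if meta["stand_age_yr"].isna().all():
        meta = meta.drop(columns=["stand_age_yr"])
    meta.to_csv(meta_path, index=False)


def _load_species_table(table: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    if table is None:
        return dict(DEFAULT_SPECIES_GROUPS)
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
        if not {"species", "group"} <= set(df.columns):
            raise TreeDataError("species table needs columns species, group")
        table = dict(zip(df["species"].astype(str), df["group"].astype(str)))
    for sp, g in table.items():
        if g not in GROUPS:
            raise TreeDataError(f"species {sp!r} maps to unknown group {g!r}")
    return dict(table)


# ---------------------------------------------------------------------------
# Per-hectare stand attributes


def basal_area(inv: PlotInventory, group: str | None = None) -> float:
    """Stand basal area, m^2 ha^-1: sum of pi*(D/200)^2 times expansion."""
    ba = sum(
        math.pi * (t.dbh / 200.0) ** 2
        for t in inv.trees
        if group is None or t.group == group
    )
    return ba * inv.expansion


def density(inv: PlotInventory, group: str | None = None) -> float:
    """Stem density, trees ha^-1, optionally for one functional group."""
    n = sum(1 for t in inv.trees if group is None or t.group == group)
    return n * inv.expansion
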