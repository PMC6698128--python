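"""Allometric biomass, timber volume, and census-difference productivity.

Aboveground biomass (AGB, kg per tree) follows power laws ``a * D**b`` with
separate coefficients for pine-type (all conifers) and oak-type (all
broadleaves) trees; coarse-root biomass (BGB) uses a single equation.  Stand
productivity is the change in standing biomass between two censuses divided
by the interval length ("method 2": turnover inside the interval is ignored,
so productivity can be negative when mortality exceeds growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .treedata import InventorySeries, PlotInventory, TreeDataError

__all__ = [
    "AllometricEquation",
    "VolumeEquation",
    "ProductivityRecord",
    "DEFAULT_AGB_EQUATIONS",
    "DEFAULT_BGB_EQUATION",
    "DEFAULT_VOLUME_EQUATION",
    "load_equations",
    "agb_tree",
    "bgb_tree",
    "volume_tree",
    "stand_biomass",
    "stand_volume",
    "crosscheck_physical",
    "productivity",
]


@dataclass(frozen=True)
class AllometricEquation:
    """Power-law biomass equation ``biomass = a * D**b`` (kg; D in cm)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometric coefficients must be positive")

    def __call__(self, dbh: float) -> float:
        if dbh <= 0:
            raise ValueError(f"dbh must be positive, got {dbh}")
        return self.a * dbh**self.b


#: AGB equations for large pines and oaks (kg, D in cm).
DEFAULT_AGB_EQUATIONS: dict[str, AllometricEquation] = {
    "pine": AllometricEquation(0.0726, 2.4459),
    "oak": AllometricEquation(0.0768, 2.4416),
}

#: Coarse-root equation, applied to every tree regardless of group.
DEFAULT_BGB_EQUATION = AllometricEquation(0.016, 2.668)

# Conifers without their own equation borrow the pine equation, broadleaves
# the oak equation.
_GROUP_TO_EQ = {
    "pine": "pine",
    "other_conifer": "pine",
    "oak": "oak",
    "other_broadleaf": "oak",
}


@dataclass(frozen=True)
class VolumeEquation:
    """Schumacher-form stem volume ``V = a * D**b * H**c`` (m^3; D cm, H m).

    ``wsg`` holds wood specific gravity (g cm^-3 == Mg m^-3) per equation
    group for the physical biomass cross-check M = V * wsg.
    """

    a: float
    b: float
    c: float
    wsg: dict[str, float] = field(default_factory=lambda: {"pine": 0.43, "oak": 0.60})

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("volume coefficients must be positive")
        for g, w in self.wsg.items():
            if not 0 < w < 1.5:
                raise ValueError(f"wood specific gravity {w} for {g} out of range")

    def __call__(self, dbh: float, height: float) -> float:
        return self.a * dbh**self.b * height**self.c


#: Default volume equation.  The coefficients are a documented placeholder
#: chosen so that V * wsg tracks the allometric AGB over the observed size
#: range; real applications should supply locally fitted coefficients.
DEFAULT_VOLUME_EQUATION = VolumeEquation(a=2.09e-4, b=2.0, c=0.45)


def load_equations(path) -> dict:
    """Load an equation set from a coefficients CSV.

    Columns: group, a, b and optionally c and wsg.  Rows with group "pine"
    or "oak" define AGB power laws (plus wood specific gravity for the
    physical cross-check); a row with group "bgb" defines the coarse-root
    equation; a row with group "volume" (a, b, c) defines the Schumacher
    volume equation.  Missing pieces fall back to the defaults.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if not {"group", "a", "b"} <= set(df.columns):
        raise ValueError("equation CSV needs columns group, a, b")
    agb = dict(DEFAULT_AGB_EQUATIONS)
    bgb = DEFAULT_BGB_EQUATION
    vol_abc = (DEFAULT_VOLUME_EQUATION.a, DEFAULT_VOLUME_EQUATION.b,
               DEFAULT_VOLUME_EQUATION.c)
    wsg = dict(DEFAULT_VOLUME_EQUATION.wsg)
    for row in df.itertuples():
        g = str(row.group)
        if g in ("pine", "oak"):
            agb[g] = AllometricEquation(float(row.a), float(row.b))
            if hasattr(row, "wsg") and not pd.isna(row.wsg):
                wsg[g] = float(row.wsg)
        elif g == "bgb":
            bgb = AllometricEquation(float(row.a), float(row.b))
        elif g == "volume":
            vol_abc = (float(row.a), float(row.b), float(row.c))
        else:
            raise ValueError(f"unknown equation group {g!r}")
    return {"agb": agb, "bgb": bgb,
            "volume": VolumeEquation(*vol_abc, wsg=wsg)}


def agb_tree(dbh: float, group: str,
             equations: dict[str, AllometricEquation] | None = None) -> float:
    """Aboveground biomass of one tree, kg."""
    eqs = equations or DEFAULT_AGB_EQUATIONS
    try:
        key = _GROUP_TO_EQ[group]
    except KeyError:
        raise ValueError(f"no allometric mapping for group {group!r}") from None
    return eqs[key](dbh)


def bgb_tree(dbh: float, equation: AllometricEquation | None = None) -> float:
    """Coarse-root (belowground) biomass of one tree, kg."""
    return (equation or DEFAULT_BGB_EQUATION)(dbh)


def volume_tree(dbh: float, height: float,
                equation: VolumeEquation | None = None) -> float:
    """Stem volume of one tree, m^3."""
    return (equation or DEFAULT_VOLUME_EQUATION)(dbh, height)


def stand_biomass(inv: PlotInventory, component: str = "agb",
                  group: str | None = None) -> float:
    """Standing biomass, Mg ha^-1, for component 'agb' or 'bgb'."""
    if component not in ("agb", "bgb"):
        raise ValueError(f"component must be 'agb' or 'bgb', got {component!r}")
    kg = 0.0
    for t in inv.trees:
        if group is not None and t.group != group:
            continue
        kg += agb_tree(t.dbh, t.group) if component == "agb" else bgb_tree(t.dbh)
    return kg * inv.expansion / 1000.0


def stand_volume(inv: PlotInventory, equation: VolumeEquation | None = None,
                 group: str | None = None) -> float:
    """Standing timber volume, m^3 ha^-1."""
    v = sum(
        volume_tree(t.dbh, t.height, equation)
        for t in inv.trees
        if group is None or t.group == group
    )
    return v * inv.expansion


def crosscheck_physical(inv: PlotInventory,
                        equation: VolumeEquation | None = None) -> dict:
    """Compare allometric AGB against the physical estimate M = V * wsg.

    Returns a diagnostic record with both stand estimates (Mg ha^-1) and
    their relative difference; never a pass/fail verdict.
    """
    eq = equation or DEFAULT_VOLUME_EQUATION
    allometric = stand_biomass(inv, "agb")
    physical = 0.0
    for t in inv.trees:
        wsg = eq.wsg[_GROUP_TO_EQ[t.group]]
        physical += volume_tree(t.dbh, t.height, eq) * wsg  # m^3 * Mg/m^3 = Mg
    physical *= inv.expansion
    rel = abs(physical - allometric) / allometric if allometric > 0 else float("nan")
    return {
        "plot_id": inv.plot_id,
        "year": inv.year,
        "agb_allometric": allometric,
        "agb_physical": physical,
        "rel_difference": rel,
    }


@dataclass(frozen=True)
class ProductivityRecord:
    """Biomass productivity of one plot over one census interval."""

    plot_id: str
    year1: int
    year2: int
    agb: float  # Mg ha^-1 yr^-1
    bgb: float  # Mg ha^-1 yr^-1

    def __post_init__(self) -> None:
        if self.year2 <= self.year1:
            raise ValueError("year2 must follow year1")

    @property
    def interval(self) -> int:
        return self.year2 - self.year1


def productivity(series: InventorySeries, period: tuple[int, int]) -> ProductivityRecord:
    """Biomass productivity over ``period = (year1, year2)``, Mg ha^-1 yr^-1."""
    y1, y2 = period
    for y in (y1, y2):
        if y not in series.years:
            raise TreeDataError(f"plot {series.plot_id} has no census in {y}")
    inv1, inv2 = series.inventory(y1), series.inventory(y2)
    dt = y2 - y1
    return ProductivityRecord(
        series.plot_id,
        y1,
        y2,
        agb=(stand_biomass(inv2, "agb") - stand_biomass(inv1, "agb")) / dt,
        bgb=(stand_biomass(inv2, "bgb") - stand_biomass(inv1, "bgb")) / dt,
    )
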