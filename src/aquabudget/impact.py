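"""Environmental-impact conversion ratios (EICR) for compound feeds.

The EICR of a farmed fish on diet *i* for impact category *k* is the
inclusion-weighted sum of per-kg ingredient impacts, scaled by the feed
conversion ratio:

    EICR_{i,k} = sum_j CF_j * EI_{j,k} * FCR_i

with CF_j the inclusion of ingredient j (kg per kg feed), EI_{j,k} its
life-cycle impact per kg, and FCR_i the diet's feed conversion ratio
(kg feed per kg fish). The inner sum is the impact per kg of feed; the
FCR converts it to impact per kg of fish produced.

Six categories are supported: global warming potential (GWP, kg CO2e),
water use (m3), land use (m2), marine eutrophication potential (MEP,
kg N), freshwater eutrophication potential (FEP, kg P), and biotic
resource use (BRU, kg C). Negative EI values are allowed (e.g. net
negative water use where process freshwater is recycled).

FCR variability across replicate tanks is the only uncertainty
propagated: the per-tank EICR values share the feed impact and differ
only in FCR, and their mean and SEM are reported. Life-cycle inventory
(LCI) uncertainty is out of scope.

Real analyses require a user-supplied inventory CSV; the bundled
:func:`synthetic_demo_inventory` contains fabricated illustrative
numbers for tests and examples only, not LCI-derived values.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

from .formulation import DietFormulation, _canon

__all__ = [
    "CATEGORIES",
    "ImpactInventory",
    "EicrResult",
    "MissingInventoryEntryError",
    "feed_impact",
    "eicr",
    "replacement_sweep",
    "synthetic_demo_inventory",
    "read_inventory_csv",
    "write_inventory_csv",
    "write_eicr_csv",
]

#: Impact categories and their units (per kg ingredient / per kg fish).
CATEGORIES: dict[str, str] = {
    "GWP": "kg CO2e",
    "water": "m3",
    "land": "m2",
    "MEP": "kg N",
    "FEP": "kg P",
    "BRU": "kg C",
}


class MissingInventoryEntryError(KeyError):
    """The inventory has no EI value for an ingredient/category pair."""

    def __init__(self, ingredient: str, category: str):
        super().__init__(f"no inventory entry for ingredient {ingredient!r}, "
                         f"category {category!r}")
        self.ingredient = ingredient
        self.category = category


@dataclass
class ImpactInventory:
    """Per-kg ingredient environmental-impact values EI_{j,k}.

    ``entries`` maps (ingredient, category) to the impact value per kg
    of ingredient; ``provenance`` carries a free-text source tag per
    entry. Ingredient names are matched case-insensitively with
    whitespace normalized. An ingredient with no burden in a category
    must be entered as an explicit zero (typically with provenance
    ``"assumed"``) — lookups never default silently.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon_e: dict[tuple[str, str], float] = {}
        canon_p: dict[tuple[str, str], str] = {}
        for (ing, cat), val in self.entries.items():
            if cat not in CATEGORIES:
                raise ValueError(
                    f"unknown impact category {cat!r}; "
                    f"expected one of {sorted(CATEGORIES)}"
                )
            key = (_canon(ing), cat)
            canon_e[key] = float(val)
            canon_p[key] = self.provenance.get((ing, cat), "")
        self.entries = canon_e
        self.provenance = canon_p

    def set(self, ingredient: str, category: str, value: float,
            source: str = "") -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown impact category {category!r}")
        key = (_canon(ingredient), category)
        self.entries[key] = float(value)
        self.provenance[key] = source

    def get(self, ingredient: str, category: str) -> float:
        key = (_canon(ingredient), category)
        if key not in self.entries:
            raise MissingInventoryEntryError(ingredient, category)
        return self.entries[key]

    def categories(self) -> list[str]:
        return sorted({cat for _, cat in self.entries},
                      key=list(CATEGORIES).index)


@dataclass
class EicrResult:
    """Per-kg-fish conversion ratio for one diet and impact category."""

    diet_id: str
    category: str
    value: float
    se: float
    units: str = ""
    n_tanks: int = 0

    def __post_init__(self) -> None:
        if not self.units:
            self.units = CATEGORIES.get(self.category, "") + "/kg fish"


def feed_impact(f: DietFormulation, inv: ImpactInventory, category: str) -> float:
    """Impact of one kg of compound feed: sum_j inclusion_j * EI_{j,category}.

    Every ingredient with non-zero inclusion must have an inventory
    entry for the category; a missing entry raises
    :class:`MissingInventoryEntryError` naming the pair.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown impact category {category!r}")
    total = 0.0
    for name, frac in f.inclusions.items():
        if frac == 0.0:
            continue
        total += frac * inv.get(name, category)
    return total


def eicr(f: DietFormulation, inv: ImpactInventory,
         fcr_per_tank: list[float], category: str) -> EicrResult:
    """Environmental-impact conversion ratio for one diet and category.

    The feed impact (per kg feed) is multiplied by each replicate
    tank's FCR (kg feed per kg fish); the reported value is the mean of
    those per-tank products and the SE their SEM.
    """
    if not fcr_per_tank:
        raise ValueError("fcr_per_tank must be non-empty")
    fi = feed_impact(f, inv, category)
    per_tank = [fi * fcr_t for fcr_t in fcr_per_tank]
    n = len(per_tank)
    mean = sum(per_tank) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in per_tank) / (n - 1)
        se = math.sqrt(var / n)
    else:
        se = 0.0
    return EicrResult(diet_id=f.diet_id, category=category,
                      value=mean, se=se, n_tanks=n)


def replacement_sweep(
    diets: list[DietFormulation],
    inv: ImpactInventory,
    fcrs_per_diet: dict[str, list[float]],
    categories: list[str] | None = None,
) -> list[EicrResult]:
    """EICR for every diet x category, tidy for the group-comparison layer.

    ``fcrs_per_diet`` maps diet_id to that diet's per-tank FCRs;
    ``categories`` defaults to every category present in the inventory.
    """
    cats = categories if categories is not None else inv.categories()
    results = []
    for f in diets:
        if f.diet_id not in fcrs_per_diet:
            raise ValueError(f"no FCRs supplied for diet {f.diet_id!r}")
        for cat in cats:
            results.append(eicr(f, inv, fcrs_per_diet[f.diet_id], cat))
    return results


def synthetic_demo_inventory() -> ImpactInventory:
    """A SYNTHETIC demo inventory for tests and examples.

    The numbers are fabricated placeholders on loosely plausible orders
    of magnitude, not values from any life-cycle inventory database.
    They exist so the EICR pipeline can be exercised end-to-end; do not
    use them for real assessments — supply your own inventory CSV.
    """
    inv = ImpactInventory()
    # (GWP kg CO2e, water m3, land m2, MEP kg N, FEP kg P, BRU kg C) per kg
    rows = {
        "Fish meal":               (1.8, 0.010, 0.10, 2e-4, 2e-5, 18.0),
        "Fish oil":                (1.5, 0.008, 0.08, 1e-4, 1e-5, 4.0),
        "Co-product meal (raw)":   (2.6, -0.004, 0.02, 1e-4, 3e-5, 0.0),
        "Feather meal":            (0.8, 0.004, 0.30, 3e-4, 2e-5, 0.0),
        "Blood meal":              (0.9, 0.005, 0.35, 3e-4, 2e-5, 0.0),
        "Corn gluten meal":        (1.9, 0.060, 1.10, 6e-4, 5e-5, 0.0),
        "Soy protein concentrate": (1.6, 0.050, 1.60, 5e-4, 4e-5, 0.0),
        "Wheat gluten":            (1.4, 0.040, 1.20, 4e-4, 3e-5, 0.0),
        "Alpha cellulose":         (0.6, 0.020, 0.50, 1e-4, 1e-5, 0.0),
        "Lecithin":                (1.0, 0.030, 0.90, 2e-4, 2e-5, 0.0),
    }
    minor = ("CaHPO4", "Vitamin-mineral premix", "Lysine", "Methionine",
             "Choline chloride", "Ascorbic acid", "Taurine", "Astaxanthin")
    for ing, vals in rows.items():
        for cat, val in zip(CATEGORIES, vals):
            inv.set(ing, cat, val, source="synthetic demo")
    for ing in minor:
        for cat in CATEGORIES:
            inv.set(ing, cat, 0.0, source="assumed")
    return inv


# ---------------------------------------------------------------------------
# Inventory CSV: `ingredient,category,value,units,source`
# EICR output CSV: `diet_id,category,value,se,units,n_tanks`

def write_inventory_csv(inv: ImpactInventory,
                        path: str | os.PathLike | io.TextIOBase) -> None:
    lines = ["ingredient,category,value,units,source"]
    for (ing, cat), val in inv.entries.items():
        units = CATEGORIES[cat] + "/kg"
        lines.append(f"{ing},{cat},{val:g},{units},{inv.provenance[(ing, cat)]}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_inventory_csv(path: str | os.PathLike | io.TextIOBase) -> ImpactInventory:
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    inv = ImpactInventory()
    for line in lines[1:]:
        if not line.strip():
            continue
        ing, cat, val, _units, source = line.split(",", 4)
        inv.set(ing, cat, float(val), source)
    return inv


def write_eicr_csv(results: list[EicrResult],
                   path: str | os.PathLike | io.TextIOBase) -> None:
    lines = ["diet_id,category,value,se,units,n_tanks"]
    for r in results:
        lines.append(
            f"{r.diet_id},{r.category},{r.value:.6g},{r.se:.6g},"
            f"{r.units},{r.n_tanks}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
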