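"""Compound-feed formulation data model and replacement arithmetic.

A :class:`DietFormulation` maps ingredient names to inclusion fractions
(kg ingredient per kg feed). Inclusions are stored as *fractions*
internally; percent is an I/O convention only, which keeps the
percent-based digestibility arithmetic and the kg/kg impact arithmetic
from silently mixing scales.

The inert digestibility marker (yttrium oxide, added on top of the basal
mix at 1.0 % of the diet) is carried as ``marker_inclusion`` on the
formulation rather than as an ingredient row, so column-sum validation of
the formulated ingredients ignores it.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

__all__ = [
    "Ingredient",
    "DietFormulation",
    "validate_formulation",
    "fm_replacement_inclusion",
    "trial_diets",
    "read_formulation_csv",
    "write_formulation_csv",
]

#: Allowed ingredient categories.
CATEGORIES = ("marine", "microalgal", "animal_byproduct", "plant", "additive")

#: Default tolerance on the ingredient-inclusion sum (fraction of feed mass).
SUM_TOL = 0.005


def _canon(name: str) -> str:
    """Canonical ingredient key: case-insensitive, whitespace-normalized."""
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class Ingredient:
    """A feed ingredient with its sourcing category.

    ``category`` is one of marine, microalgal, animal_byproduct, plant,
    additive and is informational (used for reporting, not arithmetic).
    """

    name: str
    category: str = "additive"

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("ingredient name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown ingredient category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass
class DietFormulation:
    """A compound-feed formulation.

    Parameters
    ----------
    diet_id:
        Diet label, e.g. ``"Reference"`` or ``"100N"``.
    inclusions:
        Mapping ingredient name -> inclusion fraction of feed mass
        (dimensionless, kg/kg). Keys are matched case-insensitively with
        whitespace normalized; the original spelling of the first entry
        is kept for display.
    marker_inclusion:
        Inert-marker fraction of the diet (kg/kg), outside the
        ingredient sum. Default 0.01 (1.0 % yttrium oxide).
    """

    diet_id: str
    inclusions: dict[str, float] = field(default_factory=dict)
    marker_inclusion: float = 0.01

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        display: dict[str, str] = {}
        for name, frac in self.inclusions.items():
            key = _canon(name)
            if key in canon:
                raise ValueError(f"duplicate ingredient {name!r} in {self.diet_id}")
            canon[key] = float(frac)
            display[key] = " ".join(name.split())
        self.inclusions = {display[k]: v for k, v in canon.items()}
        self._canon = canon

    def inclusion(self, name: str) -> float:
        """Inclusion fraction for ``name`` (case/whitespace-insensitive, 0 if absent)."""
        return self._canon.get(_canon(name), 0.0)

    def ingredients(self) -> list[str]:
        return list(self.inclusions)

    def total_inclusion(self) -> float:
        return float(sum(self.inclusions.values()))


def validate_formulation(f: DietFormulation, tol: float = SUM_TOL) -> list[str]:
    """Check formulation invariants; return a list of violation descriptions.

    An empty list means the formulation is valid at tolerance ``tol``
    (allowed deviation of the inclusion sum from 1). Validation never
    raises — each violation names the offending field and its magnitude.
    """
    violations: list[str] = []
    for name, frac in f.inclusions.items():
        if not (0.0 <= frac <= 1.0):
            violations.append(
                f"inclusion[{name!r}] = {frac:.6g} outside [0, 1]"
            )
    if not (0.0 <= f.marker_inclusion <= 0.05):
        violations.append(
            f"marker_inclusion = {f.marker_inclusion:.6g} outside [0, 0.05]"
        )
    total = f.total_inclusion()
    if abs(total - 1.0) > tol:
        violations.append(
            f"inclusion sum = {total:.6g}, deviates from 1 by {total - 1.0:+.6g} "
            f"(tolerance {tol:g})"
        )
    return violations


def fm_replacement_inclusion(reference_fm: float, replacement: float) -> float:
    """Fishmeal inclusion (percent) after replacing a fraction of it.

    ``reference_fm`` is the reference diet's fishmeal inclusion in
    percent; ``replacement`` is the fraction of that fishmeal replaced
    by the alternative ingredient. Returns the remaining fishmeal
    inclusion in percent, rounded to 2 decimals per the reporting
    convention (e.g. 7.5 % at 66 % replacement -> 2.55 %).
    """
    if reference_fm < 0:
        raise ValueError(f"reference_fm must be >= 0, got {reference_fm}")
    if not (0.0 <= replacement <= 1.0):
        raise ValueError(f"replacement must be in [0, 1], got {replacement}")
    return round(reference_fm * (1.0 - replacement), 2)


# The four feeding-trial diets: a commercial-style reference with 7.5 %
# fishmeal and three diets replacing 33 / 66 / 100 % of that fishmeal
# with defatted Nannochloropsis sp. QH25 co-product meal (4.1 / 7.4 /
# 10.0 % of the diet). Values are percent of feed mass as formulated;
# alpha cellulose absorbs part of the difference.
_TRIAL_ROWS: list[tuple[str, str, tuple[float, float, float, float]]] = [
    ("Fish meal",               "marine",           (7.5, 5.02, 2.55, 0.0)),
    ("Fish oil",                "marine",           (14.0, 14.0, 14.0, 14.0)),
    ("Co-product meal (raw)",   "microalgal",       (0.0, 4.1, 7.4, 10.0)),
    ("Feather meal",            "animal_byproduct", (15.0, 15.0, 15.0, 15.0)),
    ("Blood meal",              "animal_byproduct", (7.0, 7.0, 7.0, 7.0)),
    ("Corn gluten meal",        "plant",            (20.0, 20.0, 20.0, 20.0)),
    ("Soy protein concentrate", "plant",            (20.0, 20.0, 20.0, 20.0)),
    ("Wheat gluten",            "plant",            (5.0, 5.0, 5.0, 5.0)),
    ("CaHPO4",                  "additive",         (1.0, 1.0, 1.0, 1.0)),
    ("Vitamin-mineral premix",  "additive",         (0.6, 0.6, 0.6, 0.6)),
    ("Lysine",                  "additive",         (1.0, 1.0, 1.0, 1.0)),
    ("Methionine",              "additive",         (0.2, 0.2, 0.2, 0.2)),
    ("Choline chloride",        "additive",         (0.5, 0.5, 0.5, 0.5)),
    ("Alpha cellulose",         "plant",            (4.5, 3.07, 2.0, 2.0)),
    ("Ascorbic acid",           "additive",         (0.2, 0.2, 0.2, 0.2)),
    ("Taurine",                 "additive",         (0.5, 0.5, 0.5, 0.5)),
    ("Lecithin",                "additive",         (3.0, 3.0, 3.0, 3.0)),
    ("Astaxanthin",             "additive",         (0.05, 0.05, 0.05, 0.05)),
]

_TRIAL_IDS = ("Reference", "33N", "66N", "100N")


def trial_diets() -> list[DietFormulation]:
    """The four built-in feeding-trial formulations (Reference, 33N, 66N, 100N).

    Inclusions are the formulated percent values divided by 100; each
    diet carries the 1.0 % inert marker and passes
    :func:`validate_formulation` at the default tolerance (the columns
    sum to 99.95–100.25 % as formulated).
    """
    diets = []
    for i, diet_id in enumerate(_TRIAL_IDS):
        inclusions = {name: vals[i] / 100.0 for name, _, vals in _TRIAL_ROWS}
        diets.append(
            DietFormulation(diet_id=diet_id, inclusions=inclusions,
                            marker_inclusion=0.01)
        )
    return diets


def trial_ingredients() -> list[Ingredient]:
    """Ingredient objects (with categories) for the built-in trial diets."""
    return [Ingredient(name, cat) for name, cat, _ in _TRIAL_ROWS]


# ---------------------------------------------------------------------------
# Formulation file format: CSV `ingredient,inclusion_percent`, one file per
# diet, with an optional `#marker_percent=<x>` comment line. Round-trips
# bit-identically for the built-in diets.

def write_formulation_csv(f: DietFormulation, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write a formulation to its CSV dialect."""
    lines = [f"#diet_id={f.diet_id}",
             f"#marker_percent={f.marker_inclusion * 100:g}",
             "ingredient,inclusion_percent"]
    for name, frac in f.inclusions.items():
        lines.append(f"{name},{frac * 100:g}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_formulation_csv(path: str | os.PathLike | io.TextIOBase,
                         diet_id: str | None = None) -> DietFormulation:
    """Read a formulation from its CSV dialect.

    ``diet_id`` overrides any ``#diet_id=`` comment in the file; if
    neither is present the file stem is used.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        fallback_id = "diet"
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        fallback_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]

    marker = 0.01
    file_id = None
    inclusions: dict[str, float] = {}
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("marker_percent="):
                marker = float(body.split("=", 1)[1]) / 100.0
            elif body.lower().startswith("diet_id="):
                file_id = body.split("=", 1)[1]
            continue
        name, _, value = line.rpartition(",")
        if name.lower() == "ingredient" and value.lower() == "inclusion_percent":
            continue  # header
        inclusions[name] = float(value) / 100.0

    return DietFormulation(
        diet_id=diet_id or file_id or fallback_id,
        inclusions=inclusions,
        marker_inclusion=marker,
    )
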