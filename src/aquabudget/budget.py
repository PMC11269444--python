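"""Feed conversion ratio and dry-matter nutrient mass-balance budgets.

Each tank's nutrient budget partitions the ingested nutrient into what
the fish retained in body mass, what left as undigested solid (fecal)
waste, and what was digested but not retained and hence dissolved into
the water. All quantities are expressed in grams of nutrient per kg of
dry-weight gain, computed on a dry-matter basis throughout:

    intake    = feed_dry * diet_% / 100          (g/fish, then /kg gain)
    retained  = (final_dw * final_% - initial_dw * initial_%) / 100
    solid     = intake * (1 - ADC/100)
    rejected  = intake - retained
    dissolved = rejected - solid

The last two identities hold exactly by construction, so the budget
always closes: intake = retained + solid + dissolved.

Per-fish quantities are converted to per-kg-of-gain by dividing by the
dry-weight gain in grams and multiplying by 1000.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass

from .digestibility import CompositionSample

__all__ = [
    "TankObservation",
    "BodyComposition",
    "NutrientBudget",
    "DegenerateTankError",
    "fcr",
    "intake_per_fish",
    "per_kg_gain",
    "retained_per_fish",
    "solid_per_fish",
    "assemble_budget",
    "summarize_budgets",
    "read_tank_csv",
    "write_tank_csv",
    "write_budget_csv",
]


class DegenerateTankError(ValueError):
    """A tank with non-positive weight gain; ratios per kg gain are undefined."""


@dataclass
class TankObservation:
    """One tank's trial bookkeeping, dry-matter basis.

    Weights are per-fish dry weights in grams; ``feed_dry_per_fish`` is
    the total dry feed offered per fish over the trial.
    """

    tank_id: str
    diet_id: str
    n_fish: int
    initial_dry_weight_per_fish: float
    final_dry_weight_per_fish: float
    feed_dry_per_fish: float
    trial_days: int = 64

    def __post_init__(self) -> None:
        if self.n_fish <= 0:
            raise ValueError(f"n_fish must be > 0, got {self.n_fish}")
        if self.initial_dry_weight_per_fish <= 0:
            raise ValueError("initial dry weight must be > 0")
        if self.final_dry_weight_per_fish < self.initial_dry_weight_per_fish:
            raise ValueError(
                f"tank {self.tank_id}: final dry weight "
                f"{self.final_dry_weight_per_fish} < initial "
                f"{self.initial_dry_weight_per_fish}"
            )
        if self.feed_dry_per_fish <= 0:
            raise ValueError("feed per fish must be > 0")

    @property
    def gain_per_fish(self) -> float:
        """Dry-weight gain per fish over the trial, g."""
        return self.final_dry_weight_per_fish - self.initial_dry_weight_per_fish


@dataclass
class BodyComposition:
    """Whole-body nutrient concentration at one trial stage, % of dry mass."""

    stage: str  # "initial" | "final"
    nutrient_pct: float

    def __post_init__(self) -> None:
        if self.stage not in ("initial", "final"):
            raise ValueError(f"stage must be initial|final, got {self.stage!r}")
        if not (0.0 <= self.nutrient_pct <= 100.0):
            raise ValueError("nutrient_pct outside [0, 100]")


@dataclass
class NutrientBudget:
    """Mass-balance partition of one nutrient, g per kg dry-weight gain."""

    diet_id: str
    nutrient: str
    intake: float
    retained: float
    rejected: float
    solid: float
    dissolved: float
    fcr: float


def fcr(feed_intake: float, weight_gain: float) -> float:
    """Feed conversion ratio: feed consumed per unit of weight gained.

    Dimensionless when both arguments share a unit and basis.
    """
    if weight_gain <= 0:
        raise DegenerateTankError(
            f"weight gain must be > 0 to define FCR, got {weight_gain}"
        )
    return feed_intake / weight_gain


def intake_per_fish(obs: TankObservation, feed_nutrient_dry_pct: float) -> float:
    """Nutrient ingested per fish over the trial, g."""
    if not (0.0 <= feed_nutrient_dry_pct <= 100.0):
        raise ValueError("feed nutrient percent outside [0, 100]")
    return obs.feed_dry_per_fish * feed_nutrient_dry_pct / 100.0


def per_kg_gain(quantity_g_per_fish: float, obs: TankObservation) -> float:
    """Convert a per-fish quantity (g) to g per kg of dry-weight gain."""
    gain = obs.gain_per_fish
    if gain <= 0:
        raise DegenerateTankError(
            f"tank {obs.tank_id}: zero dry-weight gain, per-kg-gain undefined"
        )
    return quantity_g_per_fish / gain * 1000.0


def retained_per_fish(obs: TankObservation, initial: BodyComposition,
                      final: BodyComposition) -> float:
    """Body nutrient mass gained per fish over the trial, g.

    Final body nutrient mass minus initial body nutrient mass, each the
    product of the per-fish dry weight and the whole-body nutrient
    concentration at that stage.
    """
    if initial.stage != "initial" or final.stage != "final":
        raise ValueError("pass the initial- and final-stage compositions in order")
    return (
        obs.final_dry_weight_per_fish * final.nutrient_pct
        - obs.initial_dry_weight_per_fish * initial.nutrient_pct
    ) / 100.0


def solid_per_fish(intake_g_per_fish: float, adc_pct: float) -> float:
    """Undigested (fecal) nutrient per fish, g: the indigestible share of intake."""
    return intake_g_per_fish * (1.0 - adc_pct / 100.0)


def assemble_budget(
    obs: TankObservation,
    diet: CompositionSample,
    initial_body: BodyComposition,
    final_body: BodyComposition,
    adc_pct: float,
) -> NutrientBudget:
    """Compose the full nutrient budget for one tank.

    The closure identities (rejected = intake - retained and
    dissolved = rejected - solid) hold exactly; dissolved can be
    negative if retention plus solid waste exceed intake, which with
    real measurements signals inconsistent inputs rather than a bug.
    """
    intake_fish = intake_per_fish(obs, diet.nutrient_pct)
    retained_fish = retained_per_fish(obs, initial_body, final_body)
    solid_fish = solid_per_fish(intake_fish, adc_pct)

    intake = per_kg_gain(intake_fish, obs)
    retained = per_kg_gain(retained_fish, obs)
    solid = per_kg_gain(solid_fish, obs)
    rejected = intake - retained
    dissolved = rejected - solid

    return NutrientBudget(
        diet_id=obs.diet_id,
        nutrient=diet.nutrient,
        intake=intake,
        retained=retained,
        rejected=rejected,
        solid=solid,
        dissolved=dissolved,
        fcr=fcr(obs.feed_dry_per_fish, obs.gain_per_fish),
    )


def summarize_budgets(budgets: list[NutrientBudget]) -> dict[str, float]:
    """Mean and SEM of each budget field across replicate-tank budgets.

    Tanks are the experimental unit. Returns a flat dict with
    ``<field>`` means and ``<field>_se`` standard errors plus
    ``n_tanks``; all inputs must share diet and nutrient.
    """
    if not budgets:
        raise ValueError("no budgets to summarize")
    ids = {(b.diet_id, b.nutrient) for b in budgets}
    if len(ids) > 1:
        raise ValueError(f"mixed diet/nutrient budgets: {sorted(ids)}")
    n = len(budgets)
    out: dict[str, float] = {"n_tanks": n}
    for fld in ("intake", "retained", "rejected", "solid", "dissolved", "fcr"):
        vals = [getattr(b, fld) for b in budgets]
        mean = sum(vals) / n
        out[fld] = mean
        if n > 1:
            var = sum((v - mean) ** 2 for v in vals) / (n - 1)
            out[f"{fld}_se"] = math.sqrt(var / n)
        else:
            out[f"{fld}_se"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Tank file: CSV `tank_id,diet_id,n_fish,initial_dw_g,final_dw_g,feed_dw_g,days`

def write_tank_csv(tanks: list[TankObservation],
                   path: str | os.PathLike | io.TextIOBase) -> None:
    lines = ["tank_id,diet_id,n_fish,initial_dw_g,final_dw_g,feed_dw_g,days"]
    for t in tanks:
        lines.append(
            f"{t.tank_id},{t.diet_id},{t.n_fish},"
            f"{t.initial_dry_weight_per_fish:g},"
            f"{t.final_dry_weight_per_fish:g},"
            f"{t.feed_dry_per_fish:g},{t.trial_days}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_tank_csv(path: str | os.PathLike | io.TextIOBase) -> list[TankObservation]:
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    tanks = []
    for line in lines[1:]:
        if not line.strip():
            continue
        tank_id, diet_id, n_fish, idw, fdw, feed, days = line.split(",")
        tanks.append(TankObservation(
            tank_id=tank_id, diet_id=diet_id, n_fish=int(n_fish),
            initial_dry_weight_per_fish=float(idw),
            final_dry_weight_per_fish=float(fdw),
            feed_dry_per_fish=float(feed), trial_days=int(days),
        ))
    return tanks


def write_budget_csv(summaries: dict[tuple[str, str], dict[str, float]],
                     path: str | os.PathLike | io.TextIOBase) -> None:
    """Write per-diet x nutrient budget summaries, one row each.

    ``summaries`` maps (diet_id, nutrient) to the dict returned by
    :func:`summarize_budgets`.
    """
    fields = ("intake", "retained", "rejected", "solid", "dissolved", "fcr")
    header = ["diet_id", "nutrient", "n_tanks"]
    for f in fields:
        header += [f, f"{f}_se"]
    lines = [",".join(header)]
    for (diet_id, nutrient), s in summaries.items():
        row = [diet_id, nutrient, str(int(s["n_tanks"]))]
        for f in fields:
            row += [f"{s[f]:.6g}", f"{s[f + '_se']:.6g}"]
        lines.append(",".join(row))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
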