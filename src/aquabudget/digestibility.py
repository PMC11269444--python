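"""Marker-ratio apparent digestibility and digestible nutrient content.

The apparent digestibility coefficient (ADC) of a nutrient is estimated
from the shift in the nutrient:marker concentration ratio between diet
and feces. With an indigestible marker (here yttrium oxide at 1 % of the
diet), any nutrient that disappears from the nutrient:marker ratio
between ingestion and egestion was absorbed:

    ADC = 100 * [1 - (N_feces / N_diet) * (M_diet / M_feces)]

where N and M are the nutrient and marker concentrations in percent of
dry matter. The ratio structure makes the estimate invariant to any
consistent rescaling of either analyte, so no yttrium <-> yttrium-oxide
stoichiometric conversion is applied (it would cancel).

ADC estimates from noisy measurements can fall outside [0, 100]; they
are returned unclipped (clipping would bias replicate means) and a
warning is emitted so downstream users can flag them.
"""

from __future__ import annotations

import io
import math
import os
import warnings
from dataclasses import dataclass

__all__ = [
    "CompositionSample",
    "AdcResult",
    "adc",
    "digestible_content",
    "pool_adc",
    "read_composition_csv",
    "write_composition_csv",
]

MATERIALS = ("diet", "feces", "fish_body")


@dataclass
class CompositionSample:
    """Nutrient and marker concentrations of one material, dry-matter basis.

    ``marker_pct`` is required (and must be positive) for diet and feces
    samples; whole-body fish samples carry no marker.
    """

    material: str
    nutrient: str
    nutrient_pct: float
    marker_pct: float | None = None
    tank_id: str | None = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(
                f"material must be one of {MATERIALS}, got {self.material!r}"
            )
        if not (0.0 <= self.nutrient_pct <= 100.0):
            raise ValueError(
                f"nutrient_pct = {self.nutrient_pct!r} outside [0, 100]"
            )
        if self.material in ("diet", "feces"):
            if self.marker_pct is None or not (0.0 < self.marker_pct <= 100.0):
                raise ValueError(
                    f"{self.material} sample needs marker_pct in (0, 100], "
                    f"got {self.marker_pct!r}"
                )


@dataclass
class AdcResult:
    """Pooled ADC of one nutrient for one diet across replicate tanks."""

    diet_id: str
    nutrient: str
    adc_pct: float
    n_tanks: int
    se: float

    def __post_init__(self) -> None:
        if self.n_tanks < 1:
            raise ValueError("n_tanks must be >= 1")


def adc(diet: CompositionSample, feces: CompositionSample) -> float:
    """Apparent digestibility coefficient (percent) from the marker ratio.

    Raises on a zero diet nutrient or zero feces marker concentration
    (undefined ratio) and on mismatched nutrient identifiers. Returns
    the unclipped value; results outside [0, 100] trigger a warning.
    """
    if diet.nutrient != feces.nutrient:
        raise ValueError(
            f"nutrient mismatch: diet={diet.nutrient!r}, feces={feces.nutrient!r}"
        )
    if diet.nutrient_pct <= 0:
        raise ZeroDivisionError("diet nutrient concentration is zero: ADC undefined")
    if not feces.marker_pct or feces.marker_pct <= 0:
        raise ZeroDivisionError("feces marker concentration is zero: ADC undefined")
    if diet.marker_pct is None:
        raise ValueError("diet sample lacks a marker concentration")

    value = 100.0 * (
        1.0
        - (feces.nutrient_pct / diet.nutrient_pct)
        * (diet.marker_pct / feces.marker_pct)
    )
    if not (0.0 <= value <= 100.0):
        warnings.warn(
            f"ADC {value:.2f}% outside [0, 100] "
            f"(nutrient {diet.nutrient}, tank {feces.tank_id}); "
            "returned unclipped",
            stacklevel=2,
        )
    return value


def digestible_content(diet_nutrient_g_per_kg: float, adc_pct: float) -> float:
    """Digestible nutrient content of a feed, g per kg feed.

    The total nutrient content of the diet multiplied by the apparent
    digestibility coefficient; rounded to 2 decimals for reporting
    (e.g. total P 18.2 g/kg at ADC 73 % -> 13.29 g digestible P/kg).
    """
    if diet_nutrient_g_per_kg < 0:
        raise ValueError("nutrient content must be >= 0")
    return round(diet_nutrient_g_per_kg * adc_pct / 100.0, 2)


def pool_adc(per_tank_adcs: list[float], diet_id: str = "",
             nutrient: str = "") -> AdcResult:
    """Pool per-tank ADC estimates into a mean with its standard error.

    Tanks are the experimental unit; the SE is the SEM of the per-tank
    values (0 for a single tank, which is flagged with a warning).
    """
    if not per_tank_adcs:
        raise ValueError("cannot pool an empty list of ADC values")
    n = len(per_tank_adcs)
    mean = sum(per_tank_adcs) / n
    if n == 1:
        warnings.warn("single-tank ADC: SE reported as 0", stacklevel=2)
        se = 0.0
    else:
        var = sum((x - mean) ** 2 for x in per_tank_adcs) / (n - 1)
        se = math.sqrt(var / n)
    return AdcResult(diet_id=diet_id, nutrient=nutrient,
                     adc_pct=mean, n_tanks=n, se=se)


# ---------------------------------------------------------------------------
# Composition file format: CSV `tank_id,material,nutrient,nutrient_pct,marker_pct`
# (marker_pct empty for fish_body rows).

def write_composition_csv(samples: list[CompositionSample],
                          path: str | os.PathLike | io.TextIOBase) -> None:
    lines = ["tank_id,material,nutrient,nutrient_pct,marker_pct"]
    for s in samples:
        marker = "" if s.marker_pct is None else f"{s.marker_pct:g}"
        lines.append(
            f"{s.tank_id or ''},{s.material},{s.nutrient},{s.nutrient_pct:g},{marker}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_composition_csv(path: str | os.PathLike | io.TextIOBase) -> list[CompositionSample]:
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    samples = []
    for line in lines[1:]:
        if not line.strip():
            continue
        tank_id, material, nutrient, npct, mpct = line.split(",")
        samples.append(CompositionSample(
            material=material,
            nutrient=nutrient,
            nutrient_pct=float(npct),
            marker_pct=float(mpct) if mpct else None,
            tank_id=tank_id or None,
        ))
    return samples
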