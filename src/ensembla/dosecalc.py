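"""Chow-equivalent nutrient-intake arithmetic for supplement cocktails.

A mouse eating ~3 g chow and drinking ~4.8 mL water per day receives a
nutrient from both sources.  Expressing the combined daily intake as a
concentration in chow gives the *chow-equivalent* concentration:

    effective = (chow_conc · chow_g + water_conc · water_mL) / chow_g

with water density 1 g/mL so % w/v supplement mass is conc × mL.  Units
pass through unchanged (% w/w for amino acids, ppm for zinc).

Cocktails mix branched-chain amino acids (Leu:Ile:Val = 2:1:1), L-serine
and zinc in drinking water at 1/2, 1/4 or 1/8 of previously published
single-supplement doses.  The half cocktail's Ile/Val components are stored
at 0.225% — half the 0.45% full BCAA dose — which is the value consistent
with all the effective concentrations it produces.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "DietSpec",
    "CocktailPreset",
    "CHOW_5K54",
    "PRESETS",
    "effective_concentration",
    "cocktail_table",
]

NUTRIENTS = ("Ile", "Leu", "Val", "Ser", "Zn")
# display precision per nutrient: amino acids % to 2 decimals, zinc ppm integer
_PRECISION = {"Ile": 2, "Leu": 2, "Val": 2, "Ser": 2, "Zn": 0}


@dataclass(frozen=True)
class DietSpec:
    """Baseline chow composition plus a drinking-water supplement.

    Concentrations: % w/w in chow, % w/v in water for amino acids; ppm for
    minerals (handled identically, unit in = unit out).
    """

    chow_conc: Mapping[str, float]
    chow_intake_g_per_day: float = 3.0
    water_conc: Mapping[str, float] = field(default_factory=dict)
    water_intake_ml_per_day: float = 4.8

    def __post_init__(self) -> None:
        if self.chow_intake_g_per_day < 0 or self.water_intake_ml_per_day < 0:
            raise ValueError("intakes must be non-negative")
        for name, conc in {**dict(self.chow_conc), **dict(self.water_conc)}.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}")


@dataclass(frozen=True)
class CocktailPreset:
    """Named drinking-water cocktail (per-nutrient water concentrations)."""

    name: str
    water_conc: Mapping[str, float]


# LabDiet 5K54 maintenance chow
CHOW_5K54: dict[str, float] = {
    "Ile": 0.74,
    "Leu": 1.49,
    "Val": 0.87,
    "Ser": 0.83,
    "Zn": 81.0,
}

PRESETS: dict[str, CocktailPreset] = {
    "half": CocktailPreset(
        "half", {"Ile": 0.225, "Leu": 0.45, "Val": 0.225, "Ser": 1.0, "Zn": 20.0}
    ),
    "quarter": CocktailPreset(
        "quarter", {"Ile": 0.1125, "Leu": 0.225, "Val": 0.1125, "Ser": 1.0, "Zn": 20.0}
    ),
    "eighth": CocktailPreset(
        "eighth", {"Ile": 0.056, "Leu": 0.1125, "Val": 0.056, "Ser": 0.5, "Zn": 20.0}
    ),
}


def _round_half_up(x: float, ndigits: int) -> float:
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def effective_concentration(
    d: DietSpec, nutrient: str, rounded: bool = False
) -> float:
    """Chow-equivalent concentration of one nutrient.

    Full precision by default; ``rounded`` applies the display precision
    (2 decimals for %, integer for ppm, half-up).
    """
    if nutrient not in d.chow_conc:
        raise KeyError(f"nutrient {nutrient!r} missing from chow composition")
    if d.chow_intake_g_per_day == 0:
        raise ValueError("chow intake must be positive")
    chow = float(d.chow_conc[nutrient])
    water = float(dict(d.water_conc).get(nutrient, 0.0))
    eff = (
        chow * d.chow_intake_g_per_day + water * d.water_intake_ml_per_day
    ) / d.chow_intake_g_per_day
    if rounded:
        eff = _round_half_up(eff, _PRECISION.get(nutrient, 2))
    return eff


def cocktail_table(
    preset: CocktailPreset | str, chow: DietSpec | None = None
) -> pd.DataFrame:
    """Per-nutrient table of chow, water, and effective concentrations."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if chow is None:
        chow = DietSpec(chow_conc=CHOW_5K54)
    missing = [n for n in NUTRIENTS if n not in chow.chow_conc]
    if missing:
        raise KeyError(f"chow baseline missing nutrients {missing}")
    d = DietSpec(
        chow_conc=chow.chow_conc,
        chow_intake_g_per_day=chow.chow_intake_g_per_day,
        water_conc=preset.water_conc,
        water_intake_ml_per_day=chow.water_intake_ml_per_day,
    )
    rows = []
    for n in NUTRIENTS:
        rows.append(
            {
                "nutrient": n,
                "unit": "ppm" if n == "Zn" else "%",
                "chow": float(chow.chow_conc[n]),
                "water": float(dict(preset.water_conc).get(n, 0.0)),
                "effective": effective_concentration(d, n),
                "effective_display": effective_concentration(d, n, rounded=True),
            }
        )
    return pd.DataFrame(rows).set_index("nutrient")
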