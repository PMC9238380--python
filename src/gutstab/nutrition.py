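"""Macronutrient energy bookkeeping for prescribed intervention diets.

Converts a diet's prescribed grams per day of carbohydrate, protein and
fat into the fraction of total energy each macronutrient supplies, using
the Atwater general factors (4 kcal/g carbohydrate, 4 kcal/g protein,
9 kcal/g fat). Used to check that a prescribed diet hits its target
macronutrient distribution, e.g. a 40/30/30 protein/carbohydrate/fat
high-protein diet or a 10/60/30 protein/carbohydrate/fat
high-carbohydrate diet.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ATWATER_KCAL_PER_G", "MacronutrientEnergy", "atwater_energy_fractions"]

ATWATER_KCAL_PER_G = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class MacronutrientEnergy:
    """Energy content and percent-of-energy split of one diet."""

    kcal: dict[str, float]
    total_kcal: float
    percent: dict[str, float]


def atwater_energy_fractions(
    carbohydrate_g: float, protein_g: float, fat_g: float
) -> MacronutrientEnergy:
    """Percent of daily energy from each macronutrient via Atwater factors."""
    grams = {
        "carbohydrate": carbohydrate_g,
        "protein": protein_g,
        "fat": fat_g,
    }
    for name, g in grams.items():
        if g < 0:
            raise ValueError(f"{name} grams must be >= 0, got {g}")
    kcal = {name: g * ATWATER_KCAL_PER_G[name] for name, g in grams.items()}
    total = sum(kcal.values())
    if total == 0:
        raise ValueError("diet supplies zero energy")
    percent = {name: 100.0 * e / total for name, e in kcal.items()}
    return MacronutrientEnergy(kcal=kcal, total_kcal=total, percent=percent)
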