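"""I2KI (Lugol-type) staining-solution preparation bookkeeping.

Total iodine molarity counts iodine *atoms* from both solutes: each mole of
molecular iodine I2 contributes two, each mole of potassium iodide KI one.
The w/v concentration accounts for the small volume increase when the solid
solutes dissolve, which is why "3 g + 6 g per 100 mL" style recipes come out
slightly below their nominal percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SolutionRecipe",
    "total_iodine_mmol",
    "dilution_molarity",
    "wv_percent",
    "MOLAR_MASS_I2",
    "MOLAR_MASS_KI",
    "DENSITY_I2",
    "DENSITY_KI",
]

MOLAR_MASS_I2 = 253.81  # g/mol
MOLAR_MASS_KI = 166.00  # g/mol
DENSITY_I2 = 4.93       # g/mL, solid
DENSITY_KI = 3.12       # g/mL, solid


@dataclass(frozen=True)
class SolutionRecipe:
    """Solute masses (g) and solvent volume (L); ``final_volume`` if diluted."""

    mass_I2: float
    mass_KI: float
    solvent_volume: float
    final_volume: float | None = None

    def __post_init__(self) -> None:
        if self.mass_I2 < 0 or self.mass_KI < 0:
            raise ValueError("solute masses must be non-negative")
        if self.solvent_volume <= 0:
            raise ValueError("solvent volume must be positive")
        if self.final_volume is not None and self.final_volume <= 0:
            raise ValueError("final volume must be positive")


def total_iodine_mmol(recipe: SolutionRecipe) -> float:
    """Millimoles of iodine atoms from both solutes: 2 n(I2) + n(KI)."""
    return 1000.0 * (2.0 * recipe.mass_I2 / MOLAR_MASS_I2 + recipe.mass_KI / MOLAR_MASS_KI)


def dilution_molarity(n_iodine_mmol: float, final_volume_l: float) -> float:
    """Molarity (mmol/L) after dilution to ``final_volume_l`` litres."""
    if final_volume_l <= 0:
        raise ValueError("final volume must be positive")
    return n_iodine_mmol / final_volume_l


def molarity(recipe: SolutionRecipe) -> float:
    """Total iodine molarity of the recipe at its final (or solvent) volume."""
    vol = recipe.final_volume if recipe.final_volume is not None else recipe.solvent_volume
    return dilution_molarity(total_iodine_mmol(recipe), vol)


def wv_percent(
    recipe: SolutionRecipe,
    density_I2: float = DENSITY_I2,
    density_KI: float = DENSITY_KI,
) -> float:
    """Weight/volume concentration (g solute per 100 mL solution), in percent.

    The solution volume is the solvent volume plus the volume the dissolved
    solids add (mass over solid density) — the reason a nominal 3 % recipe
    assays at 2.97 %.
    """
    mass = recipe.mass_I2 + recipe.mass_KI
    if mass == 0.0:
        return 0.0
    total_ml = (
        recipe.solvent_volume * 1000.0
        + recipe.mass_I2 / density_I2
        + recipe.mass_KI / density_KI
    )
    return 100.0 * mass / total_ml
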