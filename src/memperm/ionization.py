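"""Henderson–Hasselbalch speciation and intrinsic partition coefficients.

Weak bases such as d-sotalol (aqueous pKa values 8.3 and 9.8) coexist in
charged and neutral forms at physiological pH; only the neutral form
accumulates appreciably in the membrane. These helpers convert between
apparent (pH-dependent) and intrinsic (neutral-form) partition
coefficients, compute speciation fractions, and express the pKa−pH gap
as a free-energy penalty for deprotonation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import LN10, kt
from .pmf_analysis import dG_from_K

__all__ = [
    "IonizationModel",
    "protonated_fraction",
    "neutral_fraction",
    "intrinsic_K",
    "deprotonation_penalty",
    "dG_from_K",
]


@dataclass
class IonizationModel:
    """Acid-dissociation constants of one solute at a working pH."""

    pKa_values: tuple[float, ...]
    pH: float
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.pKa_values)):
            raise ValueError("pKa values must be finite")
        if not 0 < self.pH < 14:
            raise ValueError(f"pH must lie in (0, 14), got {self.pH}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def fractions(self) -> dict[str, float]:
        """Protonated/deprotonated fractions at the first (governing) pKa."""
        f = protonated_fraction(self.pKa_values[0], self.pH)
        return {"protonated": f, "deprotonated": 1.0 - f}


def protonated_fraction(pKa: float, pH: float) -> float:
    """Fraction of the protonated (e.g. cationic) form: 1/(1 + 10^(pH−pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def neutral_fraction(pKa: float, pH: float) -> float:
    """Fraction of the deprotonated (neutral) form, 1 − protonated."""
    return 1.0 - protonated_fraction(pKa, pH)


def intrinsic_K(K_apparent: float, pKa: float, pH: float, mode: str = "paper") -> float:
    """Intrinsic (neutral-form) K from an apparent, pH-dependent K.

    mode="paper": K_app · 10^(pKa−pH) — the customary conversion, exact in
    the pH ≪ pKa limit where essentially all solute is protonated.
    mode="exact_hh": K_app · (1 + 10^(pKa−pH)) — divides by the exact
    neutral fraction; always ≥ the first form for pKa > pH. The first is
    the default so published apparent→intrinsic conversions reproduce
    as printed.
    """
    if K_apparent <= 0:
        raise ValueError("K_apparent must be positive")
    if mode == "paper":
        return K_apparent * 10.0 ** (pKa - pH)
    if mode == "exact_hh":
        return K_apparent * (1.0 + 10.0 ** (pKa - pH))
    raise ValueError(f"unknown mode {mode!r}")


def deprotonation_penalty(pKa: float, pH: float, temperature: float = 310.0) -> float:
    """Free-energy cost (kcal/mol) of deprotonating at the given pH.

    ΔG = ln10 · k_B T · (pKa − pH): positive when the protonated form
    dominates, i.e. shedding the proton costs energy.
    """
    return LN10 * kt(temperature) * (pKa - pH)
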