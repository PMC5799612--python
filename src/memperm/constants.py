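"""Physical constants and unit conversions used throughout the package.

All energies are kcal/mol, lengths Å, times ps unless a function says
otherwise. Diffusivities are carried internally in Å²/ps and converted to
cm²/s only at reporting boundaries.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB_KCAL: float = 1.9872041e-3

#: ln(10), the factor turning pKa differences into free energies.
LN10: float = 2.302585092994046

#: 1 Å²/ps expressed in cm²/s.
A2_PER_PS_TO_CM2_PER_S: float = 1e-4

#: 1 Å expressed in cm.
ANGSTROM_TO_CM: float = 1e-8

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 310.0


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
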