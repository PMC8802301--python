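"""Physical constants and unit conversions used throughout the package.

All energies are kept in kcal/mol and distances in Å.  Heat capacities are
conventionally reported in cal·mol⁻¹·K⁻¹ in the hydrophobic-hydration
literature, so a single centralized converter is provided.
"""

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹ (i.e. the molar gas constant R).
KB_KCAL = 0.0019872041

#: kcal → cal.
KCAL_TO_CAL = 1000.0


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
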