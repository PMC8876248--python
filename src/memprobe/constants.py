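"""Physical constants and unit conventions.

Units used throughout the package: length nm, time ps, energy kJ/mol,
temperature K, concentration mol/dm^3.  Conversions happen only at I/O
boundaries.
"""

#: Gas constant, kJ mol^-1 K^-1
R_KJ = 8.31446261815324e-3

#: Atomic mass unit in kg
AMU_KG = 1.66053906660e-27

#: Default simulation temperature (K)
T_SIM = 298.15

#: Default titration temperature (K), 37 degC
T_TITRATION = 310.15


def rt(temperature: float) -> float:
    """Thermal energy RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ * temperature
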