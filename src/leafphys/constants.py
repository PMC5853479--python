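"""Physical constants and unit helpers used throughout the package."""

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.314462618  # J / (mol K)

#: Default recording temperature, K (22 degC, low end of typical room range).
DEFAULT_TEMPERATURE_K = 295.15


def thermal_voltage_mv(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """R*T/F in millivolts at the given absolute temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


def sphere_surface_area_cm2(diameter_um: float) -> float:
    """Surface area of a spherical protoplast, cm^2, from its diameter in um.

    area = pi * d^2 for a sphere of diameter d.
    """
    import math

    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    d_cm = diameter_um * 1e-4
    return math.pi * d_cm * d_cm
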