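"""Unit conventions and converters.

Internal units are metre / day / mol / kelvin throughout the package.  The
degradation literature quotes rate constants both per second and per day; all
shipped parameter sets are per-day, and these helpers convert at the interface.
"""

SECONDS_PER_DAY = 86400.0

#: Gas constant, J/(mol K).  Activation energies are per-mole joules.
GAS_CONSTANT = 8.314


def per_second_to_per_day(value: float) -> float:
    """Convert a first-order rate (1/s) to 1/day."""
    return value * SECONDS_PER_DAY


def per_day_to_per_second(value: float) -> float:
    """Convert a first-order rate (1/day) to 1/s."""
    return value / SECONDS_PER_DAY


def m2_per_second_to_m2_per_day(value: float) -> float:
    """Convert a diffusivity (m^2/s) to m^2/day."""
    return value * SECONDS_PER_DAY


def m2_per_day_to_m2_per_second(value: float) -> float:
    """Convert a diffusivity (m^2/day) to m^2/s."""
    return value / SECONDS_PER_DAY


def days_to_seconds(value: float) -> float:
    return value * SECONDS_PER_DAY


def seconds_to_days(value: float) -> float:
    return value / SECONDS_PER_DAY


#: Diffusivity of small degradation products / bioactive molecules in aqueous
#: medium and surrounding tissue, 1e-9 m^2/s expressed per day.
AQUEOUS_DIFFUSIVITY_M2_PER_DAY = m2_per_second_to_m2_per_day(1e-9)
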