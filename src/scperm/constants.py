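"""Physical constants and the package's internal unit system.

Everything downstream of the I/O boundary works in nm, ps, kJ/mol and K.
Permeabilities are converted to cm/s only when reported.
"""
from __future__ import annotations

from dataclasses import dataclass

#: Universal gas constant in kJ mol^-1 K^-1.
R_KJ_PER_MOL_K: float = 8.31446e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE_K: float = 303.15

#: 1 nm/ps expressed in cm/s.
NM_PER_PS_TO_CM_PER_S: float = 1.0e5


def thermal_energy(temperature: float) -> float:
    """RT in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering the permeability integral."""

    R: float = R_KJ_PER_MOL_K
    default_temperature: float = DEFAULT_TEMPERATURE_K
    nm_ps_to_cm_s: float = NM_PER_PS_TO_CM_PER_S


CONSTANTS = PhysicalConstants()
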