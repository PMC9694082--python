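"""Physical constants and the thermal voltage.

The bi-ionic permeability relation and the constant-field (GHK) flux model
both depend on temperature only through the thermal voltage RT/F.  The
recording temperature is therefore a required piece of metadata for any
permeability calculation: at 22 degC, RT/F is about 25.4 mV, and a 1 degC
change shifts every fitted reversal potential's interpretation by ~0.3%.
"""

from __future__ import annotations

from dataclasses import dataclass

FARADAY = 96485.33  # C / mol
GAS_CONSTANT = 8.314  # J / (mol K)
DEFAULT_TEMPERATURE_K = 295.15  # 22 degC, typical room-temperature patch rig


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    Parameters
    ----------
    faraday : float
        C/mol.
    gas_constant : float
        J/(mol K).
    temperature : float
        Absolute temperature in kelvin; must be positive.
    """

    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.faraday <= 0 or self.gas_constant <= 0:
            raise ValueError("faraday and gas_constant must be positive")

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in millivolts (~25.43 mV at the 22 degC default)."""
        return 1e3 * self.gas_constant * self.temperature / self.faraday

    @classmethod
    def at_celsius(cls, celsius: float) -> "PhysicalConstants":
        return cls(temperature=273.15 + celsius)
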