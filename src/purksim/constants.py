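"""Physical constants and fixed temperatures used throughout the model.

All membrane voltages are millivolts, time is milliseconds, concentrations
are millimolar, current densities are mA/cm^2 unless a function states
otherwise.
"""

from dataclasses import dataclass

#: Faraday constant, C/mol.
FARADAY = 96485.332
#: Gas constant, J/(mol K).
GAS_CONSTANT = 8.31446

#: Model temperature, degrees Celsius.
TEMP_C = 36.0
#: Temperature used by the fixed-concentration GHK flux of the somatic
#: P-type Ca current, Kelvin.  This current deliberately does not track
#: the live shell concentration or the 36 C bath temperature.
GHK_TEMP_K = 295.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants held fixed for a simulation run."""

    F: float = FARADAY
    R: float = GAS_CONSTANT
    temp_c: float = TEMP_C

    @property
    def temp_k(self) -> float:
        return self.temp_c + 273.15

    @property
    def mt(self) -> float:
        """Q10-style factor 3^((T-37)/10) applied to dendritic gate rates."""
        return 3.0 ** ((self.temp_c - 37.0) / 10.0)

    @property
    def ft(self) -> float:
        """Q10-style factor 2.3^((T-36)/10) applied to the M-type tau."""
        return 2.3 ** ((self.temp_c - 36.0) / 10.0)


CONSTANTS = PhysicalConstants()
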