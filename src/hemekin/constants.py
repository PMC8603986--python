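"""Physical constants and thermodynamic conditions.

All energies in this package are molar (kJ/mol), so the "Boltzmann
constant" is realized as the gas constant R = 8.314e-3 kJ/(mol K).
Rates are s^-1, viscosities cP, ligand pressures torr (a carried unit
label, never converted).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kJ/(mol K) — the molar-energy realization of k_B.
GAS_CONSTANT_KJ_PER_MOL_K: float = 8.314462618e-3


@dataclass(frozen=True)
class Conditions:
    """Thermodynamic conditions for rate and equilibrium calculations.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin. Must be positive.
    k_B : float
        Boltzmann constant in the molar-energy convention, i.e. the gas
        constant in kJ/(mol K). Override only to change energy units.
    """

    T: float
    k_B: float = GAS_CONSTANT_KJ_PER_MOL_K

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if not self.k_B > 0:
            raise ValueError(f"k_B must be positive, got {self.k_B}")

    @property
    def thermal_energy(self) -> float:
        """k_B * T in kJ/mol."""
        return self.k_B * self.T
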