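"""Physical constants shared by every module.

A single frozen instance (:data:`CONSTANTS`) is used throughout so that the
stopping-power, transport and monitoring modules agree bit-for-bit on
``m_e c^2``, ``r_e``, ``N_Av`` and the fine-structure constant.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 values in the units used internally (MeV, cm, mol)."""

    electron_mass_energy: float = 0.51099895000  # m_e c^2, MeV
    classical_electron_radius: float = 2.8179403262e-13  # r_e, cm
    avogadro: float = 6.02214076e23  # N_Av, 1/mol
    fine_structure_constant: float = 7.2973525693e-3  # alpha, dimensionless

    def __post_init__(self) -> None:
        for name in (
            "electron_mass_energy",
            "classical_electron_radius",
            "avogadro",
            "fine_structure_constant",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = PhysicalConstants()

#: MeV -> Gy conversion for dose expressed per gram (1 MeV/g in J/kg).
MEV_PER_GRAM_TO_GY = 1.602176634e-10

#: Atomic rest-energy unit u in MeV/c^2.
ATOMIC_MASS_UNIT_MEV = 931.49410242
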