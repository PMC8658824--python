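"""Physical constants used throughout the thermodynamic calculations.

The gas constant is kept in kcal so that all activation parameters come
out in kcal/mol, the unit conventional in the enzyme-adaptation
literature. Boltzmann's and Planck's constants appear only in the
dimensionless ratio kB*T/(h*kcat) inside the Eyring equation, so their
SI units cancel.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering Arrhenius/Eyring analysis.

    Attributes
    ----------
    R_kcal : gas constant, kcal mol^-1 K^-1
    kB : Boltzmann constant, J K^-1 (2019 SI exact value)
    h : Planck constant, J s (2019 SI exact value)
    """

    R_kcal: float = 1.9872e-3
    kB: float = 1.380649e-23
    h: float = 6.62607015e-34


#: Default constants instance shared by the whole package.
CONSTANTS = PhysicalConstants()
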