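"""Physical constants and the thermodynamic state of the analysis.

All free energies in the package are in kcal/mol; lengths in Å.  The
standard state is 1 M, i.e. one molecule per V_std ≈ 1660.5 Å³, which
enters the analytic restraint-release term.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Gas constant, kcal/(mol K)
GAS_CONSTANT_KCAL = 1.987204e-3

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants at a fixed temperature.

    Parameters
    ----------
    T : float
        Absolute temperature in K.  Default 298 K, the production
        temperature of the equilibration and free-energy simulations.
    R : float
        Gas constant in kcal/(mol K).
    C_std : float
        Standard concentration in mol/L (1 M defines the standard state).
    """

    T: float = 298.0
    R: float = GAS_CONSTANT_KCAL
    C_std: float = 1.0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValidationError(f"temperature must be positive, got {self.T}")
        if not self.R > 0:
            raise ValidationError(f"gas constant must be positive, got {self.R}")
        if not self.C_std > 0:
            raise ValidationError(f"standard concentration must be positive, got {self.C_std}")

    @property
    def RT(self) -> float:
        """Thermal energy RT, kcal/mol (≈ 0.5922 at 298 K)."""
        return self.R * self.T

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(RT), mol/kcal."""
        return 1.0 / (self.R * self.T)

    @property
    def V_std(self) -> float:
        """Standard-state volume per molecule, Å³.

        1 L = 10²⁷ Å³, so V_std = 10²⁷ / (C_std · N_A) ≈ 1660.5 Å³ at 1 M.
        """
        return 1.0e27 / (self.C_std * AVOGADRO)


#: Module-level default at 298 K.
DEFAULT = Constants()
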