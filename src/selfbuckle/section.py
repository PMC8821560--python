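"""Material and geometry of the cylindrical column.

A tree trunk is idealised as a solid circular cylinder of radius ``r``
clamped at the ground, with elastic modulus ``E`` and a reference density
``rho0``.  All derived section quantities, including the scale constant
``omega`` that nondimensionalises axial position in the buckling problem,
live on :class:`ColumnSection`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ColumnSection:
    """Solid circular section of a heavy cantilever column.

    Parameters
    ----------
    E : float
        Elastic modulus, N/m^2.
    rho0 : float
        Reference density, kg/m^3.  For the trunk-plus-branches models
        (E/F) this is the trunk density.
    g : float
        Gravitational acceleration, m/s^2.
    r : float
        Radius, m.

    Derived attributes
    ------------------
    A : float
        Cross-sectional area pi r^2, m^2.
    I : float
        Second moment of area pi r^4 / 4, m^4.
    gamma0 : float
        Unit weight rho0 * g, N/m^3.
    omega : float
        Scale constant (rho0 g A / (E I))^(1/3) = (4 rho0 g / (E r^2))^(1/3),
        1/m.  The dimensionless critical length is xi_c = omega * l_c.
    """

    E: float
    rho0: float
    g: float
    r: float
    A: float = field(init=False)
    I: float = field(init=False)
    gamma0: float = field(init=False)
    omega: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("E", "rho0", "g", "r"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        object.__setattr__(self, "A", math.pi * self.r**2)
        object.__setattr__(self, "I", math.pi * self.r**4 / 4.0)
        object.__setattr__(self, "gamma0", self.rho0 * self.g)
        object.__setattr__(
            self, "omega", (4.0 * self.rho0 * self.g / (self.E * self.r**2)) ** (1.0 / 3.0)
        )


def build_section(E: float, rho0: float, g: float, r: float) -> ColumnSection:
    """Validate the physical constants and derive the section quantities."""
    return ColumnSection(E=E, rho0=rho0, g=g, r=r)
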