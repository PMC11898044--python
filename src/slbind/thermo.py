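"""Conversions between dissociation constant and standard binding free energy.

At equilibrium the standard-state Gibbs free energy of binding relates to
the dissociation constant through

    dG0 = R * T * ln(K_D)

with K_D in molar, dG0 in kcal/mol, R the ideal gas constant in
kcal mol-1 K-1 and T the absolute temperature. Tighter binders have
smaller K_D and hence more negative dG0. All experimental labels in this
package are on this scale, evaluated at T = 298.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Ideal gas constant, kcal mol-1 K-1 (CODATA value to 7 significant figures).
R_KCAL = 1.987204e-3

#: Reference temperature in Kelvin used for all label conversions.
T_REF = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature bundle for unit-safe conversions."""

    R: float = R_KCAL
    T: float = T_REF

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")


def dg_from_kd(kd: float, T: float = T_REF) -> float:
    """Standard binding free energy (kcal/mol) from a dissociation constant (M).

    Strictly increasing in ``kd``; negative for sub-molar constants.
    Raises ValueError for non-positive ``kd`` (log domain).
    """
    if not kd > 0:
        raise ValueError(f"dissociation constant must be positive, got {kd!r} M")
    c = ThermoConstants(T=T)
    return c.R * c.T * math.log(kd)


def kd_from_dg(dg: float, T: float = T_REF) -> float:
    """Dissociation constant (M) from a binding free energy (kcal/mol)."""
    c = ThermoConstants(T=T)
    return math.exp(dg / (c.R * c.T))
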