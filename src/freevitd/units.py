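"""Clinical unit handling for the binding-equilibrium calculation.

Free-hormone equilibrium arithmetic needs the carrier proteins in molar
concentration, while clinical laboratories report mass concentrations in
analyte-specific units (albumin in g/dL, VDBP in µg/mL, vitamin D
metabolites in ng/mL).  This module owns the conversion and the physical
constants: binding affinities and molecular weights.

The affinity constants are the classical single-site equilibrium values for
25(OH)D binding: Ka = 8.00 × 10⁸ M⁻¹ for VDBP and 6.00 × 10⁵ M⁻¹ for
albumin.  Molecular weights are the conventional companions of those
constants (25(OH)D 400.64 g/mol, VDBP 58 kDa, albumin 66.43 kDa); they can
be overridden through :class:`BindingConstants` if a different convention is
required.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigError, DomainError

__all__ = ["Analyte", "BindingConstants", "DEFAULT_CONSTANTS", "to_molar", "from_molar"]


class Analyte(enum.Enum):
    """Analytes with a fixed clinical native unit.

    The value of each member is the native unit label.  The native units are
    deliberately fixed — inputs in other dialects (e.g. nmol/L for 25(OH)D)
    must be converted by the caller before entering the package.
    """

    D25_TOTAL = "ng/mL"
    D25_3 = "ng/mL"
    D25_2 = "ng/mL"
    VDBP = "ug/mL"
    ALBUMIN = "g/dL"

    @property
    def native_unit(self) -> str:
        return self.value


# multiplicative factor taking the native unit to g/L
_TO_G_PER_L = {
    "ng/mL": 1e-6,
    "ug/mL": 1e-3,
    "g/dL": 10.0,
}


@dataclass(frozen=True)
class BindingConstants:
    """Equilibrium affinities (M⁻¹) and molecular weights (g/mol).

    ``ka_dbp`` must exceed ``ka_alb`` — VDBP is the high-affinity carrier —
    and all molecular weights must be strictly positive.
    """

    ka_dbp: float = 8.00e8
    ka_alb: float = 6.00e5
    mw_25ohd: float = 400.64
    mw_vdbp: float = 58_000.0
    mw_albumin: float = 66_430.0

    def __post_init__(self) -> None:
        if not (self.ka_dbp > self.ka_alb > 0):
            raise ConfigError(
                f"require ka_dbp > ka_alb > 0, got {self.ka_dbp!r}, {self.ka_alb!r}"
            )
        for name in ("mw_25ohd", "mw_vdbp", "mw_albumin"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"molecular weight {name} must be > 0")

    def molecular_weight(self, analyte: Analyte) -> float:
        if analyte in (Analyte.D25_TOTAL, Analyte.D25_3, Analyte.D25_2):
            return self.mw_25ohd
        if analyte is Analyte.VDBP:
            return self.mw_vdbp
        if analyte is Analyte.ALBUMIN:
            return self.mw_albumin
        raise ConfigError(f"no molecular weight configured for {analyte!r}")


DEFAULT_CONSTANTS = BindingConstants()


def to_molar(
    value: float, analyte: Analyte, constants: BindingConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert a concentration in the analyte's native unit to mol/L."""
    if not isinstance(analyte, Analyte):
        raise ConfigError(f"unknown analyte {analyte!r}")
    if value < 0:
        raise DomainError(f"negative concentration for {analyte.name}: {value}")
    grams_per_l = value * _TO_G_PER_L[analyte.native_unit]
    return grams_per_l / constants.molecular_weight(analyte)


def from_molar(
    value: float, analyte: Analyte, constants: BindingConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert mol/L back to the analyte's native clinical unit.

    Exact inverse of :func:`to_molar`.
    """
    if not isinstance(analyte, Analyte):
        raise ConfigError(f"unknown analyte {analyte!r}")
    if value < 0:
        raise DomainError(f"negative molar concentration for {analyte.name}: {value}")
    grams_per_l = value * constants.molecular_weight(analyte)
    return grams_per_l / _TO_G_PER_L[analyte.native_unit]
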