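"""Participant records and VDBP phenotype encoding."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

from .errors import DomainError, MissingInputError, SchemaError

__all__ = ["PHENOTYPES", "normalize_phenotype", "ParticipantRecord"]

# Canonical diplotype labels. Gc-globulin (VDBP) has three common protein
# variants — Gc1f, Gc1s, Gc2 — giving six unordered diplotypes. The display
# convention puts Gc2 first when present, otherwise Gc1f before Gc1s.
PHENOTYPES = (
    "Gc1f/Gc1f",
    "Gc1f/Gc1s",
    "Gc1s/Gc1s",
    "Gc2/Gc1f",
    "Gc2/Gc1s",
    "Gc2/Gc2",
)

REFERENCE_PHENOTYPE = PHENOTYPES[0]

_ALLELE_ORDER = {"gc2": 0, "gc1f": 1, "gc1s": 2}
_ALLELE_CANON = {"gc2": "Gc2", "gc1f": "Gc1f", "gc1s": "Gc1s"}


def normalize_phenotype(label: str) -> str:
    """Normalize a Gc diplotype string to its canonical label.

    The diplotype is an unordered pair, so ``"Gc1s/Gc2"`` and ``"Gc2/Gc1s"``
    are the same phenotype; parsing is case-insensitive.
    """
    if not isinstance(label, str):
        raise SchemaError(f"phenotype must be a string, got {type(label).__name__}")
    parts = [p.strip().lower() for p in label.split("/")]
    if len(parts) != 2 or any(p not in _ALLELE_ORDER for p in parts):
        raise SchemaError(f"unrecognized VDBP phenotype {label!r}")
    parts.sort(key=_ALLELE_ORDER.__getitem__)
    return "/".join(_ALLELE_CANON[p] for p in parts)


# Variables that are log transformed wherever they enter a regression; all
# are right-skewed biomarkers.
LOG_VARIABLES = frozenset(
    {"d25_3", "d25_2", "vdbp", "d1_25_3", "d24_25_3", "ipth", "ifgf23", "total_25ohd"}
)

# Core biomarker fields and their clinical units (also the CSV column names,
# which embed the unit so that unit errors fail loudly at parse time).
CORE_FIELDS = {
    "albumin": "g_dl",
    "d25_3": "ng_ml",
    "d25_2": "ng_ml",
    "vdbp": "ug_ml",
    "d1_25_3": "pg_ml",
    "d24_25_3": "ng_ml",
    "ipth": "pg_ml",
}


# derived 0/1 indicators usable as equation variables
_INDICATORS = {
    "sex_female": ("sex", ("f", "female")),
    "race_black": ("race", ("black",)),
    "site_pittsburgh": ("site", ("pittsburgh",)),
}


@dataclass
class ParticipantRecord:
    """One participant's biomarkers, in fixed clinical units.

    Units: albumin g/dL; 25(OH)D3, 25(OH)D2 and 24,25(OH)2D3 ng/mL; VDBP
    µg/mL; 1,25(OH)2D3, iPTH and measured free 25(OH)D pg/mL.  ``covariates``
    holds optional extras (age in years, sex, race, BMI in kg/m², season,
    site, diabetes flag, eGFR in mL/min/1.73 m², calcium and phosphate in
    mg/dL, iFGF-23 in pg/mL).
    """

    albumin: Optional[float] = None
    d25_3: Optional[float] = None
    d25_2: Optional[float] = None
    vdbp: Optional[float] = None
    d1_25_3: Optional[float] = None
    d24_25_3: Optional[float] = None
    ipth: Optional[float] = None
    phenotype: Optional[str] = None
    measured_free: Optional[float] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phenotype is not None:
            self.phenotype = normalize_phenotype(self.phenotype)
        for name in CORE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")
        if self.measured_free is not None and self.measured_free <= 0:
            raise DomainError(
                f"measured_free must be > 0, got {self.measured_free}"
            )

    def get(self, variable: str) -> Any:
        """Look up a variable by canonical name, in core fields then
        covariates. ``total_25ohd`` is derived as d25_3 + d25_2; 0/1
        indicator names (``sex_female``, ``race_black``, ``site_pittsburgh``,
        ``season_<name>``) are derived from the categorical covariates."""
        if variable in _INDICATORS:
            source, positive = _INDICATORS[variable]
            raw = self.covariates.get(source)
            if raw is None:
                return None
            return 1.0 if str(raw).strip().lower() in positive else 0.0
        if variable.startswith("season_"):
            raw = self.covariates.get("season")
            if raw is None:
                return None
            return 1.0 if str(raw).strip().lower() == variable[7:] else 0.0
        if variable == "total_25ohd":
            if self.d25_3 is None:
                return None
            return self.d25_3 + (self.d25_2 or 0.0)
        if variable == "phenotype":
            return self.phenotype
        if variable in CORE_FIELDS or variable == "measured_free":
            return getattr(self, variable)
        return self.covariates.get(variable)

    def require(self, variable: str, context: str = "") -> float:
        value = self.get(variable)
        if value is None:
            raise MissingInputError(variable, context)
        return value
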