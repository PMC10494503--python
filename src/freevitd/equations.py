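"""Free 25(OH)D estimating equations.

Implements linear estimating equations of the form

    free = b0 + Σ b_i · t_i(x_i) + Σ c_jk · ln(x_j) · ln(x_k) + offset(phenotype)

where t_i is identity or the natural logarithm, plus the classical
single-site binding-equilibrium ("Bikle") calculation

    free = total 25(OH)D / (1 + Ka_dbp·[VDBP] + Ka_alb·[albumin])

with the carrier proteins in molar concentration, and the vitamin D
metabolite ratio (VMR).

Three equation specifications are shipped as package data: ``EQ1`` (albumin,
25(OH)D3, 25(OH)D2, VDBP, 1,25(OH)2D3, 24,25(OH)2D3 with a
log×log interaction of 25(OH)D3 and 24,25(OH)2D3), ``EQ2`` (equation 1 plus
additive Gc diplotype offsets), and ``EQ3`` (clinical-laboratory variables
only: albumin, 25(OH)D3, iPTH, 1,25(OH)2D3).  All logarithms are natural.

Negative predictions are mathematically possible at extreme inputs; the
evaluator returns the raw value — callers that need a clinical floor apply
one explicitly (see the CLI's ``--floor``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .errors import DomainError, MissingInputError, SchemaError
from .records import PHENOTYPES, ParticipantRecord, normalize_phenotype
from .units import Analyte, BindingConstants, DEFAULT_CONSTANTS, to_molar

__all__ = [
    "EquationSpec",
    "EQ1",
    "EQ2",
    "EQ3",
    "evaluate",
    "estimate_eq1",
    "estimate_eq2",
    "estimate_eq3",
    "estimate_bikle",
    "free_fraction",
    "vmr",
]

_TRANSFORMS = ("identity", "log")


@dataclass(frozen=True)
class EquationSpec:
    """A linear free 25(OH)D estimating equation.

    ``terms`` are (variable, transform, coefficient) triples; ``interactions``
    are (variable_a, variable_b, coefficient) triples where both variables
    enter as natural logs; ``phenotype_offsets``, when non-empty, must cover
    all six Gc diplotypes with the reference (Gc1f/Gc1f) at 0.
    """

    name: str
    intercept: float
    terms: Tuple[Tuple[str, str, float], ...]
    interactions: Tuple[Tuple[str, str, float], ...] = ()
    phenotype_offsets: Dict[str, float] = field(default_factory=dict)
    metadata: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        object.__setattr__(
            self, "interactions", tuple(tuple(t) for t in self.interactions)
        )
        for var, transform, _ in self.terms:
            if transform not in _TRANSFORMS:
                raise SchemaError(f"unknown transform {transform!r} for {var!r}")
        if self.phenotype_offsets:
            offsets = {
                normalize_phenotype(k): float(v)
                for k, v in self.phenotype_offsets.items()
            }
            if set(offsets) != set(PHENOTYPES):
                raise SchemaError(
                    f"phenotype_offsets must cover all six diplotypes, got {sorted(offsets)}"
                )
            if offsets[PHENOTYPES[0]] != 0.0:
                raise SchemaError("reference diplotype Gc1f/Gc1f must have offset 0")
            object.__setattr__(self, "phenotype_offsets", offsets)

    @property
    def required_variables(self) -> frozenset:
        names = {v for v, _, _ in self.terms}
        for a, b, _ in self.interactions:
            names.update((a, b))
        if self.phenotype_offsets:
            names.add("phenotype")
        return frozenset(names)


def _log_value(record: ParticipantRecord, variable: str, context: str) -> float:
    value = record.require(variable, context)
    if value <= 0:
        raise DomainError(
            f"{variable} must be > 0 for the log transform, got {value}"
        )
    return math.log(value)


def evaluate(spec: EquationSpec, record: ParticipantRecord) -> float:
    """Evaluate an estimating equation on one participant, in pg/mL.

    Raises :class:`MissingInputError` naming the first absent required
    variable and :class:`DomainError` for non-positive values under a log.
    """
    total = spec.intercept
    context = f"required by equation {spec.name!r}"
    for variable, transform, coef in spec.terms:
        if transform == "log":
            total += coef * _log_value(record, variable, context)
        else:
            total += coef * record.require(variable, context)
    for var_a, var_b, coef in spec.interactions:
        total += coef * _log_value(record, var_a, context) * _log_value(
            record, var_b, context
        )
    if spec.phenotype_offsets:
        if record.phenotype is None:
            raise MissingInputError("phenotype", context)
        total += spec.phenotype_offsets[record.phenotype]
    return total


def _load_spec(resource: str) -> EquationSpec:
    raw = json.loads(
        resources.files("freevitd.data").joinpath(resource).read_text("utf-8")
    )
    return EquationSpec(
        name=raw["name"],
        intercept=raw["intercept"],
        terms=tuple((v, t, c) for v, t, c in raw["terms"]),
        interactions=tuple((a, b, c) for a, b, c in raw["interactions"]),
        phenotype_offsets=raw.get("phenotype_offsets", {}),
        metadata=raw.get("metadata", {}),
    )


EQ1 = _load_spec("eq1.json")
EQ2 = _load_spec("eq2.json")
EQ3 = _load_spec("eq3.json")

SHIPPED_EQUATIONS: Dict[str, EquationSpec] = {"eq1": EQ1, "eq2": EQ2, "eq3": EQ3}


def estimate_eq1(record: ParticipantRecord) -> float:
    """Equation 1 estimate (pg/mL): full biomarker panel, no phenotype."""
    return evaluate(EQ1, record)


def estimate_eq2(record: ParticipantRecord) -> float:
    """Equation 2 estimate (pg/mL): equation 1 panel plus Gc diplotype."""
    return evaluate(EQ2, record)


def estimate_eq3(record: ParticipantRecord) -> float:
    """Equation 3 estimate (pg/mL): clinical-laboratory variables only."""
    return evaluate(EQ3, record)


def free_fraction(
    vdbp_ug_ml: float,
    albumin_g_dl: float,
    constants: BindingConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium free fraction 1 / (1 + Ka_dbp·[VDBP] + Ka_alb·[albumin]).

    Dimensionless, in (0, 1]; equals 1 when both carriers are absent.
    """
    vdbp_m = to_molar(vdbp_ug_ml, Analyte.VDBP, constants)
    alb_m = to_molar(albumin_g_dl, Analyte.ALBUMIN, constants)
    return 1.0 / (1.0 + constants.ka_dbp * vdbp_m + constants.ka_alb * alb_m)


def estimate_bikle(
    record: ParticipantRecord, constants: BindingConstants = DEFAULT_CONSTANTS
) -> float:
    """Binding-equilibrium (Bikle) free 25(OH)D estimate, in pg/mL.

    Total 25(OH)D is the D3 + D2 sum (D2 defaults to 0 when absent); the
    result is total × free fraction, converted from ng/mL to pg/mL.
    Strictly decreasing in VDBP and albumin.
    """
    d25_3 = record.require("d25_3", "required by the Bikle equation")
    vdbp = record.require("vdbp", "required by the Bikle equation")
    albumin = record.require("albumin", "required by the Bikle equation")
    total_ng_ml = d25_3 + (record.d25_2 or 0.0)
    # ng/mL → pg/mL: ×1000
    return total_ng_ml * 1000.0 * free_fraction(vdbp, albumin, constants)


def vmr(d24_25_3: float, d25_3: float) -> float:
    """Vitamin D metabolite ratio: 100 × 24,25(OH)2D3 / 25(OH)D3.

    A marker of vitamin D catabolism; dimensionless (both inputs in ng/mL).
    """
    if d25_3 <= 0:
        raise DomainError(f"25(OH)D3 must be > 0, got {d25_3}")
    if d24_25_3 < 0:
        raise DomainError(f"24,25(OH)2D3 must be >= 0, got {d24_25_3}")
    return 100.0 * d24_25_3 / d25_3
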