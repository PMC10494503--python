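"""Cohort CSV reading/writing and equation-spec serialization.

The cohort format is plain RFC-4180 CSV (UTF-8, "." decimal) with a header
row whose column names embed the clinical units (``albumin_g_dl``,
``d25_3_ng_ml``, ...).  Lines starting with ``#`` are provenance comments
(source description, generator seed) and are preserved on write.  Missing
values are empty fields; the string ``NA`` is accepted on read, never
written.

Equation specifications serialize as JSON; the shipped files for the three
estimating equations and the binding constants live under
``freevitd/data/``.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .design import CANONICAL_COLUMNS, BLOCK_VARIABLES, CONTINUOUS_VARIABLES, records_from_frame
from .equations import EquationSpec
from .errors import SchemaError
from .records import ParticipantRecord, normalize_phenotype
from .units import BindingConstants

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "serialize_equation",
    "parse_equation",
    "read_equation",
    "write_equation",
    "read_constants",
]

SCHEMA_VERSION = "1"

_NUMERIC_COLUMNS = {
    c
    for c in CANONICAL_COLUMNS
    if c not in ("phenotype", "sex", "race", "season", "site")
}
_EXTENDED_COLUMNS = {"smoking", "sbp_mm_hg", "dbp_mm_hg"}
_KNOWN_COLUMNS = set(CANONICAL_COLUMNS) | _EXTENDED_COLUMNS


@dataclass
class CohortTable:
    """A cohort with provenance, wrapping the canonical DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""
    schema_version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> List[ParticipantRecord]:
        return records_from_frame(self.frame)


def read_cohort(
    path: Union[str, Path],
    d2_floor: Optional[float] = 0.2,
) -> CohortTable:
    """Read a cohort CSV.

    Headers are canonicalized case-insensitively; unknown columns are a
    schema error.  Phenotype strings are normalized (the diplotype is an
    unordered pair).  25(OH)D2 values that are missing or below the assay
    detection floor are replaced by ``d2_floor`` (default 0.2 ng/mL) with a
    logged warning; pass ``d2_floor=None`` to disable.  Unparseable numeric
    cells are reported with their line numbers.
    """
    path = Path(path)
    provenance_lines = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                provenance_lines.append(line[1:].strip())
            else:
                break
    frame = pd.read_csv(
        path,
        comment="#",
        na_values=["NA"],
        keep_default_na=True,
        dtype=str,
        skip_blank_lines=True,
    )
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    unknown = [c for c in frame.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s) in {path.name}: {', '.join(unknown)}")

    n_comments = len(provenance_lines)
    errors = []
    for col in frame.columns:
        if col in _NUMERIC_COLUMNS:
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = frame[col].notna() & converted.isna()
            for idx in frame.index[bad]:
                # +2: header line and 1-based numbering
                errors.append((int(idx) + n_comments + 2, col, frame.loc[idx, col]))
            frame[col] = converted
    if errors:
        preview = "; ".join(
            f"line {ln}: {col}={val!r}" for ln, col, val in errors[:5]
        )
        raise SchemaError(
            f"{len(errors)} unparseable numeric cell(s) in {path.name}: {preview}"
        )

    if "phenotype" in frame.columns:
        frame["phenotype"] = frame["phenotype"].map(
            lambda v: normalize_phenotype(v) if pd.notna(v) else v
        )
    if d2_floor is not None and "d25_2_ng_ml" in frame.columns:
        below = frame["d25_2_ng_ml"].isna() | (frame["d25_2_ng_ml"] < d2_floor)
        if below.any():
            logger.warning(
                "25(OH)D2: %d value(s) missing or below the %.2g ng/mL detection "
                "floor were floored",
                int(below.sum()),
                d2_floor,
            )
            frame.loc[below, "d25_2_ng_ml"] = d2_floor
    provenance = "; ".join(provenance_lines)
    return CohortTable(frame=frame, provenance=provenance)


def write_cohort(table: CohortTable, path: Union[str, Path]) -> None:
    """Write a cohort CSV with canonical column order and deterministic
    formatting; provenance goes into leading ``#`` comment lines."""
    path = Path(path)
    frame = table.frame
    ordered = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    frame = frame[ordered + extra]
    buf = _io.StringIO()
    buf.write(f"# schema_version: {table.schema_version}\n")
    if table.provenance:
        for piece in table.provenance.split("; "):
            buf.write(f"# {piece}\n")
    frame.to_csv(buf, index=False, float_format="%.10g", na_rep="")
    path.write_text(buf.getvalue(), encoding="utf-8")


_VALID_VARIABLES = (
    set(CONTINUOUS_VARIABLES)
    | {c for cols in BLOCK_VARIABLES.values() for c in cols}
)


def serialize_equation(spec: EquationSpec) -> str:
    """Serialize an equation spec to JSON (lossless round trip)."""
    payload = {
        "name": spec.name,
        "intercept": spec.intercept,
        "terms": [list(t) for t in spec.terms],
        "interactions": [list(t) for t in spec.interactions],
        "phenotype_offsets": dict(spec.phenotype_offsets),
        "metadata": dict(spec.metadata),
    }
    return json.dumps(payload, indent=2)


def parse_equation(text: str) -> EquationSpec:
    """Parse a JSON equation spec, validating variable names."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"equation spec is not valid JSON: {exc}") from exc
    for key in ("name", "intercept", "terms"):
        if key not in raw:
            raise SchemaError(f"equation spec missing required key {key!r}")
    for var, transform, _ in raw["terms"]:
        if var not in _VALID_VARIABLES:
            raise SchemaError(f"unknown variable {var!r} in equation spec")
        if transform not in ("identity", "log"):
            raise SchemaError(f"unknown transform {transform!r} in equation spec")
    for a, b, _ in raw.get("interactions", []):
        for var in (a, b):
            if var not in _VALID_VARIABLES:
                raise SchemaError(f"unknown variable {var!r} in equation spec")
    return EquationSpec(
        name=raw["name"],
        intercept=float(raw["intercept"]),
        terms=tuple((v, t, float(c)) for v, t, c in raw["terms"]),
        interactions=tuple((a, b, float(c)) for a, b, c in raw.get("interactions", [])),
        phenotype_offsets=raw.get("phenotype_offsets", {}),
        metadata=raw.get("metadata", {}),
    )


def read_equation(path: Union[str, Path]) -> EquationSpec:
    return parse_equation(Path(path).read_text("utf-8"))


def write_equation(spec: EquationSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_equation(spec) + "\n", encoding="utf-8")


def read_constants(path: Union[str, Path]) -> BindingConstants:
    """Read binding constants from a JSON file (same layout as the shipped
    ``bikle_constants.json``)."""
    raw = json.loads(Path(path).read_text("utf-8"))
    kwargs = {
        k: float(raw[k])
        for k in ("ka_dbp", "ka_alb", "mw_25ohd", "mw_vdbp", "mw_albumin")
        if k in raw
    }
    return BindingConstants(**kwargs)
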