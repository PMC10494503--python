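"""Cohort table schema and design-matrix construction.

A cohort is a :class:`pandas.DataFrame` whose column names embed the
clinical unit (``albumin_g_dl``, ``d25_3_ng_ml``, ...), so that a table in
the wrong unit dialect fails loudly at parse time.  This module maps the
canonical *variable* names used by equations and model selection onto those
columns, applies the log transforms, expands categorical variables into
indicator blocks, and provides a vectorized equation evaluator.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError, MissingInputError, SchemaError
from .records import PHENOTYPES, ParticipantRecord

__all__ = [
    "CANONICAL_COLUMNS",
    "CONTINUOUS_VARIABLES",
    "BLOCK_VARIABLES",
    "transformed_column",
    "build_design",
    "evaluate_frame",
    "records_from_frame",
]

# canonical CSV/DataFrame column order
CANONICAL_COLUMNS = [
    "albumin_g_dl",
    "d25_3_ng_ml",
    "d25_2_ng_ml",
    "vdbp_ug_ml",
    "d1_25_3_pg_ml",
    "d24_25_3_ng_ml",
    "ipth_pg_ml",
    "ifgf23_pg_ml",
    "phenotype",
    "free25ohd_pg_ml",
    "age_years",
    "sex",
    "race",
    "bmi_kg_m2",
    "season",
    "site",
    "diabetes",
    "egfr_ml_min_1_73m2",
    "calcium_mg_dl",
    "phosphate_mg_dl",
]

# variable -> (source column, transform); log transforms are natural logs
CONTINUOUS_VARIABLES: Dict[str, Tuple[str, str]] = {
    "albumin": ("albumin_g_dl", "identity"),
    "d25_3": ("d25_3_ng_ml", "log"),
    "d25_2": ("d25_2_ng_ml", "log"),
    "vdbp": ("vdbp_ug_ml", "log"),
    "d1_25_3": ("d1_25_3_pg_ml", "log"),
    "d24_25_3": ("d24_25_3_ng_ml", "log"),
    "ipth": ("ipth_pg_ml", "log"),
    "ifgf23": ("ifgf23_pg_ml", "log"),
    "total_25ohd": ("", "log"),  # derived: d25_3 + d25_2
    "age": ("age_years", "identity"),
    "bmi": ("bmi_kg_m2", "identity"),
    "egfr": ("egfr_ml_min_1_73m2", "identity"),
    "calcium": ("calcium_mg_dl", "identity"),
    "phosphate": ("phosphate_mg_dl", "identity"),
}

SEASONS = ("winter", "spring", "summer", "fall")

# categorical variables entering regressions as indicator blocks (all
# columns in or out together); the first level is the reference
BLOCK_VARIABLES: Dict[str, List[str]] = {
    "phenotype": [f"phenotype_{p}" for p in PHENOTYPES[1:]],
    "season": [f"season_{s}" for s in SEASONS[1:]],
    "sex": ["sex_female"],
    "race": ["race_black"],
    "site": ["site_pittsburgh"],
    "diabetes": ["diabetes"],
}

# derived 0/1 indicator -> (source column, positive values)
INDICATOR_SOURCES: Dict[str, Tuple[str, Tuple[str, ...]]] = {
    "sex_female": ("sex", ("f", "female")),
    "race_black": ("race", ("black",)),
    "site_pittsburgh": ("site", ("pittsburgh",)),
}


def _require_column(frame: pd.DataFrame, column: str) -> pd.Series:
    if column not in frame.columns:
        raise MissingInputError(column, "column absent from cohort table")
    return frame[column]


def transformed_column(frame: pd.DataFrame, variable: str) -> pd.Series:
    """The design column for one continuous variable (log applied where the
    variable is log transformed), named after the variable."""
    if variable not in CONTINUOUS_VARIABLES:
        raise SchemaError(f"unknown continuous variable {variable!r}")
    column, transform = CONTINUOUS_VARIABLES[variable]
    if variable == "total_25ohd":
        values = _require_column(frame, "d25_3_ng_ml") + _require_column(
            frame, "d25_2_ng_ml"
        )
    else:
        values = _require_column(frame, column)
    values = values.astype(float)
    if transform == "log":
        if (values <= 0).any():
            bad = int((values <= 0).sum())
            raise DomainError(
                f"{variable}: {bad} non-positive value(s) under log transform"
            )
        values = np.log(values)
    return pd.Series(np.asarray(values), index=frame.index, name=variable)


def indicator_block(frame: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Indicator columns for a categorical variable against its reference."""
    if variable not in BLOCK_VARIABLES:
        raise SchemaError(f"unknown categorical variable {variable!r}")
    out = {}
    for col in BLOCK_VARIABLES[variable]:
        if col in INDICATOR_SOURCES:
            source, positive = INDICATOR_SOURCES[col]
            raw = _require_column(frame, source).astype(str).str.strip().str.lower()
            out[col] = (raw.isin(positive)).astype(float)
        elif col == "diabetes":
            out[col] = _require_column(frame, "diabetes").astype(float)
        elif col.startswith("phenotype_"):
            level = col[len("phenotype_"):]
            out[col] = (_require_column(frame, "phenotype") == level).astype(float)
        elif col.startswith("season_"):
            level = col[len("season_"):]
            raw = _require_column(frame, "season").astype(str).str.strip().str.lower()
            out[col] = (raw == level).astype(float)
        else:  # pragma: no cover
            raise SchemaError(f"unhandled indicator column {col!r}")
    return pd.DataFrame(out, index=frame.index)


def design_columns(variable: str) -> List[str]:
    """Names of the design columns a variable contributes."""
    if variable in BLOCK_VARIABLES:
        return list(BLOCK_VARIABLES[variable])
    if variable in CONTINUOUS_VARIABLES:
        return [variable]
    raise SchemaError(f"unknown variable {variable!r}")


def build_design(
    frame: pd.DataFrame,
    variables: Sequence[str],
    interactions: Sequence[Tuple[str, str]] = (),
) -> pd.DataFrame:
    """Assemble the regression design matrix (no intercept column).

    ``interactions`` are unordered pairs of continuous variables whose
    transformed columns are multiplied.
    """
    pieces: List[pd.DataFrame] = []
    for var in variables:
        if var in BLOCK_VARIABLES:
            pieces.append(indicator_block(frame, var))
        else:
            pieces.append(transformed_column(frame, var).to_frame())
    for a, b in interactions:
        col = transformed_column(frame, a) * transformed_column(frame, b)
        pieces.append(col.rename(f"{a}:{b}").to_frame())
    if not pieces:
        return pd.DataFrame(index=frame.index)
    return pd.concat(pieces, axis=1)


def evaluate_frame(spec, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`freevitd.equations.evaluate` over a cohort table."""
    total = np.full(len(frame), float(spec.intercept))
    for variable, transform, coef in spec.terms:
        if variable in CONTINUOUS_VARIABLES:
            col = transformed_column(frame, variable)
            expected = CONTINUOUS_VARIABLES[variable][1]
            if transform != expected:
                # a spec may use identity where the registry logs (or vice
                # versa); honor the spec's transform
                raw = (
                    _require_column(frame, CONTINUOUS_VARIABLES[variable][0])
                    .astype(float)
                    .to_numpy()
                )
                if transform == "log":
                    if (raw <= 0).any():
                        raise DomainError(f"{variable}: non-positive under log")
                    col = np.log(raw)
                else:
                    col = raw
            total = total + coef * np.asarray(col)
        else:
            # derived indicator term from a developed equation
            block_frame = None
            for block, cols in BLOCK_VARIABLES.items():
                if variable in cols:
                    block_frame = indicator_block(frame, block)
                    break
            if block_frame is None:
                raise SchemaError(f"unknown equation variable {variable!r}")
            total = total + coef * block_frame[variable].to_numpy()
    for a, b, coef in spec.interactions:
        total = total + coef * np.asarray(transformed_column(frame, a)) * np.asarray(
            transformed_column(frame, b)
        )
    if spec.phenotype_offsets:
        phen = _require_column(frame, "phenotype")
        offsets = phen.map(spec.phenotype_offsets)
        if offsets.isna().any():
            raise DomainError("unknown or missing phenotype in cohort table")
        total = total + offsets.to_numpy(dtype=float)
    return total


def records_from_frame(frame: pd.DataFrame) -> List[ParticipantRecord]:
    """Convert cohort rows into :class:`ParticipantRecord` objects."""
    core = {
        "albumin": "albumin_g_dl",
        "d25_3": "d25_3_ng_ml",
        "d25_2": "d25_2_ng_ml",
        "vdbp": "vdbp_ug_ml",
        "d1_25_3": "d1_25_3_pg_ml",
        "d24_25_3": "d24_25_3_ng_ml",
        "ipth": "ipth_pg_ml",
    }
    covariate_cols = {
        "age": "age_years",
        "sex": "sex",
        "race": "race",
        "bmi": "bmi_kg_m2",
        "season": "season",
        "site": "site",
        "diabetes": "diabetes",
        "egfr": "egfr_ml_min_1_73m2",
        "calcium": "calcium_mg_dl",
        "phosphate": "phosphate_mg_dl",
        "ifgf23": "ifgf23_pg_ml",
    }
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name, col in core.items():
            if col in frame.columns and pd.notna(row[col]):
                kwargs[name] = float(row[col])
        if "phenotype" in frame.columns and pd.notna(row.get("phenotype")):
            kwargs["phenotype"] = str(row["phenotype"])
        if "free25ohd_pg_ml" in frame.columns and pd.notna(row.get("free25ohd_pg_ml")):
            kwargs["measured_free"] = float(row["free25ohd_pg_ml"])
        cov = {}
        for name, col in covariate_cols.items():
            if col in frame.columns and pd.notna(row.get(col)):
                cov[name] = row[col]
        kwargs["covariates"] = cov
        records.append(ParticipantRecord(**kwargs))
    return records
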