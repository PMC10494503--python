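"""Equation development: split, forced variables, forward selection,
interaction search, and hold-out validation.

The procedure mirrors standard estimating-equation development on a
biomarker cohort: the cohort is randomly partitioned into a development set
(default two-thirds) and a validation set; a least-squares model with a set
of forced variables is fitted; remaining candidates are added one at a time
by greedy forward selection, each retained only if it improves the adjusted
R² by at least a threshold (default 0.02); pairwise multiplicative
interaction terms among the retained continuous variables are then screened
by the same rule; and the final refitted equation is evaluated on the
held-out validation set (bias, limits of agreement, P15/P30, RMSE).

Skewed biomarkers (vitamin D metabolites, VDBP, iPTH, iFGF-23) enter as
natural logs; categorical variables (Gc phenotype, season, site, sex, race,
diabetes) enter as indicator blocks that are added or dropped as a unit and
counted with their full column count in the adjusted R² penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import metrics
from .design import (
    BLOCK_VARIABLES,
    CONTINUOUS_VARIABLES,
    build_design,
    design_columns,
    evaluate_frame,
)
from .equations import EquationSpec
from .errors import InputError, SingularDesignError
from .records import PHENOTYPES

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SelectionStep",
    "SelectionTrace",
    "OLSFit",
    "split_cohort",
    "fit_ols",
    "forward_select",
    "interaction_search",
    "develop_equation",
    "MODE_FORCED",
    "CLINICAL_CANDIDATES",
    "FULL_CANDIDATES",
]

RESPONSE_COLUMN = "free25ohd_pg_ml"

# candidate pools: the full biomarker/covariate list, and the restriction to
# variables available at a typical clinical laboratory
FULL_CANDIDATES = (
    "total_25ohd",
    "d24_25_3",
    "d1_25_3",
    "vdbp",
    "phenotype",
    "age",
    "sex",
    "race",
    "bmi",
    "season",
    "site",
    "diabetes",
    "egfr",
    "calcium",
    "phosphate",
    "ipth",
    "ifgf23",
)
CLINICAL_CANDIDATES = (
    "d25_3",
    "albumin",
    "ipth",
    "d1_25_3",
    "calcium",
    "phosphate",
    "egfr",
    "d25_2",
)

# forced-variable sets per development mode
MODE_FORCED = {
    "eq1": ("d25_2", "d25_3", "vdbp", "albumin"),
    "eq2": ("d25_2", "d25_3", "vdbp", "albumin", "phenotype"),
    "eq3": (),
}


@dataclass
class ModelConfig:
    """Configuration of one equation-development run."""

    forced_variables: Tuple[str, ...] = ()
    candidate_variables: Tuple[str, ...] = FULL_CANDIDATES
    retention_threshold: float = 0.02
    split_fraction: float = 2.0 / 3.0
    seed: int = 0
    dev_n: Optional[int] = None
    prescreen: bool = False

    def __post_init__(self) -> None:
        self.forced_variables = tuple(self.forced_variables)
        self.candidate_variables = tuple(
            c for c in self.candidate_variables if c not in self.forced_variables
        )
        if self.retention_threshold <= 0:
            raise InputError("retention_threshold must be > 0")
        if not (0 < self.split_fraction < 1):
            raise InputError("split_fraction must be in (0, 1)")
        # total 25(OH)D is collinear by construction with forced D3/D2
        if {"d25_3", "d25_2"} & set(self.forced_variables):
            self.candidate_variables = tuple(
                c for c in self.candidate_variables if c != "total_25ohd"
            )


@dataclass
class SelectionStep:
    step: int
    term: str
    adj_r2_before: float
    adj_r2_after: float
    retained: bool


@dataclass
class SelectionTrace:
    """Ordered log of every candidate evaluation during selection."""

    steps: List[SelectionStep] = field(default_factory=list)
    final_spec: Optional[EquationSpec] = None
    dev_rmse: Optional[float] = None
    val_rmse: Optional[float] = None

    @property
    def retained_terms(self) -> List[str]:
        return [s.term for s in self.steps if s.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "term": s.term,
                    "adj_r2_before": s.adj_r2_before,
                    "adj_r2_after": s.adj_r2_after,
                    "improvement": s.adj_r2_after - s.adj_r2_before,
                    "retained": s.retained,
                }
                for s in self.steps
            ]
        )


def split_cohort(
    cohort: pd.DataFrame,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    dev_n: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint development/validation partition.

    The development size defaults to ``round(fraction * n)`` (banker's
    rounding); pass ``dev_n`` to reproduce an exact published split size.
    """
    n = len(cohort)
    if n < 3:
        raise InputError(f"cohort too small to split, n={n}")
    if not (0 < fraction < 1):
        raise InputError("fraction must be in (0, 1)")
    if dev_n is None:
        dev_n = round(fraction * n)
    if not (0 < dev_n < n):
        raise InputError(f"dev_n={dev_n} out of range for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dev = cohort.iloc[np.sort(perm[:dev_n])]
    val = cohort.iloc[np.sort(perm[dev_n:])]
    return dev, val


@dataclass
class OLSFit:
    params: pd.Series
    bse: pd.Series
    adj_r2: float
    rmse: float
    fitted: np.ndarray
    resid: np.ndarray
    nobs: int
    n_predictors: int


def _collinear_columns(design: pd.DataFrame) -> List[str]:
    X = design.to_numpy(dtype=float)
    full = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    bad = []
    for j, name in enumerate(design.columns):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), reduced])) == full:
            bad.append(name)
    return bad or list(design.columns)


def fit_ols(response: Sequence[float], design: pd.DataFrame) -> OLSFit:
    """Ordinary least squares with intercept.

    ``design`` holds the already-transformed predictor columns.  The
    adjusted R² penalty counts every design column (so an indicator block
    contributes its full width).  RMSE is √(mean squared residual).
    Rank-deficient designs raise :class:`SingularDesignError` naming the
    collinear columns.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(design):
        raise InputError("response and design lengths differ")
    p = design.shape[1]
    if len(y) <= p + 1:
        raise InputError(f"need n > p + 1, got n={len(y)}, p={p}")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(_collinear_columns(design))
    res = sm.OLS(y, X).fit()
    resid = y - res.fittedvalues
    return OLSFit(
        params=res.params,
        bse=res.bse,
        adj_r2=float(res.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        fitted=np.asarray(res.fittedvalues),
        resid=np.asarray(resid),
        nobs=int(res.nobs),
        n_predictors=p,
    )


def _fit_variables(
    frame: pd.DataFrame,
    variables: Sequence[str],
    interactions: Sequence[Tuple[str, str]] = (),
) -> OLSFit:
    y = frame[RESPONSE_COLUMN].to_numpy(dtype=float)
    design = build_design(frame, variables, interactions)
    if design.shape[1] == 0:
        # intercept-only model
        fitted = np.full(len(y), y.mean())
        resid = y - fitted
        return OLSFit(
            params=pd.Series({"const": y.mean()}),
            bse=pd.Series({"const": float(np.std(y, ddof=1) / np.sqrt(len(y)))}),
            adj_r2=0.0,
            rmse=float(np.sqrt(np.mean(resid**2))),
            fitted=fitted,
            resid=resid,
            nobs=len(y),
            n_predictors=0,
        )
    return fit_ols(y, design)


def _usable_candidates(
    frame: pd.DataFrame, candidates: Sequence[str]
) -> List[str]:
    usable = []
    for cand in candidates:
        try:
            design = build_design(frame, [cand])
        except Exception as exc:
            logger.warning("skipping candidate %s: %s", cand, exc)
            continue
        variances = design.var(axis=0, ddof=0)
        if (variances <= 0).all():
            logger.warning("skipping zero-variance candidate %s", cand)
            continue
        usable.append(cand)
    return usable


def _prescreen_order(frame: pd.DataFrame, candidates: List[str]) -> List[str]:
    scored = []
    for cand in candidates:
        fit = _fit_variables(frame, [cand])
        scored.append((-fit.adj_r2, candidates.index(cand), cand))
    return [c for _, _, c in sorted(scored)]


def forward_select(frame: pd.DataFrame, config: ModelConfig) -> SelectionTrace:
    """Greedy best-improvement forward selection under the ΔadjR² rule.

    Starts from the forced-variable model; at each round every remaining
    candidate is evaluated, and the one with the largest adjusted-R²
    improvement is added if the improvement meets the retention threshold.
    Ties break by candidate-list order.  The trace records every evaluation.
    """
    trace = SelectionTrace()
    current: List[str] = list(config.forced_variables)
    base = _fit_variables(frame, current)
    remaining = _usable_candidates(frame, config.candidate_variables)
    if config.prescreen and remaining:
        remaining = _prescreen_order(frame, remaining)
    round_no = 0
    while remaining:
        round_no += 1
        evaluations = []
        for order, cand in enumerate(remaining):
            fit = _fit_variables(frame, current + [cand])
            evaluations.append((fit.adj_r2 - base.adj_r2, -order, cand, fit))
        best_improvement, _, best_cand, best_fit = max(evaluations)
        accepted = best_improvement >= config.retention_threshold
        for improvement, _, cand, fit in evaluations:
            trace.steps.append(
                SelectionStep(
                    step=round_no,
                    term=cand,
                    adj_r2_before=base.adj_r2,
                    adj_r2_after=fit.adj_r2,
                    retained=accepted and cand == best_cand,
                )
            )
        if not accepted:
            break
        current.append(best_cand)
        base = best_fit
        remaining.remove(best_cand)
    trace.final_spec = None
    trace.dev_rmse = base.rmse
    return trace


def interaction_search(
    frame: pd.DataFrame,
    retained_variables: Sequence[str],
    config: ModelConfig,
    trace: Optional[SelectionTrace] = None,
) -> Tuple[List[Tuple[str, str]], SelectionTrace]:
    """Screen pairwise products of the retained continuous variables.

    Each product of two (transformed) retained variables is evaluated in the
    model by the same ΔadjR² rule, added greedily in decreasing-improvement
    order.  Indicator blocks do not form interactions.
    """
    trace = trace or SelectionTrace()
    continuous = [v for v in retained_variables if v in CONTINUOUS_VARIABLES]
    pairs = [
        (continuous[i], continuous[j])
        for i in range(len(continuous))
        for j in range(i + 1, len(continuous))
    ]
    chosen: List[Tuple[str, str]] = []
    base = _fit_variables(frame, retained_variables, chosen)
    round_no = max((s.step for s in trace.steps), default=0)
    while pairs:
        round_no += 1
        evaluations = []
        for order, pair in enumerate(pairs):
            fit = _fit_variables(frame, retained_variables, chosen + [pair])
            evaluations.append((fit.adj_r2 - base.adj_r2, -order, pair, fit))
        best_improvement, _, best_pair, best_fit = max(evaluations)
        accepted = best_improvement >= config.retention_threshold
        for improvement, _, pair, fit in evaluations:
            trace.steps.append(
                SelectionStep(
                    step=round_no,
                    term=f"{pair[0]}:{pair[1]}",
                    adj_r2_before=base.adj_r2,
                    adj_r2_after=fit.adj_r2,
                    retained=accepted and pair == best_pair,
                )
            )
        if not accepted:
            break
        chosen.append(best_pair)
        base = best_fit
        pairs.remove(best_pair)
    trace.dev_rmse = base.rmse
    return chosen, trace


def _spec_from_fit(
    name: str,
    fit: OLSFit,
    variables: Sequence[str],
    interactions: Sequence[Tuple[str, str]],
) -> EquationSpec:
    """Translate a fitted model into a portable EquationSpec."""
    params = fit.params
    terms = []
    phenotype_offsets: Dict[str, float] = {}
    for var in variables:
        if var == "phenotype":
            phenotype_offsets[PHENOTYPES[0]] = 0.0
            for level, col in zip(PHENOTYPES[1:], BLOCK_VARIABLES["phenotype"]):
                phenotype_offsets[level] = float(params[col])
        elif var in BLOCK_VARIABLES:
            for col in BLOCK_VARIABLES[var]:
                terms.append((col, "identity", float(params[col])))
        else:
            transform = CONTINUOUS_VARIABLES[var][1]
            terms.append((var, transform, float(params[var])))
    spec_interactions = tuple(
        (a, b, float(params[f"{a}:{b}"])) for a, b in interactions
    )
    return EquationSpec(
        name=name,
        intercept=float(params["const"]),
        terms=tuple(terms),
        interactions=spec_interactions,
        phenotype_offsets=phenotype_offsets,
        metadata={"adj_r2": fit.adj_r2, "rmse_development": fit.rmse},
    )


def develop_equation(
    cohort: pd.DataFrame,
    config: ModelConfig,
    mode: Optional[str] = None,
    name: Optional[str] = None,
):
    """Full development pipeline on a cohort with measured free 25(OH)D.

    Runs split → forced model → forward selection → interaction search →
    final refit → hold-out validation.  ``mode`` ∈ {"eq1", "eq2", "eq3"}
    installs the corresponding forced-variable and candidate sets (the
    "eq3" mode forces nothing and restricts candidates to the clinical
    panel); omit it to use ``config`` as given.

    Returns ``(spec, trace, reports)`` where ``reports`` is the hold-out
    validation mapping from :func:`freevitd.metrics.validate`.
    """
    if RESPONSE_COLUMN not in cohort.columns or cohort[RESPONSE_COLUMN].isna().any():
        raise InputError(
            f"cohort must provide measured free 25(OH)D in {RESPONSE_COLUMN!r}"
        )
    if mode is not None:
        if mode not in MODE_FORCED:
            raise InputError(f"unknown mode {mode!r}")
        candidates = CLINICAL_CANDIDATES if mode == "eq3" else FULL_CANDIDATES
        config = replace(
            config,
            forced_variables=MODE_FORCED[mode],
            candidate_variables=candidates,
        )
    dev, val = split_cohort(cohort, config.split_fraction, config.seed, config.dev_n)
    trace = forward_select(dev, config)
    variables = list(config.forced_variables) + trace.retained_terms
    interactions, trace = interaction_search(dev, variables, config, trace)
    final_fit = _fit_variables(dev, variables, interactions)
    spec = _spec_from_fit(name or mode or "developed", final_fit, variables, interactions)
    trace.final_spec = spec
    trace.dev_rmse = final_fit.rmse
    estimated = evaluate_frame(spec, val)
    measured = val[RESPONSE_COLUMN].to_numpy(dtype=float)
    reports = metrics.validate(estimated, measured)
    trace.val_rmse = reports["overall"].rmse
    return spec, trace, reports
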