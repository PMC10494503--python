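"""Agreement and accuracy statistics for estimated vs measured free 25(OH)D.

Bland-Altman bias and 95% limits of agreement, P15/P30 accuracy
proportions, RMSE, and adjusted R².  Conventions: differences are
estimated − measured (overestimation ⇒ positive bias); limits of agreement
use exactly ±1.96 sample standard deviations (n−1 denominator); the P15/P30
denominator is the measured value, with ties at the threshold counting as
within.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "ValidationReport",
    "bland_altman",
    "p_within",
    "rmse",
    "adjusted_r2",
    "validate",
    "bland_altman_plot",
]


def _paired(a, b, min_n: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise InputError("series must be one-dimensional")
    if a.size != b.size:
        raise InputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < min_n:
        raise InputError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


@dataclass
class ValidationReport:
    """Agreement summary for one (estimated, measured) pairing.

    ``bias`` and the limits of agreement are in pg/mL; ``p15``/``p30`` are
    proportions in [0, 1] (percentages available via :meth:`as_dict`).
    """

    n: int
    bias: float
    loa_low: float
    loa_high: float
    p15: float
    p30: float
    rmse: float
    subgroup_label: Optional[str] = None
    complete: bool = True

    def as_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["p15_pct"] = 100.0 * self.p15 if np.isfinite(self.p15) else float("nan")
        d["p30_pct"] = 100.0 * self.p30 if np.isfinite(self.p30) else float("nan")
        return d


def bland_altman(estimated, measured) -> Tuple[float, float, float]:
    """Mean difference (bias) and 95% limits of agreement.

    Returns ``(bias, loa_low, loa_high)`` where bias = mean(estimated −
    measured) and LOA = bias ± 1.96·SD of the differences.
    """
    est, meas = _paired(estimated, measured, min_n=2)
    d = est - meas
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def p_within(estimated, measured, fraction: float) -> float:
    """Proportion of pairs with |estimated − measured| ≤ fraction × measured."""
    if fraction <= 0:
        raise InputError(f"fraction must be > 0, got {fraction}")
    est, meas = _paired(estimated, measured, min_n=1)
    if np.any(meas <= 0):
        raise DomainError("measured values must be > 0 for relative accuracy")
    return float(np.mean(np.abs(est - meas) / meas <= fraction))


def rmse(predicted, observed) -> float:
    """Root mean square error √(mean (predicted − observed)²)."""
    pred, obs = _paired(predicted, observed, min_n=1)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def adjusted_r2(observed, fitted, n_predictors: int) -> float:
    """Adjusted coefficient of determination.

    R² = 1 − SSR/SST; adjusted = 1 − (1 − R²)(n − 1)/(n − p − 1) with p the
    number of predictors (excluding the intercept).
    """
    obs, fit = _paired(observed, fitted, min_n=1)
    n = obs.size
    if n <= n_predictors + 1:
        raise InputError(f"need n > n_predictors + 1, got n={n}, p={n_predictors}")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise InputError("observed series has zero variance")
    ssr = float(np.sum((obs - fit) ** 2))
    r2 = 1.0 - ssr / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def _report(est: np.ndarray, meas: np.ndarray, label: Optional[str]) -> ValidationReport:
    if est.size < 2:
        return ValidationReport(
            n=int(est.size),
            bias=float(np.mean(est - meas)) if est.size else float("nan"),
            loa_low=float("nan"),
            loa_high=float("nan"),
            p15=p_within(est, meas, 0.15) if est.size else float("nan"),
            p30=p_within(est, meas, 0.30) if est.size else float("nan"),
            rmse=rmse(est, meas) if est.size else float("nan"),
            subgroup_label=label,
            complete=False,
        )
    bias, lo, hi = bland_altman(est, meas)
    return ValidationReport(
        n=int(est.size),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        p15=p_within(est, meas, 0.15),
        p30=p_within(est, meas, 0.30),
        rmse=rmse(est, meas),
        subgroup_label=label,
    )


def validate(
    estimated, measured, subgroups: Optional[Sequence] = None
) -> Dict[str, ValidationReport]:
    """Full agreement report, overall and (optionally) per subgroup.

    Returns a mapping with key ``"overall"`` plus one key per subgroup
    label.  Subgroups with fewer than 2 pairs are flagged ``complete=False``
    rather than raising.
    """
    est, meas = _paired(estimated, measured, min_n=1)
    if np.any(meas <= 0):
        raise DomainError("measured values must be > 0")
    reports = {"overall": _report(est, meas, None)}
    if subgroups is not None:
        labels = np.asarray(subgroups)
        if labels.size != est.size:
            raise InputError("subgroup labels must match series length")
        for label in sorted(map(str, set(labels.tolist()))):
            mask = labels.astype(str) == label
            reports[label] = _report(est[mask], meas[mask], label)
    return reports


def bland_altman_plot(estimated, measured, path, title: str = "") -> None:
    """Write a Bland-Altman plot: difference vs measured value, with the
    bias and 95% limits of agreement as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est, meas = _paired(estimated, measured, min_n=2)
    bias, lo, hi = bland_altman(est, meas)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(meas, est - meas, s=14, alpha=0.6, edgecolors="none")
    ax.axhline(bias, color="k", lw=1.2, label=f"bias {bias:.2f}")
    for y, lab in ((lo, f"LOA {lo:.2f}"), (hi, f"LOA {hi:.2f}")):
        ax.axhline(y, color="k", lw=0.8, ls="--", label=lab)
    ax.set_xlabel("measured free 25(OH)D (pg/mL)")
    ax.set_ylabel("estimated − measured (pg/mL)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
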