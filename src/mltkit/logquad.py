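"""Log-quadratic two-parameter model life table system.

The system relates the age-specific central death rate to under-five
mortality through

    log10(m_x) = a_x + b_x * log10(5q0) + c_x * log10(5q0)^2 + v_x * k,

where (a_x, b_x, c_x) capture the typical change of the age pattern
with the overall level of child mortality and v_x, obtained from a
singular value decomposition of the regression residuals, is the
dominant deviation shape scaled by the second parameter k (positive k
raises adult mortality by the sign convention adopted here).

Calibration is a two-stage procedure on a corpus of abridged life
tables: per-age-group least squares of log10(m) on the quadratic of
log10(5q0), then the leading right singular vector of the centred
residual matrix.  Prediction honours the input 5q0 exactly: the infant
rate comes from the equation and the 1-4 group probability is solved
from the under-five survival constraint
q4_1 = 1 - (1 - 5q0)/(1 - 1q0).  Consequently the 1-4 row of the
coefficient set never enters prediction, and its v entry is fixed at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import brentq

from .lifetable import (
    AbridgedLifeTable,
    AgeGrid,
    ARule,
    LifeTableError,
    indicators,
    standard_a_rule,
    table_from_q,
)

__all__ = [
    "LogQuadCoefficients",
    "fit_logquad",
    "predict_logquad",
    "constrained_table_from_rates",
    "match_k",
]


class CalibrationError(ValueError):
    """Degenerate corpus: the system cannot be calibrated."""


class TargetRangeError(ValueError):
    """A matching target lies outside the range the system can reach."""

    def __init__(self, message: str, attainable: tuple[float, float] | None = None):
        super().__init__(message)
        self.attainable = attainable


@dataclass
class LogQuadCoefficients:
    """Per-age-group coefficients (a, b, c, v) of the log-quadratic system."""

    grid: AgeGrid
    a_coef: np.ndarray
    b_coef: np.ndarray
    c_coef: np.ndarray
    v_coef: np.ndarray
    calibration_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.n_groups
        for name in ("a_coef", "b_coef", "c_coef", "v_coef"):
            vec = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, vec)
            if vec.shape != (n,):
                raise ValueError(f"{name} must have one entry per age group")

    @property
    def q5_range(self) -> tuple[float, float]:
        rng = self.calibration_meta.get("q5_0_range")
        return (rng[0], rng[1]) if rng else (0.0, 1.0)


def _adult_sign(grid: AgeGrid, v: np.ndarray) -> float:
    """Sign of the 15-60 sum of v (the adult-mortality direction)."""
    sel = (grid.group_starts >= 15) & (grid.group_starts < 60)
    s = float(v[sel].sum())
    return 1.0 if s >= 0 else -1.0


def fit_logquad(
    corpus: Iterable[AbridgedLifeTable],
    sex: str = "total",
) -> LogQuadCoefficients:
    """Calibrate the log-quadratic system on a corpus of life tables.

    Stage 1 regresses, per age group, log10(m) on
    (1, log10(5q0), log10(5q0)^2) across the corpus.  Stage 2 takes the
    leading right singular vector of the centred residual matrix
    (tables x age groups) as the unit-norm shape vector v, sign-fixed
    so that positive k raises mortality over ages 15-60.  The 1-4 age
    group is excluded from stage 2 (its v entry is 0) because
    prediction derives that group from the under-five constraint.
    """
    tables = [t for t in corpus if t.sex == sex or sex == "total" or t.sex == "total"]
    if len(tables) < 10:
        raise CalibrationError("need at least 10 life tables to calibrate")
    grid = tables[0].grid
    if any(t.grid != grid for t in tables):
        raise CalibrationError("all corpus tables must share one age grid")

    x = np.array([np.log10(indicators(t).q5_0) for t in tables])
    Y = np.log10(np.array([t.m for t in tables]))  # tables x groups
    if np.unique(np.round(x, 12)).size < 4:
        if np.allclose(Y, Y[0]):
            raise CalibrationError(
                "all corpus schedules identical: residual matrix is degenerate, v undefined"
            )
        raise CalibrationError("fewer than 4 distinct 5q0 values: design is rank-deficient")
    X = np.column_stack([np.ones_like(x), x, x * x])

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    a_coef, b_coef, c_coef = beta[0], beta[1], beta[2]

    resid = Y - X @ beta
    resid_c = resid - resid.mean(axis=0, keepdims=True)
    svd_cols = np.ones(grid.n_groups, dtype=bool)
    svd_cols[1] = False  # 1-4 group: constraint-derived in prediction
    sub = resid_c[:, svd_cols]
    if np.linalg.norm(sub) < 1e-12:
        raise CalibrationError("residual matrix is degenerate; v is undefined")
    _, s, Vt = np.linalg.svd(sub, full_matrices=False)
    if s.size < 2 or s[0] < 1e-12:
        raise CalibrationError("residual matrix is degenerate; v is undefined")
    v = np.zeros(grid.n_groups)
    v[svd_cols] = Vt[0]
    v *= _adult_sign(grid, v)

    meta = {
        "n_tables": len(tables),
        "sex": sex,
        "q5_0_range": (float(10 ** x.min()), float(10 ** x.max())),
        "singular_values": s[:5].tolist(),
    }
    return LogQuadCoefficients(grid, a_coef, b_coef, c_coef, v, meta)


def predict_logquad(
    coeffs: LogQuadCoefficients,
    q5_0: float,
    k: float = 0.0,
    a_rule: ARule = standard_a_rule,
    sex: str = "total",
    label: str = "",
) -> AbridgedLifeTable:
    """Predict a full abridged life table from (5q0, k).

    Rates at ages 0 and 5+ follow the model equation; the 1-4 group
    probability is solved so that the resulting table reproduces the
    input 5q0 exactly.
    """
    if not 0.0 < q5_0 < 1.0:
        raise ValueError("5q0 must lie in (0, 1)")
    lo, hi = coeffs.q5_range
    if not (lo <= q5_0 <= hi) and lo < hi:
        warnings.warn(
            f"5q0={q5_0:.5f} outside calibration range [{lo:.5f}, {hi:.5f}]; extrapolating",
            stacklevel=2,
        )
    x = np.log10(q5_0)
    log_m = coeffs.a_coef + coeffs.b_coef * x + coeffs.c_coef * x * x + coeffs.v_coef * k
    m = 10.0 ** log_m
    return constrained_table_from_rates(
        coeffs.grid, m, q5_0, a_rule=a_rule, sex=sex, label=label
    )


def constrained_table_from_rates(
    grid: AgeGrid,
    m: np.ndarray,
    q5_0: float,
    a_rule: ARule = standard_a_rule,
    sex: str = "total",
    label: str = "",
) -> AbridgedLifeTable:
    """Build a table from rates at ages 0 and 5+ honouring 5q0 exactly.

    The 1-4 group probability is solved from the under-five survival
    constraint q4_1 = 1 - (1 - 5q0)/(1 - q1_0); the rate supplied for
    that group (if any) is ignored.
    """
    a = a_rule(m, grid)
    q1_0 = m[0] / (1.0 + (1.0 - a[0]) * m[0])
    q4_1 = 1.0 - (1.0 - q5_0) / (1.0 - q1_0)
    if not 0.0 <= q4_1 < 1.0:
        raise TargetRangeError(
            f"input 5q0={q5_0:.6g} incompatible with predicted infant mortality "
            f"q1_0={q1_0:.6g} (implied q4_1={q4_1:.6g})"
        )

    n_w = grid.group_widths
    q = np.empty(grid.n_groups)
    q[0] = q1_0
    q[1] = q4_1
    q[2:-1] = n_w[2:-1] * m[2:-1] / (1.0 + (n_w[2:-1] - a[2:-1]) * m[2:-1])
    q[-1] = 1.0
    if np.any(q[2:-1] >= 1.0):
        raise LifeTableError("predicted rates imply q >= 1 in a closed group")
    return table_from_q(
        q, grid, a_rule=a_rule, open_group_e=1.0 / m[-1], sex=sex, label=label
    )


_INDICATOR_GETTERS = {
    "q45_15": lambda ind: ind.q45_15,
    "e0": lambda ind: ind.e0,
    "q1_0": lambda ind: ind.q1_0,
    "q20_60": lambda ind: ind.q20_60,
}


def match_k(
    coeffs: LogQuadCoefficients,
    q5_0: float,
    target: Literal["q45_15", "e0"],
    target_value: float,
    tol: float | None = None,
    a_rule: ARule = standard_a_rule,
) -> float:
    """Find k so the predicted table reproduces a second indicator.

    Bisection (Brent) on the monotone k map over [-8, 8], with the
    bracket doubled up to |k| = 32 before declaring the target
    unattainable.  Default tolerance: 1e-9 for probabilities, 1e-7
    years for e0.
    """
    if target not in ("q45_15", "e0"):
        raise ValueError("target must be 'q45_15' or 'e0'")
    if tol is None:
        tol = 1e-7 if target == "e0" else 1e-9
    get = _INDICATOR_GETTERS[target]

    def f(k: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = predict_logquad(coeffs, q5_0, k, a_rule=a_rule)
        return get(indicators(t)) - target_value

    def valid_end(k: float) -> float:
        """Largest-|k| feasible point toward ``k`` (schedules can break far out)."""
        while abs(k) > 1e-6:
            try:
                f(k)
                return k
            except (LifeTableError, TargetRangeError, ValueError):
                k /= 2.0
        return k

    lo, hi = -8.0, 8.0
    while True:
        vlo, vhi = valid_end(lo), valid_end(hi)
        flo, fhi = f(vlo), f(vhi)
        if flo * fhi <= 0:
            break
        if abs(lo) >= 32.0 or (vlo != lo and vhi != hi):
            vals = sorted((f(s) + target_value for s in (vlo, vhi)))
            raise TargetRangeError(
                f"{target}={target_value:.6g} unattainable at 5q0={q5_0:.6g}; "
                f"attainable range ({vals[0]:.6g}, {vals[1]:.6g})",
                attainable=(vals[0], vals[1]),
            )
        lo, hi = lo * 2.0, hi * 2.0
    k = brentq(f, vlo, vhi, xtol=1e-13, rtol=8.9e-16)
    if abs(f(k)) > tol:
        raise TargetRangeError(f"matching {target} did not reach tolerance {tol}")
    return float(k)
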