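"""Modified-logit relational model life table system.

A Brass-type relational system: under the logit transform
Y(x) = 0.5*ln((1 - l(x)/l0) / (l(x)/l0)), any schedule is related to a
standard Ys(x) by Y(x) = alpha + beta*Ys(x).  The modification adds two
age-specific correction vectors that depend on how the schedule's
child and adult mortality deviate from the standard:

    Y(x) = alpha + beta*Ys(x) + gamma_x * z_c + theta_x * z_a,
    z_c  = 1 - Y(5)/Ys(5),      z_a = 1 - Y(60)/Ys(60),

which removes the systematic bias of the plain two-parameter transform
when mortality departs far from the standard.  The deviation anchors
(ages 5 and 60) and the estimation of gamma/theta as per-boundary
regression slopes of two-parameter-fit residuals are this package's
documented variant of that idea.

Matching: (alpha, beta) jointly reproduce 5q0 & 45q15 (case 2) or
5q0 & e0 (case 3); with 5q0 alone (case 1) the adult level is first
predicted from a corpus-calibrated companion regression and both
anchors are then matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import brentq, root

from .lifetable import (
    AbridgedLifeTable,
    AgeGrid,
    ARule,
    indicators,
    standard_a_rule,
    table_from_q,
)
from .logquad import CalibrationError, TargetRangeError

__all__ = [
    "ModLogitStandard",
    "logit_survivorship",
    "inverse_logit_survivorship",
    "build_standard",
    "predict_modlogit",
    "match_modlogit",
]

ANCHOR_CHILD = 5.0
ANCHOR_ADULT = 60.0


def logit_survivorship(p: np.ndarray | float) -> np.ndarray | float:
    """Brass logit of survivorship: 0.5*ln((1-p)/p), p strictly in (0,1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise CalibrationError("survivorship must lie strictly in (0, 1) for the logit")
    return 0.5 * np.log((1.0 - p) / p)


def inverse_logit_survivorship(y: np.ndarray | float) -> np.ndarray | float:
    """Inverse of the Brass logit: p = 1/(1 + exp(2y))."""
    return 1.0 / (1.0 + np.exp(2.0 * np.asarray(y, dtype=float)))


@dataclass
class ModLogitStandard:
    """Standard logit survivorship with child/adult correction vectors.

    ``boundaries`` are the interior grid boundaries (1, 5, ..., open
    start); ``Ys``, ``gamma`` and ``theta`` are defined per boundary.
    ``open_group_e`` carries the standard's open-interval expectation so
    predicted tables can be closed out.
    """

    grid: AgeGrid
    boundaries: np.ndarray
    Ys: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    open_group_e: float
    anchor_ages: tuple[float, float] = (ANCHOR_CHILD, ANCHOR_ADULT)
    aux_child_adult: np.ndarray | None = None  # log10(45q15) ~ quadratic(log10 5q0)
    calibration_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("boundaries", "Ys", "gamma", "theta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.boundaries.shape == self.Ys.shape == self.gamma.shape == self.theta.shape):
            raise ValueError("boundaries, Ys, gamma, theta must share one shape")

    def _anchor_index(self, age: float) -> int:
        hits = np.nonzero(self.boundaries == age)[0]
        if hits.size == 0:
            raise ValueError(f"anchor age {age} is not a boundary")
        return int(hits[0])

    @property
    def child_index(self) -> int:
        return self._anchor_index(self.anchor_ages[0])

    @property
    def adult_index(self) -> int:
        return self._anchor_index(self.anchor_ages[1])


def _table_logits(table: AbridgedLifeTable) -> tuple[np.ndarray, np.ndarray]:
    """Interior boundaries and logit survivorship of one table."""
    boundaries = table.grid.group_starts[1:]
    p = table.l[1:] / table.l[0]
    return boundaries, np.asarray(logit_survivorship(p))


def build_standard(
    corpus: Iterable[AbridgedLifeTable],
    sex: str = "total",
) -> ModLogitStandard:
    """Calibrate the standard and the correction vectors on a corpus.

    Ys is the corpus mean logit survivorship.  For each table an
    anchor-exact two-parameter fit (alpha, beta solved from the logits
    at ages 5 and 60) is removed; the per-boundary residuals are then
    regressed on the child and adult deviation covariates z_c, z_a of
    that table (theta on the level-orthogonalised part of z_a, gamma
    on the remainder — the two covariates are nearly collinear across
    a level-dominated corpus).  Both correction vectors vanish at the
    anchors because the anchor residuals are identically zero.  A
    companion regression of log10(45q15) on a quadratic in log10(5q0)
    is fitted for the child-only input case.
    """
    tables = list(corpus)
    if len(tables) < 10:
        raise CalibrationError("need at least 10 life tables to calibrate")
    grid = tables[0].grid
    if any(t.grid != grid for t in tables):
        raise CalibrationError("all corpus tables must share one age grid")
    boundaries, _ = _table_logits(tables[0])
    Y = np.array([_table_logits(t)[1] for t in tables])  # tables x boundaries
    Ys = Y.mean(axis=0)

    std = ModLogitStandard(
        grid=grid, boundaries=boundaries, Ys=Ys,
        gamma=np.zeros_like(Ys), theta=np.zeros_like(Ys),
        open_group_e=float(np.mean([t.e[-1] for t in tables])),
    )
    ic, ia = std.child_index, std.adult_index

    # per-table two-parameter fit pinned at the anchors: alpha, beta
    # solved exactly from Y(5) and Y(60), so every table's residual
    # vanishes at both anchor boundaries and the fitted corrections go
    # smoothly through 0 there — no kink for the transform to amplify
    beta_t = (Y[:, ia] - Y[:, ic]) / (Ys[ia] - Ys[ic])
    alpha_t = Y[:, ic] - beta_t * Ys[ic]
    resid = Y - (alpha_t[:, None] + beta_t[:, None] * Ys[None, :])
    z_c = 1.0 - Y[:, ic] / Ys[ic]
    z_a = 1.0 - Y[:, ia] / Ys[ia]

    # z_c and z_a are nearly collinear over a corpus whose dominant
    # variation is the mortality level, so a joint least-squares split
    # is unstable; identify hierarchically — theta from the component
    # of z_a orthogonal to z_c (the adult-specific deviation), gamma
    # from what z_c explains of the remainder
    var_c = float(z_c @ z_c)
    if var_c < 1e-12:
        gamma = np.zeros_like(Ys)
        theta = np.zeros_like(Ys)
    else:
        lam = float(z_a @ z_c) / var_c
        z_a_perp = z_a - lam * z_c
        var_ap = float(z_a_perp @ z_a_perp)
        theta = (resid.T @ z_a_perp) / var_ap if var_ap > 1e-12 else np.zeros_like(Ys)
        gamma = ((resid - np.outer(z_a, theta)).T @ z_c) / var_c
    for vec in (gamma, theta):  # exact zeros at both anchors (residuals vanish there)
        vec[ic] = 0.0
        vec[ia] = 0.0

    # companion child-to-adult regression: when only 5q0 is supplied,
    # the expected adult level is predicted from it and the table is
    # then matched on both anchors (a free beta=1 transform cannot
    # follow how the age slope changes with the level)
    inds = [indicators(t) for t in tables]
    xq = np.log10([i.q5_0 for i in inds])
    y45 = np.log10([i.q45_15 for i in inds])
    X_aux = np.column_stack([np.ones_like(xq), xq, xq * xq])
    aux, *_ = np.linalg.lstsq(X_aux, y45, rcond=None)

    std.gamma = gamma
    std.theta = theta
    std.aux_child_adult = aux
    std.calibration_meta = {"n_tables": len(tables), "sex": sex}
    return std


def predict_modlogit(
    std: ModLogitStandard,
    alpha: float,
    beta: float,
    a_rule: ARule = standard_a_rule,
    open_group_e: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    sex: str = "total",
    label: str = "",
) -> AbridgedLifeTable:
    """Generate a life table from (alpha, beta) through the standard.

    First pass Y0 = alpha + beta*Ys; the deviation covariates z_c, z_a
    are evaluated on the first pass (corrections do not feed back into
    them — the calibration defines them on the uncorrected transform),
    so the corrected schedule is the fixed point of the update map and
    the iteration below settles immediately; the loop guards the
    contract rather than doing real work.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    Ys = std.Ys
    Y0 = alpha + beta * Ys
    ic, ia = std.child_index, std.adult_index
    z_c = 1.0 - Y0[ic] / Ys[ic]
    z_a = 1.0 - Y0[ia] / Ys[ia]
    Y = Y0.copy()
    for _ in range(max_iter):
        Y_new = Y0 + std.gamma * z_c + std.theta * z_a
        delta = float(np.max(np.abs(Y_new - Y)))
        Y = Y_new
        if delta < tol:
            break
    else:
        raise CalibrationError(
            f"correction fixed point not reached in {max_iter} iterations "
            f"(last change {delta:.3g})"
        )

    p = np.asarray(inverse_logit_survivorship(Y))  # survivorship at interior boundaries
    l_ratio = np.concatenate([[1.0], p])
    if np.any(np.diff(l_ratio) >= 0):
        raise CalibrationError("predicted survivorship not strictly decreasing")
    q = np.empty(std.grid.n_groups)
    q[:-1] = 1.0 - l_ratio[1:] / l_ratio[:-1]
    q[-1] = 1.0
    return table_from_q(
        q, std.grid, a_rule=a_rule,
        open_group_e=open_group_e if open_group_e is not None else std.open_group_e,
        sex=sex, label=label,
    )


Case = Literal["q5_0", "q5_0&q45_15", "q5_0&e0"]


def _solve_alpha_for_q5(std: ModLogitStandard, beta: float, q5_target: float,
                        a_rule: ARule) -> float:
    """Inner 1-D solve: alpha such that the output 5q0 hits the target."""

    def f(alpha: float) -> float:
        return indicators(predict_modlogit(std, alpha, beta, a_rule=a_rule)).q5_0 - q5_target

    return _feasible_brentq(f, -6.0, 6.0,
                            f"5q0={q5_target:.6g} unattainable for beta={beta:.4g}")


def _feasible_brentq(f, lo: float, hi: float, fail_msg: str, n_scan: int = 49) -> float:
    """Brent root search tolerant of infeasible stretches of the axis.

    The correction terms can make predicted survivorship non-monotone
    far from the standard, so parts of [lo, hi] raise; scan a grid,
    keep the feasible points, and bracket the sign change among them.
    """
    def try_f(p: float) -> float | None:
        try:
            return f(p)
        except (CalibrationError, ValueError):
            return None

    grid_pts = np.linspace(lo, hi, n_scan)
    vals = [try_f(float(p)) for p in grid_pts]
    feas: list[tuple[float, float]] = []
    for i, (p, v) in enumerate(zip(grid_pts, vals)):
        if v is None:
            continue
        feas.append((float(p), v))
        # push toward adjacent infeasible grid points to cover the
        # sliver between the grid and the feasibility boundary
        for j in (i - 1, i + 1):
            if 0 <= j < n_scan and vals[j] is None:
                inner, outer = float(p), float(grid_pts[j])
                edge_val = v
                for _ in range(30):
                    mid = 0.5 * (inner + outer)
                    fv = try_f(mid)
                    if fv is None:
                        outer = mid
                    else:
                        inner, edge_val = mid, fv
                feas.append((inner, edge_val))
    feas.sort()
    if not feas:
        raise TargetRangeError(fail_msg)
    for (p0, f0), (p1, f1) in zip(feas[:-1], feas[1:]):
        if f0 == 0.0:
            return p0
        if f0 * f1 <= 0:
            return float(brentq(f, p0, p1, xtol=1e-14, rtol=8.9e-16))
    if feas[-1][1] == 0.0:
        return feas[-1][0]
    extremes = sorted(v for _, v in feas)
    raise TargetRangeError(fail_msg, attainable=(extremes[0], extremes[-1]))


def _nested_solve(std: ModLogitStandard, q5_target: float, second: str,
                  second_target: float, a_rule: ARule) -> tuple[float, float]:
    """Outer bisection on beta with the 5q0-exact inner alpha solve."""
    getter = {"q45_15": lambda i: i.q45_15, "e0": lambda i: i.e0}[second]

    def g(beta: float) -> float:
        alpha = _solve_alpha_for_q5(std, beta, q5_target, a_rule)
        return getter(indicators(predict_modlogit(std, alpha, beta, a_rule=a_rule))) - second_target

    beta = _feasible_brentq(
        g, 0.2, 4.0,
        f"{second}={second_target:.6g} unattainable with 5q0={q5_target:.6g}",
    )
    alpha = _solve_alpha_for_q5(std, beta, q5_target, a_rule)
    return alpha, beta


def match_modlogit(
    std: ModLogitStandard,
    case: Case,
    values: dict[str, float],
    a_rule: ARule = standard_a_rule,
    tol_q: float = 1e-9,
    tol_e0: float = 1e-7,
    method: Literal["newton", "nested"] = "newton",
) -> tuple[float, float]:
    """Solve (alpha, beta) so the output reproduces the case's inputs.

    Case "q5_0" fixes beta = 1 and solves alpha alone.  The
    two-indicator cases use a Newton-type 2-D root (scipy hybr) with
    the nested bisection solver as fallback; the returned pair always
    satisfies the 5q0 tolerance because the inner solve is re-polished
    at the final beta.
    """
    q5_target = values["q5_0"]
    if case == "q5_0":
        if std.aux_child_adult is None:
            # no companion regression available: plain child-matched transform
            alpha = _solve_alpha_for_q5(std, 1.0, q5_target, a_rule)
            return alpha, 1.0
        # predict the adult level from the child level, then match both
        # anchors: a beta = 1 transform cannot follow how the age slope
        # changes with the mortality level
        xq = np.log10(q5_target)
        p0, p1, p2 = std.aux_child_adult
        q45_hat = 10.0 ** (p0 + p1 * xq + p2 * xq * xq)
        return match_modlogit(std, "q5_0&q45_15",
                              {"q5_0": q5_target, "q45_15": q45_hat},
                              a_rule=a_rule, tol_q=tol_q, tol_e0=tol_e0,
                              method=method)

    second = "q45_15" if case == "q5_0&q45_15" else "e0"
    if case not in ("q5_0&q45_15", "q5_0&e0"):
        raise ValueError(f"unknown case {case!r}")
    second_target = values[second]
    getter = {"q45_15": lambda i: i.q45_15, "e0": lambda i: i.e0}[second]

    alpha = beta = None
    if method == "newton":
        def F(p):
            a_, b_ = p
            if b_ <= 0.05:
                return np.array([1e3, 1e3])
            try:
                ind = indicators(predict_modlogit(std, a_, b_, a_rule=a_rule))
            except (CalibrationError, ValueError):
                return np.array([1e3, 1e3])
            return np.array([ind.q5_0 - q5_target, getter(ind) - second_target])

        sol = root(F, x0=np.array([0.0, 1.0]), method="hybr", tol=1e-13)
        if sol.success:
            alpha, beta = float(sol.x[0]), float(sol.x[1])
    if alpha is None:
        alpha, beta = _nested_solve(std, q5_target, second, second_target, a_rule)

    # polish: guarantee the 5q0 tolerance at the final beta
    alpha = _solve_alpha_for_q5(std, beta, q5_target, a_rule)
    ind = indicators(predict_modlogit(std, alpha, beta, a_rule=a_rule))
    tol2 = tol_e0 if second == "e0" else tol_q
    if abs(ind.q5_0 - q5_target) > tol_q or abs(getter(ind) - second_target) > tol2:
        alpha, beta = _nested_solve(std, q5_target, second, second_target, a_rule)
        alpha = _solve_alpha_for_q5(std, beta, q5_target, a_rule)
        ind = indicators(predict_modlogit(std, alpha, beta, a_rule=a_rule))
        if abs(ind.q5_0 - q5_target) > tol_q or abs(getter(ind) - second_target) > tol2:
            raise TargetRangeError("matching did not reach tolerance")
    return alpha, beta
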