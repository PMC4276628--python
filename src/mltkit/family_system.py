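"""Family/level model life table system.

A discrete-pattern, continuous-level system in the tradition of the
regional model life tables: calibration tables are clustered into K
mortality-pattern "families" by model-based clustering of their
residual age profiles (after removing a pooled log-quadratic level
fit), and each family carries a one-dimensional level model — its own
log-quadratic fit restricted to k = 0, indexed by 5q0.

Given an input, a family is first selected (from 5q0 alone, or from
5q0 together with 45q15) and the family's level is then solved so the
output reproduces the chosen level parameter (5q0, 45q15 or e0)
exactly.  When the level parameter is not 5q0, the output's 5q0
generally differs from the observed one — the mechanism behind the
sign flips this system shows in the level-45q15 and level-e0 cases.

The module also provides the 45q15-range diagnostic: the envelope of
family-implied 45q15 values at a given 5q0 and the bookkeeping of
observed points falling below/above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .lifetable import (
    AbridgedLifeTable,
    AgeGrid,
    ARule,
    indicators,
    standard_a_rule,
)
from .logquad import (
    CalibrationError,
    LogQuadCoefficients,
    TargetRangeError,
    predict_logquad,
)

__all__ = [
    "FamilySystem",
    "RangeDiagnostic",
    "fit_families",
    "assign_family",
    "assign_family_from_table",
    "predict_family",
    "range_45q15",
    "range_diagnostic",
]


def _stage1_fit(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS of log-rates on (1, x, x^2); returns 3 x groups coefficients."""
    X = np.column_stack([np.ones_like(x), x, x * x])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta


@dataclass
class FamilySystem:
    """K family centroids with per-family one-dimensional level models."""

    K: int
    grid: AgeGrid
    centroids: np.ndarray                 # K x groups mean residual profiles
    level_models: list[LogQuadCoefficients]
    labels: np.ndarray                    # calibration assignment
    q5_stats: np.ndarray                  # K x 2: mean, sd of member log10(5q0)
    assignment_meta: dict = field(default_factory=dict)

    def family_q5_range(self, family: int) -> tuple[float, float]:
        return self.level_models[family].q5_range


def fit_families(
    corpus: Iterable[AbridgedLifeTable],
    sex: str = "total",
    K: int = 5,
    seed: int = 0,
) -> FamilySystem:
    """Cluster a calibration corpus into K mortality-pattern families.

    Features are per-table residual log-rate profiles after removing a
    pooled log-quadratic level fit; clustering is a full-covariance
    Gaussian mixture with a fixed seed (k-means fallback).  Each
    family's level model is then refit on its own members only.  An
    empty (or too small) cluster triggers a refit with K - 1.
    """
    tables = list(corpus)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(tables) < 5 * K:
        raise CalibrationError(f"corpus of {len(tables)} too small for K={K} (need >= {5 * K})")
    grid = tables[0].grid
    if any(t.grid != grid for t in tables):
        raise CalibrationError("all corpus tables must share one age grid")

    x = np.array([np.log10(indicators(t).q5_0) for t in tables])
    Y = np.log10(np.array([t.m for t in tables]))
    pooled = _stage1_fit(x, Y)
    X = np.column_stack([np.ones_like(x), x, x * x])
    resid = Y - X @ pooled

    # cluster in the leading principal subspace of the residual profiles:
    # a full-covariance mixture on all 20 age groups would carry far more
    # covariance parameters than tables per family
    n_comp = min(max(K + 1, 3), resid.shape[1], max(len(tables) // (5 * K), 2))
    features = PCA(n_components=n_comp, random_state=0).fit_transform(resid)

    while True:
        if K == 1:
            labels = np.zeros(len(tables), dtype=int)
        else:
            try:
                gmm = GaussianMixture(
                    n_components=K, covariance_type="full", random_state=seed,
                    n_init=5, reg_covar=1e-8,
                )
                labels = gmm.fit_predict(features)
            except Exception:  # singular fits on degenerate features
                labels = KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(features)
        counts = np.bincount(labels, minlength=K)
        if np.all(counts >= 4):
            break
        warnings.warn(f"cluster with < 4 members at K={K}; refitting with K={K - 1}",
                      stacklevel=2)
        K -= 1

    # canonical family order: ascending adult mortality deviation
    sel = (grid.group_starts >= 15) & (grid.group_starts < 60)
    adult_dev = np.array([resid[labels == j][:, sel].mean() for j in range(K)])
    order = np.argsort(adult_dev, kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    labels = remap[labels]

    centroids = np.array([resid[labels == j].mean(axis=0) for j in range(K)])
    level_models: list[LogQuadCoefficients] = []
    q5_stats = np.empty((K, 2))
    for j in range(K):
        mask = labels == j
        beta = _stage1_fit(x[mask], Y[mask])
        xs = x[mask]
        q5_stats[j] = (xs.mean(), max(xs.std(), 1e-3))
        level_models.append(
            LogQuadCoefficients(
                grid, beta[0], beta[1], beta[2], np.zeros(grid.n_groups),
                calibration_meta={
                    "n_tables": int(mask.sum()),
                    "sex": sex,
                    "q5_0_range": (float(10 ** xs.min()), float(10 ** xs.max())),
                    "family": j,
                },
            )
        )

    return FamilySystem(
        K=K, grid=grid, centroids=centroids, level_models=level_models,
        labels=labels, q5_stats=q5_stats,
        assignment_meta={"seed": seed, "sex": sex, "n_tables": len(tables),
                         "counts": np.bincount(labels, minlength=K).tolist()},
    )


def _implied_q45(system: FamilySystem, family: int, q5_0: float,
                 a_rule: ARule = standard_a_rule) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = predict_logquad(system.level_models[family], q5_0, 0.0, a_rule=a_rule)
    return indicators(t).q45_15


def assign_family(
    system: FamilySystem,
    q5_0: float,
    q45_15: float | None = None,
) -> int:
    """Pick the family for an observation.

    With 5q0 alone: the family whose calibration members' 5q0
    distribution (Gaussian on the log scale) gives the observation the
    highest density — i.e. the pattern most typical at that mortality
    level.  With 45q15 as well: the family whose level model at that
    5q0 implies the 45q15 closest (squared mismatch) to the observed
    one.  Ties break to the lowest family id.
    """
    lo = min(r[0] for r in (system.family_q5_range(j) for j in range(system.K)))
    hi = max(system.family_q5_range(j)[1] for j in range(system.K))
    if not (lo <= q5_0 <= hi):
        warnings.warn(f"5q0={q5_0:.5f} outside calibration range [{lo:.5f}, {hi:.5f}]",
                      stacklevel=2)
    if q45_15 is None:
        xq = np.log10(q5_0)
        mu, sd = system.q5_stats[:, 0], system.q5_stats[:, 1]
        logdens = -0.5 * ((xq - mu) / sd) ** 2 - np.log(sd)
        return int(np.argmax(np.round(logdens, 12)))
    mismatch = np.array(
        [(_implied_q45(system, j, q5_0) - q45_15) ** 2 for j in range(system.K)]
    )
    return int(np.argmin(np.round(mismatch, 15)))


def assign_family_from_table(system: FamilySystem, table: AbridgedLifeTable) -> int:
    """Nearest-centroid assignment of a full table in residual-profile space.

    Radix-invariant: only the age pattern of m enters.
    """
    x = np.log10(indicators(table).q5_0)
    # residual against each family's own level model at the table's 5q0
    Y = np.log10(table.m)
    dists = []
    for j in range(system.K):
        lm = system.level_models[j]
        fitted = lm.a_coef + lm.b_coef * x + lm.c_coef * x * x
        dists.append(float(np.linalg.norm(Y - fitted)))
    return int(np.argmin(np.round(dists, 12)))


def predict_family(
    system: FamilySystem,
    family: int,
    level_param: Literal["q5_0", "q45_15", "e0"],
    level_value: float,
    a_rule: ARule = standard_a_rule,
) -> AbridgedLifeTable:
    """Solve the family's level so the output matches the level parameter.

    With level_param = "q5_0" the level is the 5q0 index itself and the
    output's 5q0 equals the input exactly.  With "q45_15" or "e0" the
    5q0-level is found by bisection so the output reproduces the target
    to 1e-9 (probabilities) or 1e-7 years (e0); the output's 5q0 then
    generally differs from any observed value.
    """
    if not 0 <= family < system.K:
        raise ValueError(f"family {family} out of range (K={system.K})")
    lm = system.level_models[family]
    if level_param == "q5_0":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return predict_logquad(lm, level_value, 0.0, a_rule=a_rule)

    getter = {"q45_15": lambda i: i.q45_15, "e0": lambda i: i.e0}[level_param]
    tol = 1e-7 if level_param == "e0" else 1e-9
    lo, hi = lm.q5_range
    xlo, xhi = np.log10(lo), np.log10(hi)

    def f(xq: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = predict_logquad(lm, 10.0 ** xq, 0.0, a_rule=a_rule)
        return getter(indicators(t)) - level_value

    flo, fhi = f(xlo), f(xhi)
    expand = 0
    while flo * fhi > 0 and expand < 6:
        xlo -= 0.3
        xhi = min(xhi + 0.3, np.log10(0.5))
        flo, fhi = f(xlo), f(xhi)
        expand += 1
    if flo * fhi > 0:
        vals = sorted((f(s) + level_value for s in (xlo, xhi)))
        raise TargetRangeError(
            f"{level_param}={level_value:.6g} outside family {family}'s level range "
            f"({vals[0]:.6g}, {vals[1]:.6g})",
            attainable=(vals[0], vals[1]),
        )
    xq = brentq(f, xlo, xhi, xtol=1e-14, rtol=8.9e-16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = predict_logquad(lm, 10.0 ** xq, 0.0, a_rule=a_rule)
    if abs(getter(indicators(out)) - level_value) > tol:
        raise TargetRangeError(f"level matching did not reach tolerance {tol}")
    return out


def range_45q15(system: FamilySystem, q5_0: float,
                a_rule: ARule = standard_a_rule) -> tuple[float, float]:
    """Envelope (min, max) of family-implied 45q15 at a given 5q0."""
    vals = [_implied_q45(system, j, q5_0, a_rule) for j in range(system.K)]
    return (min(vals), max(vals))


@dataclass
class RangeDiagnostic:
    """Bookkeeping of observed (5q0, 45q15) points against the family envelope."""

    flags: list[str]                       # "below" | "within" | "above"
    relative_errors: np.ndarray            # % vs nearer bound; NaN when within
    percent_below: float
    percent_above: float
    percent_outside: float
    are_below: float                       # % (NaN when no such point)
    are_above: float
    are_outside: float
    n: int


def range_diagnostic(
    system: FamilySystem,
    observed_series: Sequence[tuple[float, float]],
    a_rule: ARule = standard_a_rule,
) -> RangeDiagnostic:
    """Flag each observed (5q0, 45q15) pair against the family envelope.

    A point outside the envelope gets a relative error measured
    against the nearer bound, 100*|obs - bound|/obs; aggregates are
    percentages of the series length.
    """
    pairs = list(observed_series)
    if not pairs:
        raise ValueError("observed series is empty")
    flags: list[str] = []
    rel = np.full(len(pairs), np.nan)
    for i, (q5, q45) in enumerate(pairs):
        lo, hi = range_45q15(system, q5, a_rule)
        if q45 < lo:
            flags.append("below")
            rel[i] = 100.0 * abs(q45 - lo) / q45
        elif q45 > hi:
            flags.append("above")
            rel[i] = 100.0 * abs(q45 - hi) / q45
        else:
            flags.append("within")
    n = len(pairs)
    below = np.array([f == "below" for f in flags])
    above = np.array([f == "above" for f in flags])

    def _mean(mask: np.ndarray) -> float:
        return float(rel[mask].mean()) if mask.any() else float("nan")

    return RangeDiagnostic(
        flags=flags,
        relative_errors=rel,
        percent_below=100.0 * below.sum() / n,
        percent_above=100.0 * above.sum() / n,
        percent_outside=100.0 * (below.sum() + above.sum()) / n,
        are_below=_mean(below),
        are_above=_mean(above),
        are_outside=_mean(below | above),
        n=n,
    )
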