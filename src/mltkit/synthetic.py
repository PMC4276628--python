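"""Synthetic calibration corpora and observed mortality series.

No mortality data ship with this package; everything the pipeline
consumes is generated here with the statistical structure the analysis
assumes:

* a calibration corpus of abridged life tables spanning a wide 5q0
  range, drawn from a known log-quadratic generative model (optionally
  with K family deviation patterns and log-rate noise), with the truth
  returned for parameter-recovery testing;
* a China-like annual observed series in which 5q0 declines at a
  constant (geometric) rate between printed endpoints, females have
  higher 5q0 than males in all but the final year yet higher e0 in
  every year, and adult/old-age rates sit below the calibration
  pattern so that systems matched on 5q0 alone overestimate 45q15 and
  20q60;
* matched other-country series from the published per-country 5q0
  endpoints, without the crossover and without the pattern deviation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lifetable import (
    AbridgedLifeTable,
    AgeGrid,
    MortalityIndicators,
    default_grid,
    indicators,
)
from .logquad import LogQuadCoefficients, constrained_table_from_rates

__all__ = [
    "CorpusConfig",
    "SeriesConfig",
    "SexSeries",
    "COUNTRY_5Q0_RANGES",
    "default_truth_coefficients",
    "family_deviation_patterns",
    "generate_corpus",
    "generate_china_like_series",
    "generate_country_series",
]


def default_truth_coefficients(sex: str = "total",
                               grid: AgeGrid | None = None) -> LogQuadCoefficients:
    """A realistic generative coefficient set on the standard 20-group grid.

    Constructed so that (i) rates increase with the 5q0 level at every
    age, with child mortality the most responsive; (ii) the implied
    1q0 stays at roughly 0.7-0.8 of 5q0 over the whole calibration
    range, leaving the 1-4 group constraint feasible; and (iii) the
    shape vector v is a unit-norm adult bump (ages 15-79), so positive
    k raises adult mortality.  The 1-4 row is non-generative (the
    under-five constraint determines that group) and its v entry is 0.

    ``sex="female"`` lowers the adult and old-age baseline (15+) by a
    factor 0.75 — the usual female survival advantage — so that
    per-sex calibration corpora and observed series share one base
    pattern; "male" and "total" use the base itself.
    """
    grid = grid if grid is not None else default_grid()
    if grid.n_groups != 20:
        raise ValueError("default truth coefficients are defined on the 20-group grid")
    base = np.array([-2.125, -3.30, -3.70, -3.82, -3.40, -3.22, -3.15, -3.05,
                     -2.92, -2.74, -2.55, -2.35, -2.15, -1.96, -1.74, -1.52,
                     -1.30, -1.05, -0.82, -0.60])
    b = np.array([1.05, 1.40, 1.30, 1.20, 1.00, 0.95, 0.90, 0.85, 0.80, 0.75,
                  0.68, 0.60, 0.52, 0.45, 0.38, 0.32, 0.26, 0.21, 0.17, 0.13])
    c = np.array([0.02, 0.10, 0.10, 0.10, 0.12, 0.12, 0.12, 0.11, 0.10, 0.09,
                  0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02, 0.015, 0.01, 0.008])
    a = base + 2.0 * b - 4.0 * c  # base values are log10(m) at 5q0 = 0.01
    v = np.array([0, 0, 0, 0, 0.15, 0.30, 0.38, 0.40, 0.38, 0.34, 0.30, 0.26,
                  0.22, 0.18, 0.14, 0.10, 0.06, 0, 0, 0], dtype=float)
    v /= np.linalg.norm(v)
    if sex == "female":
        a = a + np.where(grid.group_starts >= 15, np.log10(0.75), 0.0)
    elif sex not in ("male", "total"):
        raise ValueError("sex must be 'male', 'female' or 'total'")
    return LogQuadCoefficients(
        grid, a, b, c, v,
        calibration_meta={"q5_0_range": (0.0025, 0.13), "source": "synthetic truth",
                          "sex": sex},
    )


def family_deviation_patterns(K: int = 5, grid: AgeGrid | None = None,
                              spread: float = 0.10) -> np.ndarray:
    """K log10-rate deviation profiles (adult bump, ordered by severity).

    Family j's profile is delta_j * w with delta evenly spaced in
    [-spread, spread] and w a fixed bump over ages 15-79; childhood
    groups are untouched so the under-five constraint stays feasible.
    """
    grid = grid if grid is not None else default_grid()
    if grid.n_groups != 20:
        raise ValueError("patterns are defined on the 20-group grid")
    w = np.array([0, 0, 0, 0, 0.5, 0.8, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                  0.9, 0.8, 0.7, 0.6, 0.3, 0.15, 0], dtype=float)
    deltas = np.linspace(-spread, spread, K) if K > 1 else np.array([0.0])
    return np.outer(deltas, w)


@dataclass(frozen=True)
class CorpusConfig:
    """Generative settings for a calibration corpus."""

    n_tables: int = 200
    q5_range: tuple[float, float] = (0.0025, 0.10)
    coeffs: LogQuadCoefficients | None = None  # default truth when None
    k_bounds: tuple[float, float] = (-1.0, 1.0)
    noise_sd: float = 0.0
    family_patterns: np.ndarray | None = None  # K x groups deviations
    family_weights: np.ndarray | None = None   # default uniform
    family_q5_window: float = 1.0              # fraction of the log range per family
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.q5_range
        if not (0 < lo < hi < 1):
            raise ValueError("q5_range endpoints must be increasing and in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.family_weights is not None:
            w = np.asarray(self.family_weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
                raise ValueError("family weights must be non-negative and sum to 1")


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[AbridgedLifeTable], dict]:
    """Draw a corpus of abridged life tables plus the generative truth.

    Each table samples a 5q0 (log-uniform) and a k, computes log rates
    from the truth coefficients (+ optional family deviation + noise)
    and is built so its 5q0 equals the sampled value exactly.  The
    returned truth holds the coefficient arrays (the 1-4 row as NaN —
    that group is constraint-derived, not generative), per-table x =
    log10(5q0), k and family labels.
    """
    rng = np.random.default_rng(config.seed)
    coeffs = config.coeffs if config.coeffs is not None else default_truth_coefficients()
    grid = coeffs.grid
    xlo, xhi = np.log10(config.q5_range[0]), np.log10(config.q5_range[1])

    K = 0
    weights = None
    windows: list[tuple[float, float]] = []
    if config.family_patterns is not None:
        patterns = np.asarray(config.family_patterns, dtype=float)
        K = patterns.shape[0]
        weights = (np.asarray(config.family_weights, dtype=float)
                   if config.family_weights is not None else np.full(K, 1.0 / K))
        # per-family 5q0 windows: the full range when the window covers
        # it (families then vary pattern independently of level), else
        # overlapping windows ordered with pattern severity
        span = xhi - xlo
        if config.family_q5_window >= 1.0:
            windows = [(xlo, xhi)] * K
        else:
            half = 0.5 * config.family_q5_window * span
            centers = xlo + (np.arange(K) + 1.0) / (K + 1.0) * span
            windows = [(max(xlo, c - half), min(xhi, c + half)) for c in centers]

    # draw levels, scores and family labels up front
    fams = np.full(config.n_tables, -1)
    xs = np.empty(config.n_tables)
    for i in range(config.n_tables):
        if K:
            fams[i] = int(rng.choice(K, p=weights))
            wlo, whi = windows[fams[i]]
        else:
            wlo, whi = xlo, xhi
        xs[i] = rng.uniform(wlo, whi)
    ks = rng.uniform(*config.k_bounds, size=config.n_tables)
    if config.n_tables > 3:
        # canonical gauge: shape scores orthogonal to the level design
        # (1, x, x^2) — the component of k lying in the design space is
        # indistinguishable from a shift of (a, b, c) and is removed so
        # the generative parameters are the identifiable ones
        X = np.column_stack([np.ones_like(xs), xs, xs * xs])
        ks = ks - X @ np.linalg.lstsq(X, ks, rcond=None)[0]

    tables: list[AbridgedLifeTable] = []
    for i in range(config.n_tables):
        dev = patterns[fams[i]] if K else 0.0
        x, k = xs[i], ks[i]
        log_m_clean = (coeffs.a_coef + coeffs.b_coef * x + coeffs.c_coef * x * x
                       + coeffs.v_coef * k + dev)
        for _ in range(10):  # rare: noise may break the under-five constraint
            log_m = log_m_clean
            if config.noise_sd > 0:
                log_m = log_m + rng.normal(0.0, config.noise_sd, grid.n_groups)
            try:
                table = constrained_table_from_rates(
                    grid, 10.0 ** log_m, 10.0 ** x, label=f"synthetic-{i}"
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a feasible table; check config")
        tables.append(table)

    truth_a = coeffs.a_coef.copy()
    truth_b = coeffs.b_coef.copy()
    truth_c = coeffs.c_coef.copy()
    for vec in (truth_a, truth_b, truth_c):
        vec[1] = np.nan  # constraint-derived group
    truth = {
        "a": truth_a, "b": truth_b, "c": truth_c, "v": coeffs.v_coef.copy(),
        "x": xs, "k": ks,
        "family": fams if K else None,
        "nongenerative_groups": [1],
    }
    return tables, truth


# ---------------------------------------------------------------------------
# observed series
# ---------------------------------------------------------------------------

#: Published per-country 5q0 endpoints (start, end) per sex, with the
#: period and its calendar-year count n.
COUNTRY_5Q0_RANGES: dict[str, dict] = {
    "Bulgaria": {"period": "1961-2010", "n_years": 50,
                 "male": (0.05062, 0.01313), "female": (0.04134, 0.00981)},
    "Chile": {"period": "1992-2005", "n_years": 14,
              "male": (0.01941, 0.01070), "female": (0.01602, 0.00879)},
    "Poland": {"period": "1964-2009", "n_years": 46,
               "male": (0.05706, 0.00693), "female": (0.04557, 0.00693)},
    "China": {"period": "1994-2012", "n_years": 19,
              "male": (0.03946, 0.00698), "female": (0.05280, 0.00514)},
    "Japan": {"period": "1956-2012", "n_years": 57,
              "male": (0.05708, 0.00314), "female": (0.05036, 0.00293)},
    "Australia": {"period": "1950-2009", "n_years": 60,
                  "male": (0.03476, 0.00568), "female": (0.02715, 0.00442)},
    "Canada": {"period": "1950-2009", "n_years": 60,
               "male": (0.05472, 0.00588), "female": (0.04314, 0.00529)},
    "Denmark": {"period": "1950-2011", "n_years": 62,
                "male": (0.04090, 0.00408), "female": (0.03011, 0.00388)},
    "England and Wales": {"period": "1950-2011", "n_years": 62,
                          "male": (0.03823, 0.00578), "female": (0.03018, 0.00442)},
    "Italy": {"period": "1964-2009", "n_years": 46,
              "male": (0.04616, 0.00431), "female": (0.03907, 0.00364)},
    "USA": {"period": "1950-2010", "n_years": 61,
            "male": (0.04130, 0.00789), "female": (0.03230, 0.00789)},
}


@dataclass(frozen=True)
class SeriesConfig:
    """Settings for a China-like observed annual series.

    The default endpoints are the published Chinese 1994-2012 values
    per sex.  ``adult_mult``/``old_mult`` scale the 15-59 / 60-79
    rates relative to the (per-sex) calibration pattern; values below
    1 make 5q0-based model fits overestimate 45q15 and 20q60, the
    bias this series is meant to exhibit.  ``female_deviation_extra``
    multiplies the female deviation on top (below 1 deepens it, which
    both widens the female e0 lead and makes female adult-mortality
    errors the larger ones).  The female survival advantage itself
    lives in the per-sex truth coefficients, not here.
    """

    n_years: int = 19
    start_year: int = 1994
    male_q5: tuple[float, float] = (0.03946, 0.00698)
    female_q5: tuple[float, float] = (0.05280, 0.00514)
    crossover: bool = True
    adult_mult: float = 0.7
    old_mult: float = 0.7
    female_deviation_extra: float = 0.9
    level_scale: float = 1.0       # urban (<1) / rural (>1) overall 5q0 level
    deviation_scale: float = 1.0   # extra pattern deviation (urban > 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("need at least 3 years")
        for s, e in (self.male_q5, self.female_q5):
            if not (0 < e < s < 1):
                raise ValueError("5q0 must decline: start > end, both in (0, 1)")


@dataclass
class SexSeries:
    """One sex's annual series: indicator observations plus the tables behind them."""

    sex: str
    years: list[int]
    q5_path: np.ndarray
    indicators: list[MortalityIndicators]
    tables: list[AbridgedLifeTable]

    def labelled(self) -> list[tuple[str, MortalityIndicators]]:
        return [(str(y), ind) for y, ind in zip(self.years, self.indicators)]


def _geometric_path(start: float, end: float, n: int) -> np.ndarray:
    return start * (end / start) ** (np.arange(n) / (n - 1))


def _series_tables(
    coeffs: LogQuadCoefficients,
    q5_path: np.ndarray,
    sex: str,
    years: Sequence[int],
    adult_mult: float,
    old_mult: float,
    late_mult: float,
) -> tuple[list[MortalityIndicators], list[AbridgedLifeTable]]:
    grid = coeffs.grid
    starts = grid.group_starts
    adult = (starts >= 15) & (starts < 60)
    old = (starts >= 60) & (starts < 80)
    late = starts >= 80
    shift = np.zeros(grid.n_groups)
    shift[adult] = np.log10(adult_mult)
    shift[old] = np.log10(old_mult)
    shift[late] = np.log10(late_mult)
    inds, tabs = [], []
    for y, q5 in zip(years, q5_path):
        x = np.log10(q5)
        log_m = coeffs.a_coef + coeffs.b_coef * x + coeffs.c_coef * x * x + shift
        t = constrained_table_from_rates(grid, 10.0 ** log_m, q5, sex=sex, label=str(y))
        tabs.append(t)
        inds.append(indicators(t))
    return inds, tabs


def generate_china_like_series(
    config: SeriesConfig | None = None,
    coeffs: dict[str, LogQuadCoefficients] | None = None,
) -> dict[str, SexSeries]:
    """Generate the per-sex China-like observed series.

    5q0 declines geometrically between the configured endpoints.  With
    the crossover on, the female path is held above 1.02x the male
    path through the penultimate year (the minimal departure from the
    geometric path compatible with the published endpoints), and the
    generated schedules must give females the higher e0 in every year;
    endpoint infeasibility is signalled.  ``coeffs`` optionally maps
    sex to the truth coefficients to deviate from (defaults to the
    per-sex truths).
    """
    config = config if config is not None else SeriesConfig()
    if coeffs is None:
        coeffs = {s: default_truth_coefficients(s) for s in ("male", "female")}
    n = config.n_years
    years = [config.start_year + i for i in range(n)]

    male_path = _geometric_path(*config.male_q5, n) * config.level_scale
    female_path = _geometric_path(*config.female_q5, n) * config.level_scale
    if config.crossover:
        if not (female_path[0] > male_path[0] and female_path[-1] < male_path[-1]):
            raise ValueError(
                "crossover infeasible: need female 5q0 above male at the start "
                "and below at the end"
            )
        female_path[1:-1] = np.maximum(female_path[1:-1], 1.02 * male_path[1:-1])

    dev = config.deviation_scale
    adult_m = config.adult_mult ** dev
    old_m = config.old_mult ** dev
    out: dict[str, SexSeries] = {}
    for sex, path, extra in (("male", male_path, 1.0),
                             ("female", female_path, config.female_deviation_extra)):
        inds, tabs = _series_tables(
            coeffs[sex], path, sex, years,
            adult_mult=adult_m * extra, old_mult=old_m * extra, late_mult=1.0,
        )
        out[sex] = SexSeries(sex=sex, years=years, q5_path=path,
                             indicators=inds, tables=tabs)

    if config.crossover:
        e0_m = np.array([i.e0 for i in out["male"].indicators])
        e0_f = np.array([i.e0 for i in out["female"].indicators])
        if not np.all(e0_f > e0_m):
            raise ValueError(
                "crossover infeasible under these pattern settings: "
                "female e0 not above male in every year"
            )
        q5_m, q5_f = out["male"].q5_path, out["female"].q5_path
        assert np.all(q5_f[:-1] > q5_m[:-1]) and q5_f[-1] < q5_m[-1]
    return out


def generate_country_series(
    seed: int = 0,
    coeffs: dict[str, LogQuadCoefficients] | None = None,
    countries: Sequence[str] | None = None,
) -> dict[str, dict[str, SexSeries]]:
    """Per-country, per-sex series from the published 5q0 endpoints.

    Every country uses geometric 5q0 interpolation without pattern
    deviation; China alone keeps its crossover and deflated
    adult/old-age pattern (the China-like generator's defaults).
    """
    if coeffs is None:
        coeffs = {s: default_truth_coefficients(s) for s in ("male", "female")}
    names = list(countries) if countries is not None else list(COUNTRY_5Q0_RANGES)
    out: dict[str, dict[str, SexSeries]] = {}
    for name in names:
        spec = COUNTRY_5Q0_RANGES[name]
        start_year = int(spec["period"].split("-")[0])
        if name == "China":
            out[name] = generate_china_like_series(
                SeriesConfig(n_years=spec["n_years"], start_year=start_year,
                             male_q5=spec["male"], female_q5=spec["female"],
                             seed=seed),
                coeffs,
            )
            continue
        per_sex: dict[str, SexSeries] = {}
        years = [start_year + i for i in range(spec["n_years"])]
        for sex in ("male", "female"):
            path = _geometric_path(*spec[sex], spec["n_years"])
            inds, tabs = _series_tables(coeffs[sex], path, sex, years,
                                        adult_mult=1.0, old_mult=1.0, late_mult=1.0)
            per_sex[sex] = SexSeries(sex=sex, years=years, q5_path=path,
                                     indicators=inds, tables=tabs)
        out[name] = per_sex
    return out
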