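"""Evaluation pipeline: residuals, AREs, bias signs, trends, comparisons.

Each model system x input-case combination (the ten shorthand cases
C1, C2(level:5q0), C2(level:45q15), C3, W1-W3, M1-M3) is run on an
observed annual series of mortality indicators; for every year the
estimated full life table is summarised by 1q0, 5q0, 45q15, 20q60 and
e0 and compared with the observation.  Residuals are estimated minus
observed, so "+" means overestimation.  Accuracy is summarised by the
average relative error, ARE = 100 * mean(|est - obs| / obs), which is
comparable across mortality levels where a root-mean-squared error
would not be.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .lifetable import MortalityIndicators, indicators
from .logquad import LogQuadCoefficients, match_k, predict_logquad
from .modlogit import ModLogitStandard, match_modlogit, predict_modlogit
from .family_system import FamilySystem, assign_family, predict_family

__all__ = [
    "CaseSpec",
    "ALL_CASES",
    "ResidualRecord",
    "AREResult",
    "BiasClassification",
    "TrendResult",
    "run_case",
    "are",
    "classify_bias",
    "annual_decrease_rate",
    "annual_increase_age",
    "compare_groups",
]

INDICATORS = ("q1_0", "q5_0", "q45_15", "q20_60", "e0")

SystemName = Literal["logquad", "modlogit", "family"]
InputCase = Literal["q5_0", "q5_0&q45_15", "q5_0&e0"]


@dataclass(frozen=True)
class CaseSpec:
    """One model system with one input case (optionally a level choice)."""

    system: SystemName
    inputs: InputCase
    level_param: str | None = None  # family system only

    _SHORTHANDS = {
        "W1": ("logquad", "q5_0", None),
        "W2": ("logquad", "q5_0&q45_15", None),
        "W3": ("logquad", "q5_0&e0", None),
        "M1": ("modlogit", "q5_0", None),
        "M2": ("modlogit", "q5_0&q45_15", None),
        "M3": ("modlogit", "q5_0&e0", None),
        "C1": ("family", "q5_0", "q5_0"),
        "C2(level:5q0)": ("family", "q5_0&q45_15", "q5_0"),
        "C2(level:45q15)": ("family", "q5_0&q45_15", "q45_15"),
        "C3": ("family", "q5_0&e0", "e0"),
    }

    @classmethod
    def from_shorthand(cls, name: str) -> "CaseSpec":
        key = name.replace(" ", "")
        for short, spec in cls._SHORTHANDS.items():
            if short.replace(" ", "") == key:
                return cls(*spec)
        raise ValueError(f"unknown case shorthand {name!r}")

    @property
    def shorthand(self) -> str:
        for short, spec in self._SHORTHANDS.items():
            if spec == (self.system, self.inputs, self.level_param):
                return short
        return f"{self.system}:{self.inputs}:{self.level_param}"

    @property
    def exact_indicators(self) -> tuple[str, ...]:
        """Indicators reproduced exactly by construction of this case."""
        if self.system == "family":
            return (self.level_param,)
        if self.inputs == "q5_0":
            return ("q5_0",)
        second = "q45_15" if self.inputs == "q5_0&q45_15" else "e0"
        return ("q5_0", second)


ALL_CASES: tuple[str, ...] = tuple(CaseSpec._SHORTHANDS)


@dataclass(frozen=True)
class ResidualRecord:
    year: str
    case: str
    indicator: str
    observed: float
    estimated: float

    @property
    def residual(self) -> float:
        return self.estimated - self.observed


@dataclass(frozen=True)
class AREResult:
    indicator: str
    are_percent: float
    n: int
    case: str = ""
    group: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class BiasClassification:
    indicator: str
    cls: str  # one of "+", "-", "-+", "+-", "0"


@dataclass(frozen=True)
class TrendResult:
    decrease_rate_percent: float
    e0_gain_per_year: float | None
    period: str
    n_years: int


def _estimate_table(case: CaseSpec, systems: Mapping[str, object],
                    obs: MortalityIndicators):
    if case.system == "logquad":
        coeffs: LogQuadCoefficients = systems["logquad"]
        if case.inputs == "q5_0":
            k = 0.0
        elif case.inputs == "q5_0&q45_15":
            k = match_k(coeffs, obs.q5_0, "q45_15", obs.q45_15)
        else:
            k = match_k(coeffs, obs.q5_0, "e0", obs.e0)
        return predict_logquad(coeffs, obs.q5_0, k)
    if case.system == "modlogit":
        std: ModLogitStandard = systems["modlogit"]
        values = {"q5_0": obs.q5_0, "q45_15": obs.q45_15, "e0": obs.e0}
        alpha, beta = match_modlogit(std, case.inputs, values)
        return predict_modlogit(std, alpha, beta)
    fam_sys: FamilySystem = systems["family"]
    if case.inputs == "q5_0&q45_15":
        fam = assign_family(fam_sys, obs.q5_0, obs.q45_15)
    else:  # C1 and C3 pick the family from 5q0 alone
        fam = assign_family(fam_sys, obs.q5_0)
    level_value = getattr(obs, case.level_param)
    return predict_family(fam_sys, fam, case.level_param, level_value)


def run_case(
    case: CaseSpec | str,
    systems: Mapping[str, object],
    observed_series: Sequence[tuple[str, MortalityIndicators]] | Sequence[MortalityIndicators],
) -> list[ResidualRecord]:
    """Run one case over an observed series and emit residual records.

    ``observed_series`` is a sequence of (year label, indicators) pairs
    (bare indicator sequences get positional labels).  A year whose
    targets are unattainable is recorded with NaN estimates and a
    warning rather than aborting the run.
    """
    if isinstance(case, str):
        case = CaseSpec.from_shorthand(case)
    series: list[tuple[str, MortalityIndicators]] = []
    for i, item in enumerate(observed_series):
        if isinstance(item, MortalityIndicators):
            series.append((str(i), item))
        else:
            year, ind = item
            series.append((str(year), ind))

    records: list[ResidualRecord] = []
    for year, obs in series:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = indicators(_estimate_table(case, systems, obs))
            est_d = est.as_dict()
        except Exception as exc:  # record, do not abort the series
            warnings.warn(f"case {case.shorthand}, year {year}: {exc}", stacklevel=2)
            est_d = {name: float("nan") for name in INDICATORS}
        obs_d = obs.as_dict()
        for name in INDICATORS:
            records.append(ResidualRecord(
                year=year, case=case.shorthand, indicator=name,
                observed=obs_d[name], estimated=est_d[name],
            ))
    return records


def residuals_frame(records: Iterable[ResidualRecord]) -> pd.DataFrame:
    """Tidy frame: one row per year x case x indicator."""
    df = pd.DataFrame([
        {"year": r.year, "case": r.case, "indicator": r.indicator,
         "observed": r.observed, "estimated": r.estimated, "residual": r.residual}
        for r in records
    ])
    return df


def are(
    records: Sequence[ResidualRecord],
    case: str = "",
    group: Mapping[str, str] | None = None,
) -> AREResult:
    """Average relative error, 100 * mean(|est - obs|/obs), for one slice.

    All records must concern a single indicator; observations equal to
    zero are excluded with a warning.
    """
    inds = {r.indicator for r in records}
    if len(inds) != 1:
        raise ValueError(f"records mix indicators {sorted(inds)}; pass one slice")
    obs = np.array([r.observed for r in records], dtype=float)
    est = np.array([r.estimated for r in records], dtype=float)
    keep = obs != 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero observations from ARE",
                      stacklevel=2)
    obs, est = obs[keep], est[keep]
    if obs.size == 0:
        raise ValueError("no usable observations for ARE")
    value = 100.0 * float(np.mean(np.abs(est - obs) / obs))
    return AREResult(indicator=inds.pop(), are_percent=value, n=int(obs.size),
                     case=case or (records[0].case if records else ""),
                     group=dict(group or {}))


def classify_bias(
    residuals: Sequence[float],
    tol: float = 1e-8,
    indicator: str = "",
) -> BiasClassification:
    """Classify the sign pattern of a residual series.

    "0" when all residuals are within tolerance; "+" / "-" when at
    least 90% of the above-tolerance residuals share a sign; "-+" or
    "+-" when the (3-point median smoothed) sign sequence has exactly
    one sign change; otherwise the majority sign.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals to classify")
    nz = r[np.abs(r) > tol]
    if nz.size == 0:
        return BiasClassification(indicator, "0")
    pos_frac = float((nz > 0).mean())
    if pos_frac >= 0.9:
        return BiasClassification(indicator, "+")
    if pos_frac <= 0.1:
        return BiasClassification(indicator, "-")

    signs = np.sign(nz)
    padded = np.concatenate([[signs[0]], signs, [signs[-1]]])
    smooth = np.array([np.median(padded[i:i + 3]) for i in range(signs.size)])
    smooth = smooth[smooth != 0]
    changes = int(np.count_nonzero(np.diff(smooth) != 0))
    if changes == 1:
        return BiasClassification(indicator, "-+" if smooth[0] < 0 else "+-")
    return BiasClassification(indicator, "+" if pos_frac >= 0.5 else "-")


def annual_decrease_rate(q1: float, q2: float, n_years: int) -> float:
    """Constant annual decline rate r (%/year) of 5q0 over a period.

    Solves q1 * (1 - r/100)^(n_years - 1) = q2 — compounding over the
    n_years - 1 intervals between the first and last calendar year —
    and returns the positive decline rate when mortality falls.
    """
    if q1 <= 0 or q2 <= 0:
        raise ValueError("probabilities must be positive")
    if n_years < 2:
        raise ValueError("need at least 2 calendar years")
    return 100.0 * (1.0 - (q2 / q1) ** (1.0 / (n_years - 1)))


def annual_increase_age(e01: float, e02: float, n_years: int) -> float:
    """Average annual gain of e0 (years/year), same interval convention."""
    if n_years < 2:
        raise ValueError("need at least 2 calendar years")
    return (e02 - e01) / (n_years - 1)


def trend(q1: float, q2: float, n_years: int, period: str = "",
          e01: float | None = None, e02: float | None = None) -> TrendResult:
    gain = annual_increase_age(e01, e02, n_years) if e01 is not None and e02 is not None else None
    return TrendResult(
        decrease_rate_percent=annual_decrease_rate(q1, q2, n_years),
        e0_gain_per_year=gain, period=period, n_years=n_years,
    )


def compare_groups(
    results: Mapping[str, Sequence[AREResult]],
    group_key: str = "group",
) -> pd.DataFrame:
    """Long-format comparison of AREs across groups with larger-group flags.

    ``results`` maps a group label (e.g. "male"/"female") to its
    AREResults.  Rows are case x indicator x group; ``is_larger`` flags
    the strictly largest ARE within each (case, indicator) pair (ties
    are left unflagged).  Cells missing in a group are flagged absent.
    """
    rows = []
    for label, ares in results.items():
        for a in ares:
            rows.append({
                "case": a.case, "indicator": a.indicator, group_key: label,
                "are_percent": a.are_percent, "n": a.n,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(is_larger=[], absent=[])

    full_index = pd.MultiIndex.from_product(
        [df["case"].unique(), df["indicator"].unique(), list(results)],
        names=["case", "indicator", group_key],
    )
    df = (df.set_index(["case", "indicator", group_key])
            .reindex(full_index)
            .reset_index())
    df["absent"] = df["are_percent"].isna()

    grp = df.groupby(["case", "indicator"])["are_percent"]
    grp_max = grp.transform("max")
    n_at_max = grp.transform(lambda v: (v == v.max()).sum())
    df["is_larger"] = (df["are_percent"] == grp_max) & df["are_percent"].notna() & (n_at_max == 1)
    return df
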