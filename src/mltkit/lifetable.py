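"""Abridged life table machinery.

Age grid, construction of abridged life tables from central death rates
(m) or from death probabilities (q), and extraction of the summary
mortality indicators (1q0, 5q0, 45q15, 20q60, e0) that the model life
table systems in this package are matched against.

Conventions
-----------
* Ages are exact years; age groups are half-open intervals [x, x+n).
* The default grid is 0-1, 1-4, then 5-year groups with an open
  interval starting at 90 (configurable to 100).
* Probabilities are stored as proportions; the radix is 100 000.
* In the open interval q = 1 and L = l/m, i.e. e at the open age equals
  1/m there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

RADIX = 100_000.0

__all__ = [
    "RADIX",
    "AgeGrid",
    "AbridgedLifeTable",
    "MortalityIndicators",
    "default_grid",
    "standard_a_rule",
    "build_life_table",
    "table_from_q",
    "indicators",
]


class LifeTableError(ValueError):
    """Inconsistent or out-of-range life table inputs."""


@dataclass(frozen=True)
class AgeGrid:
    """Contiguous abridged age grid with a single open terminal group.

    ``group_starts`` are the exact starting ages and ``group_widths``
    the interval lengths in years; the terminal width is ``np.inf``.
    """

    group_starts: np.ndarray
    group_widths: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.group_starts, dtype=float)
        widths = np.asarray(self.group_widths, dtype=float)
        object.__setattr__(self, "group_starts", starts)
        object.__setattr__(self, "group_widths", widths)
        if starts.ndim != 1 or starts.shape != widths.shape:
            raise LifeTableError("group_starts and group_widths must be 1-D and equal length")
        if not np.isinf(widths[-1]):
            raise LifeTableError("terminal group must be open (infinite width)")
        if np.isinf(widths[:-1]).any():
            raise LifeTableError("only the terminal group may be open")
        if not np.allclose(starts[1:], starts[:-1] + widths[:-1]):
            raise LifeTableError("age groups must be contiguous")

    @property
    def n_groups(self) -> int:
        return self.group_starts.size

    @property
    def open_interval_start(self) -> float:
        return float(self.group_starts[-1])

    def index_of_age(self, age: float) -> int:
        """Index of the group starting exactly at ``age``."""
        hits = np.nonzero(self.group_starts == age)[0]
        if hits.size == 0:
            raise LifeTableError(f"age {age} is not a group boundary of this grid")
        return int(hits[0])

    def __eq__(self, other: object) -> bool:  # arrays make the default unusable
        if not isinstance(other, AgeGrid):
            return NotImplemented
        return np.array_equal(self.group_starts, other.group_starts) and np.array_equal(
            self.group_widths, other.group_widths
        )

    def __hash__(self) -> int:
        return hash((tuple(self.group_starts), tuple(self.group_widths[:-1])))


def default_grid(open_age: int = 90) -> AgeGrid:
    """The standard abridged grid: 0-1, 1-4, 5-year groups, open at 90 (or 100)."""
    if open_age not in (90, 100):
        raise LifeTableError("open_age must be 90 or 100")
    starts = [0.0, 1.0] + list(np.arange(5.0, open_age + 1, 5.0))
    widths = [1.0, 4.0] + [5.0] * (len(starts) - 3) + [np.inf]
    return AgeGrid(np.array(starts), np.array(widths))


# ---------------------------------------------------------------------------
# separation factors
# ---------------------------------------------------------------------------

ARule = Callable[[np.ndarray, AgeGrid], np.ndarray]


def standard_a_rule(m: np.ndarray, grid: AgeGrid) -> np.ndarray:
    """Average years lived in-group by decedents (nax) for closed groups.

    a0 = 0.3 when infant mortality is high (m0 >= 0.01), else the smooth
    low-mortality value 0.1 + 20*m0; a(1-4) = 1.5; n/2 elsewhere.  The
    open-group entry is NaN (handled via L = l/m).
    """
    a = grid.group_widths / 2.0
    m0 = float(m[0])
    a[0] = 0.3 if m0 >= 0.01 else 0.1 + 20.0 * m0
    a[1] = 1.5
    a[-1] = np.nan
    return a


@dataclass
class AbridgedLifeTable:
    """One sex-period mortality schedule with full life table columns."""

    grid: AgeGrid
    m: np.ndarray
    q: np.ndarray
    a: np.ndarray
    l: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    sex: str = "total"
    label: str = ""

    def validate(self, atol: float = 1e-9) -> None:
        q, l = self.q, self.l
        if np.any((q < -atol) | (q > 1 + atol)):
            raise LifeTableError("q outside [0, 1]")
        if abs(q[-1] - 1.0) > atol:
            raise LifeTableError("open-group q must be 1")
        if np.any(np.diff(l) > atol * RADIX):
            raise LifeTableError("l must be non-increasing")
        if abs(l[0] - RADIX) > atol * RADIX:
            raise LifeTableError("l(0) must equal the radix")
        if np.any(self.e < -atol):
            raise LifeTableError("negative life expectancy")

    def survivorship(self, age: float) -> float:
        """l(age)/l(0) at a grid boundary."""
        if age == 0:
            return 1.0
        return float(self.l[self.grid.index_of_age(age)] / self.l[0])

    def with_labels(self, sex: str | None = None, label: str | None = None) -> "AbridgedLifeTable":
        return replace(self, sex=sex if sex is not None else self.sex,
                       label=label if label is not None else self.label)


@dataclass(frozen=True)
class MortalityIndicators:
    """The five summary indicators used throughout the assessment."""

    q1_0: float
    q5_0: float
    q45_15: float
    q20_60: float
    e0: float

    def as_dict(self) -> dict[str, float]:
        return {
            "q1_0": self.q1_0,
            "q5_0": self.q5_0,
            "q45_15": self.q45_15,
            "q20_60": self.q20_60,
            "e0": self.e0,
        }


def _chain_columns(
    grid: AgeGrid, m: np.ndarray, q: np.ndarray, a: np.ndarray, open_group_e: float
) -> AbridgedLifeTable:
    """Chain l, L, T, e from per-group q (and open-group expectation)."""
    n = grid.n_groups
    l = np.empty(n)
    l[0] = RADIX
    for i in range(n - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty(n)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]
    L = np.empty(n)
    widths = grid.group_widths
    L[:-1] = widths[:-1] * l[1:] + a[:-1] * d[:-1]
    L[-1] = l[-1] * open_group_e
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return AbridgedLifeTable(grid=grid, m=m, q=q, a=a, l=l, L=L, T=T, e=e)


def build_life_table(
    m_schedule: np.ndarray,
    grid: AgeGrid | None = None,
    a_rule: ARule = standard_a_rule,
    sex: str = "total",
    label: str = "",
) -> AbridgedLifeTable:
    """Construct an abridged life table from central death rates.

    Closed groups use q = n*m / (1 + (n - a)*m); the open group has
    q = 1 and L = l/m.
    """
    grid = grid if grid is not None else default_grid()
    m = np.asarray(m_schedule, dtype=float)
    if m.shape != (grid.n_groups,):
        raise LifeTableError(
            f"m schedule has length {m.size}, grid has {grid.n_groups} groups"
        )
    if m[-1] <= 0:
        raise LifeTableError("open-group m must be strictly positive")
    if np.any(m[:-1] < 0):
        raise LifeTableError("negative death rate")
    a = a_rule(m, grid)
    n_w = grid.group_widths
    q = np.empty_like(m)
    q[:-1] = n_w[:-1] * m[:-1] / (1.0 + (n_w[:-1] - a[:-1]) * m[:-1])
    q[-1] = 1.0
    if np.any(q[:-1] < 0) or np.any(q[:-1] >= 1):
        raise LifeTableError("m/a inputs imply q outside [0, 1) in a closed group")
    table = _chain_columns(grid, m, q, a, open_group_e=1.0 / m[-1])
    return table.with_labels(sex=sex, label=label)


def table_from_q(
    q_schedule: np.ndarray,
    grid: AgeGrid | None = None,
    a_rule: ARule = standard_a_rule,
    open_group_e: float = 4.0,
    sex: str = "total",
    label: str = "",
) -> AbridgedLifeTable:
    """Construct an abridged life table from death probabilities.

    The open group is specified through ``open_group_e``, the
    expectation of life at the open-interval start (so m there is
    1/open_group_e).  Closed-group m is recovered consistently with
    ``build_life_table`` via m = q / (n - (n - a)*q); because the a
    rule may depend on m0, the (a0, m0) pair is resolved by a short
    fixed-point iteration.
    """
    grid = grid if grid is not None else default_grid()
    q = np.asarray(q_schedule, dtype=float)
    if q.shape != (grid.n_groups,):
        raise LifeTableError("q schedule length mismatch")
    if np.any(q[:-1] < 0) or np.any(q[:-1] >= 1):
        raise LifeTableError("closed-group q must lie in [0, 1)")
    if open_group_e <= 0:
        raise LifeTableError("open_group_e must be positive")
    q = q.copy()
    q[-1] = 1.0
    n_w = grid.group_widths

    # resolve a (which may depend on m0) against m implied by q
    m = np.empty_like(q)
    m[0] = q[0]  # starting guess
    a = a_rule(m, grid)
    for _ in range(50):
        m[:-1] = q[:-1] / (n_w[:-1] - (n_w[:-1] - a[:-1]) * q[:-1])
        new_a = a_rule(m, grid)
        if abs(new_a[0] - a[0]) < 1e-15:
            a = new_a
            break
        a = new_a
    m[:-1] = q[:-1] / (n_w[:-1] - (n_w[:-1] - a[:-1]) * q[:-1])
    m[-1] = 1.0 / open_group_e
    table = _chain_columns(grid, m, q, a, open_group_e=open_group_e)
    return table.with_labels(sex=sex, label=label)


def indicators(table: AbridgedLifeTable) -> MortalityIndicators:
    """Extract 1q0, 5q0, 45q15, 20q60 and e0 from a life table."""
    s = table.survivorship
    return MortalityIndicators(
        q1_0=1.0 - s(1),
        q5_0=1.0 - s(5),
        q45_15=1.0 - s(60) / s(15),
        q20_60=1.0 - s(80) / s(60),
        e0=float(table.T[0] / table.l[0]),
    )
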