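"""Readers and writers for life tables and calibrated systems.

Life tables travel as plain CSV with one row per age group (columns
age_start, age_width with -1 for the open interval, m, q, a, l, L, T,
e).  HMD-style single-year period life table text files (whitespace
delimited, "110+"-style terminal age) are aggregated onto the abridged
grid conserving person-years.  Calibrated systems serialise to CSV
plus a JSON sidecar of calibration metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import (
    RADIX,
    AbridgedLifeTable,
    AgeGrid,
    LifeTableError,
    default_grid,
)
from .logquad import LogQuadCoefficients
from .modlogit import ModLogitStandard
from .family_system import FamilySystem

__all__ = [
    "read_life_table_csv",
    "write_life_table_csv",
    "read_hmd_life_table",
    "write_logquad_csv",
    "read_logquad_csv",
    "write_modlogit_csv",
    "read_modlogit_csv",
    "write_family_system",
    "read_family_system",
]

_LT_COLUMNS = ["age_start", "age_width", "m", "q", "a", "l", "L", "T", "e"]


def write_life_table_csv(table: AbridgedLifeTable, path: str | Path) -> None:
    widths = np.where(np.isinf(table.grid.group_widths), -1.0, table.grid.group_widths)
    df = pd.DataFrame({
        "age_start": table.grid.group_starts,
        "age_width": widths,
        "m": table.m, "q": table.q, "a": table.a,
        "l": table.l, "L": table.L, "T": table.T, "e": table.e,
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_life_table_csv(path: str | Path, sex: str = "total",
                        label: str = "") -> AbridgedLifeTable:
    """Read the life table CSV schema; violations report row numbers."""
    df = pd.read_csv(path)
    missing = [c for c in _LT_COLUMNS if c not in df.columns]
    if missing:
        raise LifeTableError(f"{path}: missing columns {missing}")
    starts = df["age_start"].to_numpy(dtype=float)
    if np.any(np.diff(starts) <= 0):
        row = int(np.nonzero(np.diff(starts) <= 0)[0][0]) + 1
        raise LifeTableError(f"{path}: non-monotone age_start at row {row}")
    widths = df["age_width"].to_numpy(dtype=float)
    widths = np.where(widths < 0, np.inf, widths)
    q = df["q"].to_numpy(dtype=float)
    bad = np.nonzero((q[:-1] < 0) | (q[:-1] >= 1))[0]
    if bad.size:
        raise LifeTableError(f"{path}: q out of [0, 1) at row {int(bad[0])}")
    grid = AgeGrid(starts, widths)
    table = AbridgedLifeTable(
        grid=grid,
        m=df["m"].to_numpy(dtype=float), q=q, a=df["a"].to_numpy(dtype=float),
        l=df["l"].to_numpy(dtype=float), L=df["L"].to_numpy(dtype=float),
        T=df["T"].to_numpy(dtype=float), e=df["e"].to_numpy(dtype=float),
        sex=sex, label=label or Path(path).stem,
    )
    table.validate(atol=1e-6)
    return table


def read_hmd_life_table(path: str | Path, grid: AgeGrid | None = None,
                        sex: str = "total", label: str = "") -> AbridgedLifeTable:
    """Aggregate an HMD-style single-year period life table onto a grid.

    Expects whitespace-delimited columns Age, mx, qx, ax, lx, dx, Lx,
    Tx, ex (a leading Year column is tolerated); the terminal age is
    written "110+".  Aggregation conserves person-years: group L and d
    are sums of the single-year values, l is taken at group starts,
    and m, q, a, T, e are rebuilt from those.
    """
    grid = grid if grid is not None else default_grid()
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        first = parts[0]
        if first.lower() in ("age", "year") and not first.rstrip("+").isdigit():
            continue
        # tolerate a leading Year column
        if len(parts) >= 10 and parts[1].rstrip("+").isdigit():
            parts = parts[1:]
        if len(parts) < 9 or not parts[0].rstrip("+").isdigit():
            continue
        age = int(parts[0].rstrip("+"))
        try:
            vals = [float(v) for v in parts[1:9]]
        except ValueError:
            continue
        rows.append((age, *vals))
    if not rows:
        raise LifeTableError(f"{path}: no parsable rows")
    df = pd.DataFrame(rows, columns=["age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"])
    df = df.sort_values("age").reset_index(drop=True)

    starts = grid.group_starts
    n = grid.n_groups
    l = np.empty(n)
    L = np.empty(n)
    d = np.empty(n)
    a = np.empty(n)
    scale = RADIX / df["lx"].iloc[0]
    for i in range(n):
        lo = starts[i]
        hi = starts[i + 1] if i + 1 < n else np.inf
        block = df[(df["age"] >= lo) & (df["age"] < hi)]
        if block.empty or df[df["age"] == lo].empty:
            raise LifeTableError(f"{path}: missing ages for group starting {lo}")
        l[i] = df.loc[df["age"] == lo, "lx"].iloc[0] * scale
        L[i] = block["Lx"].sum() * scale
        d[i] = block["dx"].sum() * scale
    q = np.empty(n)
    q[:-1] = d[:-1] / l[:-1]
    q[-1] = 1.0
    m = d / L
    widths = grid.group_widths
    with np.errstate(invalid="ignore"):
        a[:-1] = (L[:-1] - widths[:-1] * (l[:-1] - d[:-1])) / d[:-1]
    a[-1] = np.nan
    T = np.cumsum(L[::-1])[::-1]
    e = T / l
    table = AbridgedLifeTable(grid=grid, m=m, q=q, a=a, l=l, L=L, T=T, e=e,
                              sex=sex, label=label or Path(path).stem)
    table.validate(atol=1e-6)
    return table


# ---------------------------------------------------------------------------
# calibrated systems
# ---------------------------------------------------------------------------

def write_logquad_csv(coeffs: LogQuadCoefficients, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({
        "age_start": coeffs.grid.group_starts,
        "a": coeffs.a_coef, "b": coeffs.b_coef, "c": coeffs.c_coef, "v": coeffs.v_coef,
    }).to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(".meta.json").write_text(
        json.dumps(coeffs.calibration_meta, indent=1, default=str))


def read_logquad_csv(path: str | Path, grid: AgeGrid | None = None) -> LogQuadCoefficients:
    path = Path(path)
    df = pd.read_csv(path)
    grid = grid if grid is not None else default_grid()
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if "q5_0_range" in meta:
        meta["q5_0_range"] = tuple(meta["q5_0_range"])
    return LogQuadCoefficients(
        grid, df["a"].to_numpy(), df["b"].to_numpy(), df["c"].to_numpy(),
        df["v"].to_numpy(), calibration_meta=meta)


def write_modlogit_csv(std: ModLogitStandard, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({
        "age_boundary": std.boundaries,
        "Ys": std.Ys, "gamma": std.gamma, "theta": std.theta,
    }).to_csv(path, index=False, float_format="%.17g")
    meta = dict(std.calibration_meta)
    meta["open_group_e"] = std.open_group_e
    meta["anchor_ages"] = list(std.anchor_ages)
    if std.aux_child_adult is not None:
        meta["aux_child_adult"] = list(map(float, std.aux_child_adult))
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def read_modlogit_csv(path: str | Path, grid: AgeGrid | None = None) -> ModLogitStandard:
    path = Path(path)
    df = pd.read_csv(path)
    grid = grid if grid is not None else default_grid()
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    aux = meta.pop("aux_child_adult", None)
    return ModLogitStandard(
        grid=grid, boundaries=df["age_boundary"].to_numpy(),
        Ys=df["Ys"].to_numpy(), gamma=df["gamma"].to_numpy(),
        theta=df["theta"].to_numpy(),
        open_group_e=float(meta.pop("open_group_e")),
        anchor_ages=tuple(meta.pop("anchor_ages", (5.0, 60.0))),
        aux_child_adult=np.asarray(aux, dtype=float) if aux is not None else None,
        calibration_meta=meta)


def write_family_system(system: FamilySystem, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j, lm in enumerate(system.level_models):
        write_logquad_csv(lm, directory / f"family_{j}.csv")
    manifest = {
        "K": system.K,
        "assignment_meta": system.assignment_meta,
        "labels": system.labels.tolist(),
        "q5_stats": system.q5_stats.tolist(),
        "centroids": system.centroids.tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def read_family_system(directory: str | Path, grid: AgeGrid | None = None) -> FamilySystem:
    directory = Path(directory)
    grid = grid if grid is not None else default_grid()
    manifest = json.loads((directory / "manifest.json").read_text())
    K = int(manifest["K"])
    level_models = [read_logquad_csv(directory / f"family_{j}.csv", grid) for j in range(K)]
    return FamilySystem(
        K=K, grid=grid,
        centroids=np.asarray(manifest["centroids"], dtype=float),
        level_models=level_models,
        labels=np.asarray(manifest["labels"], dtype=int),
        q5_stats=np.asarray(manifest["q5_stats"], dtype=float),
        assignment_meta=manifest.get("assignment_meta", {}),
    )
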