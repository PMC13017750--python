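"""Reading, validation and preprocessing of digitized Kaplan-Meier curves.

Digitized survival curves arrive as sparse (time, probability) coordinates
extracted from published figures, together with the number-at-risk table
printed beneath the plot.  This module turns those raw series into
analysis-ready curves on a uniform time grid:

* :class:`KMCoordinates` -- validated, time-sorted raw coordinates;
* :func:`enforce_monotone` -- running-minimum repair of digitization noise;
* :func:`interpolate_to_grid` -- linear interpolation onto a uniform grid
  (default 0.5-month step), truncated, never extrapolated;
* :class:`RiskTable` / :class:`KMCurve` -- the downstream containers.

CSV dialect
-----------
Curve files: columns ``time_months,survival`` (header optional), UTF-8,
``.`` decimal separator, ``#`` comment lines allowed.  Times in months,
survival as a fraction in [0, 1] -- percent-scale inputs are rejected, not
rescaled.  Risk tables: columns ``time_months,n_at_risk``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "KMValidationError",
    "ExtrapolationError",
    "KMCoordinates",
    "RiskTable",
    "KMCurve",
    "read_km_csv",
    "read_risk_table_csv",
    "write_km_csv",
    "enforce_monotone",
    "interpolate_to_grid",
    "common_t_max",
]

#: survival values in (1, 1 + BOUND_TOL] are clamped to 1; beyond that, error
BOUND_TOL = 1e-6


class KMValidationError(ValueError):
    """Raised when digitized coordinates or risk tables violate invariants."""


class ExtrapolationError(ValueError):
    """Raised when a grid would extend beyond the digitized follow-up."""


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise KMValidationError("non-finite value in coordinate series")
    return a


@dataclass(frozen=True)
class KMCoordinates:
    """One arm's digitized survival coordinates, normalized.

    Normalization applied on construction: time-sort; duplicate times
    collapsed to their minimum survival; a (0, 1.0) anchor prepended when
    absent (and survival forced to 1.0 at t=0, since S(0)=1 by definition);
    values in (1, 1+1e-6] clamped to 1.  Survival outside [0, 1] beyond that
    tolerance, or negative times, raise :class:`KMValidationError`.
    """

    times: np.ndarray
    survival: np.ndarray
    arm_label: str = ""
    source_trial: str = ""

    def __post_init__(self):
        t = _as_float_array(self.times)
        s = _as_float_array(self.survival)
        if t.size != s.size:
            raise KMValidationError("times and survival have different lengths")
        if t.size == 0:
            raise KMValidationError("empty coordinate series")
        if np.any(t < 0):
            raise KMValidationError("negative time in coordinates")
        s = np.where((s > 1.0) & (s <= 1.0 + BOUND_TOL), 1.0, s)
        if np.any(s < -BOUND_TOL) or np.any(s > 1.0):
            bad = s[(s < -BOUND_TOL) | (s > 1.0)][0]
            raise KMValidationError(f"survival value {bad!r} outside [0, 1]")
        s = np.clip(s, 0.0, 1.0)
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        uniq, inverse = np.unique(t, return_inverse=True)
        if uniq.size != t.size:
            smin = np.full(uniq.size, np.inf)
            np.minimum.at(smin, inverse, s)
            t, s = uniq, smin
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        else:
            s = s.copy()
            s[0] = 1.0
        if t.size < 2:
            raise KMValidationError("need at least 2 coordinate points")
        t.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def last_time(self) -> float:
        return float(self.times[-1])

    def is_monotone(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.diff(self.survival) <= tol))


@dataclass(frozen=True)
class RiskTable:
    """Published number-at-risk counts at scheduled times.

    Times strictly increasing starting at 0; counts nonnegative integers,
    non-increasing.  The count at time 0 is the arm's sample size.
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.times)
        c = np.asarray(self.counts).ravel()
        if t.size != c.size:
            raise KMValidationError("risk table times/counts length mismatch")
        if t.size == 0:
            raise KMValidationError("empty risk table")
        if np.any(np.diff(t) <= 0):
            raise KMValidationError("risk table times must be strictly increasing")
        if t[0] != 0:
            raise KMValidationError("risk table must start at time 0")
        if np.any(c != np.floor(c)) or np.any(np.asarray(c, dtype=float) < 0):
            raise KMValidationError("n_at_risk must be nonnegative integers")
        c = np.asarray(c, dtype=int)
        if np.any(np.diff(c) > 0):
            raise KMValidationError("n_at_risk must be non-increasing")
        t.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    @property
    def n0(self) -> int:
        """Sample size at time 0."""
        return int(self.counts[0])

    def truncate(self, t_max: float) -> "RiskTable":
        """Keep entries with time <= t_max (at least the t=0 entry)."""
        keep = self.times <= t_max + 1e-9
        keep[0] = True
        return RiskTable(self.times[keep], self.counts[keep])


@dataclass(frozen=True)
class KMCurve:
    """A survival curve on a uniform time grid.

    Invariants: grid starts at 0 with uniform step ``grid_step``;
    survival is non-increasing, in [0, 1], and equals 1 at t=0.
    """

    grid_times: np.ndarray
    survival: np.ndarray
    grid_step: float
    arm_label: str = ""
    risk_table: Optional[RiskTable] = None
    total_events: Optional[int] = None

    def __post_init__(self):
        t = _as_float_array(self.grid_times)
        s = _as_float_array(self.survival)
        if t.size != s.size or t.size < 2:
            raise KMValidationError("grid needs >= 2 aligned points")
        step = float(self.grid_step)
        if step <= 0:
            raise KMValidationError("grid_step must be positive")
        if abs(t[0]) > 1e-9 or np.any(np.abs(np.diff(t) - step) > 1e-9):
            raise KMValidationError("grid must start at 0 with uniform step")
        if abs(s[0] - 1.0) > 1e-9:
            raise KMValidationError("survival at t=0 must be 1.0")
        if np.any(np.diff(s) > 1e-9):
            raise KMValidationError("survival must be non-increasing on the grid")
        if np.any(s < -1e-12) or np.any(s > 1.0 + 1e-12):
            raise KMValidationError("survival outside [0, 1]")
        # scrub fp noise so downstream code sees exact invariants
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
        s[0] = 1.0
        t.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "grid_times", t)
        object.__setattr__(self, "survival", s)
        object.__setattr__(self, "grid_step", step)

    @property
    def t_max(self) -> float:
        return float(self.grid_times[-1])

    def survival_at(self, times) -> np.ndarray:
        """Linear interpolation on the grid (no extrapolation past t_max)."""
        times = np.asarray(times, dtype=float)
        if np.any(times > self.t_max + 1e-9) or np.any(times < 0):
            raise ExtrapolationError("query outside grid extent")
        return np.interp(times, self.grid_times, self.survival)

    def truncated(self, t_max: float) -> "KMCurve":
        """Curve restricted to grid points <= t_max."""
        if t_max > self.t_max + 1e-9:
            raise ExtrapolationError("cannot truncate beyond curve extent")
        keep = self.grid_times <= t_max + 1e-9
        rt = None if self.risk_table is None else self.risk_table.truncate(t_max)
        return KMCurve(
            self.grid_times[keep],
            self.survival[keep],
            self.grid_step,
            arm_label=self.arm_label,
            risk_table=rt,
            total_events=self.total_events,
        )

    def with_risk_table(self, risk_table: RiskTable) -> "KMCurve":
        return replace(self, risk_table=risk_table)


# ---------------------------------------------------------------------------
# CSV I/O

def _read_two_column_csv(path: Union[str, Path], cols: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise KMValidationError(f"{path}: no data rows")
    first = [c.strip() for c in lines[0].split(",")]

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    header = 0 if not all(_numeric(c) for c in first[:2]) else None
    df = pd.read_csv(io.StringIO("\n".join(lines)), header=header)
    if df.shape[1] < 2:
        raise KMValidationError(f"{path}: expected two columns {cols}")
    df = df.iloc[:, :2]
    df.columns = list(cols)
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
        if df[c].isna().any():
            raise KMValidationError(f"{path}: non-numeric cell in column {c!r}")
    return df


def read_km_csv(path: Union[str, Path], arm_label: str = "", source_trial: str = "") -> KMCoordinates:
    """Read digitized curve coordinates from CSV (``time_months,survival``)."""
    df = _read_two_column_csv(path, ("time_months", "survival"))
    return KMCoordinates(
        df["time_months"].to_numpy(),
        df["survival"].to_numpy(),
        arm_label=arm_label,
        source_trial=source_trial,
    )


def read_risk_table_csv(path: Union[str, Path]) -> RiskTable:
    """Read a number-at-risk table from CSV (``time_months,n_at_risk``)."""
    df = _read_two_column_csv(path, ("time_months", "n_at_risk"))
    return RiskTable(df["time_months"].to_numpy(), df["n_at_risk"].to_numpy())


def write_km_csv(obj: Union[KMCoordinates, KMCurve], path: Union[str, Path]) -> None:
    """Write a curve or coordinate series in the curve CSV dialect."""
    if isinstance(obj, KMCurve):
        t, s = obj.grid_times, obj.survival
    else:
        t, s = obj.times, obj.survival
    pd.DataFrame({"time_months": t, "survival": s}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing

def enforce_monotone(coords: KMCoordinates) -> KMCoordinates:
    """Replace survival by its running minimum (idempotent); times unchanged."""
    return KMCoordinates(
        coords.times,
        np.minimum.accumulate(coords.survival),
        arm_label=coords.arm_label,
        source_trial=coords.source_trial,
    )


def interpolate_to_grid(
    coords: KMCoordinates,
    grid_step: float = 0.5,
    t_max: Optional[float] = None,
) -> KMCurve:
    """Linearly interpolate monotone coordinates onto a uniform grid.

    The grid runs 0, grid_step, ..., up to the largest multiple of
    ``grid_step`` not exceeding ``t_max`` (default: the last coordinate
    time).  Requesting ``t_max`` beyond the digitized follow-up raises
    :class:`ExtrapolationError` -- curves are truncated, never extrapolated.
    """
    if grid_step <= 0:
        raise KMValidationError("grid_step must be positive")
    if not coords.is_monotone(tol=1e-9):
        raise KMValidationError("coordinates must be monotone; run enforce_monotone first")
    if t_max is None:
        t_max = coords.last_time
    if t_max > coords.last_time + 1e-9:
        raise ExtrapolationError(
            f"t_max={t_max} exceeds last coordinate time {coords.last_time}"
        )
    n = int(np.floor(t_max / grid_step + 1e-9))
    if n < 1:
        raise KMValidationError("grid would contain fewer than 2 points")
    grid = np.arange(n + 1) * grid_step
    s = np.interp(grid, coords.times, coords.survival)
    return KMCurve(grid, s, grid_step, arm_label=coords.arm_label)


def common_t_max(*coords: KMCoordinates) -> float:
    """Largest common follow-up: minimum of the last coordinate times."""
    if not coords:
        raise ValueError("no coordinate series given")
    return min(c.last_time for c in coords)
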