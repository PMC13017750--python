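"""Reconstruction of individual patient data from a KM curve + risk table.

Published survival figures carry enough information -- the curve's drop
coordinates and the number-at-risk table beneath it -- to rebuild a pseudo
patient-level dataset whose Kaplan-Meier estimate reproduces the published
curve (the Guyot-style inversion).  The reconstruction here is fully
deterministic: event times sit exactly at the curve's drop points and
censoring times are spread at equal spacing within each risk-table interval,
so identical inputs yield byte-identical outputs.

Algorithm per risk-table interval [T_i, T_{i+1}):

1. guess the interval's censoring count c (starting at 0);
2. place c censoring times at equal spacing strictly inside the interval;
3. walk the curve's drop points chronologically, removing censored subjects
   as their times pass and solving the product-limit recursion
   S_k = S_{k-1} * (1 - d_k / n_k) for the event count
   d_k = round(n_k * (1 - S_k / S_{k-1})) (round half away from zero),
   where S_{k-1} is the *implied* running estimate, which makes rounding
   self-correcting;
4. compare the implied at-risk count at T_{i+1} with the published value and
   move c by the difference;
5. iterate to convergence or stall (max 50 iterations; on a stall the
   censoring count with the smallest at-risk discrepancy wins).

After the last published risk time the tail is walked with no interior
censoring and every remaining subject is censored at the end of follow-up;
if a published total event count is supplied, the tail is adjusted so the
reconstructed event count matches it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .km_io import KMCoordinates, KMCurve, RiskTable

__all__ = [
    "ReconstructionError",
    "IPDDataset",
    "reconstruct_ipd",
    "km_estimate",
    "step_survival",
]


class ReconstructionError(RuntimeError):
    """Inversion failed: infeasible risk table or unmatchable event total."""


@dataclass
class IPDDataset:
    """Patient-level records: columns ``time`` (months > 0), ``event`` (0/1), ``arm``.

    ``diagnostics`` records reconstruction repairs per arm: at-risk
    mismatches accepted in nearest mode and tail event adjustments.
    """

    data: pd.DataFrame
    diagnostics: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing = {"time", "event", "arm"} - set(df.columns)
        if missing:
            raise ValueError(f"IPD data missing columns {sorted(missing)}")
        if len(df) and not ((df["time"] > 0).all() and np.isfinite(df["time"]).all()):
            raise ValueError("IPD times must be positive and finite")
        if len(df) and not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = df.reset_index(drop=True)

    @property
    def arms(self) -> List[str]:
        return list(self.data["arm"].unique())

    def for_arm(self, arm_label: str) -> pd.DataFrame:
        return self.data[self.data["arm"] == arm_label]

    def n(self, arm_label: str) -> int:
        return int(len(self.for_arm(arm_label)))

    def n_events(self, arm_label: str) -> int:
        return int(self.for_arm(arm_label)["event"].sum())

    @classmethod
    def from_arrays(cls, time, event, arm_label: str, diagnostics: Optional[dict] = None) -> "IPDDataset":
        df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                           "event": np.asarray(event, dtype=int),
                           "arm": arm_label})
        return cls(df, diagnostics={arm_label: diagnostics} if diagnostics else {})

    @classmethod
    def concat(cls, *datasets: "IPDDataset") -> "IPDDataset":
        diag: Dict[str, dict] = {}
        for d in datasets:
            diag.update(d.diagnostics)
        return cls(pd.concat([d.data for d in datasets], ignore_index=True), diagnostics=diag)

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.data.rename(columns={"time": "time_months"})
        out[["time_months", "event", "arm"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "IPDDataset":
        df = pd.read_csv(path)
        df = df.rename(columns={"time_months": "time"})
        return cls(df[["time", "event", "arm"]])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _walk_interval(
    n0: int,
    s0: float,
    drop_t: np.ndarray,
    drop_s: np.ndarray,
    c: int,
    t_lo: float,
    t_hi: float,
) -> Tuple[List[Tuple[float, int]], List[float], int, float]:
    """Walk one interval with c equally spaced censorings.

    Returns (events as (time, count), censoring times used, at-risk at the
    interval end, implied survival at the interval end).
    """
    cens = [t_lo + (j + 1) * (t_hi - t_lo) / (c + 1) for j in range(c)]
    n, s = n0, s0
    events: List[Tuple[float, int]] = []
    used: List[float] = []
    ci = 0
    for t, s_target in zip(drop_t, drop_s):
        while ci < len(cens) and cens[ci] < t - 1e-12:
            if n > 0:
                n -= 1
                used.append(cens[ci])
            ci += 1
        if n <= 0 or s <= 0:
            break
        d = _round_half_away(n * (1.0 - s_target / s))
        d = max(0, min(d, n))
        if d > 0:
            s *= 1.0 - d / n
            n -= d
            events.append((t, d))
    while ci < len(cens):
        if n > 0:
            n -= 1
            used.append(cens[ci])
        ci += 1
    return events, used, n, s


_MAX_ITER = 50


def reconstruct_ipd(
    curve: KMCurve,
    risk_table: Optional[RiskTable] = None,
    total_events: Optional[int] = None,
    arm_label: Optional[str] = None,
    on_infeasible: str = "nearest",
) -> IPDDataset:
    """Invert a KM curve plus risk table into patient-level records.

    Parameters
    ----------
    curve
        Survival curve on a uniform grid; events are placed at its drop
        points.
    risk_table
        Published at-risk counts (defaults to ``curve.risk_table``).
    total_events
        If given, the reconstructed event count is made to match exactly.
    on_infeasible
        ``"nearest"`` (default) accepts the censoring count minimizing the
        at-risk discrepancy when no count reproduces the published value
        (mismatches recorded in diagnostics); ``"error"`` raises
        :class:`ReconstructionError` naming the offending interval.

    The reconstruction is deterministic; the returned dataset's KM estimate
    reproduces the input curve up to event-count rounding.
    """
    if on_infeasible not in ("nearest", "error"):
        raise ValueError("on_infeasible must be 'nearest' or 'error'")
    rt = risk_table if risk_table is not None else curve.risk_table
    if rt is None:
        raise ReconstructionError("a risk table is required for reconstruction")
    arm = arm_label if arm_label is not None else (curve.arm_label or "arm")
    t_end = curve.t_max
    if rt.times[-1] > t_end + 1e-9:
        raise ReconstructionError("risk-table times extend beyond the curve")
    if total_events is None:
        total_events = curve.total_events

    ds = np.diff(curve.survival)
    idx = np.nonzero(ds < -1e-12)[0] + 1
    drop_t = curve.grid_times[idx]
    drop_s = curve.survival[idx]

    n_cur = rt.n0
    s_hat = 1.0
    all_events: List[Tuple[float, int]] = []
    all_cens: List[float] = []
    mismatches: List[dict] = []

    bounds = list(rt.times) + [math.inf]
    for i in range(len(rt.times)):
        t_lo, t_hi = bounds[i], bounds[i + 1]
        in_iv = (drop_t >= t_lo - 1e-12) & (drop_t < t_hi - 1e-12)
        dts, dss = drop_t[in_iv], drop_s[in_iv]

        if not math.isfinite(t_hi):
            # tail: no interior censoring; leftovers censored at follow-up end
            ev, used, n_end, s_end = _walk_interval(n_cur, s_hat, dts, dss, 0, t_lo, t_end)
            all_events += ev
            all_cens += used
            all_cens += [t_end] * n_end
            n_cur, s_hat = 0, s_end
            break

        target = int(rt.counts[i + 1])
        tried: Dict[int, Tuple[int, list, list, int, float]] = {}
        c = 0
        accepted = None
        for _ in range(_MAX_ITER):
            ev, used, n_end, s_end = _walk_interval(n_cur, s_hat, dts, dss, c, t_lo, t_hi)
            diff = n_end - target
            tried[c] = (diff, ev, used, n_end, s_end)
            if diff == 0:
                accepted = c
                break
            c_next = max(0, c + diff)
            if c_next in tried:
                break
            c = c_next
        if accepted is None:
            best = min(tried, key=lambda cc: (abs(tried[cc][0]), cc))
            if tried[best][0] != 0:
                if on_infeasible == "error":
                    raise ReconstructionError(
                        f"arm {arm!r}: published at-risk count {target} at "
                        f"t={t_hi} unattainable in interval [{t_lo}, {t_hi}) "
                        f"(nearest achievable {tried[best][3]})"
                    )
                mismatches.append(
                    {"interval": (float(t_lo), float(t_hi)),
                     "published": target, "achieved": int(tried[best][3])}
                )
            accepted = best
        diff, ev, used, n_end, s_end = tried[accepted]
        all_events += ev
        all_cens += used
        n_cur, s_hat = n_end, s_end

    if n_cur > 0:  # defensive; the +inf tail bound drains the risk set
        all_cens += [t_end] * n_cur
        n_cur = 0

    tail_adjust = 0
    if total_events is not None:
        got = sum(d for _, d in all_events)
        delta = int(total_events) - got
        if delta > 0:
            # promote end-of-follow-up censorings to events at the final time
            end_cens = sum(1 for t in all_cens if abs(t - t_end) < 1e-12)
            if delta > end_cens:
                raise ReconstructionError(
                    f"arm {arm!r}: cannot reach total_events={total_events} "
                    f"(short by {delta - end_cens})"
                )
            for _ in range(delta):
                all_cens.remove(t_end)
            all_events.append((t_end, delta))
            tail_adjust = delta
        elif delta < 0:
            # demote the latest events to censorings at their own times
            need = -delta
            for j in range(len(all_events) - 1, -1, -1):
                if need == 0:
                    break
                t, d = all_events[j]
                take = min(d, need)
                all_events[j] = (t, d - take)
                all_cens += [t] * take
                need -= take
            if need:
                raise ReconstructionError(
                    f"arm {arm!r}: total_events={total_events} below zero-event floor"
                )
            all_events = [(t, d) for t, d in all_events if d > 0]
            tail_adjust = delta

    times: List[float] = []
    status: List[int] = []
    for t, d in all_events:
        times += [t] * d
        status += [1] * d
    times += all_cens
    status += [0] * len(all_cens)

    diag = {"at_risk_mismatches": mismatches, "tail_event_adjustment": tail_adjust}
    out = IPDDataset.from_arrays(times, status, arm, diagnostics=diag)
    if out.n(arm) != rt.n0:
        raise ReconstructionError(
            f"arm {arm!r}: reconstructed {out.n(arm)} records, expected {rt.n0}"
        )
    return out


def km_estimate(ipd: IPDDataset, arm_label: str) -> KMCoordinates:
    """Product-limit estimate of one arm as step-function coordinates.

    Censorings at a time are processed after events at the same time (the
    standard KM convention).  Evaluate anywhere with :func:`step_survival`.
    """
    df = ipd.for_arm(arm_label)
    if df.empty:
        raise ValueError(f"no records for arm {arm_label!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    return KMCoordinates(t, s, arm_label=arm_label)


def step_survival(coords: KMCoordinates, times) -> np.ndarray:
    """Evaluate step-function coordinates: value of the last knot <= t.

    Beyond the last knot the final value is held (the KM estimate is
    undefined there; callers should stay within follow-up).
    """
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(coords.times, times + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, coords.times.size - 1)
    return coords.survival[idx]
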