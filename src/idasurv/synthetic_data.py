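"""Simulation of the two-trial structure the analysis assumes.

The pipeline consumes four published-style survival curves: a combination arm
and a comparator doublet from one trial, and the second doublet plus its
control from another.  This module simulates exactly that layout with a known
ground-truth synergy parameter so every downstream stage is testable without
external data.

Event times are exponential per arm with hazards (per month)

    control      lam_0
    doublet A    lam_A
    doublet B    lam_B
    combination  psi * (lam_A + lam_B - lam_0)

Under exponential arms the additive (independent-action) combination hazard
is exactly lam_A + lam_B - lam_0, so psi = 1 reproduces the additive null in
closed form and the observed-vs-predicted hazard ratio has psi as its exact
estimand.  psi < 1 injects synergy, psi > 1 antagonism.  Each subject is
censored at the earlier of an exponential loss-to-follow-up time
(``censor_rate``) and the administrative cutoff (``censor_admin_time``).

:func:`digitize_like` then emulates figure digitization: it computes the
arm's exact KM step curve, samples a fixed number of coordinates (plus all
risk-table times), optionally jitters them vertically, and tabulates the true
number at risk at fixed intervals -- yielding the same inputs a reader would
extract from a published figure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .ipd_reconstruct import IPDDataset, km_estimate, step_survival
from .km_io import KMCoordinates, RiskTable

__all__ = [
    "SimulationScenario",
    "simulate_trials",
    "digitize_like",
    "ARM_CONTROL",
    "ARM_DOUBLET_A",
    "ARM_DOUBLET_B",
    "ARM_COMBINATION",
]

ARM_CONTROL = "control"
ARM_DOUBLET_A = "doublet_A"
ARM_DOUBLET_B = "doublet_B"
ARM_COMBINATION = "combination"


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth parameters for a two-trial simulation.

    Defaults describe a realistic metastatic-cancer OS setting: monthly
    hazards 0.08 (control), 0.05 and 0.04 (doublets), 60-month
    administrative cutoff, light exponential loss to follow-up
    (0.005/month), 6-monthly risk tables and 25 digitized coordinates per
    curve.
    """

    lambda_control: float = 0.08
    lambda_A: float = 0.05
    lambda_B: float = 0.04
    psi: float = 1.0
    n_per_arm: int = 700
    censor_admin_time: float = 24.0
    censor_rate: float = 0.005
    risk_table_step: float = 6.0
    n_coordinates: int = 25
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_control", "lambda_A", "lambda_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.additive_hazard <= 0:
            raise ValueError(
                "lambda_A + lambda_B - lambda_control must be > 0 "
                "(otherwise the additive model implies an improper survival function)"
            )
        if self.psi <= 0:
            raise ValueError("psi must be > 0")
        if self.n_per_arm < 10:
            raise ValueError("n_per_arm must be >= 10")
        if self.censor_admin_time <= 0 or self.censor_rate < 0:
            raise ValueError("invalid censoring configuration")
        if self.risk_table_step <= 0:
            raise ValueError("risk_table_step must be > 0")
        if self.n_coordinates < 10:
            raise ValueError("n_coordinates must be >= 10")

    @property
    def additive_hazard(self) -> float:
        """Hazard of the additive (independent-action) combination null."""
        return self.lambda_A + self.lambda_B - self.lambda_control

    @property
    def lambda_combination(self) -> float:
        return self.psi * self.additive_hazard

    @property
    def arm_hazards(self) -> Dict[str, float]:
        return {
            ARM_CONTROL: self.lambda_control,
            ARM_DOUBLET_A: self.lambda_A,
            ARM_DOUBLET_B: self.lambda_B,
            ARM_COMBINATION: self.lambda_combination,
        }


def _simulate_arm(
    rng: np.random.Generator,
    hazard: float,
    n: int,
    censor_rate: float,
    admin_time: float,
    arm_label: str,
) -> IPDDataset:
    event_t = rng.exponential(1.0 / hazard, size=n)
    if censor_rate > 0:
        loss_t = rng.exponential(1.0 / censor_rate, size=n)
    else:
        loss_t = np.full(n, np.inf)
    censor_t = np.minimum(loss_t, admin_time)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    # KM-invalid zero times cannot occur (exponential draws are > 0), but
    # guard against float underflow
    time = np.maximum(time, 1e-9)
    return IPDDataset.from_arrays(time, event, arm_label)


def simulate_trials(scenario: SimulationScenario) -> Dict[str, IPDDataset]:
    """Simulate the four arms; reproducible from ``scenario.seed``.

    Each arm draws from its own random stream spawned off the master seed,
    so modifying one arm's parameters leaves the other arms' data unchanged.
    Returns a dict keyed by arm label.
    """
    children = np.random.SeedSequence(scenario.seed).spawn(4)
    arms = {}
    for child, (label, hazard) in zip(children, scenario.arm_hazards.items()):
        arms[label] = _simulate_arm(
            np.random.default_rng(child),
            hazard,
            scenario.n_per_arm,
            scenario.censor_rate,
            scenario.censor_admin_time,
            label,
        )
    return arms


def digitize_like(
    ipd: IPDDataset,
    n_coordinates: int = 25,
    risk_table_step: float = 6.0,
    jitter_sd: float = 0.0,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> Tuple[KMCoordinates, RiskTable]:
    """Emulate figure digitization of one arm's KM curve.

    Computes the exact KM step curve, samples coordinates at the union of
    evenly spaced times over follow-up and all risk-table times (all drop
    points if there are fewer than ``n_coordinates``), optionally adds
    truncated-normal vertical jitter (clipped to [0, 1]; repair downstream
    with ``enforce_monotone``), and tabulates the true number at risk at
    multiples of ``risk_table_step``.
    """
    if n_coordinates < 10:
        raise ValueError("n_coordinates must be >= 10")
    arms = ipd.arms
    if len(arms) != 1:
        raise ValueError("digitize_like expects a single-arm dataset")
    arm = arms[0]
    df = ipd.for_arm(arm)
    if df.empty:
        raise ValueError("empty IPD")
    km = km_estimate(ipd, arm)
    t_last = float(df["time"].max())

    rt_times = np.arange(0.0, t_last + 1e-9, risk_table_step)
    counts = np.array(
        [(df["time"].to_numpy() >= t - 1e-9).sum() for t in rt_times], dtype=int
    )
    keep = counts > 0
    keep[0] = True
    risk_table = RiskTable(rt_times[keep], counts[keep])

    drop_times = km.times[np.diff(km.survival, prepend=2.0) < 0]
    if drop_times.size <= n_coordinates:
        sample_t = np.union1d(drop_times, [0.0, t_last])
    else:
        sample_t = np.linspace(0.0, t_last, n_coordinates)
    sample_t = np.union1d(sample_t, risk_table.times)
    s = step_survival(km, sample_t)

    if jitter_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        s = np.clip(s + gen.normal(0.0, jitter_sd, size=s.size), 0.0, 1.0)

    coords = KMCoordinates(sample_t, s, arm_label=arm)
    return coords, risk_table
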