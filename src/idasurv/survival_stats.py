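"""Observed-vs-predicted cohort comparison: log-rank, Cox HR, classification.

The synergy question reduces to a two-group survival comparison between the
reconstructed observed cohort and the reconstructed predicted (additive)
cohort.  A hazard ratio below 1 with a 95% CI excluding 1 marks a
greater-than-additive (synergistic) benefit; a CI entirely above 1 marks a
less-than-additive effect; anything else is consistent with additivity.

The Cox fit is the two-group proportional-hazards partial likelihood
(statsmodels PHReg; Efron tie correction by default, Breslow available --
reconstruction places events on a shared grid, so ties are heavy).  The CI
and p-value are Wald on the log-HR scale with z = 1.959964, so
exp(log HR +/- 1.959964 * se) reproduces the bounds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy import stats
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg

from .ipd_reconstruct import IPDDataset

__all__ = [
    "NonEstimableError",
    "ComparisonResult",
    "classify_interaction",
    "logrank_test",
    "cox_fit",
    "Z_975",
]

#: 97.5% normal quantile used for the Wald CI (fixed so the CI invariant is exact)
Z_975 = 1.959964

GREATER = "greater_than_additive"
CONSISTENT = "consistent_with_additive"
LESS = "less_than_additive"


class NonEstimableError(RuntimeError):
    """Monotone partial likelihood: the HR diverges and no finite fit exists."""


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison summary (group A vs group B; HR < 1 favors A)."""

    hr: float
    ci_low: float
    ci_high: float
    se_log_hr: float
    logrank_chi2: float
    p_cox: float
    p_logrank: float
    classification: str
    n_obs: int
    n_pred: int
    events_obs: int
    events_pred: int

    def to_dict(self) -> dict:
        return asdict(self)


def classify_interaction(hr: float, ci_low: float, ci_high: float) -> str:
    """Synergy decision rule from the HR and its 95% CI.

    greater_than_additive iff the CI lies entirely below 1;
    less_than_additive iff entirely above 1; otherwise consistent.
    """
    if not (0 < ci_low <= hr <= ci_high):
        raise ValueError(f"inverted or invalid bounds: {ci_low}, {hr}, {ci_high}")
    if ci_high < 1.0:
        return GREATER
    if ci_low > 1.0:
        return LESS
    return CONSISTENT


def _two_groups(ipd: IPDDataset, group_a: str, group_b: str):
    da = ipd.for_arm(group_a)
    db = ipd.for_arm(group_b)
    if da.empty:
        raise ValueError(f"group {group_a!r} absent from dataset")
    if db.empty:
        raise ValueError(f"group {group_b!r} absent from dataset")
    return da, db


def logrank_test(ipd: IPDDataset, group_a: str, group_b: str) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Standard observed-minus-expected sum over distinct event times,
    normalized by the hypergeometric variance; chi-square with 1 df.
    """
    da, db = _two_groups(ipd, group_a, group_b)
    if int(da["event"].sum() + db["event"].sum()) == 0:
        raise ValueError("log-rank test undefined with zero events overall")
    res = _ll_logrank(
        da["time"].to_numpy(), db["time"].to_numpy(),
        event_observed_A=da["event"].to_numpy(),
        event_observed_B=db["event"].to_numpy(),
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    ipd: IPDDataset,
    group_a: str,
    group_b: str,
    ties: str = "efron",
) -> ComparisonResult:
    """Two-group Cox proportional-hazards fit of group A relative to group B.

    Maximizes the partial likelihood with the chosen tie correction
    (``"efron"`` default, ``"breslow"`` available) and returns the full
    comparison summary: HR = exp(beta), Wald 95% CI and p-value, the
    log-rank statistic on the same two groups, and the additivity
    classification.

    Raises :class:`NonEstimableError` when the likelihood is monotone in
    beta (e.g. every event in one group precedes the other group's events),
    rather than reporting a spuriously huge HR.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    da, db = _two_groups(ipd, group_a, group_b)
    if int(da["event"].sum()) < 1 or int(db["event"].sum()) < 1:
        raise NonEstimableError("each group needs at least one event for a finite HR")

    import pandas as pd

    df = pd.concat([da, db], ignore_index=True)
    x = (df["arm"] == group_a).to_numpy(dtype=float)[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(df["time"].to_numpy(), x, status=df["event"].to_numpy(), ties=ties)
        fit = model.fit()
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not (np.isfinite(beta) and np.isfinite(se)) or abs(beta) > 15 or se > 50:
        raise NonEstimableError(
            "monotone partial likelihood: hazard ratio not estimable"
        )
    hr = float(np.exp(beta))
    ci_low = float(np.exp(beta - Z_975 * se))
    ci_high = float(np.exp(beta + Z_975 * se))
    p_cox = float(2.0 * stats.norm.sf(abs(beta) / se))
    chi2, p_lr = logrank_test(ipd, group_a, group_b)
    return ComparisonResult(
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        se_log_hr=se,
        logrank_chi2=chi2,
        p_cox=p_cox,
        p_logrank=p_lr,
        classification=classify_interaction(hr, ci_low, ci_high),
        n_obs=int(len(da)),
        n_pred=int(len(db)),
        events_obs=int(da["event"].sum()),
        events_pred=int(db["event"].sum()),
    )
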