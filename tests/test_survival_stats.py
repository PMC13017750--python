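"""Log-rank, Cox partial likelihood (vs brute-force oracle), classification."""

import math

import numpy as np
import pandas as pd
import pytest

from helpers import COX_FIXTURES, brute_force_cox_beta, hand_logrank_chi2

from idasurv import IPDDataset, NonEstimableError
from idasurv import classify_interaction, cox_fit, logrank_test
from idasurv.survival_stats import Z_975


def _two_group(time, event, x):
    return IPDDataset(pd.DataFrame({
        "time": np.asarray(time, float),
        "event": np.asarray(event, int),
        "arm": np.where(np.asarray(x) == 1, "a", "b"),
    }))


# ------------------------------------------------------------------ log-rank

def test_logrank_exchangeable_groups_gives_zero_statistic():
    ipd = IPDDataset(pd.DataFrame({
        "time": [1, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0],
        "arm": ["a"] * 3 + ["b"] * 3,
    }))
    chi2, p = logrank_test(ipd, "a", "b")
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_label_symmetry():
    ipd = _two_group([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 1], [1, 0, 1, 0, 1, 0])
    ab = logrank_test(ipd, "a", "b")
    ba = logrank_test(ipd, "b", "a")
    assert ab[0] == pytest.approx(ba[0], rel=1e-9)
    assert ab[1] == pytest.approx(ba[1], rel=1e-9)


def test_logrank_matches_hand_hypergeometric_tabulation():
    time, event, x = [1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0]
    chi2, _ = logrank_test(_two_group(time, event, x), "a", "b")
    assert chi2 == pytest.approx(hand_logrank_chi2(time, event, np.array(x)), rel=1e-9)


def test_logrank_requires_groups_and_events():
    ipd = _two_group([1, 2], [1, 1], [1, 0])
    with pytest.raises(ValueError):
        logrank_test(ipd, "a", "missing")
    none = _two_group([1, 2], [0, 0], [1, 0])
    with pytest.raises(ValueError):
        logrank_test(none, "a", "b")


# ----------------------------------------------------------------------- Cox

@pytest.mark.parametrize("ties", ["efron", "breslow"])
@pytest.mark.parametrize("fixture", COX_FIXTURES, ids=range(len(COX_FIXTURES)))
def test_cox_matches_brute_force_partial_likelihood(fixture, ties):
    time, event, x = fixture
    res = cox_fit(_two_group(time, event, x), "a", "b", ties=ties)
    oracle = brute_force_cox_beta(time, event, x, ties)
    assert math.log(res.hr) == pytest.approx(oracle, abs=1e-6)
    # CI/SE consistency holds for every fit
    assert res.ci_low == pytest.approx(math.exp(math.log(res.hr) - Z_975 * res.se_log_hr), rel=1e-9)
    assert res.ci_high == pytest.approx(math.exp(math.log(res.hr) + Z_975 * res.se_log_hr), rel=1e-9)


def test_cox_label_swap_inverts_hazard_ratio():
    time, event, x = COX_FIXTURES[2]
    ab = cox_fit(_two_group(time, event, x), "a", "b")
    ba = cox_fit(_two_group(time, event, x), "b", "a")
    assert ab.hr == pytest.approx(1 / ba.hr, rel=1e-8)
    assert ab.ci_low == pytest.approx(1 / ba.ci_high, rel=1e-8)
    assert ab.ci_high == pytest.approx(1 / ba.ci_low, rel=1e-8)


def test_cox_monotone_likelihood_not_estimable():
    # every group-a event precedes every group-b event: beta diverges
    ipd = _two_group([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 0, 0])
    with pytest.raises(NonEstimableError):
        cox_fit(ipd, "a", "b")


def test_cox_requires_an_event_per_group():
    ipd = _two_group([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])
    with pytest.raises(NonEstimableError):
        cox_fit(ipd, "a", "b")


def test_cox_large_sample_consistency_and_p_value_agreement():
    """True hazard ratio 0.5 with 20% uniform censoring: the estimate lands
    near 0.5 and Wald/log-rank p-values agree to an order of magnitude."""
    rng = np.random.default_rng(11)
    n = 2000
    ta = rng.exponential(1 / 0.05, n)   # group a, hazard 0.05
    tb = rng.exponential(1 / 0.10, n)   # group b, hazard 0.10
    ca = rng.uniform(0, 4 / 0.05, n)    # roughly 20% censoring
    cb = rng.uniform(0, 4 / 0.10, n)
    df = pd.DataFrame({
        "time": np.concatenate([np.minimum(ta, ca), np.minimum(tb, cb)]),
        "event": np.concatenate([(ta <= ca).astype(int), (tb <= cb).astype(int)]),
        "arm": ["a"] * n + ["b"] * n,
    })
    res = cox_fit(IPDDataset(df), "a", "b")
    assert 0.45 < res.hr < 0.55


def test_wald_and_logrank_p_values_agree_for_moderate_effects():
    """Both tests are asymptotically equivalent under proportional hazards;
    with a moderate effect their p-values agree to an order of magnitude."""
    rng = np.random.default_rng(13)
    n = 2000
    ta = rng.exponential(1 / 0.050, n)
    tb = rng.exponential(1 / 0.055, n)  # true HR ~ 0.91
    ca = rng.uniform(0, 80, n)
    cb = rng.uniform(0, 80, n)
    df = pd.DataFrame({
        "time": np.concatenate([np.minimum(ta, ca), np.minimum(tb, cb)]),
        "event": np.concatenate([(ta <= ca).astype(int), (tb <= cb).astype(int)]),
        "arm": ["a"] * n + ["b"] * n,
    })
    res = cox_fit(IPDDataset(df), "a", "b")
    assert abs(math.log10(res.p_cox) - math.log10(res.p_logrank)) < 1.0


def test_cox_exchangeable_groups_hr_near_one():
    rng = np.random.default_rng(23)
    n = 3000
    t = rng.exponential(10, n)
    df = pd.DataFrame({
        "time": np.concatenate([t, t]),
        "event": 1,
        "arm": ["a"] * n + ["b"] * n,
    })
    res = cox_fit(IPDDataset(df), "a", "b")
    assert 0.99 <= res.hr <= 1.01


# -------------------------------------------------------------- classification

@pytest.mark.parametrize(
    "hr,lo,hi,expected",
    [
        (0.824, 0.681, 0.998, "greater_than_additive"),
        (0.90, 0.70, 1.10, "consistent_with_additive"),
        (1.30, 1.05, 1.60, "less_than_additive"),
        (1.0, 1.0, 1.0, "consistent_with_additive"),
    ],
)
def test_classification_rule(hr, lo, hi, expected):
    assert classify_interaction(hr, lo, hi) == expected


def test_classification_rejects_inverted_bounds():
    with pytest.raises(ValueError):
        classify_interaction(1.0, 1.2, 0.8)
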