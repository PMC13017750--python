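"""Independent oracles used by the tests.

These deliberately re-derive the statistics from their textbook definitions
(written-out partial likelihood, hypergeometric log-rank terms) so they share
no code path with the package implementations they check.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def cox_log_partial_likelihood(beta, time, event, x, ties):
    """Two-group Cox partial log-likelihood, written out term by term."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for td in np.unique(time[event == 1]):
        at_risk = time >= td - 1e-12
        dead = (time == td) & (event == 1)
        d = int(dead.sum())
        sum_risk = float(np.sum(np.exp(beta * x[at_risk])))
        sum_dead = float(np.sum(np.exp(beta * x[dead])))
        ll += beta * float(np.sum(x[dead]))
        if ties == "breslow":
            ll -= d * np.log(sum_risk)
        else:  # efron
            for ell in range(d):
                ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return ll


def brute_force_cox_beta(time, event, x, ties):
    """Maximize the written-out partial likelihood over beta in [-5, 5]."""
    res = minimize_scalar(
        lambda b: -cox_log_partial_likelihood(b, time, event, x, ties),
        bounds=(-5.0, 5.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def hand_logrank_chi2(time, event, group):
    """Log-rank chi-square from the hypergeometric O-E/V tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for td in np.unique(time[event == 1]):
        at_risk = time >= td - 1e-12
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == group[0])).sum())
        dead = (time == td) & (event == 1)
        d = int(dead.sum())
        d1 = int((dead & (group == group[0])).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


#: small two-group survival fixtures (time, event, group indicator), all with
#: overlapping event histories so the partial likelihood has a finite maximum
COX_FIXTURES = [
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [1, 0, 1, 0, 1, 0]),
    ([1, 1, 2, 2, 3, 3], [1, 1, 1, 0, 1, 1], [1, 0, 1, 0, 1, 0]),
    ([2, 2, 2, 4, 4, 5, 6, 7], [1, 1, 0, 1, 1, 1, 0, 1], [1, 1, 1, 0, 0, 1, 0, 0]),
    ([1, 3, 3, 5], [1, 1, 1, 1], [0, 1, 1, 0]),
    ([2, 3, 3, 3, 5, 8], [1, 1, 1, 0, 1, 1], [1, 1, 0, 0, 1, 1]),
]
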