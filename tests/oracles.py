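"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive pair
counting for the AUC, an exhaustive simplex grid for stacking weights, and
a grid-search maximizer of the Efron partial likelihood for two-group Cox
models.
"""

from __future__ import annotations

import numpy as np


def pairwise_auc(y, scores) -> float:
    """AUC by enumerating every (positive, negative) pair; ties count 1/2."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def simplex_grid_best(Z, y, step=0.01):
    """Best squared-error loss over the probability simplex on a fixed grid."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    m = int(round(1.0 / step))
    best_loss, best_w = np.inf, None
    for i in range(m + 1):
        for j in range(m + 1 - i):
            w = np.array([i, j, m - i - j]) * step
            loss = float(((Z @ w - y) ** 2).mean())
            if loss < best_loss:
                best_loss, best_w = loss, w
    return best_loss, best_w


def efron_log_partial_likelihood(beta, time, event, group) -> float:
    """Efron-tie-corrected Cox log partial likelihood for a binary covariate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(group, dtype=float)
    eta = x * beta
    exp_eta = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event]):
        deaths = event & (time == t)
        at_risk = time >= t
        d = int(deaths.sum())
        sum_risk = exp_eta[at_risk].sum()
        sum_dead = exp_eta[deaths].sum()
        ll += eta[deaths].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return ll


def grid_search_log_hr(time, event, group, lo=-3.0, hi=3.0, step=1e-4) -> float:
    """Maximize the Efron partial likelihood over a 1e-4 grid of log-HRs."""
    betas = np.arange(lo, hi + step, step)
    lls = [efron_log_partial_likelihood(b, time, event, group) for b in betas]
    return float(betas[int(np.argmax(lls))])
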