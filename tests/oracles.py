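"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: risk sets are
enumerated explicitly and the quantile fit is done by grid refinement, so
agreement is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

CDF_TARGETS = (0.025, 0.5, 0.975)


def efron_loglik_bruteforce(time, event, X, beta) -> float:
    """Efron-corrected Cox partial log-likelihood by explicit risk-set
    enumeration."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    beta = np.asarray(beta, dtype=float)
    n = len(time)
    eta = [float(X[i] @ beta) for i in range(n)]
    ll = 0.0
    for t in sorted({time[i] for i in range(n) if event[i]}):
        deaths = [i for i in range(n) if event[i] and time[i] == t]
        risk = [i for i in range(n) if time[i] >= t]
        d = len(deaths)
        s_deaths = sum(math.exp(eta[i]) for i in deaths)
        s_risk = sum(math.exp(eta[i]) for i in risk)
        ll += sum(eta[i] for i in deaths)
        for ell in range(d):
            ll -= math.log(s_risk - (ell / d) * s_deaths)
    return ll


def grid_fit_normal(q025, q50, q975, passes=5, half_width=None, grid=81):
    """Least-squares normal fit to three quantiles by iterative grid
    refinement over (mean, sd). Returns (mean, sd) to ~1e-5 resolution."""
    targets = np.array(CDF_TARGETS)
    q = np.array([q025, q50, q975], dtype=float)
    mean = q[1]
    sd = max((q[2] - q[0]) / (2 * 1.959963984540054), 1e-4)
    mh = half_width if half_width is not None else max(abs(q[2] - q[0]), 0.5)
    sh = sd  # search sd in [sd - sh, sd + sh] clipped positive
    for _ in range(passes):
        means = np.linspace(mean - mh, mean + mh, grid)
        sds = np.linspace(max(sd - sh, 1e-6), sd + sh, grid)
        M, S = np.meshgrid(means, sds, indexing="ij")
        obj = np.zeros_like(M)
        for qi, ti in zip(q, targets):
            obj += (norm.cdf(qi, loc=M, scale=S) - ti) ** 2
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        mean, sd = float(M[i, j]), float(S[i, j])
        mh *= 2.5 / grid
        sh *= 2.5 / grid
    return mean, sd
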