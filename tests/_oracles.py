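"""Independent brute-force oracles used by the test suite only.

Each oracle is deliberately implemented from first principles (loops,
enumeration, closed forms) and shares no code with the package paths it
checks.
"""

import math

import numpy as np


def ols_normal_equations(X, y):
    """Closed-form OLS: beta, SEs, R2 and adjusted R2 from the normal
    equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sigma2 = ssr / (n - p)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if ss_tot > 0 else float("nan")
    return beta, se, r2, adj


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher exact P by full hypergeometric enumeration over the
    fixed margins: sum the probabilities of all tables no more probable than
    the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(m, k):
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    def log_p(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return log_comb(r1, x) + log_comb(r2, c1 - x) - log_comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(log_p(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_p(x))
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def g_statistic_direct(observed, expected):
    """G = 2 * sum O*ln(O/E) over O > 0, via a plain loop."""
    g = 0.0
    for o, e in zip(observed, expected):
        if o > 0:
            g += o * math.log(o / e)
    return 2.0 * g


def moving_average_loop(values, window):
    """Edge-truncated centered moving average by direct loop."""
    n = len(values)
    h = (window - 1) // 2
    out = []
    for i in range(n):
        k = min(h, i, n - 1 - i)
        sub = values[i - k: i + k + 1]
        out.append(sum(sub) / len(sub))
    return out
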