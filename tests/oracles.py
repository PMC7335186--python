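"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — direct formula transcriptions and
enumerations kept free of the library code they check.
"""

import math

import numpy as np


def quantile_linear(values, q):
    """Linear-interpolation quantile between order statistics."""
    a = np.sort(np.asarray(values, dtype=float))
    h = (a.size - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, a.size - 1)
    return a[lo] + (a[hi] - a[lo]) * (h - lo)


def multinomial_pmf(x, p):
    """Exact multinomial pmf by factorial enumeration."""
    n = int(sum(x))
    coef = math.factorial(n)
    for xi in x:
        coef //= math.factorial(int(xi))
    prob = 1.0
    for xi, pi in zip(x, p):
        prob *= pi ** xi
    return coef * prob


def bayes_posterior(x, alphas, pis):
    """Direct Bayes posterior over mixture components for one droplet."""
    joint = np.array([pi * multinomial_pmf(x, a) for a, pi in zip(alphas, pis)])
    return joint / joint.sum()


def mixture_loglik(counts_cols, alphas, pis):
    """Observed-data log-likelihood by direct summation (coefficient-free)."""
    total = 0.0
    for x in counts_cols:
        s = 0.0
        for a, pi in zip(alphas, pis):
            term = pi
            for xi, ai in zip(x, a):
                term *= ai ** xi
            s += term
        total += math.log(s)
    return total


def welch_t(a, b):
    """Welch's t statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def bh_qvalues(pvals):
    """Benjamini-Hochberg step-up, implemented literally."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return np.minimum(q, 1.0)


def gaussian_equal_density_point(m1, s1, w1, m2, s2, w2):
    """Equal weighted-density point between two Gaussians, via the quadratic."""
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = (
        m2 ** 2 / (2 * s2 ** 2)
        - m1 ** 2 / (2 * s1 ** 2)
        + math.log(w1 * s2 / (w2 * s1))
    )
    if abs(a) < 1e-15:
        return -c / b
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > min(m1, m2)) & (roots < max(m1, m2))]
    return float(inside[0])
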