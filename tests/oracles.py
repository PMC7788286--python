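"""Independent reference implementations used only as test oracles.

Written separately from the package, directly from the published formulas,
with deliberately different numerics (per-row loops, brentq root finding for
the trigamma inverse, O(n^2) step-up minimization) so agreement is evidence
of correctness rather than shared code.
"""

import numpy as np
from scipy import optimize, special
from scipy import stats as sps


def moderated_t_oracle(x, test_idx, ref_idx):
    """Row-wise moderated t from the hierarchical-model equations.

    Returns (log_fc, t, p, d0, s0_sq). x is a 2-D array; test_idx/ref_idx
    are column index lists.
    """
    x = np.asarray(x, dtype=float)
    n1, n2 = len(test_idx), len(ref_idx)
    d_g = n1 + n2 - 2
    log_fc, s2 = [], []
    for row in x:
        a, b = row[test_idx], row[ref_idx]
        log_fc.append(a.mean() - b.mean())
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        s2.append(ss / d_g)
    log_fc = np.array(log_fc)
    s2 = np.array(s2)

    # hyperparameters by matching mean/variance of log s^2 to the scaled-F model
    z = np.log(s2[s2 > 0])
    e = z - special.digamma(d_g / 2) + np.log(d_g / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, d_g / 2)
    if evar > 0:
        # trigamma(d0/2) = evar, solved by bracketed root finding
        f = lambda u: special.polygamma(1, u) - evar
        lo, hi = 1e-8, 1e8
        u = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
        d0 = 2 * u
        s0_sq = np.exp(np.mean(e) + special.digamma(u) - np.log(u))
    else:
        d0 = np.inf
        s0_sq = np.exp(np.mean(e))

    t_out, p_out = [], []
    for fc, v in zip(log_fc, s2):
        if np.isinf(d0):
            s_post = s0_sq
            df_tot = np.inf
        else:
            s_post = (d0 * s0_sq + d_g * v) / (d0 + d_g)
            df_tot = d0 + d_g
        se = np.sqrt(s_post * (1 / n1 + 1 / n2))
        t = fc / se if se > 0 else 0.0
        t_out.append(t)
        p_out.append(2 * sps.t.sf(abs(t), df=df_tot))
    return log_fc, np.array(t_out), np.array(p_out), d0, s0_sq


def bh_oracle(p):
    """Literal O(n^2) step-up: q_i = min over j with p_j >= p_i of m p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = []
    for i in range(m):
        q = min(m * p[order[j]] / (j + 1) for j in range(i, m))
        q_sorted.append(min(q, 1.0))
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return np.array(out)
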