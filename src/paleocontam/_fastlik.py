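"""Compiled per-site log-likelihood kernels.

Sites sharing identical (a, d, w, y, flag) tuples are aggregated upstream;
``wt`` carries each tuple's multiplicity.

Each kernel receives the per-site counts together with small lookup tables
(log q_i indexed by unique contaminant frequency, log genotype priors
indexed by unique anchor frequency or anchor-count cell) and returns the
total log-likelihood.  The per-site term is a logsumexp over the three
genotypes (times the error-mixture components where applicable); ``lc``
holds the precomputed log binomial coefficients, which never change across
MCMC steps.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def ll_single(a, d, wt, iw, iy, lq, l1q, lp, lc):
    # logsumexp over genotypes with underflow short-circuits: at high
    # coverage one genotype usually dominates by far, so most sites need
    # no transcendental call at all beyond the three linear terms
    tot = 0.0
    for j in range(a.shape[0]):
        w = iw[j]
        y = iy[j]
        n0 = lp[y, 0] + d[j] * lq[w, 0] + a[j] * l1q[w, 0]
        n1 = lp[y, 1] + d[j] * lq[w, 1] + a[j] * l1q[w, 1]
        n2 = lp[y, 2] + d[j] * lq[w, 2] + a[j] * l1q[w, 2]
        if n0 >= n1 and n0 >= n2:
            m, r1, r2 = n0, n1 - n0, n2 - n0
        elif n1 >= n2:
            m, r1, r2 = n1, n0 - n1, n2 - n1
        else:
            m, r1, r2 = n2, n0 - n2, n1 - n2
        s = 1.0
        if r1 > -37.0:
            s += np.exp(r1)
        if r2 > -37.0:
            s += np.exp(r2)
        term = lc[j] + m
        if s > 1.0:
            term += np.log(s)
        tot += wt[j] * term
    return tot


@njit(cache=True, fastmath=False)
def ll_tstv(a, d, wt, iw, iy, it, lq_tv, l1q_tv, lq_ts, l1q_ts, lp, lc):
    tot = 0.0
    for j in range(a.shape[0]):
        w = iw[j]
        y = iy[j]
        if it[j] == 1:
            lq = lq_ts
            l1q = l1q_ts
        else:
            lq = lq_tv
            l1q = l1q_tv
        n0 = lp[y, 0] + d[j] * lq[w, 0] + a[j] * l1q[w, 0]
        n1 = lp[y, 1] + d[j] * lq[w, 1] + a[j] * l1q[w, 1]
        n2 = lp[y, 2] + d[j] * lq[w, 2] + a[j] * l1q[w, 2]
        m = n0
        if n1 > m:
            m = n1
        if n2 > m:
            m = n2
        tot += wt[j] * (lc[j] + m + np.log(np.exp(n0 - m) + np.exp(n1 - m) + np.exp(n2 - m)))
    return tot


@njit(cache=True, fastmath=False)
def ll_two_error(a, d, wt, iw, iy, lq1, l1q1, lq2, l1q2, lphi, l1phi, lp, lc):
    tot = 0.0
    for j in range(a.shape[0]):
        w = iw[j]
        y = iy[j]
        m = -1.0e308
        t0 = lphi + lp[y, 0] + d[j] * lq1[w, 0] + a[j] * l1q1[w, 0]
        t1 = lphi + lp[y, 1] + d[j] * lq1[w, 1] + a[j] * l1q1[w, 1]
        t2 = lphi + lp[y, 2] + d[j] * lq1[w, 2] + a[j] * l1q1[w, 2]
        t3 = l1phi + lp[y, 0] + d[j] * lq2[w, 0] + a[j] * l1q2[w, 0]
        t4 = l1phi + lp[y, 1] + d[j] * lq2[w, 1] + a[j] * l1q2[w, 1]
        t5 = l1phi + lp[y, 2] + d[j] * lq2[w, 2] + a[j] * l1q2[w, 2]
        for t in (t0, t1, t2, t3, t4, t5):
            if t > m:
                m = t
        s = (np.exp(t0 - m) + np.exp(t1 - m) + np.exp(t2 - m)
             + np.exp(t3 - m) + np.exp(t4 - m) + np.exp(t5 - m))
        tot += wt[j] * (lc[j] + m + np.log(s))
    return tot


@njit(cache=True, fastmath=False)
def ll_asm(a, d, wt, iw, iy, lq, l1q, lqf, l1qf, lp, lpf, lr, l1r, lc):
    # flipped component: counts swapped (derived count becomes a), q tables
    # at 1-w, genotype prior at 1-y
    tot = 0.0
    for j in range(a.shape[0]):
        w = iw[j]
        y = iy[j]
        m = -1.0e308
        t0 = l1r + lp[y, 0] + d[j] * lq[w, 0] + a[j] * l1q[w, 0]
        t1 = l1r + lp[y, 1] + d[j] * lq[w, 1] + a[j] * l1q[w, 1]
        t2 = l1r + lp[y, 2] + d[j] * lq[w, 2] + a[j] * l1q[w, 2]
        t3 = lr + lpf[y, 0] + a[j] * lqf[w, 0] + d[j] * l1qf[w, 0]
        t4 = lr + lpf[y, 1] + a[j] * lqf[w, 1] + d[j] * l1qf[w, 1]
        t5 = lr + lpf[y, 2] + a[j] * lqf[w, 2] + d[j] * l1qf[w, 2]
        for t in (t0, t1, t2, t3, t4, t5):
            if t > m:
                m = t
        s = (np.exp(t0 - m) + np.exp(t1 - m) + np.exp(t2 - m)
             + np.exp(t3 - m) + np.exp(t4 - m) + np.exp(t5 - m))
        tot += wt[j] * (lc[j] + m + np.log(s))
    return tot
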