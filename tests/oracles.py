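"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's algorithms: the imputation oracle
sums over every hidden-state path explicitly, and the regression-influence
oracle refits the model once per left-out sample.
"""

import itertools

import numpy as np


def enumerate_diploid_posteriors(haps, ref, alt, rho, mu, eps):
    """Genotype posteriors by explicit summation over all (H^2)^L paths.

    haps: H x L binary matrix; ref/alt: per-site read counts.
    Transition per copied haplotype: stay w.p. 1-rho, else jump to a
    uniformly random haplotype (self included) w.p. rho.
    """
    h, length = haps.shape
    q = haps * (1.0 - mu) + (1.0 - haps) * mu
    states = list(itertools.product(range(h), repeat=2))

    def emit(state, t):
        q1, q2 = q[state[0], t], q[state[1], t]
        theta = 0.5 * (q1 + q2)
        theta = theta * (1 - eps) + (1 - theta) * eps
        return theta ** alt[t] * (1 - theta) ** ref[t]

    def trans1(i, j):
        return (1.0 - rho) * (i == j) + rho / h

    post = np.zeros((length, 3))
    total = 0.0
    for path in itertools.product(states, repeat=length):
        prob = 1.0 / (h * h) * emit(path[0], 0)
        for t in range(1, length):
            a, b = path[t - 1], path[t]
            prob *= trans1(a[0], b[0]) * trans1(a[1], b[1]) * emit(path[t], t)
        total += prob
        for t in range(length):
            q1, q2 = q[path[t][0], t], q[path[t][1], t]
            post[t, 0] += prob * (1 - q1) * (1 - q2)
            post[t, 2] += prob * q1 * q2
            post[t, 1] += prob * (q1 * (1 - q2) + (1 - q1) * q2)
    return post / total


def loo_diagnostics(x, y):
    """Influence measures by explicit leave-one-out refits.

    Returns dict of arrays: studentized, dffits, cooks_d, covratio.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    rss = resid @ resid
    s2 = rss / (n - p - 1)
    xtx_inv = np.linalg.inv(design.T @ design)
    hat = np.einsum("ij,jk,ik->i", design, xtx_inv, design)

    student = np.empty(n)
    dffits = np.empty(n)
    cooks = np.empty(n)
    covratio = np.empty(n)
    full_cov_det = np.linalg.det(s2 * xtx_inv)
    for i in range(n):
        keep = np.arange(n) != i
        di, yi = design[keep], y[keep]
        bi, *_ = np.linalg.lstsq(di, yi, rcond=None)
        ri = yi - di @ bi
        s2i = (ri @ ri) / (n - 1 - p - 1)
        student[i] = resid[i] / np.sqrt(s2i * (1 - hat[i]))
        yhat_full = design @ beta
        yhat_del = design @ bi
        dffits[i] = (yhat_full[i] - yhat_del[i]) / np.sqrt(s2i * hat[i])
        cooks[i] = ((yhat_full - yhat_del) ** 2).sum() / ((p + 1) * s2)
        cov_det_i = np.linalg.det(s2i * np.linalg.inv(di.T @ di))
        covratio[i] = cov_det_i / full_cov_det
    return {"studentized": student, "dffits": dffits, "cooks_d": cooks,
            "covratio": covratio, "leverage": hat, "residual": resid,
            "standardized": resid / np.sqrt(s2 * (1 - hat))}
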