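"""Linear-time pruning evaluation of the model's tip likelihood.

One flat-array kernel computes, in a single pass: upsilon products and
effective branch lengths, directional mean offsets, variance-adjusted
times, and the full multivariate-normal log-density via Felsenstein-style
peeling (merging k children of a node contributes
``prod_c N(mu_c; a, v_c) = N(a; m, v_node) * C`` with the constant C
accumulated into the log-likelihood).  Compiled with numba when
available; the pure-Python function is the fallback.

Status codes: 0 ok; 1 covariance singular (two or more zero-variance
subtrees meet, or the root variance collapses) -- the third return value
is the node id where the degeneracy was detected.
"""

import math

import numpy as np

_LOG2PI = math.log(2.0 * math.pi)


def _prune_loglik_py(parent, postorder, child_ptr, child_idx, lengths,
                     is_tip, tip_slot, y, beta, ups, alpha, sigma2,
                     beta_g, include_stem, jitter):
    n = parent.shape[0]
    acc = np.empty(n)
    eff = np.zeros(n)
    off = np.zeros(n)
    T = np.zeros(n)
    acc[0] = ups[0]
    for i in range(1, n):
        p = parent[i]
        acc[i] = acc[p] * ups[i]
        eff[i] = lengths[i] * (acc[i] if include_stem else acc[p])
        off[i] = off[p] + beta[i] * lengths[i]
        T[i] = T[p] + eff[i]

    mu = np.zeros(n)
    var = np.zeros(n)
    logl = 0.0
    for k in range(n):
        node = postorder[k]
        if is_tip[node]:
            mu[node] = y[tip_slot[node]] - off[node] - beta_g * T[node]
            var[node] = jitter
            continue
        lo, hi = child_ptr[node], child_ptr[node + 1]
        nzero = 0
        zchild = -1
        for j in range(lo, hi):
            c = child_idx[j]
            if var[c] + sigma2 * eff[c] <= 0.0:
                nzero += 1
                zchild = c
        if nzero >= 2:
            return -np.inf, 1, node
        if nzero == 1:
            # one child pins the node value exactly (zero-variance path);
            # the other children become plain normal factors around it.
            m = mu[zchild]
            for j in range(lo, hi):
                c = child_idx[j]
                if c == zchild:
                    continue
                v = var[c] + sigma2 * eff[c]
                d = mu[c] - m
                logl += -0.5 * (_LOG2PI + math.log(v) + d * d / v)
            mu[node] = m
            var[node] = 0.0
        else:
            prec = 0.0
            wmean = 0.0
            for j in range(lo, hi):
                c = child_idx[j]
                v = var[c] + sigma2 * eff[c]
                prec += 1.0 / v
                wmean += mu[c] / v
            m = wmean / prec
            vnode = 1.0 / prec
            quad = 0.0
            logdet = 0.0
            for j in range(lo, hi):
                c = child_idx[j]
                v = var[c] + sigma2 * eff[c]
                d = mu[c] - m
                quad += d * d / v
                logdet += math.log(v)
            kk = hi - lo
            logl += (-0.5 * (kk - 1) * _LOG2PI - 0.5 * logdet
                     + 0.5 * math.log(vnode) - 0.5 * quad)
            mu[node] = m
            var[node] = vnode
    vr = var[0]
    if vr <= 0.0:
        return -np.inf, 1, 0
    d = mu[0] - alpha
    logl += -0.5 * (_LOG2PI + math.log(vr) + d * d / vr)
    return logl, 0, -1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    prune_loglik = njit(cache=True, fastmath=False)(_prune_loglik_py)
except Exception:  # pragma: no cover
    prune_loglik = _prune_loglik_py
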