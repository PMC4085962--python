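"""Numba kernels for the pruning-algorithm likelihood.

The 4x4 matrix exponential uses scaling-and-squaring with a Taylor
series: robust for every generator the optimizer can visit, including
the defective (Jordan-block) matrices that arise when backward rates hit
zero, where an eigendecomposition route would lose accuracy.  Loops are
written allocation-free because the optimizer evaluates the likelihood
many thousands of times per fit.

Partial likelihoods are rescaled per internal node (log factors
accumulated) so 1000-tip trees do not underflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_ZERO = -1e12  # finite stand-in for log(0); keeps L-BFGS-B well-posed


@njit(cache=True, inline="always")
def _matmul4(x, y, out):
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += x[i, k] * y[k, j]
            out[i, j] = s


@njit(cache=True)
def _expm4_into(q, t, p, term, scratch):
    """p <- exp(q * t), scaling-and-squaring + Taylor; no allocation."""
    nrm = 0.0
    for i in range(4):
        s = 0.0
        for j in range(4):
            s += abs(q[i, j]) * t
        if s > nrm:
            nrm = s
    n_squarings = 0
    while nrm > 0.5:
        nrm *= 0.5
        n_squarings += 1
    scale = t / (2.0 ** n_squarings)
    # term <- B = q*scale ; p <- I + B
    for i in range(4):
        for j in range(4):
            b = q[i, j] * scale
            term[i, j] = b
            p[i, j] = b
        p[i, i] += 1.0
    for k in range(2, 30):
        # scratch <- term @ B / k ; B stored implicitly as q*scale
        tmax = 0.0
        for i in range(4):
            for j in range(4):
                s = 0.0
                for m in range(4):
                    s += term[i, m] * q[m, j]
                s *= scale / k
                scratch[i, j] = s
                a = abs(s)
                if a > tmax:
                    tmax = a
        for i in range(4):
            for j in range(4):
                term[i, j] = scratch[i, j]
                p[i, j] += scratch[i, j]
        if tmax < 1e-18:
            break
    for _ in range(n_squarings):
        _matmul4(p, p, scratch)
        for i in range(4):
            for j in range(4):
                p[i, j] = scratch[i, j]


def expm4(a):
    """exp(A) for a 4x4 real matrix (thin wrapper over the kernel)."""
    a = np.asarray(a, dtype=np.float64)
    p = np.empty((4, 4))
    _expm4_into(a, 1.0, p, np.empty((4, 4)), np.empty((4, 4)))
    return p


@njit(cache=True)
def ard_loglik(rates, internal_nodes, child_ptr, child_idx, child_blen,
               tip_state, n_nodes, root_prior):
    """Felsenstein pruning log-likelihood of tip states under a 4-state
    all-rates-different model.

    ``rates`` holds the 12 off-diagonal rates in row-major order
    (1->2, 1->3, 1->4, 2->1, 2->3, 2->4, 3->1, 3->2, 3->4, 4->1, 4->2,
    4->3), i.e. cells A..L of the estimated-rate layout.
    """
    q = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = rates[k]
                k += 1
    for i in range(4):
        s = 0.0
        for j in range(4):
            if j != i:
                s += q[i, j]
        q[i, i] = -s

    partial = np.zeros((n_nodes, 4))
    for nd in range(n_nodes):
        st = tip_state[nd]
        if st >= 0:
            partial[nd, st] = 1.0

    p = np.empty((4, 4))
    term = np.empty((4, 4))
    scratch = np.empty((4, 4))
    logscale = 0.0
    for ii in range(internal_nodes.shape[0]):
        nd = internal_nodes[ii]
        v0 = 1.0
        v1 = 1.0
        v2 = 1.0
        v3 = 1.0
        for ci in range(child_ptr[nd], child_ptr[nd + 1]):
            c = child_idx[ci]
            _expm4_into(q, child_blen[ci], p, term, scratch)
            c0 = partial[c, 0]
            c1 = partial[c, 1]
            c2 = partial[c, 2]
            c3 = partial[c, 3]
            for a in range(4):
                acc = (max(p[a, 0], 0.0) * c0 + max(p[a, 1], 0.0) * c1
                       + max(p[a, 2], 0.0) * c2 + max(p[a, 3], 0.0) * c3)
                if a == 0:
                    v0 *= acc
                elif a == 1:
                    v1 *= acc
                elif a == 2:
                    v2 *= acc
                else:
                    v3 *= acc
        m = max(max(v0, v1), max(v2, v3))
        if not (m > 0.0) or not np.isfinite(m):
            return _LOG_ZERO
        partial[nd, 0] = v0 / m
        partial[nd, 1] = v1 / m
        partial[nd, 2] = v2 / m
        partial[nd, 3] = v3 / m
        logscale += np.log(m)

    root = internal_nodes[internal_nodes.shape[0] - 1]
    total = 0.0
    for a in range(4):
        total += root_prior[a] * partial[root, a]
    if total <= 0.0:
        return _LOG_ZERO
    return np.log(total) + logscale
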