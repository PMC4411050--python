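"""Numba-compiled inner loops: gwesp change statistics and the MH sampler.

Everything here operates on a dense uint8 adjacency matrix with an
empty diagonal. The geometrically weighted edgewise-shared-partner
(gwesp) statistic with decay alpha is

    gwesp(y) = e^alpha * sum_{k>=1} [1 - (1 - e^{-alpha})^k] * EP_k(y)

where EP_k is the number of directed edges with exactly k shared
partners. Writing r = 1 - e^{-alpha}, an edge's contribution is
w(k) = e^alpha (1 - r^k), and w(k+1) - w(k) = r^k, which is what the
incremental formulas below exploit.

Shared-partner orientation codes (directed edge u -> v):
  0 "transitive": w with u -> w and w -> v (outgoing two-path)
  1 "cyclic":     w with v -> w and w -> u (incoming two-path)
  2 "any":        w adjacent to both u and v in either direction
"""

from __future__ import annotations

import numpy as np
from numba import njit

SP_TRANSITIVE, SP_CYCLIC, SP_ANY = 0, 1, 2


@njit(cache=False)
def _sp_count(A, u, v, code):
    """Number of shared partners of the ordered pair (u, v)."""
    n = A.shape[0]
    c = 0
    if code == 0:
        for w in range(n):
            if A[u, w] and A[w, v]:
                c += 1
    elif code == 1:
        for w in range(n):
            if A[v, w] and A[w, u]:
                c += 1
    else:
        for w in range(n):
            if w != u and w != v:
                if (A[u, w] or A[w, u]) and (A[v, w] or A[w, v]):
                    c += 1
    return c


@njit(cache=False)
def gwesp_delta_add(A, i, j, r, exp_alpha, code):
    """Change in gwesp from adding the absent edge (i, j) to A.

    A must not contain (i, j). The delta has two parts: the new edge's
    own weight w(sp(i, j)), and r^k for every existing edge whose
    shared-partner count k rises by one because the new tie completes a
    two-path for it (each affected edge gains at most one partner).
    """
    n = A.shape[0]
    d = exp_alpha * (1.0 - r ** _sp_count(A, i, j, code))
    if code == 0:
        # new tie i->j is the u->w leg (w=j) for edges (i, v) with j->v,
        # and the w->v leg (w=i) for edges (u, j) with u->i
        for v in range(n):
            if A[i, v] and A[j, v]:
                d += r ** _sp_count(A, i, v, 0)
        for u in range(n):
            if A[u, j] and A[u, i]:
                d += r ** _sp_count(A, u, j, 0)
    elif code == 1:
        # two-path v->w->u closing edge (u, v): new tie as (v,w)=(i,j)
        # affects edges (u, i) with j->u; as (w,u)=(i,j) affects (j, v)
        # with v->i
        for u in range(n):
            if A[u, i] and A[j, u]:
                d += r ** _sp_count(A, u, i, 1)
        for v in range(n):
            if A[j, v] and A[v, i]:
                d += r ** _sp_count(A, j, v, 1)
    else:
        # the undirected pair {i, j} becomes adjacent only if j->i is
        # also absent; then i or j becomes a new shared partner for
        # edges with the other endpoint adjacent to the far node
        if not A[j, i]:
            for v in range(n):
                if v != j and A[i, v] and (A[j, v] or A[v, j]):
                    d += r ** _sp_count(A, i, v, 2)
            for u in range(n):
                if u != j and A[u, i] and (A[u, j] or A[j, u]):
                    d += r ** _sp_count(A, u, i, 2)
            for v in range(n):
                if v != i and A[j, v] and (A[i, v] or A[v, i]):
                    d += r ** _sp_count(A, j, v, 2)
            for u in range(n):
                if u != i and A[u, j] and (A[u, i] or A[i, u]):
                    d += r ** _sp_count(A, u, j, 2)
    return d


@njit(cache=False)
def gwesp_global(A, r, exp_alpha, code):
    """Full gwesp statistic of A."""
    n = A.shape[0]
    s = 0.0
    for u in range(n):
        for v in range(n):
            if A[u, v]:
                s += exp_alpha * (1.0 - r ** _sp_count(A, u, v, code))
    return s


@njit(cache=False)
def gwesp_change_matrix(A, r, exp_alpha, code):
    """Toggle deltas g(y+ij) - g(y-ij) of gwesp for every ordered dyad."""
    n = A.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if A[i, j]:
                A[i, j] = 0
                out[i, j] = gwesp_delta_add(A, i, j, r, exp_alpha, code)
                A[i, j] = 1
            else:
                out[i, j] = gwesp_delta_add(A, i, j, r, exp_alpha, code)
    return out


@njit(cache=False)
def mh_kernel(
    A,
    g,
    static_mats,
    theta,
    idx_od0,
    idx_gwesp,
    r,
    exp_alpha,
    sp_code,
    max_out,
    burnin,
    interval,
    ndraws,
    tnt,
    keep_nets,
    seed,
):
    """Metropolis-Hastings over single-dyad toggles.

    A (uint8, modified in place) is the starting state; g the matching
    statistic vector, updated incrementally. static_mats[t] holds the
    state-independent toggle delta of term t (zeros for the odegree0 /
    gwesp slots named by idx_od0 / idx_gwesp; -1 when absent).

    Proposal: tie/no-tie when ``tnt`` (with prob 1/2 toggle a uniformly
    chosen existing tie, else a uniform dyad) with the exact Hastings
    correction, or plain uniform-dyad. A toggle-on that would push the
    ego past ``max_out`` out-ties (when >= 0) is rejected outright,
    which restricts the stationary law to the constrained space.

    Returns (stats draws x T, kept networks, accepted count, proposals).
    """
    np.random.seed(seed)
    n = A.shape[0]
    T = theta.shape[0]
    D = n * (n - 1)
    out_deg = np.zeros(n, dtype=np.int64)
    ei = np.empty(D, dtype=np.int64)
    ej = np.empty(D, dtype=np.int64)
    pos = np.full((n, n), -1, dtype=np.int64)
    E = 0
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                out_deg[i] += 1
                ei[E] = i
                ej[E] = j
                pos[i, j] = E
                E += 1
    stats = np.empty((ndraws, T))
    nets = np.empty((ndraws if keep_nets else 0, n, n), dtype=np.uint8)
    dadd = np.empty(T)
    n_accept = 0
    n_propose = 0
    total = burnin + ndraws * interval
    drawn = 0
    for step in range(total):
        # --- propose a dyad ---
        if tnt and E > 0 and np.random.random() < 0.5:
            k = np.random.randint(E)
            i = ei[k]
            j = ej[k]
        else:
            i = np.random.randint(n)
            j = np.random.randint(n - 1)
            if j >= i:
                j += 1
        removing = A[i, j] == 1
        n_propose += 1
        if (not removing) and max_out >= 0 and out_deg[i] >= max_out:
            pass  # infeasible toggle-on: reject at the proposal stage
        else:
            if tnt:
                if removing:
                    q_f = 0.5 / E + 0.5 / D
                    q_b = (0.5 if E > 1 else 1.0) / D
                else:
                    q_f = (0.5 if E > 0 else 1.0) / D
                    q_b = 0.5 / (E + 1) + 0.5 / D
                log_corr = np.log(q_b) - np.log(q_f)
            else:
                log_corr = 0.0
            # --- toggle delta, computed on the state without the edge ---
            if removing:
                A[i, j] = 0
                out_deg[i] -= 1
                k = pos[i, j]
                E -= 1
                ei[k] = ei[E]
                ej[k] = ej[E]
                pos[ei[k], ej[k]] = k
                pos[i, j] = -1
            for t in range(T):
                if t == idx_od0:
                    dadd[t] = -1.0 if out_deg[i] == 0 else 0.0
                elif t == idx_gwesp:
                    dadd[t] = gwesp_delta_add(A, i, j, r, exp_alpha, sp_code)
                else:
                    dadd[t] = static_mats[t, i, j]
            lp = 0.0
            for t in range(T):
                lp += theta[t] * dadd[t]
            logratio = (-lp if removing else lp) + log_corr
            if np.log(np.random.random()) < logratio:
                n_accept += 1
                if removing:
                    for t in range(T):
                        g[t] -= dadd[t]
                else:
                    A[i, j] = 1
                    out_deg[i] += 1
                    ei[E] = i
                    ej[E] = j
                    pos[i, j] = E
                    E += 1
                    for t in range(T):
                        g[t] += dadd[t]
            elif removing:
                # rejected removal: restore the edge
                A[i, j] = 1
                out_deg[i] += 1
                ei[E] = i
                ej[E] = j
                pos[i, j] = E
                E += 1
        if step >= burnin and (step - burnin + 1) % interval == 0:
            stats[drawn, :] = g
            if keep_nets:
                nets[drawn, :, :] = A
            drawn += 1
    return stats, nets, n_accept, n_propose
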