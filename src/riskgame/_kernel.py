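"""Compiled simulation loop.

This mirrors, operation for operation and random draw for random draw, the
composed reference path in :mod:`riskgame.evolution` (partition ->
contributions -> central punishment -> peer punishment -> risk resolution
-> synchronous Fermi learning -> mutation), so the two engines produce
bit-identical results from the same seed; a regression test asserts this.
The per-round random-call sequence is: ``permutation(N)``,
``integers(0, N-1, size=N)``, ``random(N)``, then for mutation ``n_mut``
scalar ``integers(i, N)`` draws (partial Fisher-Yates) followed by
``integers(0, L-1, size=n_mut)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# strategy codes, fixed by model_core.Strategy
_C, _CP, _PP, _D = 0, 1, 2, 3


@njit(cache=True)
def simulate(
    rng,
    strat0,
    codes,
    t_rounds,
    a,
    n,
    m,
    u,
    w1,
    w,
    w2,
    t1,
    t2,
    u_risk,
    beta,
    n_mut,
    tol,
):
    n_ind = a * n
    n_codes = codes.size
    strat = strat0.copy()
    newstrat = np.empty(n_ind, strat0.dtype)
    counts = np.zeros((t_rounds, 4), np.int64)
    succ = np.zeros(t_rounds, np.int64)
    succ_collab = np.zeros(t_rounds, np.int64)
    contrib = np.zeros(t_rounds)
    c_loss = np.zeros(t_rounds)
    c_cost = np.zeros(t_rounds)
    p_loss = np.zeros(t_rounds)
    p_cost = np.zeros(t_rounds)
    res = np.zeros(n_ind)

    for t in range(t_rounds):
        perm = rng.permutation(n_ind)
        for g in range(a):
            base = g * n
            n_cp = 0
            n_pp = 0
            n_d = 0
            for k in range(n):
                s = strat[perm[base + k]]
                if s == _CP:
                    n_cp += 1
                elif s == _PP:
                    n_pp += 1
                elif s == _D:
                    n_d += 1
            total = u * (n - n_d)
            inst = w1 * n_cp >= w - tol
            ok = total >= u_risk - tol
            for k in range(n):
                idx = perm[base + k]
                s = strat[idx]
                bal = m
                if s != _D:
                    bal -= u
                if s == _CP:
                    bal -= w1
                elif s == _PP:
                    bal -= w2 * n_d
                elif s == _D:
                    if inst:
                        bal -= t1
                    bal -= t2 * n_pp
                res[idx] = bal if ok else 0.0
            contrib[t] += total
            c_cost[t] += w1 * n_cp
            if inst:
                c_loss[t] += t1 * n_d
            p_loss[t] += t2 * n_pp * n_d
            p_cost[t] += w2 * n_pp * n_d
            if ok:
                succ[t] += 1
                succ_collab[t] += n - n_d
        for i in range(n_ind):
            counts[t, strat[i]] += 1

        # synchronous Fermi imitation against the frozen snapshot
        partners = rng.integers(0, n_ind - 1, size=n_ind)
        coin = rng.random(n_ind)
        for i in range(n_ind):
            j = partners[i]
            if j >= i:
                j += 1
            x = (res[j] - res[i]) / beta
            if x >= 0.0:
                pij = 1.0 / (1.0 + np.exp(-x))
            else:
                e = np.exp(x)
                pij = e / (1.0 + e)
            newstrat[i] = strat[j] if coin[i] < pij else strat[i]
        tmp = strat
        strat = newstrat
        newstrat = tmp

        if n_mut > 0:
            pool = np.arange(n_ind)
            for i in range(n_mut):
                j = rng.integers(i, n_ind)
                swap = pool[i]
                pool[i] = pool[j]
                pool[j] = swap
            alt = rng.integers(0, n_codes - 1, size=n_mut)
            for i in range(n_mut):
                idx = pool[i]
                cur = strat[idx]
                pos = 0
                for q in range(n_codes):
                    if codes[q] == cur:
                        pos = q
                        break
                r = alt[i]
                if r >= pos:
                    r += 1
                strat[idx] = codes[r]

    return counts, succ, succ_collab, contrib, c_loss, c_cost, p_loss, p_cost, res
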