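"""Independent brute-force oracles used to cross-check the optimization code.

Everything here is deliberately written as plain enumeration with explicit
loops, sharing no code path with the MILP/LP implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_cstep_optimum(F, U, panel, c_max, lam1, lam2):
    """Exhaustive C-step optimum for the unique N=3 topology (two leaves + root).

    Enumerates, per variant, its allele d and placement (absent, leaf 0 or
    leaf 1, mates jointly) and, per segment, all allele-specific copy-number
    assignments of the two leaves, scoring data + lam1*R + lam2*S directly
    from the definitions. Returns the minimal objective value.
    """
    F = np.asarray(F, float)
    U = np.asarray(U, float)
    m = F.shape[0]
    l, g, r = panel.l, panel.g, panel.r
    V = l + g
    seg_of = panel.segment_of
    mate = panel.mate_of

    seg_tot = F[:, V : V + r] + F[:, V + r :]
    psi = seg_tot[:, seg_of] if V else np.zeros((m, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(psi > 0, F[:, :V] / np.where(psi > 0, psi, 1.0), 0.0)
    pi = np.clip(pi, 0.0, 1.0)

    # variant pattern = (d, place) with place in (-1 absent, 0, 1); mates share
    groups = []  # list of variant-index tuples sharing a pattern
    seen = set()
    for b in range(V):
        if b < l:
            mb = int(mate[b])
            if b in seen:
                continue
            groups.append((b, mb))
            seen.update((b, mb))
        else:
            groups.append((b,))
    pattern_choices = list(itertools.product((1, 0), (-1, 0, 1)))

    best = np.inf
    for assign in itertools.product(pattern_choices, repeat=len(groups)):
        pat = {}
        for grp, (d, place) in zip(groups, assign):
            for b in grp:
                pat[b] = (d, place)
        total = 0.0
        feasible = True
        for s in range(r):
            vars_here = [b for b in range(V) if seg_of[b] == s]
            best_seg = np.inf
            for cols in itertools.product(range(c_max + 1), repeat=4):
                # allele copies: (leaf0 a1, leaf1 a1, leaf0 a2, leaf1 a2)
                a1 = np.array([cols[0], cols[1], 1.0])
                a2 = np.array([cols[2], cols[3], 1.0])
                cost = 0.0
                for p in range(m):
                    cost += abs(F[p, V + s] - float(U[p] @ a1))
                    cost += abs(F[p, V + r + s] - float(U[p] @ a2))
                cost += lam1 * (abs(a1[0] - 1) + abs(a1[1] - 1)
                                + abs(a2[0] - 1) + abs(a2[1] - 1))
                for b in vars_here:
                    d, place = pat[b]
                    gam = a1 if d == 1 else a2
                    gtot = a1 + a2
                    if place == -1:
                        c_b = np.zeros(3)
                        vcost = _var_cost(F, U, pi, psi, b, c_b, gtot, lam2, m)
                    else:
                        cap = int(gam[place])
                        if cap < 1:
                            cost = np.inf
                            break
                        vcost = np.inf
                        for v in range(1, min(c_max, cap) + 1):
                            c_b = np.zeros(3)
                            c_b[place] = v
                            vcost = min(vcost, _var_cost(F, U, pi, psi, b, c_b, gtot, lam2, m))
                    cost += vcost
                    if not np.isfinite(cost):
                        break
                best_seg = min(best_seg, cost)
            if not np.isfinite(best_seg):
                feasible = False
                break
            total += best_seg
        if feasible:
            best = min(best, total)
    return best


def _var_cost(F, U, pi, psi, b, c_b, gtot, lam2, m):
    cost = 0.0
    for p in range(m):
        pred = float(U[p] @ c_b)
        cost += abs(F[p, b] - pred)
        if psi[p, b] > 0:
            cost += lam2 * abs(pi[p, b] * float(U[p] @ gtot) - pred)
    return cost


def grid_ustep_optimum(F_row, C, step=0.001):
    """Grid search of min_u sum |F - uC| over the 3-simplex (single sample)."""
    F_row = np.asarray(F_row, float)
    C = np.asarray(C, float)
    best = np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for u0 in ticks:
        u1s = np.arange(0.0, 1.0 - u0 + step / 2, step)
        if len(u1s) == 0:
            continue
        u2s = 1.0 - u0 - u1s
        Us = np.column_stack([np.full_like(u1s, u0), u1s, u2s])
        obj = np.abs(Us @ C - F_row).sum(axis=1)
        best = min(best, float(obj.min()))
    return best


def brute_force_assignment(F_obs, seg, tree, U, C, V, r, admissibility="gt1"):
    """Reference mapper: explicit loops over (allele, node, scenario).

    ``F_obs`` (m,) observed copies of one held-out variant; ``seg`` its
    segment index. Returns (node, d, scenario, distance).
    """
    N = tree.N
    A = tree.ancestry()
    parents = tree.parents()
    best = None
    for i in range(N - 1):  # root excluded
        for d in (1, 0):
            col = V + seg if d == 1 else V + r + seg
            chat_i = float(C[i, col])
            chat_par = float(C[parents[i], col])
            for scenario in (1, 2):
                if scenario == 1:
                    gap_ok = chat_i - chat_par > 1 if admissibility == "gt1" else chat_i - chat_par >= 1
                    if not (chat_i == 1 or gap_ok):
                        continue
                    pred = U[:, i] * chat_i
                    for k in range(N):
                        if A[i, k]:
                            pred = pred + U[:, k] * float(C[k, col])
                else:
                    if chat_i < 1:
                        continue
                    pred = U[:, i] * 1.0
                    for k in range(N):
                        if A[i, k]:
                            pred = pred + U[:, k] * float(C[k, col]) / chat_i
                dist = float(np.abs(pred - F_obs).sum())
                if best is None or dist < best[3] - 1e-15:
                    best = (i, d, scenario, dist)
    return best
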