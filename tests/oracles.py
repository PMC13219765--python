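"""Independent reference implementations used only to check solband.

These deliberately use different algorithms from the package: the QP oracle
enumerates KKT active sets exhaustively, and the Wilcoxon oracle enumerates
all 2^n sign assignments.  Both are exponential-time and meant for tiny
problems.
"""

from __future__ import annotations

import itertools

import numpy as np

FREE, LOWER, UPPER = 0, 1, 2


def qp_box_oracle(G, tau, w, lb=None, ub=None, tol=1e-8):
    """Exact solution of min sum w_i a_i^2 s.t. G a = tau, lb <= a <= ub.

    Enumerates every assignment of variables to {free, at lower, at upper},
    solves the equality-constrained KKT system for the free block, and keeps
    the candidates satisfying primal bounds and dual sign conditions;
    returns the feasible candidate with the smallest objective.  Exponential
    in m — use only for m <= ~6.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n_dof, m = G.shape
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(w, dtype=float)
    lb = np.zeros(m) if lb is None else np.asarray(lb, dtype=float)
    ub = np.ones(m) if ub is None else np.asarray(ub, dtype=float)

    best, best_obj = None, np.inf
    for assign in itertools.product((FREE, LOWER, UPPER), repeat=m):
        assign = np.asarray(assign)
        a = np.where(assign == LOWER, lb, np.where(assign == UPPER, ub, 0.0))
        free = assign == FREE
        nf = int(free.sum())
        rhs_tau = tau - G[:, ~free] @ a[~free]
        if nf:
            # KKT: [2W_F, -G_F'; G_F, 0] [a_F; lam] = [0; rhs]
            K = np.zeros((nf + n_dof, nf + n_dof))
            K[:nf, :nf] = np.diag(2.0 * w[free])
            K[:nf, nf:] = -G[:, free].T
            K[nf:, :nf] = G[:, free]
            rhs = np.concatenate([np.zeros(nf), rhs_tau])
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            if np.linalg.norm(K @ sol - rhs) > tol * max(1.0, np.linalg.norm(rhs)):
                continue  # singular/inconsistent block
            a[free] = sol[:nf]
            lam = sol[nf:]
        else:
            if np.linalg.norm(rhs_tau) > tol * max(1.0, np.linalg.norm(tau)):
                continue
            # any lam certifying the bounds works; try least squares on the
            # active stationarity conditions
            lam, *_ = np.linalg.lstsq(G.T, 2.0 * w * a, rcond=None)
        if np.any(a < lb - tol) or np.any(a > ub + tol):
            continue
        glam = G.T @ lam
        dual_ok = True
        for i in range(m):
            if assign[i] == LOWER and 2 * w[i] * lb[i] - glam[i] < -tol:
                dual_ok = False
            elif assign[i] == UPPER and glam[i] - 2 * w[i] * ub[i] < -tol:
                dual_ok = False
        if not dual_ok:
            continue
        obj = float(np.dot(w, a * a))
        if obj < best_obj - 1e-15:
            best, best_obj = np.clip(a, lb, ub), obj
    return best


def wilcoxon_brute_p(x, y):
    """Exact two-sided signed-rank p-value by enumerating 2^n sign patterns.

    Midranks for tied |differences|; zero differences dropped.  Returns the
    doubled smaller tail of the W+ null distribution, capped at 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    # midranks
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sa = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[d > 0].sum()
    values = []
    for signs in itertools.product((0, 1), repeat=n):
        values.append(sum(r for s, r in zip(signs, ranks) if s))
    values = np.asarray(values)
    eps = 1e-9
    cdf = np.mean(values <= w_obs + eps)
    sf = np.mean(values >= w_obs - eps)
    return min(1.0, 2.0 * min(cdf, sf))
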