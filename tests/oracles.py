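"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solver paths: the LP oracle
enumerates polytope vertices directly, and the ODE oracle is a plain
fixed-step RK4 over the documented mass-balance equations.
"""

from __future__ import annotations

import itertools

import numpy as np

from fedflux.kinetics import death_rate, growth_rate, specific_rates
from fedflux.twin import SPECIES


def vertex_enumeration_lp(S, c, lo, hi, tol=1e-9):
    """max c'v s.t. S v = 0, lo <= v <= hi by vertex enumeration.

    A vertex fixes (n - rank(S)) variables at a bound; the remaining square
    system is solved exactly.  Returns (best objective, best vertex).
    """
    S = np.asarray(S, float)
    n = S.shape[1]
    m = int(np.linalg.matrix_rank(S))
    d = n - m
    best, best_v = -np.inf, None
    idx = np.arange(n)
    # all 2^d lo/hi sign patterns, shared across subsets
    patterns = np.array(list(itertools.product((0, 1), repeat=d)))
    for J in itertools.combinations(range(n), d):
        J = list(J)
        F = [j for j in idx if j not in J]
        SF = S[:, F]
        SJ = S[:, J]
        # all bound choices at once: columns of VJ are the fixed values
        VJ = np.where(patterns.T == 0, lo[J][:, None], hi[J][:, None])
        rhs = -SJ @ VJ
        try:
            VF, res, rank, _ = np.linalg.lstsq(SF, rhs, rcond=None)
        except np.linalg.LinAlgError:
            continue
        if rank < m:
            continue
        resid = np.max(np.abs(SF @ VF - rhs), axis=0)
        scale = np.maximum(1.0, np.max(np.abs(VF), axis=0))
        for k in range(VJ.shape[1]):
            if resid[k] > tol * scale[k]:
                continue
            v = np.empty(n)
            v[J] = VJ[:, k]
            v[F] = VF[:, k]
            if np.any(v < lo - 1e-7) or np.any(v > hi + 1e-7):
                continue
            obj = float(c @ v)
            if obj > best:
                best, best_v = obj, v
    return best, best_v


def rk4_reference(x0, policy, p, t_end, dt=0.01):
    """Fixed-step RK4 on the reactor mass balances, written out directly."""

    def deriv(t, y):
        V = max(y[0], 1e-12)
        Xv = max(y[1], 0.0)
        Xd = max(y[2], 0.0)
        C = {s: max(y[3 + i], 0.0) for i, s in enumerate(SPECIES)}
        P = max(y[-1], 0.0)
        F_in, F_out, _ = policy.at(t)
        feed = policy.feed_concentrations(t)
        mu = growth_rate(C, p)
        mu_d = death_rate(C, p)
        q = specific_rates(C, p)
        dy = np.empty_like(y)
        dy[0] = F_in - F_out
        dy[1] = (mu - mu_d) * Xv - F_in * Xv / V
        dy[2] = mu_d * Xv - F_in * Xd / V
        for i, s in enumerate(SPECIES):
            dy[3 + i] = (F_in * feed.get(s, 0.0) - F_in * C[s]) / V + q[s] * Xv
        dy[-1] = (p.alpha * mu + p.beta) * Xv - F_in * P / V
        return dy

    n = int(round((t_end - x0.t) / dt))
    y = x0.to_vector()
    t = x0.t
    for _ in range(n):
        k1 = deriv(t, y)
        k2 = deriv(t + dt / 2, y + dt / 2 * k1)
        k3 = deriv(t + dt / 2, y + dt / 2 * k2)
        k4 = deriv(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y[1:] = np.maximum(y[1:], 0.0)
        t += dt
    return y
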