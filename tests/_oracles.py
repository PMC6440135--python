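"""Independent oracles kept free of the implementation paths they check."""

from __future__ import annotations

import math

import numpy as np


def loglik(d, n, x, beta):
    """Direct binomial log-likelihood (no combinatorial constant)."""
    eta = x @ np.asarray(beta, float)
    p = 1.0 / (1.0 + np.exp(-eta))
    out = 0.0
    for di, ni, pi in zip(d, n, p):
        if di > 0:
            out += di * math.log(pi)
        if ni - di > 0:
            out += (ni - di) * math.log(1.0 - pi)
    return out


def brute_force_fit_2d(d, n, x, span=4.0, points=41, zooms=40):
    """Maximise a 2-coefficient binomial log-likelihood by grid refinement.

    Evaluates the likelihood over a square grid, recentres on the best
    cell and shrinks the window, expanding instead when the optimum sits
    on the boundary. Accurate to far better than 1e-6 after 40 zooms.
    """
    assert x.shape[1] == 2
    center = np.zeros(2)
    half = span
    for _ in range(zooms):
        g0 = np.linspace(center[0] - half, center[0] + half, points)
        g1 = np.linspace(center[1] - half, center[1] + half, points)
        best, best_ll = None, -np.inf
        for i, b0 in enumerate(g0):
            for j, b1 in enumerate(g1):
                ll = loglik(d, n, x, (b0, b1))
                if ll > best_ll:
                    best_ll, best = ll, (i, j)
        i, j = best
        center = np.array([g0[i], g1[j]])
        on_edge = i in (0, points - 1) or j in (0, points - 1)
        half = half * 2.0 if on_edge else half * (2.0 / (points - 1)) * 2.0
    return center


def deviance_by_summation(d, n, p):
    """Residual deviance as 2*(saturated - model) log-likelihood, term by term."""
    total = 0.0
    for di, ni, pi in zip(d, n, p):
        sat = 0.0
        if di > 0:
            sat += di * math.log(di / ni)
        if ni - di > 0:
            sat += (ni - di) * math.log((ni - di) / ni)
        mod = 0.0
        if di > 0:
            mod += di * math.log(pi)
        if ni - di > 0:
            mod += (ni - di) * math.log(1.0 - pi)
        total += 2.0 * (sat - mod)
    return total
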