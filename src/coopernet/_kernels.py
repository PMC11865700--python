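"""Compiled inner loops for the penalized Cox solver.

Everything here operates on rows pre-sorted by ascending time, with tie
groups described by ``group_start`` (length G+1, trailing sentinel n).  The
covariate matrix is Fortran-ordered so column access is contiguous.

The solver combines:

* the Breslow partial-likelihood recursions (value / gradient / diagonal
  Hessian in the linear predictor),
* IRLS with step-halving on the penalized objective, and
* cyclic coordinate descent with per-feature penalty factors over a working
  set, finished by a full Karush-Kuhn-Tucker sweep that admits violators.

Objective convention: (1/n) * NLL + lambda * sum_j w_j (alpha |b_j| +
(1-alpha)/2 b_j^2); the l1/l2 penalty vectors passed in already contain the
lambda * w_j products.
"""

import numpy as np
from numba import njit

__all__ = [
    "breslow_stats",
    "solve_penalized_cox",
    "minimize_theta_golden",
    "theta_objective",
]


@njit(cache=True, fastmath=True)
def breslow_stats(eta, delta, group_start, group_delta):
    """Breslow NLL, gradient and diagonal Hessian w.r.t. the linear predictor."""
    n = eta.shape[0]
    G = group_delta.shape[0]
    grad = np.zeros(n)
    hess = np.zeros(n)
    nev = 0.0
    for g in range(G):
        nev += group_delta[g]
    if nev == 0.0:
        return 0.0, grad, hess
    m = eta[0]
    for i in range(1, n):
        if eta[i] > m:
            m = eta[i]
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - m)
    # suffix risk sums per tie group
    S = np.empty(G)
    acc = 0.0
    for g in range(G - 1, -1, -1):
        for i in range(group_start[g], group_start[g + 1]):
            acc += e[i]
        S[g] = acc
    nll = 0.0
    a = 0.0
    b = 0.0
    for g in range(G):
        d = group_delta[g]
        if d > 0.0:
            nll += d * (np.log(S[g]) + m)
            a += d / S[g]
            b += d / (S[g] * S[g])
        for i in range(group_start[g], group_start[g + 1]):
            if delta[i] > 0.0:
                nll -= eta[i]
            grad[i] = -delta[i] + e[i] * a
            hi = e[i] * a - e[i] * e[i] * b
            hess[i] = hi if hi > 0.0 else 0.0
    return nll, grad, hess


@njit(cache=True)
def _penalty_value(beta, pen_l1, pen_l2):
    s = 0.0
    for j in range(beta.shape[0]):
        bj = beta[j]
        if bj != 0.0:
            s += pen_l1[j] * abs(bj) + 0.5 * pen_l2[j] * bj * bj
    return s


@njit(cache=True, fastmath=True)
def _cd_pass(Xs, W, wr, beta, ws_idx, v, pen_l1, pen_l2):
    """One cyclic coordinate-descent sweep; returns the largest weighted change.

    ``wr`` carries the weighted working residual W * (z - X beta), updated
    in place, so each coordinate's inner product streams two arrays.
    """
    n = Xs.shape[0]
    dmax = 0.0
    for k in range(ws_idx.shape[0]):
        j = ws_idx[k]
        vj = v[k]
        denom = vj + pen_l2[j]
        if denom <= 0.0:
            continue
        bj = beta[j]
        u = vj * bj
        for i in range(n):
            u += Xs[i, j] * wr[i]
        l1 = pen_l1[j]
        if u > l1:
            bnew = (u - l1) / denom
        elif u < -l1:
            bnew = (u + l1) / denom
        else:
            bnew = 0.0
        if bnew != bj:
            diff = bj - bnew
            for i in range(n):
                wr[i] += W[i] * Xs[i, j] * diff
            beta[j] = bnew
            change = vj * diff * diff
            if change > dmax:
                dmax = change
    return dmax


@njit(cache=True, fastmath=True)
def solve_penalized_cox(Xs, delta, group_start, group_delta, pen_l1, pen_l2,
                        beta, ws_mask, cd_tol, irls_tol, max_irls, max_cd,
                        kkt_tol, full_kkt):
    """Minimize (1/n) NLL(Xs beta) + penalty over beta, warm-started in place.

    ``ws_mask`` seeds the working set (ever-active and strong-rule
    candidates); with ``full_kkt`` a final sweep over all coordinates admits
    any violator and re-solves, so screening only affects speed.  With
    ``full_kkt`` false the solve is restricted to the working set (used for
    intermediate alternation steps; the caller must validate the final
    solution).  Returns ``(nll, grad_beta, n_new)`` where ``grad_beta =
    Xs.T @ dNLL/deta / n`` at the solution (reusable for path screening;
    zeros when ``full_kkt`` is false) and ``n_new`` counts working-set
    admissions.
    """
    n, p = Xs.shape
    inv_n = 1.0 / n
    for j in range(p):
        if beta[j] != 0.0:
            ws_mask[j] = True
    eta = np.zeros(n)
    for j in range(p):
        if beta[j] != 0.0:
            bj = beta[j]
            for i in range(n):
                eta[i] += Xs[i, j] * bj
    nll, g_eta, h_eta = breslow_stats(eta, delta, group_start, group_delta)
    kkt_rounds = 0
    n_admitted = 0
    while True:
        kkt_rounds += 1
        ws_idx = np.flatnonzero(ws_mask)
        nws = ws_idx.shape[0]
        pobj = nll * inv_n + _penalty_value(beta, pen_l1, pen_l2)
        for _irls in range(max_irls):
            if nws == 0:
                break
            # working weights / response on the current linearization
            W = np.empty(n)
            wr = np.empty(n)       # W * (z - eta), the weighted residual
            allzero = True
            for i in range(n):
                hi = h_eta[i]
                if hi > 1e-12:
                    W[i] = hi * inv_n
                    wr[i] = -g_eta[i] * inv_n
                    allzero = False
                else:
                    W[i] = 0.0
                    wr[i] = 0.0
            if allzero:
                break
            v = np.empty(nws)
            for k in range(nws):
                j = ws_idx[k]
                s = 0.0
                for i in range(n):
                    s += W[i] * Xs[i, j] * Xs[i, j]
                v[k] = s
            beta_old = beta.copy()
            # CD: converge the current actives first, then verify with a
            # sweep over the full working set; repeat until the sweep is clean
            for _cd in range(max_cd):
                nact = 0
                for k in range(nws):
                    if beta[ws_idx[k]] != 0.0:
                        nact += 1
                act_idx = np.empty(nact, dtype=ws_idx.dtype)
                act_v = np.empty(nact)
                m_ = 0
                for k in range(nws):
                    if beta[ws_idx[k]] != 0.0:
                        act_idx[m_] = ws_idx[k]
                        act_v[m_] = v[k]
                        m_ += 1
                for _ in range(max_cd):
                    dmax = _cd_pass(Xs, W, wr, beta, act_idx, act_v, pen_l1, pen_l2)
                    if dmax < cd_tol:
                        break
                dmax = _cd_pass(Xs, W, wr, beta, ws_idx, v, pen_l1, pen_l2)
                if dmax < cd_tol:
                    break
            # candidate step with halving on the penalized objective
            delta_eta = np.zeros(n)
            moved = False
            for k in range(nws):
                j = ws_idx[k]
                db = beta[j] - beta_old[j]
                if db != 0.0:
                    moved = True
                    for i in range(n):
                        delta_eta[i] += Xs[i, j] * db
            if not moved:
                break
            accepted = False
            frac = 1.0
            for _ in range(12):
                eta_new = eta + frac * delta_eta
                nll_new, g_new, h_new = breslow_stats(eta_new, delta, group_start, group_delta)
                cand = beta_old + frac * (beta - beta_old)
                pobj_new = nll_new * inv_n + _penalty_value(cand, pen_l1, pen_l2)
                if pobj_new <= pobj + 1e-12:
                    for j in range(p):
                        beta[j] = cand[j]
                    eta = eta_new
                    nll, g_eta, h_eta = nll_new, g_new, h_new
                    accepted = True
                    break
                frac *= 0.5
            if not accepted:
                for j in range(p):
                    beta[j] = beta_old[j]
                break
            step_max = 0.0  # weighted squared coefficient move of this step
            for k in range(nws):
                j = ws_idx[k]
                db = beta[j] - beta_old[j]
                c = v[k] * db * db
                if c > step_max:
                    step_max = c
            if step_max < cd_tol or pobj - pobj_new < irls_tol * (abs(pobj) + 1.0):
                pobj = pobj_new
                break
            pobj = pobj_new
        if not full_kkt:
            return nll, np.zeros(p), n_admitted
        # full KKT sweep over all coordinates
        grad_beta = np.empty(p)
        n_viol = 0
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += Xs[i, j] * g_eta[i]
            gj = s * inv_n
            grad_beta[j] = gj
            if not ws_mask[j] and beta[j] == 0.0 and abs(gj) > pen_l1[j] + kkt_tol:
                ws_mask[j] = True
                n_viol += 1
        n_admitted += n_viol
        if n_viol == 0 or kkt_rounds >= 10:
            return nll, grad_beta, n_admitted


@njit(cache=True)
def theta_objective(z, pen, theta):
    """sum_j pen_j * w_j(theta) with w_j = sum_l exp(z_l th) / (p exp(z_j th)).

    Evaluated in log space; a positive sum of exponentials of theta, hence
    convex in theta.
    """
    p = z.shape[0]
    m = z[0] * theta
    for j in range(1, p):
        s = z[j] * theta
        if s > m:
            m = s
    acc = 0.0
    for j in range(p):
        acc += np.exp(z[j] * theta - m)
    lse = m + np.log(acc)
    logp = np.log(p)
    total = 0.0
    for j in range(p):
        if pen[j] != 0.0:
            total += pen[j] * np.exp(lse - logp - z[j] * theta)
    return total


@njit(cache=True)
def theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, theta):
    """:func:`theta_objective` exploiting that most scores are exactly zero.

    All zero-score features share one weight, so only the distinct positive
    scores (length k << p) need exponentials: O(k) instead of O(p).
    """
    k = z_nz.shape[0]
    p = n_zero + k
    m = 0.0  # exponent of the zero-score block
    for j in range(k):
        s = z_nz[j] * theta
        if s > m:
            m = s
    acc = n_zero * np.exp(-m)
    for j in range(k):
        acc += np.exp(z_nz[j] * theta - m)
    log_s = m + np.log(acc)
    logp = np.log(p)
    total = q_zero_sum * np.exp(log_s - logp)
    for j in range(k):
        if q_nz[j] != 0.0:
            total += q_nz[j] * np.exp(log_s - logp - z_nz[j] * theta)
    return total


@njit(cache=True)
def minimize_theta_sparse(z_nz, q_nz, n_zero, q_zero_sum, lo, hi, tol):
    """Golden-section minimizer of the sparse theta objective on [lo, hi]."""
    invphi = 0.6180339887498949
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, c)
    fd = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, d)
    for _ in range(200):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, d)
    x = 0.5 * (a + b)
    fx = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, x)
    flo = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, lo)
    fhi = theta_objective_sparse(z_nz, q_nz, n_zero, q_zero_sum, hi)
    if flo < fx:
        x, fx = lo, flo
    if fhi < fx:
        x, fx = hi, fhi
    return x, fx


@njit(cache=True)
def minimize_theta_golden(z, pen, lo, hi, tol):
    """Golden-section minimizer of :func:`theta_objective` on [lo, hi]."""
    invphi = 0.6180339887498949
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = theta_objective(z, pen, c)
    fd = theta_objective(z, pen, d)
    for _ in range(200):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = theta_objective(z, pen, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = theta_objective(z, pen, d)
    x = 0.5 * (a + b)
    fx = theta_objective(z, pen, x)
    # the boundary can be the minimizer of a monotone section
    flo = theta_objective(z, pen, lo)
    fhi = theta_objective(z, pen, hi)
    if flo < fx:
        x, fx = lo, flo
    if fhi < fx:
        x, fx = hi, fhi
    return x, fx
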