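"""Coordinate descent for L1-penalized logistic regression on a binary design.

The design is the rule-indicator matrix, stored column-compressed
(indptr/rowind of the 1-entries): per-coordinate work touches only the
rows supporting that rule.

The solver is the standard proximal-Newton / working-set scheme for the
logistic lasso:

* an outer loop maintains a working set of coordinates — for a single
  penalty, coordinates enter through KKT screening passes; along a
  descending penalty path (:func:`run_path`), the working set is seeded
  by the sequential strong rule ``|g_j| > 2*lam - lam_prev`` and
  corrected by the same KKT safety pass, with warm starts between
  penalties;
* inside, an IRLS loop forms the local quadratic approximation of the
  logistic loss (weights ``p(1-p)``, working residual ``y - p``) and
  cyclic coordinate descent with soft-thresholded updates solves the
  penalized weighted least-squares subproblem on the working set,
  alternating full working-set passes with passes over the currently
  non-zero coordinates.

Coordinate steps move along *weighted-centered* columns — each update
of a rule coefficient is paired with the exactly compensating intercept
change — which removes the dominant intercept/column collinearity of
high-support binary indicators.  Because the columns are binary, the
centering correction to the weighted residual is proportional to the
weights and is carried as a single scalar, so every update stays
sparse.  Only quadratic re-approximations and screening passes evaluate
the logistic function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_cd", "run_path", "build_csc"]


def build_csc(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-compressed indices of the 1-entries of a binary matrix."""
    n, q = X.shape
    indptr = np.zeros(q + 1, dtype=np.int64)
    rows = []
    for j in range(q):
        r = np.flatnonzero(X[:, j])
        rows.append(r)
        indptr[j + 1] = indptr[j] + r.size
    rowind = (np.concatenate(rows) if rows else np.zeros(0)).astype(np.int64)
    return indptr, rowind


@njit(cache=True)
def _quad_sweep(indptr, rowind, n, lam, beta, b0, s_hat, s_sum, rho,
                w, wsum, h, coords):
    """One centered coordinate pass on the quadratic subproblem.

    The true weighted working residual is ``s_i = s_hat_i + w_i * rho``;
    ``s_sum`` tracks ``sum(s_hat)``.  Each coordinate step along the
    weighted-centered column ``x_j - c_j`` (``c_j = h_j / wsum``) pairs
    the coefficient change ``d`` with the intercept change ``-d * c_j``,
    whose residual effect is uniform in ``w`` and absorbed into ``rho``.
    Returns (max |change|, b0, s_sum, rho).
    """
    maxd = 0.0
    nwsum = n * wsum
    # exact intercept step, O(1) through the running sums
    stot = s_sum + rho * nwsum
    d0 = stot / nwsum
    if d0 != 0.0:
        b0 += d0
        rho -= d0
    if abs(d0) > maxd:
        maxd = abs(d0)
    for jj in range(coords.size):
        j = coords[jj]
        cj = h[j] / wsum
        ht = h[j] * (1.0 - cj)
        if ht <= 1e-12:
            continue
        gsum = rho * n * h[j]
        for t in range(indptr[j], indptr[j + 1]):
            gsum += s_hat[rowind[t]]
        stot = s_sum + rho * nwsum
        g = (gsum - cj * stot) / n
        u = ht * beta[j] + g
        if u > lam:
            nb = (u - lam) / ht
        elif u < -lam:
            nb = (u + lam) / ht
        else:
            nb = 0.0
        d = nb - beta[j]
        if d != 0.0:
            beta[j] = nb
            for t in range(indptr[j], indptr[j + 1]):
                i = rowind[t]
                s_hat[i] -= w[i] * d
            s_sum -= d * n * h[j]
            rho += d * cj
            b0 -= d * cj
        if abs(d) > maxd:
            maxd = abs(d)
    return maxd, b0, s_sum, rho


@njit(cache=True)
def _refresh_eta(indptr, rowind, n, q, beta, intercept, eta):
    for i in range(n):
        eta[i] = intercept
    for j in range(q):
        if beta[j] != 0.0:
            b = beta[j]
            for t in range(indptr[j], indptr[j + 1]):
                eta[rowind[t]] += b


@njit(cache=True)
def _irls_restricted(indptr, rowind, n, q, y, lam, tol, budget,
                     beta, intercept, eta, coords, w, s_hat, h):
    """IRLS + coordinate descent restricted to ``coords``.

    ``eta`` must be in sync with (beta, intercept) on entry and is on
    exit.  Returns (intercept, sweeps used).
    """
    sweeps = 0
    for _outer in range(200):
        wsum = 0.0
        s_sum = 0.0
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(-eta[i]))
            pw = p * (1.0 - p)
            if pw < 1e-9:
                pw = 1e-9
            w[i] = pw
            s_hat[i] = y[i] - p
            s_sum += s_hat[i]
            wsum += pw
        wsum /= n
        rho = 0.0
        for jj in range(coords.size):
            j = coords[jj]
            acc = 0.0
            for t in range(indptr[j], indptr[j + 1]):
                acc += w[rowind[t]]
            h[j] = acc / n
        outer_maxd = 0.0
        while sweeps < budget:
            maxd, intercept, s_sum, rho = _quad_sweep(
                indptr, rowind, n, lam, beta, intercept, s_hat, s_sum, rho,
                w, wsum, h, coords)
            sweeps += 1
            if maxd > outer_maxd:
                outer_maxd = maxd
            if maxd < tol:
                break
            while sweeps < budget:
                nz = np.flatnonzero(beta)
                maxd, intercept, s_sum, rho = _quad_sweep(
                    indptr, rowind, n, lam, beta, intercept, s_hat, s_sum,
                    rho, w, wsum, h, nz)
                sweeps += 1
                if maxd > outer_maxd:
                    outer_maxd = maxd
                if maxd < tol:
                    break
        _refresh_eta(indptr, rowind, n, q, beta, intercept, eta)
        if outer_maxd < tol or sweeps >= budget:
            break
    return intercept, sweeps


@njit(cache=True)
def run_cd(indptr, rowind, n, q, y, lam, tol, max_sweeps, beta, intercept,
           kkt_eps=1e-9):
    """Solve one penalty to convergence; mutates ``beta``.

    Returns (intercept, sweeps).  Convergence: the restricted fit moves
    no coefficient by ``tol`` or more over a re-quadratization step, and
    no out-of-set coordinate violates KKT by more than ``kkt_eps``.
    """
    eta = np.empty(n)
    _refresh_eta(indptr, rowind, n, q, beta, intercept, eta)
    in_set = np.zeros(q, dtype=np.bool_)
    for j in range(q):
        if beta[j] != 0.0:
            in_set[j] = True
    w = np.empty(n)
    s_hat = np.empty(n)
    h = np.empty(q)
    resid = np.empty(n)
    sweeps = 0
    for _screen in range(200):
        coords = np.flatnonzero(in_set)
        intercept, used = _irls_restricted(indptr, rowind, n, q, y, lam, tol,
                                           max_sweeps - sweeps, beta, intercept,
                                           eta, coords, w, s_hat, h)
        sweeps += used
        # KKT screening pass over every coordinate
        for i in range(n):
            resid[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]
        added = False
        for j in range(q):
            if in_set[j]:
                continue
            g = 0.0
            for t in range(indptr[j], indptr[j + 1]):
                g += resid[rowind[t]]
            g /= n
            if abs(g) - lam > kkt_eps:
                in_set[j] = True
                added = True
        if not added or sweeps >= max_sweeps:
            break
    return intercept, sweeps


@njit(cache=True)
def run_path(indptr, rowind, n, q, y, lambdas, tol, sweeps_per_lambda,
             betas_out, intercepts_out, kkt_eps=1e-7):
    """Warm-started solutions along a descending penalty path.

    The working set per penalty is seeded by the sequential strong rule
    ``|g_j| > 2*lam - lam_prev`` (gradient at the previous solution)
    plus the currently active coordinates, then corrected by KKT safety
    passes.  Fills ``betas_out`` (len(lambdas) x q) and
    ``intercepts_out`` in place; returns total sweeps.
    """
    pbar = 0.0
    for i in range(n):
        pbar += y[i]
    pbar /= n
    intercept = np.log(pbar / (1.0 - pbar))
    beta = np.zeros(q)
    eta = np.full(n, intercept)
    w = np.empty(n)
    s_hat = np.empty(n)
    h = np.empty(q)
    resid = np.empty(n)
    g = np.empty(q)
    in_set = np.zeros(q, dtype=np.bool_)
    total = 0
    for l in range(lambdas.size):
        lam = lambdas[l]
        lam_prev = lambdas[l - 1] if l > 0 else lam
        for i in range(n):
            resid[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]
        thr = 2.0 * lam - lam_prev
        for j in range(q):
            acc = 0.0
            for t in range(indptr[j], indptr[j + 1]):
                acc += resid[rowind[t]]
            g[j] = acc / n
            in_set[j] = beta[j] != 0.0 or abs(g[j]) > thr
        budget = sweeps_per_lambda
        for _safety in range(50):
            coords = np.flatnonzero(in_set)
            intercept, used = _irls_restricted(indptr, rowind, n, q, y, lam,
                                               tol, budget, beta, intercept,
                                               eta, coords, w, s_hat, h)
            total += used
            budget -= used
            for i in range(n):
                resid[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]
            added = False
            for j in range(q):
                if in_set[j]:
                    continue
                acc = 0.0
                for t in range(indptr[j], indptr[j + 1]):
                    acc += resid[rowind[t]]
                acc /= n
                if abs(acc) - lam > kkt_eps:
                    in_set[j] = True
                    added = True
            if not added or budget <= 0:
                break
        for j in range(q):
            betas_out[l, j] = beta[j]
        intercepts_out[l] = intercept
    return total
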