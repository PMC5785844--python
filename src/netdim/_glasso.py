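"""Numba kernels for the graphical lasso.

Block coordinate descent (one lasso per row/column of the covariance, the
classic glasso scheme): the penalty applies to off-diagonal precision
entries only, and solutions are warm-started along a decreasing penalty
path.  Written as explicit loops so numba compiles the whole path into one
tight kernel — bootstrap EGA solves tens of thousands of these problems.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _glasso_single(S, lam, W, B, max_iter, tol):
    """One penalized solve.  W (working covariance) and B (per-column lasso
    coefficients) carry warm starts in and out; returns (Theta, n_sweeps,
    converged)."""
    p = S.shape[0]
    converged = False
    sweeps = 0
    c = np.zeros(p)  # running W11 @ b for the active column
    for it in range(max_iter):
        sweeps = it + 1
        max_delta = 0.0
        for j in range(p):
            # lasso on column j: min_b  0.5 b'W11 b - s12'b + lam|b|_1
            # c_k tracks sum_{l != j} W[k,l] B[l,j] and is updated in O(p)
            # only when a coefficient actually moves
            for k in range(p):
                val = 0.0
                for l in range(p):
                    if l != j:
                        val += W[k, l] * B[l, j]
                c[k] = val
            for _inner in range(max_iter):
                delta_inner = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    bold = B[k, j]
                    r = S[k, j] - c[k] + W[k, k] * bold
                    if r > lam:
                        bnew = (r - lam) / W[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W[k, k]
                    else:
                        bnew = 0.0
                    diff = bnew - bold
                    if diff != 0.0:
                        B[k, j] = bnew
                        for m in range(p):
                            c[m] += W[m, k] * diff
                        if abs(diff) > delta_inner:
                            delta_inner = abs(diff)
                if delta_inner < tol * 0.1:
                    break
            for k in range(p):
                if k == j:
                    continue
                d = abs(c[k] - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = c[k]
                W[j, k] = c[k]
        if max_delta < tol:
            converged = True
            break
    theta = np.zeros((p, p))
    for j in range(p):
        denom = W[j, j]
        for l in range(p):
            if l != j:
                denom -= W[l, j] * B[l, j]
        tjj = 1.0 / denom
        theta[j, j] = tjj
        for k in range(p):
            if k != j:
                theta[k, j] = -B[k, j] * tjj
    for i in range(p):
        for k in range(i + 1, p):
            v = 0.5 * (theta[i, k] + theta[k, i])
            theta[i, k] = v
            theta[k, i] = v
    return theta, sweeps, converged


@njit(cache=True)
def glasso_path_kernel(S, lams, max_iter, tol):
    """Precision matrices along a decreasing penalty path with warm starts.

    Returns (n_lam, p, p) array plus per-lambda sweep counts and
    convergence flags."""
    p = S.shape[0]
    n_lam = lams.shape[0]
    out = np.zeros((n_lam, p, p))
    sweep_counts = np.zeros(n_lam, dtype=np.int64)
    conv = np.zeros(n_lam, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p))
    for i in range(n_lam):
        theta, sweeps, ok = _glasso_single(S, lams[i], W, B, max_iter, tol)
        out[i] = theta
        sweep_counts[i] = sweeps
        conv[i] = ok
    return out, sweep_counts, conv
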