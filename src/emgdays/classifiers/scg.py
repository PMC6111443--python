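"""Scaled conjugate gradient (SCG) minimizer, Møller (1993).

SCG is a conjugate-gradient method that replaces the line search with a
model-trust-region step computed from a one-sided estimate of the Hessian
curvature along the search direction, regularized by a Levenberg-Marquardt
scale parameter.  One accepted iteration costs two gradient evaluations.
Used here to train the sparse-autoencoder layers and the softmax heads.
"""

from __future__ import annotations

import numpy as np


class OptimizationError(RuntimeError):
    pass


def scg_minimize(
    fun,
    w0: np.ndarray,
    max_iters: int = 400,
    grad_tol: float = 1e-6,
    sigma0: float = 5e-5,
    lambda0: float = 5e-7,
):
    """Minimize ``fun(w) -> (loss, grad)`` starting from ``w0``.

    Returns ``(w, info)`` where ``info`` has the accepted-loss history
    (non-increasing), iteration and function-evaluation counts, and the
    reason for stopping.
    """
    w = np.asarray(w0, dtype=float).copy()
    n = w.size
    f, g = fun(w)
    n_evals = 1
    if not np.isfinite(f):
        raise OptimizationError("non-finite loss at the initial point")
    r = -g
    p = r.copy()
    lamb = lambda0
    lamb_bar = 0.0
    success = True
    history = [float(f)]
    reason = "max_iters"
    delta = p2 = 1.0  # defined on first success branch

    for k in range(1, max_iters + 1):
        if success:
            p2 = float(p @ p)
            if p2 <= 1e-300:
                reason = "zero_direction"
                break
            sigma = sigma0 / np.sqrt(p2)
            _, g_sigma = fun(w + sigma * p)
            n_evals += 1
            s = (g_sigma - g) / sigma
            delta = float(p @ s)

        # Levenberg-Marquardt scaling; force positive curvature
        delta += (lamb - lamb_bar) * p2
        if delta <= 0:
            lamb_bar = 2.0 * (lamb - delta / p2)
            delta = -delta + lamb * p2
            lamb = lamb_bar

        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun(w + alpha * p)
        n_evals += 1
        if not np.isfinite(f_new):
            raise OptimizationError(
                f"non-finite loss at iteration {k} (step {alpha:.3g})"
            )
        big_delta = 2.0 * delta * (f - f_new) / (mu * mu)

        if big_delta >= 0:  # successful reduction
            w = w + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lamb_bar = 0.0
            success = True
            history.append(float(f))
            if k % n == 0:  # restart with steepest descent
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if big_delta >= 0.75:
                lamb = max(lamb * 0.25, 1e-300)
            if np.linalg.norm(r) < grad_tol:
                reason = "grad_tol"
                break
        else:
            lamb_bar = lamb
            success = False

        if big_delta < 0.25:
            lamb = lamb + delta * (1.0 - big_delta) / p2
        if lamb > 1e100:
            reason = "lambda_overflow"
            break

    info = {
        "loss_history": history,
        "n_iters": k if max_iters > 0 else 0,
        "n_evals": n_evals,
        "final_loss": float(f),
        "reason": reason,
    }
    return w, info
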