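"""Simplex-constrained weight estimation for weighted quantile sum training.

The training objective for one bootstrap sample is the profiled Gaussian
negative log-likelihood of

    y ~ beta0 + beta1 * (Q @ w) + covariates,   w on the simplex,
    sign(beta1) fixed by the index direction,

plus a ridge penalty ``lam * sum(w_i^2)`` on the weights.  Weights are
parameterized through a softmax map (last logit pinned at zero), which
enforces the simplex smoothly; the linear parameters (beta0, covariate
coefficients, and the magnitude of beta1) are profiled out in closed
form, leaving a low-dimensional smooth objective

    F(w) = (n/2) * log(RSS_A - 1{sign ok} * (w'a)^2 / (w'Bw)) + lam * w'w

where a, B and RSS_A are the exposure/outcome cross-moments after
projecting out the unpenalized design (intercept + covariates).  When
the profiled slope has the wrong sign its contribution is zero (the
sign-constrained optimum sits at beta1 -> 0); both branches meet
smoothly at w'a = 0, so F is continuously differentiable.

Optimization is a batched multi-start Adam pass over all bootstrap
samples simultaneously (basin selection) followed by a per-sample damped
Newton polish (precision).  Everything here is deterministic given the
starting points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["ProfiledProblem", "reduce_problem", "solve_batch", "softmax_weights"]


@dataclass
class ProfiledProblem:
    """Cross-moments of one (possibly resampled) training set."""

    a: np.ndarray  # (m,)  Q' M y   after projecting out [1, covariates]
    B: np.ndarray  # (m, m) Q' M Q
    rss_a: float  # residual sum of squares of the covariate-only model
    n: int  # rows in the training sample
    p: int  # unpenalized columns (intercept + covariates)


def reduce_problem(Q: np.ndarray, y: np.ndarray, A: np.ndarray) -> ProfiledProblem:
    """Project out the unpenalized design and collect cross-moments."""
    G = cho_factor(A.T @ A)
    coefA = cho_solve(G, A.T @ y)
    ym = y - A @ coefA
    Qm = Q - A @ cho_solve(G, A.T @ Q)
    return ProfiledProblem(
        a=Qm.T @ ym,
        B=Qm.T @ Qm,
        rss_a=float(ym @ ym),
        n=len(y),
        p=A.shape[1],
    )


def softmax_weights(Z: np.ndarray) -> np.ndarray:
    """Map logits (rows x (m-1)) to simplex weights (rows x m)."""
    full = np.concatenate([Z, np.zeros((Z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _objective_grad(
    Z: np.ndarray,
    a: np.ndarray,
    B: np.ndarray,
    rss_a: np.ndarray,
    n: int,
    lam: float,
    direction: int,
):
    """Batched objective and gradient in logit space.

    ``a`` is (R, m), ``B`` is (R, m, m), ``rss_a`` is (R,); each row of
    ``Z`` refers to the corresponding row's cross-moments.
    """
    W = softmax_weights(Z)
    u = np.einsum("rm,rm->r", a, W)
    Bw = np.einsum("rmk,rk->rm", B, W)
    v = np.einsum("rm,rm->r", W, Bw)
    feasible = (direction * u) > 0
    gain = np.where(feasible, u * u / v, 0.0)
    # floor protects the noiseless (interpolating) case where RSS -> 0
    rss = np.maximum(rss_a - gain, np.maximum(rss_a, 1e-12) * 1e-12)
    F = 0.5 * n * np.log(rss) + lam * np.einsum("rm,rm->r", W, W)
    # d(gain)/dw = 2u(a*v - u*Bw)/v^2 on the feasible branch, 0 otherwise
    dgain = np.where(
        feasible[:, None], 2.0 * u[:, None] * (a * v[:, None] - u[:, None] * Bw) / (v * v)[:, None], 0.0
    )
    gw = -0.5 * n * dgain / rss[:, None] + 2.0 * lam * W
    inner = np.einsum("rm,rm->r", W, gw)
    gz = (W * (gw - inner[:, None]))[:, :-1]
    return F, gz


def _row_objective_grad(z, a, B, rss_a, n, lam, direction):
    F, g = _objective_grad(z[None, :], a[None], B[None], np.array([rss_a]), n, lam, direction)
    return float(F[0]), g[0]


def _newton_polish(z, a, B, rss_a, n, lam, direction, iters: int, tol: float):
    d = len(z)
    F, g = _row_objective_grad(z, a, B, rss_a, n, lam, direction)
    if d == 0:
        return z, F, True
    eps = 1e-6
    mu = 1e-4
    converged = False
    for _ in range(iters):
        gnorm = np.abs(g).max()
        if gnorm < tol:
            converged = True
            break
        H = np.empty((d, d))
        for j in range(d):
            zj = z.copy()
            zj[j] += eps
            _, gj = _row_objective_grad(zj, a, B, rss_a, n, lam, direction)
            H[:, j] = (gj - g) / eps
        H = (H + H.T) / 2.0
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(H + mu * np.eye(d), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            z_new = z + step
            F_new, g_new = _row_objective_grad(z_new, a, B, rss_a, n, lam, direction)
            if np.isfinite(F_new) and F_new <= F + 1e-12:
                z, F, g = z_new, F_new, g_new
                mu = max(mu / 3.0, 1e-8)
                break
            mu *= 10.0
        else:
            break
    else:
        converged = np.abs(g).max() < tol
    return z, F, bool(converged or np.abs(g).max() < tol)


def solve_batch(
    problems: list[ProfiledProblem],
    lam: float,
    direction: int,
    starts: np.ndarray,
    adam_steps: int = 150,
    newton_iters: int = 8,
    grad_tol: float = 1e-8,
):
    """Fit weights for a batch of bootstrap problems.

    ``starts`` has shape (n_starts, n_problems, m-1): explicit starting
    logits for every problem (uniform, prescreen-proportional, random).
    Returns weights (n_problems x m), beta1, tstat and convergence flags.
    """
    nb = len(problems)
    m = len(problems[0].a)
    d = m - 1
    n = problems[0].n
    a_all = np.stack([p.a for p in problems])
    B_all = np.stack([p.B for p in problems])
    rssa_all = np.array([p.rss_a for p in problems])

    n_starts = starts.shape[0]
    if d == 0:
        Zbest = np.zeros((nb, 0))
        conv = np.ones(nb, bool)
    else:
        Z = starts.reshape(n_starts * nb, d).astype(float).copy()
        a_rep = np.tile(a_all, (n_starts, 1))
        B_rep = np.tile(B_all, (n_starts, 1, 1))
        rss_rep = np.tile(rssa_all, n_starts)
        # Adam with cosine-decayed learning rate: basin selection only,
        # the Newton polish supplies the precision.
        m1 = np.zeros_like(Z)
        m2 = np.zeros_like(Z)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for t in range(1, adam_steps + 1):
            lr = 0.01 + 0.5 * (0.3 - 0.01) * (1 + np.cos(np.pi * t / adam_steps))
            _, g = _objective_grad(Z, a_rep, B_rep, rss_rep, n, lam, direction)
            m1 = b1 * m1 + (1 - b1) * g
            m2 = b2 * m2 + (1 - b2) * g * g
            Z -= lr * (m1 / (1 - b1**t)) / (np.sqrt(m2 / (1 - b2**t)) + eps)
        F, _ = _objective_grad(Z, a_rep, B_rep, rss_rep, n, lam, direction)
        F = F.reshape(n_starts, nb)
        Z = Z.reshape(n_starts, nb, d)
        pick = np.nanargmin(np.where(np.isfinite(F), F, np.inf), axis=0)
        Zbest = Z[pick, np.arange(nb)]
        conv = np.zeros(nb, bool)
        tol = grad_tol * n
        for i in range(nb):
            Zbest[i], _, ok = _newton_polish(
                Zbest[i], a_all[i], B_all[i], rssa_all[i], n, lam, direction,
                newton_iters, tol,
            )
            conv[i] = ok

    W = softmax_weights(Zbest)
    u = np.einsum("rm,rm->r", a_all, W)
    v = np.einsum("rm,rmk,rk->r", W, B_all, W)
    feasible = (direction * u) > 0
    beta1 = np.where(feasible, u / v, 0.0)
    rss = rssa_all - np.where(feasible, u * u / v, 0.0)
    # an interpolating fit (residuals at numerical zero) is a converged
    # optimum even though the floored gradient never meets the tolerance
    conv |= rss <= np.maximum(rssa_all, 1e-12) * 2e-12
    dof = max(n - problems[0].p - 1, 1)
    sigma2 = np.maximum(rss, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / v)
        tstat = np.where(feasible & (se > 0), beta1 / np.where(se > 0, se, 1.0), 0.0)
    # interpolating fits have zero residual: cap instead of infinite signal
    tstat = np.where(feasible & (se == 0) & (beta1 != 0), 1e6, tstat)
    conv &= np.isfinite(W).all(axis=1)
    return W, beta1, tstat, conv
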