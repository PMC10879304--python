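"""Minimal Hamiltonian Monte Carlo for smooth, unconstrained posteriors.

A standard HMC kernel with

* leapfrog integration under a diagonal mass matrix,
* dual-averaging step-size adaptation to a target acceptance rate
  during warm-up (Nesterov/dual-averaging as used by Stan),
* diagonal mass-matrix estimation from the second half of warm-up,
* jittered trajectory lengths (uniformly random leapfrog step counts)
  to avoid resonances with the target's characteristic scales.

The caller supplies ``logp_grad(x) -> (float, ndarray)``.  All parameters
must already live on an unconstrained scale (log-transform positive
scales before calling).
"""

from __future__ import annotations

import numpy as np

__all__ = ["hmc_sample"]


def _leapfrog(logp_grad, x, p, grad, eps, inv_mass, n_steps):
    x = x.copy()
    p = p + 0.5 * eps * grad
    for _ in range(n_steps - 1):
        x = x + eps * inv_mass * p
        _, grad = logp_grad(x)
        p = p + eps * grad
    x = x + eps * inv_mass * p
    lp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    min_steps: int = 8,
    max_steps: int = 32,
):
    """Run one HMC chain; returns (draws, accept_rate, final_step_size)."""
    x = np.asarray(x0, float).copy()
    ndim = x.size
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    # dual averaging state; restarted when the mass matrix changes
    eps = 0.1
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0

    mass = np.ones(ndim)
    inv_mass = 1.0 / mass
    mass_update_at = n_warmup // 2
    warm_buf = []
    draws = np.empty((n_draws, ndim))
    n_acc = 0
    total = n_warmup + n_draws

    for it in range(total):
        p0 = rng.standard_normal(ndim) * np.sqrt(mass)
        n_steps = int(rng.integers(min_steps, max_steps + 1))
        with np.errstate(all="ignore"):
            x_new, p_new, lp_new, grad_new = _leapfrog(
                logp_grad, x, p0, grad, eps, inv_mass, n_steps
            )
            h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)
            h1 = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
        log_alpha = min(0.0, h0 - h1) if np.isfinite(h1) else -np.inf
        alpha = np.exp(log_alpha)
        if np.log(rng.random()) < log_alpha:
            x, lp, grad = x_new, lp_new, grad_new
            if it >= n_warmup:
                n_acc += 1

        if it < n_warmup:
            m_adapt += 1
            h_bar = (1 - 1 / (m_adapt + t0)) * h_bar + (target_accept - alpha) / (
                m_adapt + t0
            )
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            w = m_adapt**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if n_warmup // 4 <= it < mass_update_at:
                warm_buf.append(x.copy())
            if it == mass_update_at - 1 and len(warm_buf) > 10:
                var = np.var(np.asarray(warm_buf), axis=0)
                inv_mass = np.maximum(var, 1e-8)
                mass = 1.0 / inv_mass
                # restart dual averaging for the new metric
                mu = np.log(10 * eps)
                log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        if it >= n_warmup:
            draws[it - n_warmup] = x
    return draws, n_acc / max(n_draws, 1), eps
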