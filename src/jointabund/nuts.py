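"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained NUTS implementation (recursive tree doubling with a slice
variable, dual-averaging step-size adaptation toward a target acceptance
statistic, and Stan-style windowed adaptation of a diagonal mass matrix).
Operates on a flat unconstrained parameter vector via a callable
``logp_grad(theta) -> (float, ndarray)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChainResult", "sample_chain"]

_MAX_ENERGY_CHANGE = 1000.0  # beyond this the trajectory is divergent


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim) post-warmup positions
    logp: np.ndarray  # (n_draws,) log posterior at each draw
    step_size: float
    mean_accept: float
    divergences: int
    max_treedepth_hits: int


def _kinetic(p, inv_mass):
    # overflow to inf is handled by the divergence check
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


class _Hamiltonian:
    def __init__(self, logp_grad, inv_mass):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass

    def leapfrog(self, theta, p, grad, eps):
        p_half = p + 0.5 * eps * grad
        theta_new = theta + eps * self.inv_mass * p_half
        logp_new, grad_new = self.logp_grad(theta_new)
        p_new = p_half + 0.5 * eps * grad_new
        return theta_new, p_new, logp_new, grad_new

    def draw_momentum(self, rng, dim):
        return rng.standard_normal(dim) / np.sqrt(self.inv_mass)


def _find_reasonable_step_size(ham, theta, logp, grad, rng):
    eps = 1.0
    dim = theta.shape[0]
    p = ham.draw_momentum(rng, dim)
    h0 = logp - _kinetic(p, ham.inv_mass)
    _, p1, logp1, _ = ham.leapfrog(theta, p, grad, eps)
    h1 = logp1 - _kinetic(p1, ham.inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = ham.leapfrog(theta, p, grad, eps)
        h1 = logp1 - _kinetic(p1, ham.inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.count = 0
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.log_eps = np.log(eps0)

    def update(self, accept_stat):
        self.count += 1
        w = 1.0 / (self.count + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        eta = self.count ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar

    @property
    def step_size(self):
        return float(np.exp(self.log_eps))

    @property
    def adapted_step_size(self):
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim):
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x):
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)

    def variance(self):
        if self.count < 2:
            return None
        var = self.m2 / (self.count - 1)
        # regularize toward unit scale as Stan does
        w = self.count / (self.count + 5.0)
        return w * var + (1.0 - w) * 1e-3


class _Tree:
    """Recursive NUTS tree state for one doubling step."""

    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "logp_prop", "n_valid", "keep_going",
        "sum_accept", "n_leapfrog",
    )


def _build_tree(ham, theta, p, grad, log_u, direction, depth, eps, h0, rng):
    if depth == 0:
        theta1, p1, logp1, grad1 = ham.leapfrog(theta, p, grad, direction * eps)
        h1 = logp1 - _kinetic(p1, ham.inv_mass) if np.isfinite(logp1) else -np.inf
        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.logp_prop = logp1
        t.n_valid = 1 if log_u <= h1 else 0
        t.keep_going = log_u < h1 + _MAX_ENERGY_CHANGE
        t.sum_accept = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        t.n_leapfrog = 1
        return t

    t = _build_tree(ham, theta, p, grad, log_u, direction, depth - 1, eps, h0, rng)
    if not t.keep_going:
        return t
    if direction == -1:
        t2 = _build_tree(
            ham, t.theta_minus, t.p_minus, t.grad_minus, log_u, direction,
            depth - 1, eps, h0, rng,
        )
        t.theta_minus, t.p_minus, t.grad_minus = (
            t2.theta_minus, t2.p_minus, t2.grad_minus,
        )
    else:
        t2 = _build_tree(
            ham, t.theta_plus, t.p_plus, t.grad_plus, log_u, direction,
            depth - 1, eps, h0, rng,
        )
        t.theta_plus, t.p_plus, t.grad_plus = t2.theta_plus, t2.p_plus, t2.grad_plus
    total = t.n_valid + t2.n_valid
    if t2.n_valid > 0 and rng.uniform() < t2.n_valid / max(total, 1):
        t.theta_prop, t.logp_prop = t2.theta_prop, t2.logp_prop
    t.n_valid = total
    t.sum_accept += t2.sum_accept
    t.n_leapfrog += t2.n_leapfrog
    t.keep_going = t2.keep_going and _no_u_turn(ham, t)
    return t


def _no_u_turn(ham, t):
    dtheta = t.theta_plus - t.theta_minus
    return (
        float(np.dot(dtheta, ham.inv_mass * t.p_minus)) >= 0
        and float(np.dot(dtheta, ham.inv_mass * t.p_plus)) >= 0
    )


def _adaptation_windows(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Iteration indices at which to update the mass matrix (Stan schedule)."""
    if n_warmup < init_buffer + term_buffer + base_window:
        return []
    boundaries = []
    start = init_buffer
    window = base_window
    while start + window < n_warmup - term_buffer:
        if start + 2 * window >= n_warmup - term_buffer:
            window = n_warmup - term_buffer - start
        boundaries.append(start + window)
        start += window
        window *= 2
    return boundaries


def _transition(ham, theta, logp, grad, eps, max_treedepth, rng):
    dim = theta.shape[0]
    p0 = ham.draw_momentum(rng, dim)
    h0 = logp - _kinetic(p0, ham.inv_mass)
    log_u = h0 - rng.exponential()
    theta_minus = theta_plus = theta
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    theta_prop, logp_prop = theta, logp
    n_valid = 1
    sum_accept = 0.0
    n_leapfrog = 0
    divergent = False
    depth = 0
    keep_going = True
    while keep_going and depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == -1:
            t = _build_tree(
                ham, theta_minus, p_minus, grad_minus, log_u, -1, depth, eps, h0, rng
            )
            theta_minus, p_minus, grad_minus = t.theta_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(
                ham, theta_plus, p_plus, grad_plus, log_u, 1, depth, eps, h0, rng
            )
            theta_plus, p_plus, grad_plus = t.theta_plus, t.p_plus, t.grad_plus
        if t.keep_going and t.n_valid > 0:
            if rng.uniform() < t.n_valid / n_valid:
                theta_prop, logp_prop = t.theta_prop, t.logp_prop
        elif not t.keep_going:
            divergent = divergent or not t.keep_going
        n_valid += t.n_valid
        sum_accept += t.sum_accept
        n_leapfrog += t.n_leapfrog
        dummy = _Tree()
        dummy.theta_plus, dummy.theta_minus = theta_plus, theta_minus
        dummy.p_plus, dummy.p_minus = p_plus, p_minus
        keep_going = t.keep_going and _no_u_turn(ham, dummy)
        depth += 1
    accept_stat = sum_accept / max(n_leapfrog, 1)
    # grad at the accepted position is recomputed lazily by the caller
    return theta_prop, logp_prop, accept_stat, divergent, depth


def sample_chain(
    logp_grad,
    theta0,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_mass0=None,
) -> ChainResult:
    """Run one NUTS chain and return the post-warmup draws.

    Step size is adapted during warmup by dual averaging; the diagonal mass
    matrix starts at ``inv_mass0`` (identity by default) and is refined in
    expanding windows when ``n_warmup`` is large enough (>= 150
    iterations).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.shape[0]
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log posterior")

    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float)
    ham = _Hamiltonian(logp_grad, inv_mass)
    eps = _find_reasonable_step_size(ham, theta, logp, grad, rng)
    adapter = _DualAveraging(eps, target=target_accept)
    boundaries = set(_adaptation_windows(n_warmup))
    welford = _Welford(dim)

    divergences = 0
    depth_hits = 0
    accepts = []
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        step = adapter.step_size if warming else adapter.adapted_step_size
        theta, logp, accept_stat, divergent, depth = _transition(
            ham, theta, logp, grad, step, max_treedepth, rng
        )
        logp, grad = logp_grad(theta)
        if divergent and not warming:
            divergences += 1
        if depth >= max_treedepth and not warming:
            depth_hits += 1
        if warming:
            adapter.update(accept_stat)
            if len(boundaries) > 0 and it >= 75:
                welford.add(theta)
            if it + 1 in boundaries:
                var = welford.variance()
                if var is not None and np.all(np.isfinite(var)):
                    ham.inv_mass = np.clip(var, 1e-10, 1e10)
                    welford = _Welford(dim)
                    eps = _find_reasonable_step_size(ham, theta, logp, grad, rng)
                    adapter = _DualAveraging(eps, target=target_accept)
        else:
            accepts.append(accept_stat)
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = logp

    return ChainResult(
        draws=draws,
        logp=logps,
        step_size=adapter.adapted_step_size,
        mean_accept=float(np.mean(accepts)) if accepts else float("nan"),
        divergences=divergences,
        max_treedepth_hits=depth_hits,
    )
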