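"""No-U-Turn sampler with dual-averaging step size and diagonal mass
matrix adaptation.

A self-contained implementation of adaptive Hamiltonian Monte Carlo in
the style of modern Bayesian inference engines: multinomial sampling
across the trajectory, generalized U-turn criterion, Stan-style
three-phase warmup (fast start buffer, doubling slow windows for the
metric, fast terminal buffer for the step size).  The target is any
callable ``theta -> (log density, gradient)`` on an unconstrained
parameter space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NutsConfig", "NutsStats", "sample_nuts"]


@dataclass
class NutsConfig:
    n_warmup: int = 1000
    n_samples: int = 1000
    max_treedepth: int = 10
    target_accept: float = 0.8
    init_jitter: float = 2.0  # initial values ~ Uniform(-j, j)
    divergence_threshold: float = 1000.0
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25
    max_init_attempts: int = 20


@dataclass
class NutsStats:
    """Per-chain sampler health indicators."""

    n_divergent: int = 0
    treedepths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    accept_stat: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_size: float = float("nan")
    inv_mass: np.ndarray = field(default_factory=lambda: np.empty(0))


class _Tree:
    """One subtree of the doubling trajectory."""

    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "g_prop", "logp_prop", "log_weight", "sum_p",
        "n_divergent", "sum_accept", "n_leapfrog", "turning",
    )


def _leapfrog(target, q, p, g, eps, inv_mass):
    p_half = p + 0.5 * eps * g
    q_new = q + eps * inv_mass * p_half
    logp_new, g_new = target(q_new)
    p_new = p_half + 0.5 * eps * g_new
    return q_new, p_new, g_new, logp_new


def _kinetic(p, inv_mass):
    return 0.5 * float(p @ (inv_mass * p))


def _is_turning(q_plus, q_minus, p_plus, p_minus, inv_mass):
    dq = q_plus - q_minus
    return (dq @ (inv_mass * p_minus)) < 0 or (dq @ (inv_mass * p_plus)) < 0


def _find_initial_step(target, q, g, logp, inv_mass, rng):
    """Coarse step-size heuristic: double/halve until the one-step
    acceptance probability crosses 0.5."""
    eps = 1.0
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, _, logp1 = _leapfrog(target, q, p, g, eps, inv_mass)
    if not np.isfinite(logp1):
        delta = -np.inf
    else:
        delta = (logp1 - _kinetic(p1, inv_mass)) - h0
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, _, logp1 = _leapfrog(target, q, p, g, eps, inv_mass)
        delta = (
            (logp1 - _kinetic(p1, inv_mass)) - h0 if np.isfinite(logp1) else -np.inf
        )
        if direction == 1 and not delta > np.log(0.5):
            break
        if direction == -1 and not delta < np.log(0.5):
            break
    return max(eps, 1e-10)


def _build_tree(target, depth, q, p, g, direction, eps, inv_mass, h0, cfg, rng):
    """Recursively double one side of the trajectory.

    Subtree states are weighted by exp(H0 - H); a proposal is drawn
    multinomially among leaves (progressive sampling between subtrees).
    """
    t = _Tree()
    if depth == 0:
        q1, p1, g1, logp1 = _leapfrog(target, q, p, g, direction * eps, inv_mass)
        h1 = (logp1 - _kinetic(p1, inv_mass)) if np.isfinite(logp1) else -np.inf
        delta = h1 - h0
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.logp_prop = logp1
        t.log_weight = delta
        t.sum_p = p1.copy()
        t.n_divergent = int(delta < -cfg.divergence_threshold or not np.isfinite(delta))
        t.sum_accept = float(np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
        t.n_leapfrog = 1
        t.turning = False
        return t

    first = _build_tree(target, depth - 1, q, p, g, direction, eps, inv_mass, h0, cfg, rng)
    if first.turning or first.n_divergent:
        return first
    if direction == 1:
        second = _build_tree(
            target, depth - 1, first.q_plus, first.p_plus, first.g_plus,
            direction, eps, inv_mass, h0, cfg, rng,
        )
        first.q_plus, first.p_plus, first.g_plus = (
            second.q_plus, second.p_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            target, depth - 1, first.q_minus, first.p_minus, first.g_minus,
            direction, eps, inv_mass, h0, cfg, rng,
        )
        first.q_minus, first.p_minus, first.g_minus = (
            second.q_minus, second.p_minus, second.g_minus,
        )

    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and np.log(rng.random()) < second.log_weight - total:
        first.q_prop, first.g_prop, first.logp_prop = (
            second.q_prop, second.g_prop, second.logp_prop,
        )
    first.log_weight = total
    first.sum_p += second.sum_p
    first.n_divergent += second.n_divergent
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    first.turning = second.turning or _is_turning(
        first.q_plus, first.q_minus, first.p_plus, first.p_minus, inv_mass
    )
    return first


def _nuts_step(target, q, g, logp, eps, inv_mass, cfg, rng):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(p0, inv_mass)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = g
    q_prop, g_prop, logp_prop = q, g, logp
    log_weight = 0.0  # weight of the initial point: exp(h0 - h0)
    sum_p = p0.copy()
    sum_accept, n_leapfrog, n_divergent = 0.0, 0, 0
    depth = 0
    while depth < cfg.max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            t = _build_tree(
                target, depth, q_plus, p_plus, g_plus, 1, eps, inv_mass, h0, cfg, rng
            )
            q_plus, p_plus, g_plus = t.q_plus, t.p_plus, t.g_plus
        else:
            t = _build_tree(
                target, depth, q_minus, p_minus, g_minus, -1, eps, inv_mass, h0, cfg, rng
            )
            q_minus, p_minus, g_minus = t.q_minus, t.p_minus, t.g_minus
        sum_accept += t.sum_accept
        n_leapfrog += t.n_leapfrog
        n_divergent += t.n_divergent
        if t.turning or t.n_divergent:
            break
        # biased progressive sampling favours the new subtree
        if np.isfinite(t.log_weight) and np.log(rng.random()) < t.log_weight - log_weight:
            q_prop, g_prop, logp_prop = t.q_prop, t.g_prop, t.logp_prop
        log_weight = np.logaddexp(log_weight, t.log_weight)
        sum_p += t.sum_p
        depth += 1
        if _is_turning(q_plus, q_minus, p_plus, p_minus, inv_mass) or _is_turning(
            q_plus, q_minus, sum_p, sum_p, inv_mass
        ):
            break
    accept_stat = sum_accept / max(n_leapfrog, 1)
    return q_prop, g_prop, logp_prop, accept_stat, depth, n_divergent


def _warmup_schedule(n_warmup, cfg):
    """Stan-style expanding windows for metric adaptation."""
    if n_warmup < cfg.init_buffer + cfg.term_buffer + cfg.base_window:
        # degenerate short warmup: single window covering the middle half
        a = n_warmup // 4
        return a, [max(a + 1, n_warmup - a)], n_warmup
    slow_end = n_warmup - cfg.term_buffer
    bounds, w, pos = [], cfg.base_window, cfg.init_buffer
    while pos + w < slow_end:
        nxt = pos + w
        if nxt + 2 * w >= slow_end:
            nxt = slow_end
        bounds.append(nxt)
        pos = nxt
        w *= 2
    if not bounds or bounds[-1] != slow_end:
        bounds.append(slow_end)
    return cfg.init_buffer, bounds, n_warmup


def sample_nuts(
    target,
    dim: int,
    rng: np.random.Generator,
    config: NutsConfig | None = None,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns post-warmup draws ``(n_samples, dim)``."""
    cfg = config or NutsConfig()

    for attempt in range(cfg.max_init_attempts):
        q = (
            initial.copy()
            if initial is not None and attempt == 0
            else rng.uniform(-cfg.init_jitter, cfg.init_jitter, size=dim)
        )
        logp, g = target(q)
        if np.isfinite(logp) and np.all(np.isfinite(g)):
            break
    else:
        raise RuntimeError(
            f"no finite log density/gradient after {cfg.max_init_attempts} initializations"
        )

    inv_mass = np.ones(dim)
    eps = _find_initial_step(target, q, g, logp, inv_mass, rng)

    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    init_buf, slow_bounds, _ = _warmup_schedule(cfg.n_warmup, cfg)
    window_iter = 0
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((cfg.n_samples, dim))
    stats = NutsStats(
        treedepths=np.empty(cfg.n_samples, dtype=int),
        accept_stat=np.empty(cfg.n_samples),
    )

    total = cfg.n_warmup + cfg.n_samples
    for it in range(total):
        q, g, logp, accept, depth, ndiv = _nuts_step(
            target, q, g, logp, eps, inv_mass, cfg, rng
        )
        if it < cfg.n_warmup:
            # dual averaging update
            m = it + 1
            h_bar = (1 - 1 / (m + t0_da)) * h_bar + (cfg.target_accept - accept) / (m + t0_da)
            log_eps = mu_da - np.sqrt(m) / gamma_da * h_bar
            w = m**-kappa_da
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric accumulation inside slow windows
            if init_buf <= it < slow_bounds[-1]:
                welford_n += 1
                d = q - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (q - welford_mean)
                if it + 1 == slow_bounds[window_iter]:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        # regularize toward unit metric as Stan does
                        shrink = welford_n / (welford_n + 5.0)
                        inv_mass = shrink * var + (1 - shrink) * 1e-3 * np.ones(dim)
                        inv_mass = np.clip(inv_mass, 1e-10, None)
                    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
                    window_iter += 1
                    eps = _find_initial_step(target, q, g, logp, inv_mass, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar = np.log(eps), 0.0
            if it + 1 == cfg.n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - cfg.n_warmup
            draws[k] = q
            stats.treedepths[k] = depth
            stats.accept_stat[k] = accept
            stats.n_divergent += ndiv

    stats.step_size = eps
    stats.inv_mass = inv_mass
    if stats.n_divergent:
        logger.warning("%d divergent transitions after warmup", stats.n_divergent)
    return draws, stats
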