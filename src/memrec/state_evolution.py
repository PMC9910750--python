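"""Scalar state evolution: the exact asymptotic theory of the AMP iteration.

For uncorrelated patterns the P×P order parameter M^t = Σ_i x̂_i x*_iᵀ/N
stays proportional to the identity, M^t = m^t·I_P, so the whole dynamics of
reconstruction collapses onto one scalar overlap m^t ∈ [0, m2].  Its update
is

    m^{t+1} = E_{x0, z}[ f(m/Δ, (m/Δ)·x0 + √(m/Δ)·z) · x0 ],

with x0 a draw from the prior, z standard Gaussian, f the single-component
posterior-mean (threshold) function and Δ the channel's effective noise.
The expectation over x0 is an exact sum over the discrete support and the
z-integral is evaluated by Gauss–Hermite quadrature.  This single generic
update specialises to each prior family's closed form; the closed forms
serve as test oracles rather than as the implementation.

Fixed points of the recursion predict the asymptotic error of AMP:
normalized mse = (m2 − m_fixed)/m2.  The trivial point m = 0 loses
stability at Δ_c = m2² — below it random-initialisation AMP recovers the
patterns, above it the estimate collapses to zero.  Disagreement between
the fixed points reached from random and informed initialisations signals
a hard phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import roots_hermite

from .channel import effective_noise, p_connect, ChannelSpec
from .priors import PriorSpec, posterior_mean_var_mf, prior_moments

__all__ = [
    "SEResult",
    "PhaseDiagram",
    "se_step",
    "iterate_se",
    "critical_delta",
    "phase_diagram",
]


@lru_cache(maxsize=8)
def _gauss_hermite(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilists' normalisation: E_z g(z) = sum w_i g(sqrt(2) t_i) / sqrt(pi)
    # (scipy's rule stays stable at large node counts)
    t, w = roots_hermite(n_nodes)
    return np.sqrt(2.0) * t, w / np.sqrt(np.pi)


@dataclass
class SEResult:
    """Trajectory and fixed point of the scalar state evolution."""

    m_trajectory: np.ndarray
    m_fixed: float
    mse_predicted: float
    iterations: int
    initialisation: str
    converged: bool


def se_step(
    m: float, delta: float, prior: PriorSpec, n_nodes: int = 201
) -> float:
    """One update of the scalar overlap m under effective noise delta.

    m = 0 is always a fixed point (an uninformative estimate stays
    uninformative); near zero the map is linear with slope m2²/Δ, which is
    what defines the critical noise.
    """
    if m < 0:
        raise ValueError("the overlap m must be non-negative")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if m == 0.0:
        return 0.0
    a = m / delta
    z, wz = _gauss_hermite(n_nodes)
    s = prior.support
    p = prior.probabilities
    # fields b for every (support value, quadrature node)
    b = a * s[:, None] + np.sqrt(a) * z[None, :]
    mean, _ = posterior_mean_var_mf(prior, np.full_like(b, a), b)
    ez = mean @ wz  # E_z f per support value
    return float(np.sum(p * s * ez))


def iterate_se(
    delta: float,
    prior: PriorSpec,
    init: str = "random",
    delta_seed: float = 1e-6,
    tol: float = 1e-10,
    max_iter: int = 5000,
    n_nodes: int = 201,
) -> SEResult:
    """Fixed-point iteration of :func:`se_step` from a chosen start.

    ``random`` starts from an infinitesimal overlap m0 = δ·m2 (what a
    random prior draw achieves at finite N); ``informed`` starts from
    m0 = (1−δ)·m2, i.e. essentially the planted solution.  The two
    branches coincide except in a hard phase.
    """
    if init not in ("random", "informed"):
        raise ValueError(f"unknown init {init!r}")
    m2 = prior.second_moment
    m = delta_seed * m2 if init == "random" else (1.0 - delta_seed) * m2
    traj = [m]
    converged = False
    for _ in range(max_iter):
        m_next = se_step(m, delta, prior, n_nodes=n_nodes)
        traj.append(m_next)
        if abs(m_next - m) < tol:
            m = m_next
            converged = True
            break
        m = m_next
    mse = (m2 - m) / m2
    return SEResult(
        m_trajectory=np.array(traj),
        m_fixed=float(m),
        mse_predicted=float(mse),
        iterations=len(traj) - 1,
        initialisation=init,
        converged=converged,
    )


def critical_delta(prior: PriorSpec) -> float:
    """Critical effective noise Δ_c = m2² where the trivial point destabilises.

    Closed forms: 1 (binary), ρ² (sparse), ρ²(1−ρ)² (low coding level).
    Equivalently the squared second moment of the prior, since the SE map
    linearised at m = 0 has slope m2²/Δ.
    """
    m2 = prior_moments(prior)[1]
    return m2 * m2


@dataclass
class PhaseDiagram:
    """Recoverability of patterns over a (τ, ν) grid for a fixed prior.

    ``recoverable[i, j]`` is True where the effective noise at
    (tau_grid[i], nu_grid[j]) lies below the prior's critical noise;
    ``p_connect`` holds the connection-probability on the same grid for
    contour overlays.
    """

    tau_grid: np.ndarray
    nu_grid: np.ndarray
    delta: np.ndarray
    p_connect: np.ndarray
    recoverable: np.ndarray
    delta_critical: float


def phase_diagram(
    prior: PriorSpec, tau_grid: np.ndarray, nu_grid: np.ndarray
) -> PhaseDiagram:
    """Evaluate Δ(τ, ν) < Δ_c over a grid of channel parameters."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(tau_grid < 0) or np.any(nu_grid <= 0):
        raise ValueError("grids must have tau >= 0 and nu > 0")
    dc = critical_delta(prior)
    delta = np.empty((len(tau_grid), len(nu_grid)))
    pc = np.empty_like(delta)
    for i, tau in enumerate(tau_grid):
        for j, nu in enumerate(nu_grid):
            ch = ChannelSpec(tau, nu)
            delta[i, j] = effective_noise(ch)
            pc[i, j] = p_connect(ch)
    return PhaseDiagram(
        tau_grid=tau_grid,
        nu_grid=nu_grid,
        delta=delta,
        p_connect=pc,
        recoverable=delta < dc,
        delta_critical=dc,
    )
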