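"""The rectified-Gaussian output channel of the noisy Hebbian learning rule.

An observed synaptic weight is J = max(0, W − τ + ζ), where W is the O(1/√N)
Hebbian signal, τ ≥ 0 a rectification threshold and ζ ~ N(0, ν²) symmetric
synaptic noise.  Conditional on the signal w, the weight follows a mixed
distribution: a point mass at J = 0 (the synapse is absent) plus a truncated
Gaussian density on J > 0.

Everything the Bayesian reconstruction needs from this channel is carried by
two objects derived here:

* the Fisher score matrix S_ij = ∂_w log P_out(J_ij | w) |_{w=0}, the
  sufficient statistic driving message passing and the improved spectral
  baseline, and
* the effective noise Δ, the inverse Fisher information of the channel at
  the null signal.  Δ is the single scalar through which (τ, ν) affect
  reconstruction performance ("channel universality").

The module also provides the inversions used to parameterise experiments
directly in terms of Δ or of the connection probability p_C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.special import erfc, erfcinv

from .priors import PriorSpec

__all__ = [
    "ChannelSpec",
    "p_connect",
    "log_output_density",
    "fisher_score",
    "score_at_zero",
    "effective_noise",
    "solve_nu_for_delta",
    "critical_nu_of_pc",
]

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ChannelSpec:
    """Rectified-Gaussian channel parameters.

    Parameters
    ----------
    tau : float
        Rectification threshold, dimensionless, ≥ 0.  Controls network
        sparsity through the connection probability p_C = erfc(τ/√2ν)/2.
    nu : float
        Standard deviation of the symmetric Gaussian synaptic noise, > 0.
    """

    tau: float
    nu: float

    def __post_init__(self) -> None:
        if not self.tau >= 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not self.nu > 0.0:
            raise ValueError(f"nu must be > 0, got {self.nu}")

    def to_dict(self) -> dict:
        return {"tau": self.tau, "nu": self.nu}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        return cls(tau=float(d["tau"]), nu=float(d["nu"]))


def p_connect(ch: ChannelSpec) -> float:
    """Probability that a synapse survives rectification, erfc(τ/√2ν)/2."""
    return 0.5 * erfc(ch.tau / (_SQRT2 * ch.nu))


def log_output_density(
    J: np.ndarray | float, w: np.ndarray | float, ch: ChannelSpec
) -> np.ndarray | float:
    """Log of the mixed channel law P_out(J | w).

    Returns log P(J = 0 | w) = log[erfc((w − τ)/√2ν)/2] at J = 0 and the
    log of the Gaussian density with mean w − τ and scale ν on J > 0.  The
    atom and the density together integrate to one.
    """
    J = np.asarray(J, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(J < 0):
        raise ValueError("weights must be non-negative")
    tau, nu = ch.tau, ch.nu
    with np.errstate(divide="ignore"):
        log_atom = np.log(0.5 * erfc((w - tau) / (_SQRT2 * nu)))
    z = (J - w + tau) / nu
    log_dens = -0.5 * z * z - np.log(_SQRT_2PI * nu)
    out = np.where(J > 0, log_dens, log_atom)
    if out.ndim == 0:
        return float(out)
    return out


def score_at_zero(ch: ChannelSpec) -> float:
    """Fisher score assigned to an absent synapse (J = 0) at w = 0.

    Differentiating log P(J=0|w) at w = 0 gives
    −√(2/π)·exp(−τ²/2ν²) / (ν·erfc(−τ/√2ν)).
    """
    tau, nu = ch.tau, ch.nu
    a = tau / nu
    return -np.sqrt(2.0 / np.pi) * np.exp(-0.5 * a * a) / (nu * erfc(-a / _SQRT2))


def fisher_score(
    J: np.ndarray, ch: ChannelSpec, *, validate: bool = True
) -> np.ndarray:
    """Elementwise Fisher score matrix S of an observed connectivity J.

    S_ij = (J_ij + τ)/ν² where a synapse is present, and the (negative)
    constant :func:`score_at_zero` where it is absent.  The diagonal is
    zeroed: self-couplings are unobserved and carry no information.
    """
    J = np.asarray(J, dtype=float)
    if validate:
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"J must be square, got shape {J.shape}")
        if np.any(J < 0):
            raise ValueError("J must be non-negative")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
    S = np.where(J > 0, (J + ch.tau) / ch.nu**2, score_at_zero(ch))
    np.fill_diagonal(S, 0.0)
    return S


# ---------------------------------------------------------------------------
# Effective noise
# ---------------------------------------------------------------------------


def _inverse_delta_analytic(ch: ChannelSpec) -> float:
    # 1/Δ = E_{P_out(J|0)}[S(J)²], reduced in closed form:
    # atom:  P(J=0|0) · S(0)²  =  e^{−τ²/ν²} / (π ν² erfc(−τ/√2ν))
    # tail:  ∫₀^∞ ((J+τ)/ν²)² N(J; −τ, ν²) dJ
    #     =  τ e^{−τ²/2ν²}/(√2π ν³) + erfc(τ/√2ν)/(2ν²)
    # (This differs from one printed rendering of the closed form by a
    # factor 2 in the atom term; the defining expectation, evaluated by
    # quadrature, confirms the expression above.)
    tau, nu = ch.tau, ch.nu
    a = tau / nu
    atom = np.exp(-a * a) / (np.pi * nu * nu * erfc(-a / _SQRT2))
    tail = tau * np.exp(-0.5 * a * a) / (_SQRT_2PI * nu**3) + erfc(a / _SQRT2) / (
        2.0 * nu * nu
    )
    return atom + tail


def _inverse_delta_quadrature(ch: ChannelSpec) -> float:
    tau, nu = ch.tau, ch.nu
    atom_prob = 0.5 * erfc(-tau / (_SQRT2 * nu))
    atom = atom_prob * score_at_zero(ch) ** 2

    def integrand(J: float) -> float:
        dens = np.exp(-0.5 * ((J + tau) / nu) ** 2) / (_SQRT_2PI * nu)
        return ((J + tau) / nu**2) ** 2 * dens

    tail, err = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-13, epsrel=1e-12)
    if err > 1e-8:
        raise RuntimeError(f"effective-noise quadrature did not converge (err={err})")
    return atom + tail


def effective_noise(ch: ChannelSpec, method: str = "analytic") -> float:
    """Effective noise Δ = 1 / Fisher information of the channel at w = 0.

    The ``analytic`` path evaluates the closed-form reduction of the
    defining expectation; ``quadrature`` integrates the definition
    directly and logs a warning if the two disagree beyond 1e−6 relative
    (they agree to better than 1e−8 in tests).
    """
    if method == "analytic":
        inv = _inverse_delta_analytic(ch)
    elif method == "quadrature":
        inv = _inverse_delta_quadrature(ch)
        ref = _inverse_delta_analytic(ch)
        if abs(inv - ref) > 1e-6 * abs(ref):
            logger.warning(
                "effective_noise: quadrature (%.12g) and analytic (%.12g) "
                "reductions disagree at tau=%g nu=%g",
                1.0 / inv,
                1.0 / ref,
                ch.tau,
                ch.nu,
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(inv) or inv < 0:
        raise FloatingPointError("negative or non-finite Fisher information")
    if inv < 1e-300:
        # deep rectification (tau >> nu): no information survives
        return float(np.inf)
    return 1.0 / inv


# ---------------------------------------------------------------------------
# Inversions used to parameterise experiments
# ---------------------------------------------------------------------------


def solve_nu_for_delta(
    delta_target: float,
    tau: float,
    nu_range: tuple[float, float] = (1e-4, 1e3),
    grid_size: int = 400,
) -> list[float]:
    """All noise levels ν with effective_noise(τ, ν) = delta_target.

    At τ = 0 the map is exactly invertible, ν = √(Δ(1/2 + 1/π)), and the
    unique root is returned.  For τ > 0, Δ(ν) is non-monotone (stochastic
    resonance), so sign changes are enumerated on a geometric ν grid and
    isolated by bracketing; up to two roots can exist.
    """
    if delta_target <= 0:
        raise ValueError("delta_target must be positive")
    if tau == 0.0:
        return [float(np.sqrt(delta_target * (0.5 + 1.0 / np.pi)))]

    def g(nu: float) -> float:
        # cap the deep-rectification Delta = inf plateau for bracketing
        return min(effective_noise(ChannelSpec(tau, nu)), 1e300) - delta_target

    nus = np.geomspace(nu_range[0], nu_range[1], grid_size)
    vals = np.array([g(nu) for nu in nus])
    roots: list[float] = []
    for lo, hi, vlo, vhi in zip(nus[:-1], nus[1:], vals[:-1], vals[1:]):
        if vlo == 0.0:
            roots.append(float(lo))
        elif np.sign(vlo) != np.sign(vhi):
            roots.append(float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)))
    if vals[-1] == 0.0:
        roots.append(float(nus[-1]))
    if not roots:
        raise ValueError(
            f"unreachable Delta={delta_target} at tau={tau}: "
            f"min over the search range is {delta_target + vals.min():.6g}"
        )
    return roots


def critical_nu_of_pc(p_C: float, prior: PriorSpec) -> float:
    """Largest noise ν* at which reconstruction is still possible at fixed p_C.

    Solves the two-equation system {Δ(τ, ν) = Δ_c(prior), p_connect = p_C}.
    The connection probability is exactly invertible, τ = √2·ν·erfc⁻¹(2 p_C),
    which reduces the system to a one-dimensional root search in ν; the
    largest root is returned.
    """
    from .state_evolution import critical_delta

    if not (0.0 < p_C <= 0.5):
        raise ValueError("p_C must lie in (0, 0.5] for a non-negative threshold")
    delta_c = critical_delta(prior)
    k = _SQRT2 * erfcinv(2.0 * p_C)

    def g(nu: float) -> float:
        return effective_noise(ChannelSpec(k * nu, nu)) - delta_c

    nus = np.geomspace(1e-6, 1e3, 400)
    vals = np.array([g(nu) for nu in nus])
    roots = []
    for lo, hi, vlo, vhi in zip(nus[:-1], nus[1:], vals[:-1], vals[1:]):
        if vlo * vhi < 0:
            roots.append(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16))
    if not roots:
        raise ValueError(f"no critical nu found for p_C={p_C}")
    return float(max(roots))
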