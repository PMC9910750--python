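"""Pattern priors for memory reconstruction in rectified Hopfield networks.

Patterns are the activity configurations a recurrent network has stored in
its Hebbian connectivity.  Each neuron's "tuning curve" is a length-P vector
whose components are i.i.d. draws from one of three zero-mean families:

``binary``
    The classic Hopfield prior, x ∈ {−1, +1} with equal probability.
``sparse``
    Sparse Hopfield patterns, x ∈ {−1, 0, +1}; a fraction ``rho`` of
    components is non-zero (±1 equiprobable).
``low_coding``
    The Tsodyks–Feigel'man low-coding-level prior: a neuron is active in a
    pattern with probability ``rho``.  Activity is measured as deviation from
    the mean, so the support is {−rho, 1−rho} with weights {1−rho, rho}.

All families have zero mean; their second moments are 1, rho and
rho·(1−rho) respectively.  The module also provides the posterior-mean
("threshold") functions used by the message-passing reconstruction: the
exact tilted-prior mean over the full P-dimensional support, its factorised
mean-field counterpart, and the skewness criterion signalling a hard
inference phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "PriorSpec",
    "sample_patterns",
    "prior_moments",
    "posterior_mean_cov",
    "posterior_mean_var_mf",
    "hard_phase_criterion",
]

FAMILIES = ("binary", "sparse", "low_coding")

#: Largest P for which the exact threshold function enumerates support**P.
#: Beyond these, callers must switch to the mean-field threshold.
ENUMERATION_CAPS = {"binary": 20, "sparse": 12, "low_coding": 20}


@dataclass(frozen=True)
class PriorSpec:
    """Distribution family and coding level of the stored patterns.

    Parameters
    ----------
    family : {"binary", "sparse", "low_coding"}
        Pattern distribution family.
    rho : float, optional
        Coding level / sparsity in (0, 1).  Ignored for ``binary`` (fixed
        to 1).  For ``sparse``, ``rho = 1`` is allowed and reduces exactly
        to the binary family.
    """

    family: str
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown prior family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "binary":
            object.__setattr__(self, "rho", 1.0)
            return
        if self.rho is None:
            raise ValueError(f"family {self.family!r} requires a coding level rho")
        rho = float(self.rho)
        hi_ok = rho <= 1.0 if self.family == "sparse" else rho < 1.0
        if not (0.0 < rho and hi_ok):
            raise ValueError(
                f"rho={rho} outside the valid range for family {self.family!r}"
            )
        object.__setattr__(self, "rho", rho)

    # -- support -----------------------------------------------------------

    @property
    def support(self) -> np.ndarray:
        """Values a single pattern component can take."""
        if self.family == "binary":
            return np.array([-1.0, 1.0])
        if self.family == "sparse":
            return np.array([-1.0, 0.0, 1.0])
        return np.array([-self.rho, 1.0 - self.rho])

    @property
    def probabilities(self) -> np.ndarray:
        """Probability of each support value, same order as :attr:`support`."""
        if self.family == "binary":
            return np.array([0.5, 0.5])
        if self.family == "sparse":
            r = self.rho
            return np.array([r / 2.0, 1.0 - r, r / 2.0])
        r = self.rho
        return np.array([1.0 - r, r])

    @property
    def sign_symmetric(self) -> bool:
        """Whether the prior is invariant under x → −x (binary, sparse)."""
        return self.family in ("binary", "sparse")

    @property
    def second_moment(self) -> float:
        return prior_moments(self)[1]

    @property
    def enumeration_cap(self) -> int:
        return ENUMERATION_CAPS[self.family]

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "rho": self.rho}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(family=d["family"], rho=d.get("rho"))


def sample_patterns(
    spec: PriorSpec,
    P: int,
    N: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a P×N pattern matrix with i.i.d. entries from the prior.

    Rows are patterns; column ``i`` is the tuning curve of neuron ``i``.
    """
    if P < 1 or N < 1:
        raise ValueError("P and N must be positive")
    rng = np.random.default_rng(seed)
    support = spec.support
    idx = rng.choice(len(support), size=(P, N), p=spec.probabilities)
    return support[idx]


def prior_moments(spec: PriorSpec) -> tuple[float, float, float]:
    """Exact first three per-component moments (m1, m2, m3).

    m1 is zero for every family.  m2 is 1 (binary), rho (sparse) or
    rho(1−rho) (low_coding); m3 is non-zero only for the skewed
    low-coding family, where it equals rho(1−rho)(1−2rho).
    """
    if spec.family == "binary":
        return (0.0, 1.0, 0.0)
    r = spec.rho
    if spec.family == "sparse":
        return (0.0, r, 0.0)
    return (0.0, r * (1.0 - r), r * (1.0 - r) * (1.0 - 2.0 * r))


# ---------------------------------------------------------------------------
# Threshold (posterior-mean) functions
# ---------------------------------------------------------------------------


def _configurations(spec: PriorSpec, P: int) -> tuple[np.ndarray, np.ndarray]:
    """All support**P configurations (K×P) with their log prior weights (K,)."""
    s = spec.support
    logp = np.log(np.clip(spec.probabilities, 1e-300, None))
    grids = np.meshgrid(*([np.arange(len(s))] * P), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=-1)  # (K, P)
    configs = s[idx]
    logprior = logp[idx].sum(axis=-1)
    return configs, logprior


def posterior_mean_cov(
    spec: PriorSpec, A: np.ndarray | float, b: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the prior tilted by a Gaussian data term.

    Computes the mean of ``p(x) ∝ p_X(x) exp(b·x − x'Ax/2)`` over the
    discrete support, i.e. the exact Bayesian threshold function f(A, b),
    together with its covariance (which equals the Jacobian ∂f/∂b).
    Normalisation is done in log-space so large fields do not overflow.

    Raises
    ------
    ValueError
        If P exceeds the family's enumeration cap (use
        :func:`posterior_mean_var_mf` instead).
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    A = np.asarray(A, dtype=float)
    P = b.shape[-1]
    if A.shape == ():
        A = A.reshape(1, 1)
    if A.shape != (P, P):
        raise ValueError(f"A has shape {A.shape}, expected ({P}, {P})")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("A must be symmetric")
    mean, cov = _posterior_mean_cov_batch(spec, A[None], b[None])
    return mean[0], cov[0]


def _posterior_mean_cov_batch(
    spec: PriorSpec, A: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised exact threshold function for a batch of (A_i, b_i).

    A: (n, P, P); b: (n, P).  Returns means (n, P) and covariances (n, P, P).
    """
    n, P = b.shape
    if P > spec.enumeration_cap:
        raise ValueError(
            f"P={P} exceeds the exact-enumeration cap "
            f"({spec.enumeration_cap} for family {spec.family!r}); "
            "use the mean-field threshold posterior_mean_var_mf instead"
        )
    configs, logprior = _configurations(spec, P)  # (K, P), (K,)
    # log weight of each configuration under each tilt
    quad = 0.5 * np.einsum("npq,kp,kq->nk", A, configs, configs)
    logw = logprior[None, :] + b @ configs.T - quad  # (n, K)
    logw -= logsumexp(logw, axis=1, keepdims=True)
    w = np.exp(logw)
    mean = w @ configs  # (n, P)
    exx = np.einsum("nk,kp,kq->npq", w, configs, configs)
    cov = exx - np.einsum("np,nq->npq", mean, mean)
    return mean, cov


def posterior_mean_var_mf(
    spec: PriorSpec, a: np.ndarray | float, b: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Factorised (mean-field) posterior mean and variance, componentwise.

    Each component is tilted independently: ``p(x_j) ∝ p_x(x_j)
    exp(b_j x_j − a_j x_j²/2)``.  ``a`` and ``b`` broadcast against each
    other; outputs have the broadcast shape.  Exact for P = 1, and for the
    binary family the quadratic tilt cancels (x² ≡ 1) so the mean reduces
    to tanh(b).  Evaluated in log-space to guard against overflow at
    strong fields.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = spec.support  # (K,)
    logp = np.log(np.clip(spec.probabilities, 1e-300, None))
    # (..., K) log weights
    logw = logp + np.multiply.outer(b, s) - 0.5 * np.multiply.outer(a, s * s)
    logw -= logsumexp(logw, axis=-1, keepdims=True)
    w = np.exp(logw)
    mean = w @ s
    ex2 = w @ (s * s)
    var = ex2 - mean * mean
    return mean, np.maximum(var, 0.0)


# ---------------------------------------------------------------------------
# Hard-phase criterion
# ---------------------------------------------------------------------------


def hard_phase_criterion(spec: PriorSpec) -> tuple[bool, float | None]:
    """Skewness criterion for a first-order transition / hard phase.

    A zero-mean prior whose skewness satisfies ⟨x³⟩² > 2⟨x²⟩³ gives rise
    to a first-order transition in the scalar state evolution and hence a
    hard inference phase.  Sign-symmetric priors (binary, sparse) have
    ⟨x³⟩ = 0 and can never satisfy it — the criterion is sufficient, not
    necessary.

    For the low-coding family the boundary coding level on (0, 1/2) is also
    returned: substituting the exact moments reduces the equality
    ⟨x³⟩² = 2⟨x²⟩³ to 6ρ² − 6ρ + 1 = 0, i.e. ρ_c = 1/2 − 1/√12 ≈ 0.2113,
    with the criterion holding (hard phase) for ρ < ρ_c.

    Returns
    -------
    skewed : bool
        Whether the criterion holds for this prior.
    rho_critical : float or None
        The critical coding level (low_coding only), else None.
    """
    _, m2, m3 = prior_moments(spec)
    skewed = m3 * m3 > 2.0 * m2**3
    if spec.family != "low_coding":
        return skewed, None

    def gap(r: float) -> float:
        _, q2, q3 = prior_moments(PriorSpec("low_coding", r))
        return q3 * q3 - 2.0 * q2**3

    rho_critical = brentq(gap, 1e-9, 0.5 - 1e-9, xtol=1e-14, rtol=8.9e-16)
    return skewed, float(rho_critical)
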