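"""Synthetic instance generator for the rectified Hopfield model.

Produces complete test instances (ground-truth patterns X*, Hebbian signal
W, observed connectivity J) of the generative model: patterns drawn i.i.d.
from a zero-mean prior, Hebbian weights W = X*ᵀX*/√N, and observed weights
J = max(0, W − τ + ζ) with symmetric Gaussian noise ζ.

The 1/√N scaling of the Hebbian term places the model at the spiked-Wigner
signal-to-noise scale where reconstruction is neither trivial nor
impossible: the signal W_ij and the noise ζ_ij then contribute at the same
order to the Fisher score field, which is what makes the message-passing
analysis self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import ChannelSpec
from .priors import PriorSpec, sample_patterns

__all__ = ["Instance", "generate_instance"]


@dataclass
class Instance:
    """One synthetic realisation of the generative model.

    Attributes
    ----------
    patterns : ndarray, shape (P, N)
        Ground-truth stored patterns X*.
    hebbian : ndarray, shape (N, N)
        Noise-free Hebbian signal W = X*ᵀX*/√N (diagonal zeroed).
    connectivity : ndarray, shape (N, N)
        Observed weights J = max(0, W − τ + ζ), symmetric, non-negative,
        diagonal stored as 0 (self-couplings are unobserved).
    """

    patterns: np.ndarray
    hebbian: np.ndarray
    connectivity: np.ndarray
    prior: PriorSpec
    channel: ChannelSpec
    seed: int | None

    @property
    def n_neurons(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]


def generate_instance(
    prior: PriorSpec,
    ch: ChannelSpec,
    N: int,
    P: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> Instance:
    """Sample a full (X*, W, J) instance; bit-reproducible for a fixed seed.

    The noise ζ is drawn on the strict upper triangle only and mirrored,
    so J is exactly symmetric.  An entry of J is zero iff the pre-activation
    W − τ + ζ is ≤ 0.
    """
    if N < 2 or P < 1:
        raise ValueError("need N >= 2 and P >= 1")
    rng = np.random.default_rng(seed)
    X = sample_patterns(prior, P, N, rng)
    W = (X.T @ X) / np.sqrt(N)
    np.fill_diagonal(W, 0.0)

    Z = rng.standard_normal((N, N))
    Z *= ch.nu
    Z = np.triu(Z, 1)
    Z += Z.T

    J = W - ch.tau + Z
    np.maximum(J, 0.0, out=J)
    np.fill_diagonal(J, 0.0)
    stored_seed = seed if isinstance(seed, int) else None
    return Instance(
        patterns=X,
        hebbian=W,
        connectivity=J,
        prior=prior,
        channel=ch,
        seed=stored_seed,
    )
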