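"""Reparameterized latent bottleneck.

Two dense maps take the flattened backbone features h to the per-sample
latent mean mu = f_m(h) and log-variance f_s(h) (so sigma = exp(f_s(h)/2) is
positive by construction).  Training-mode sampling uses the reparameterization
trick Z = eps * sigma + mu with eps ~ N(0, 1), which keeps the sampling step
differentiable; inference mode returns Z = mu so evaluation is deterministic
(sampled inference is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class LatentParams:
    """Per-sample latent Gaussian parameters (mean, log-variance).

    Arrays may be 1-D ``(J,)`` for a single sample or 2-D ``(N, J)`` for a
    batch.
    """

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have identical shapes")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_var / 2.0)

    @property
    def J(self) -> int:
        return self.mu.shape[-1]


class ReparamHead:
    """The f_m / f_s pair mapping h (dim ``in_dim``) to a J-dim latent."""

    def __init__(self, in_dim: int, latent_dim: int, rng: np.random.Generator | None = None):
        if latent_dim < 1:
            raise ValueError("latent_dim must be >= 1 (J = 0 bypasses the bottleneck)")
        rng = rng or np.random.default_rng()
        self.in_dim = in_dim
        self.latent_dim = latent_dim
        self.fm = nn.Linear(in_dim, latent_dim, rng=rng, init="xavier")
        # f_s starts at zero so the initial latent SD is exactly 1 (log-var 0)
        self.fs = nn.Linear(in_dim, latent_dim, rng=rng, init="zeros")

    def params(self):
        return self.fm.params() + self.fs.params()

    def encode(self, h: np.ndarray, training: bool = False) -> LatentParams:
        h = np.atleast_2d(np.asarray(h, dtype=nn.DTYPE))
        if h.shape[1] != self.in_dim:
            raise ValueError(f"h has dim {h.shape[1]}, head expects {self.in_dim}")
        mu = self.fm.forward(h, training=training)
        log_var = self.fs.forward(h, training=training)
        if mu.shape[0] == 1 and h.ndim == 2:
            pass  # keep batch form; squeeze is the caller's business
        return LatentParams(mu=mu, log_var=log_var)

    def backward(self, dmu: np.ndarray, dlog_var: np.ndarray) -> np.ndarray:
        """Accumulate f_m/f_s gradients; returns dL/dh."""
        return (self.fm.backward(np.atleast_2d(dmu).astype(nn.DTYPE))
                + self.fs.backward(np.atleast_2d(dlog_var).astype(nn.DTYPE)))


def encode(h: np.ndarray, head: ReparamHead) -> LatentParams:
    """Functional wrapper around :meth:`ReparamHead.encode` (inference mode)."""
    params = head.encode(h, training=False)
    if np.asarray(h).ndim == 1:
        return LatentParams(params.mu[0], params.log_var[0])
    return params


def sample(params: LatentParams, eps: np.ndarray | None = None,
           training: bool = True, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw Z = eps * sigma + mu.

    In training mode ``eps`` is standard normal (from ``rng`` or supplied
    explicitly); in inference mode Z = mu exactly (eps = 0), making repeated
    evaluation deterministic.
    """
    if not training:
        return params.mu.copy()
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.standard_normal(params.mu.shape)
    eps = np.asarray(eps, dtype=float)
    if eps.shape != params.mu.shape:
        raise ValueError(f"eps shape {eps.shape} != latent shape {params.mu.shape}")
    return eps * params.sigma + params.mu
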