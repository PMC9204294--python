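"""Combined training objective: cross-entropy plus a weighted KL penalty.

The total loss is ``l = l_ce + alpha * l_kl`` where l_ce is the mean
cross-entropy of the softmax class probabilities and l_kl pulls each latent
Gaussian N(mu_j, sigma_j^2) toward the standard normal prior via the closed
form

    l_kl = 1/2 * sum_j (mu_j^2 + sigma_j^2 - 1 - log sigma_j^2),

which is KL(q || N(0,1)) for a diagonal Gaussian q.  Per batch, l_kl is the
mean of the per-sample sums, so the meaning of alpha does not depend on the
batch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reparam import LatentParams

#: Probability floor inside the log; keeps perfect-confidence mistakes finite
#: without perturbing any value at realistic probabilities.
LOG_FLOOR = 1e-12


@dataclass
class LossConfig:
    """alpha >= 0 trades classification fit against the latent prior."""

    alpha: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class LossValue:
    total: float
    ce: float
    kl: float


def cross_entropy(probs: np.ndarray, labels: np.ndarray, floor: float = LOG_FLOOR) -> float:
    """Mean negative log-probability of the true class.

    ``probs`` is an (N, M) row-stochastic matrix, ``labels`` the length-N
    integer class indices.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int).ravel()
    if probs.shape[0] != labels.size:
        raise ValueError("probs and labels disagree on N")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= probs.shape[1]:
        raise ValueError("labels out of class range")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("rows of probs must sum to 1")
    p_true = probs[np.arange(labels.size), labels]
    return float(-np.mean(np.log(np.maximum(p_true, floor))))


def kl_divergence(params: LatentParams):
    """KL(q || N(0,1)) per Eq. above; scalar for a single sample, a length-N
    array for a batch of latent parameters."""
    mu, log_var = params.mu, params.log_var
    sigma2 = np.exp(log_var)
    per_dim = 0.5 * (mu ** 2 + sigma2 - 1.0 - log_var)
    # provably >= 0; clamp float round-off near the prior
    if mu.ndim == 1:
        return max(float(per_dim.sum()), 0.0)
    return np.maximum(per_dim.sum(axis=-1), 0.0)


def batch_kl(params: LatentParams) -> float:
    """Batch reduction: mean over samples of the per-sample KL sum."""
    kl = kl_divergence(params)
    return float(np.mean(kl))


def total_loss(ce: float, kl: float, cfg: LossConfig) -> LossValue:
    return LossValue(total=float(ce + cfg.alpha * kl), ce=float(ce), kl=float(kl))
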