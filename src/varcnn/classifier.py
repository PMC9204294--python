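"""Fusion MLP: sampled latent features concatenated with morphological metrics.

The classifier input is the fixed-order concatenation ``[Z || morph]`` — the
J latent features first, then the M_f morphological metrics (z-scored with
training-split statistics upstream).  With J = 0 the model degenerates to an
MLP on the metrics alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn


@dataclass
class ClassifierSpec:
    latent_dim: int = 100
    morph_dim: int = 3
    hidden_sizes: tuple[int, ...] = (64, 32)
    n_classes: int = 2

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.latent_dim < 0 or self.morph_dim < 0 or self.latent_dim + self.morph_dim < 1:
            raise ValueError("need at least one input feature (J + M_f >= 1)")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")

    @property
    def in_dim(self) -> int:
        return self.latent_dim + self.morph_dim


class MLPClassifier:
    """Multi-layer perceptron with ReLU hidden layers and softmax output."""

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        layers: list[nn.Layer] = []
        d = spec.in_dim
        for h in spec.hidden_sizes:
            layers += [nn.Linear(d, h, rng=rng, init="xavier"), nn.ReLU()]
            d = h
        layers.append(nn.Linear(d, spec.n_classes, rng=rng, init="xavier"))
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    # -- forward/backward on pre-concatenated batches (training path) -------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=nn.DTYPE))
        if x.shape[1] != self.spec.in_dim:
            raise ValueError(f"classifier expects {self.spec.in_dim} inputs, got {x.shape[1]}")
        return self.net.forward(x, training=training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(np.atleast_2d(dlogits).astype(nn.DTYPE))

    # -- public prediction surface ------------------------------------------
    def predict_proba(self, z: np.ndarray, morph: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for latent + morph inputs (batched)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        morph = np.atleast_2d(np.asarray(morph, dtype=float))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"z has dim {z.shape[1]}, spec says J={self.spec.latent_dim}")
        if morph.shape[1] != self.spec.morph_dim:
            raise ValueError(f"morph has dim {morph.shape[1]}, spec says M_f={self.spec.morph_dim}")
        x = np.concatenate([z, morph], axis=1)
        return nn.softmax(self.forward_logits(x, training=False))


def classify(z: np.ndarray, morph: np.ndarray, model: MLPClassifier) -> np.ndarray:
    """Probability vector (length 2) for a single sample."""
    return model.predict_proba(z, morph)[0]


def first_layer_weight_profile(model: MLPClassifier) -> np.ndarray:
    """Aggregate first-layer weight magnitude per *latent* input feature.

    For each of the J latent inputs, returns the maximum absolute weight over
    its outgoing connections into the first hidden layer.  After training with
    a strong KL constraint, profiles of redundant latent features collapse
    toward zero while informative ones keep substantial weight.
    """
    layers = getattr(getattr(model, "net", None), "layers", None)
    if not layers or not isinstance(layers[0], nn.Linear):
        raise ValueError("model has no first dense layer to profile")
    w = layers[0].w.value  # (in_dim, hidden)
    if w is None or w.size == 0:
        raise ValueError("model weights are uninitialized")
    j = model.spec.latent_dim
    return np.abs(w[:j, :]).max(axis=1) if j > 0 else np.zeros(0)
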