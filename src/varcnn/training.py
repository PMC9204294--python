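"""End-to-end training protocol.

Seeded stratified 80/20 splits, inverse-frequency oversampling of the
minority class, Adam with a two-epoch linear warm-up and a divide-by-5 step
decay every 40 epochs, and repeated cross-validation over a list of seeds.
All randomness (weight init, oversampling draws, reparameterization noise)
derives from the single configured seed, so a run is bitwise reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import nn
from .backbone import ArchitectureSpec, BlockSpec, Backbone
from .classifier import ClassifierSpec, MLPClassifier
from .evaluation import EvalReport, confusion
from .loss import LossConfig, batch_kl, cross_entropy, total_loss
from .reparam import LatentParams, ReparamHead
from .volume_io import SampleRecord


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr_base: float = 0.0005
    batch_size: int = 32
    epochs: int = 120
    warmup_epochs: int = 2
    decay_every: int = 40
    decay_factor: float = 5.0
    train_fraction: float = 0.8
    alpha: float = 10.0
    weight_decay: float = 0.05
    seed: int = 0
    use_best_epoch: bool = False
    threshold: float = 0.5

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("batch_size", "epochs", "warmup_epochs", "decay_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochRecord:
    epoch: int
    ce: float
    kl: float
    total: float
    lr: float
    val_acc: float
    val_se: float | None
    val_sp: float | None
    val_auc: float | None
    val_kl: float


@dataclass
class RunHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    reports: list[EvalReport] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.epochs])

    def final_report(self) -> EvalReport:
        return self.reports[-1]

    def best_report(self) -> EvalReport:
        i = int(np.argmax([e.val_auc if e.val_auc is not None else -1.0 for e in self.epochs]))
        return self.reports[i]


def split_cohort(samples: list[SampleRecord], fraction: float = 0.8,
                 seed: int = 0) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Stratified-by-label shuffle split; train size floor(fraction*n) per class."""
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    labels = np.array([s.label for s in samples])
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in (0, 1):
        ids = np.flatnonzero(labels == cls)
        if ids.size == 0:
            raise ValueError(f"class {cls} absent from cohort; cannot stratify")
        perm = rng.permutation(ids)
        n_tr = math.floor(fraction * ids.size)
        train_idx.extend(perm[:n_tr])
        val_idx.extend(perm[n_tr:])
    return [samples[i] for i in train_idx], [samples[i] for i in val_idx]


def oversample_weights(labels) -> np.ndarray:
    """Per-sample draw probabilities inversely proportional to class frequency,
    normalised to sum 1 — the expected drawn class ratio is 1:1."""
    labels = np.asarray(labels, dtype=int).ravel()
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("oversampling needs both classes present")
    w = 1.0 / counts[labels]
    return w / w.sum()


def learning_rate(step: int, steps_per_epoch: int, cfg: TrainConfig) -> float:
    """Per-step schedule: linear 0 -> lr_base over the warm-up epochs, then a
    plateau at lr_base divided by decay_factor every decay_every epochs."""
    if step < 0:
        raise ValueError("step must be >= 0")
    epoch = step // steps_per_epoch
    if epoch < cfg.warmup_epochs:
        return cfg.lr_base * step / (cfg.warmup_epochs * steps_per_epoch)
    return cfg.lr_base / cfg.decay_factor ** (epoch // cfg.decay_every)


class FusionModel:
    """Backbone -> flatten -> reparameterized bottleneck -> [Z || morph] -> MLP.

    With ``latent_dim == 0`` the imaging branch is bypassed entirely and the
    model is an MLP on the (z-scored) morphological metrics alone.
    """

    def __init__(self, arch: ArchitectureSpec | None, cls_spec: ClassifierSpec,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cls_spec = cls_spec
        self.arch = arch
        if cls_spec.latent_dim > 0:
            if arch is None:
                raise ValueError("latent_dim > 0 requires an ArchitectureSpec")
            self.backbone = Backbone(arch, rng=rng)
            self.head = ReparamHead(arch.flat_dim(), cls_spec.latent_dim, rng=rng)
        else:
            self.backbone = None
            self.head = None
        self.mlp = MLPClassifier(cls_spec, rng=rng)
        self.morph_mean = np.zeros(cls_spec.morph_dim)
        self.morph_sd = np.ones(cls_spec.morph_dim)

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        if self.backbone is not None:
            ps += self.backbone.params() + self.head.params()
        return ps + self.mlp.params()

    def fit_morph_scaler(self, morph: np.ndarray) -> None:
        """Z-scoring statistics from the training split."""
        morph = np.atleast_2d(morph)
        if morph.shape[1] != self.cls_spec.morph_dim:
            raise ValueError("morph dimension mismatch")
        if morph.shape[1]:
            self.morph_mean = morph.mean(axis=0)
            sd = morph.std(axis=0)
            self.morph_sd = np.where(sd > 0, sd, 1.0)

    def scale_morph(self, morph: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(morph) - self.morph_mean) / self.morph_sd

    # ----- inference -------------------------------------------------------
    def encode_batch(self, x: np.ndarray, training: bool = False) -> LatentParams:
        fmap = self.backbone.forward_batch(x, training=training)
        h = fmap.reshape(fmap.shape[0], -1)
        return self.head.encode(h, training=training)

    def encode_records(self, samples: list[SampleRecord], chunk: int = 16) -> LatentParams:
        """Inference-mode latent parameters for a list of records."""
        if self.cls_spec.latent_dim == 0:
            n = len(samples)
            return LatentParams(np.zeros((n, 0)), np.zeros((n, 0)))
        mus, lvs = [], []
        for i in range(0, len(samples), chunk):
            x = np.stack([s.patch.data for s in samples[i:i + chunk]])[:, None].astype(nn.DTYPE)
            p = self.encode_batch(x, training=False)
            mus.append(p.mu)
            lvs.append(p.log_var)
        return LatentParams(np.concatenate(mus), np.concatenate(lvs))

    def predict_records(self, samples: list[SampleRecord], chunk: int = 16) -> np.ndarray:
        """Inference-mode class probabilities, (n, 2); Z = mu (no sampling)."""
        morph = self.scale_morph(np.array([s.morph for s in samples]))
        params = self.encode_records(samples, chunk=chunk)
        return self.mlp.predict_proba(params.mu, morph)

    def score_records(self, samples: list[SampleRecord]) -> np.ndarray:
        """AD probability per record."""
        return self.predict_records(samples)[:, 1]

    # ----- persistence -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param{i:03d}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn{i:02d}_mean"] = bn.running_mean
            state[f"bn{i:02d}_var"] = bn.running_var
        state["morph_mean"] = self.morph_mean
        state["morph_sd"] = self.morph_sd
        return state

    def _batchnorms(self):
        bns = []
        if self.backbone is not None:
            bns += [l for l in self.backbone.net.layers if isinstance(l, nn.BatchNorm3d)]
        return bns

    def save(self, path) -> None:
        meta = {
            "arch": None if self.arch is None else {
                "input_shape": list(self.arch.input_shape),
                "blocks": [asdict(b) for b in self.arch.blocks],
            },
            "cls_spec": {"latent_dim": self.cls_spec.latent_dim,
                         "morph_dim": self.cls_spec.morph_dim,
                         "hidden_sizes": list(self.cls_spec.hidden_sizes),
                         "n_classes": self.cls_spec.n_classes},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        arch = None
        if meta["arch"] is not None:
            arch = ArchitectureSpec(tuple(BlockSpec(**b) for b in meta["arch"]["blocks"]),
                                    input_shape=tuple(meta["arch"]["input_shape"]))
        spec = ClassifierSpec(**{**meta["cls_spec"],
                                 "hidden_sizes": tuple(meta["cls_spec"]["hidden_sizes"])})
        model = cls(arch, spec, rng=np.random.default_rng(0))
        for i, p in enumerate(model.params()):
            p.value[...] = arrays[f"param{i:03d}"]
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean = arrays[f"bn{i:02d}_mean"]
            bn.running_var = arrays[f"bn{i:02d}_var"]
        model.morph_mean = arrays["morph_mean"]
        model.morph_sd = arrays["morph_sd"]
        return model


def _stack(samples: list[SampleRecord]):
    x = np.stack([s.patch.data for s in samples])[:, None].astype(nn.DTYPE)
    morph = np.array([s.morph for s in samples], dtype=float).reshape(len(samples), -1)
    y = np.array([s.label for s in samples], dtype=int)
    return x, morph, y


def train(samples: list[SampleRecord], arch: ArchitectureSpec | None,
          cls_spec: ClassifierSpec, cfg: TrainConfig) -> tuple[FusionModel, RunHistory]:
    """Run the full protocol: split, oversample, warm-up/decay Adam loop."""
    ss = np.random.SeedSequence(cfg.seed)
    s_init, s_data, s_eps = ss.spawn(3)
    rng_init = np.random.default_rng(s_init)
    rng_data = np.random.default_rng(s_data)
    rng_eps = np.random.default_rng(s_eps)

    tr, va = split_cohort(samples, cfg.train_fraction, cfg.seed)
    x_tr, m_tr, y_tr = _stack(tr)
    y_va = np.array([s.label for s in va], dtype=int)
    j = cls_spec.latent_dim
    use_image = j > 0

    model = FusionModel(arch if use_image else None, cls_spec, rng=rng_init)
    model.fit_morph_scaler(m_tr)
    m_tr_s = model.scale_morph(m_tr)
    m_va_s = model.scale_morph(np.array([s.morph for s in va], dtype=float).reshape(len(va), -1))

    weights = oversample_weights(y_tr)
    opt = nn.Adam(model.params(), weight_decay=cfg.weight_decay)
    n_tr = len(tr)
    steps_per_epoch = math.ceil(n_tr / cfg.batch_size)
    loss_cfg = LossConfig(alpha=cfg.alpha)
    history = RunHistory()
    step = 0
    for epoch in range(cfg.epochs):
        draw = rng_data.choice(n_tr, size=n_tr, replace=True, p=weights)
        ce_sum = kl_sum = 0.0
        for b0 in range(0, n_tr, cfg.batch_size):
            idx = draw[b0:b0 + cfg.batch_size]
            nb = idx.size
            lr = learning_rate(step, steps_per_epoch, cfg)
            opt.zero_grad()
            morph_b = m_tr_s[idx]
            if use_image:
                params = model.encode_batch(x_tr[idx], training=True)
                sigma = params.sigma
                eps = rng_eps.standard_normal(params.mu.shape)
                z = eps * sigma + params.mu
                feats = np.concatenate([z, morph_b], axis=1)
            else:
                params, eps, sigma = None, None, None
                feats = morph_b
            logits = model.mlp.forward_logits(feats, training=True)
            probs = nn.softmax(logits)
            ce = cross_entropy(probs, y_tr[idx])
            kl = batch_kl(params) if use_image else 0.0
            lv = total_loss(ce, kl, loss_cfg)
            if not np.isfinite(lv.total):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"ce={lv.ce}, kl={lv.kl}")
            # backward: softmax + CE, then KL terms into mu / log-var
            onehot = np.zeros_like(probs)
            onehot[np.arange(nb), y_tr[idx]] = 1.0
            dlogits = (probs - onehot) / nb
            dfeats = model.mlp.backward(dlogits)
            if use_image:
                dz = dfeats[:, :j]
                dmu = dz + cfg.alpha * params.mu / nb
                dlog_var = dz * eps * sigma * 0.5 + cfg.alpha * (sigma ** 2 - 1.0) / (2.0 * nb)
                dh = model.head.backward(dmu, dlog_var)
                c, spatial = arch.output_shape()
                model.backbone.backward_batch(dh.reshape(nb, c, *spatial))
            opt.step(lr)
            ce_sum += ce * nb
            kl_sum += kl * nb
            step += 1
        # epoch-end validation in inference mode (one encoder pass)
        val_params = model.encode_records(va, chunk=32)
        val_scores = model.mlp.predict_proba(val_params.mu, m_va_s)[:, 1]
        report = confusion(val_scores, y_va, threshold=cfg.threshold)
        val_kl = batch_kl(val_params) if use_image else 0.0
        ce_m, kl_m = ce_sum / n_tr, kl_sum / n_tr
        history.reports.append(report)
        history.epochs.append(EpochRecord(
            epoch=epoch, ce=ce_m, kl=kl_m, total=ce_m + cfg.alpha * kl_m,
            lr=learning_rate(step - 1, steps_per_epoch, cfg),
            val_acc=report.acc, val_se=report.se, val_sp=report.sp,
            val_auc=report.auc, val_kl=val_kl))
    return model, history


def cross_validate(samples: list[SampleRecord], arch: ArchitectureSpec | None,
                   cls_spec: ClassifierSpec, cfg: TrainConfig,
                   seeds: list[int] | None = None):
    """One independent train/validation run per seed.

    Returns ``(reports, summary)``: the per-seed final (or best-epoch)
    validation :class:`EvalReport` list and a ``{metric: (mean, sd)}``
    summary in the mean +/- SD reporting style.
    """
    seeds = list(range(5)) if seeds is None else list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    reports = []
    for seed in seeds:
        _, history = train(samples, arch, cls_spec, replace(cfg, seed=seed))
        reports.append(history.best_report() if cfg.use_best_epoch
                       else history.final_report())
    summary = {}
    for metric in ("acc", "se", "sp", "auc"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        summary[metric] = (float(np.mean(vals)), float(np.std(vals)))
    return reports, summary
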