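"""Classification performance metrics and latent-space diagnostics.

Positive class is AD (label 1).  ACC, SE (sensitivity), SP (specificity) come
from the thresholded confusion counts; AUC is the Mann-Whitney rank statistic
(ties counted 1/2), which is exact under ties and equals the area under the
ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    se: float | None
    sp: float | None
    auc: float | None
    precision: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _check_pair(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.size != labels.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and nonempty")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0 = NC, 1 = AD)")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Threshold scores (predict AD iff score >= threshold) and count.

    With one-sided labels the undefined rate (SE without positives, SP
    without negatives) is reported as None rather than 0.  AUC is filled in
    when both classes are present.
    """
    scores, labels = _check_pair(scores, labels)
    pred = scores >= threshold  # ties predicted positive, fixed for reproducibility
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    fp = int(np.sum(pred & neg))
    tn = int(np.sum(~pred & neg))
    n = tp + tn + fp + fn
    se = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    prec = tp / (tp + fp) if (tp + fp) else None
    auc_val = auc(scores, labels) if (pos.any() and neg.any()) else None
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=(tp + tn) / n,
                      se=se, sp=sp, auc=auc_val, precision=prec)


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_AD > score_NC) + 0.5 * P(tie)."""
    scores, labels = _check_pair(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def latent_histogram(model, samples):
    """Pooled inference-mode latent values for distribution inspection.

    ``model`` is a trained fusion model (see :mod:`varcnn.training`);
    ``samples`` a list of :class:`~varcnn.volume_io.SampleRecord`.  Returns
    ``(values, summary)`` where values is the (n_samples, J) matrix of latent
    means and summary a DataFrame with per-dimension mean and SD — the raw
    material of a latent-distribution histogram.
    """
    params = model.encode_records(samples)
    values = np.atleast_2d(params.mu)
    summary = pd.DataFrame({
        "dimension": np.arange(values.shape[1]),
        "mean": values.mean(axis=0),
        "sd": values.std(axis=0),
    })
    return values, summary
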