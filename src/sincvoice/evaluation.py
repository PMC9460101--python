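"""Utterance-level scoring: confusion matrices, accuracy/sensitivity/UAR,
and embedding extraction for t-SNE scatter plots.

An utterance's posterior is the arithmetic mean of its chunk posteriors;
the prediction is the argmax with lowest-class-index tie-break.  Metrics
follow the standard definitions: accuracy = 100 x trace / total,
per-class sensitivity = 100 x diagonal / row sum, and UAR (unweighted
average recall) = the plain mean of per-class sensitivities, which makes
it robust to class imbalance.  Specificity = 100 x TN / (TN + FP) is
reported for binary detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import VoiceNet
from .pipeline import chunk_waveform
from .vowelsynth import LabeledWaveform

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "aggregate_utterance",
    "confusion",
    "metrics",
    "predict_utterance",
    "score_utterances",
    "collect_embeddings",
    "tsne_scatter",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted class
    class_order: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (each row sums to 100 for nonzero rows)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / np.where(sums > 0, sums, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity_per_class: dict
    uar: float
    specificity: float | None = None

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "uar": self.uar,
             "sensitivity_per_class": dict(self.sensitivity_per_class)}
        if self.specificity is not None:
            d["specificity"] = self.specificity
        return d


def aggregate_utterance(chunk_posteriors) -> tuple[int, np.ndarray]:
    """Mean chunk posterior and its argmax (lowest index wins ties)."""
    post = np.asarray(chunk_posteriors, dtype=float)
    if post.ndim != 2 or post.shape[0] == 0:
        raise ValueError("need at least one chunk posterior")
    mean = post.mean(axis=0)
    return int(np.argmax(mean)), mean


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lbl: i for i, lbl in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label {t!r}/{p!r} not in class order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_order))


def metrics(cm: ConfusionMatrix, positive_label: str | None = None) -> MetricsReport:
    """Accuracy, per-class sensitivity, UAR (and specificity for detection).

    Classes with an empty row (no test samples) have undefined sensitivity;
    they are excluded from the UAR with a warning rather than counted as 0.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * np.trace(counts) / total
    sens: dict = {}
    for i, lbl in enumerate(cm.class_order):
        row = counts[i].sum()
        if row == 0:
            warnings.warn(f"class {lbl!r} has no test samples; "
                          "sensitivity undefined, excluded from UAR")
            continue
        sens[lbl] = 100.0 * counts[i, i] / row
    uar = float(np.mean(list(sens.values())))
    specificity = None
    if positive_label is not None:
        if len(cm.class_order) != 2:
            raise ValueError("specificity is defined for binary detection only")
        neg = 1 - cm.class_order.index(positive_label)
        tn = counts[neg, neg]
        fp = counts[neg, 1 - neg]
        specificity = 100.0 * tn / (tn + fp) if tn + fp else None
    return MetricsReport(float(accuracy), sens, uar, specificity)


def predict_utterance(model: VoiceNet, w: LabeledWaveform,
                      chunk_s: float = 0.2, shift_s: float = 0.1,
                      ) -> tuple[int, np.ndarray]:
    chunks = chunk_waveform(w, chunk_s, shift_s)
    return aggregate_utterance(model.predict_batch(chunks))


def score_utterances(model: VoiceNet, utterances, class_order,
                     chunk_s: float = 0.2, shift_s: float = 0.1,
                     positive_label: str | None = None,
                     ) -> tuple[ConfusionMatrix, MetricsReport]:
    """End-to-end utterance-level evaluation of a trained model."""
    true, pred = [], []
    for w in utterances:
        idx, _ = predict_utterance(model, w, chunk_s, shift_s)
        true.append(w.label)
        pred.append(class_order[idx])
    cm = confusion(true, pred, class_order)
    return cm, metrics(cm, positive_label=positive_label)


def collect_embeddings(model: VoiceNet, utterances,
                       chunk_s: float = 0.2, shift_s: float = 0.1) -> pd.DataFrame:
    """One row per utterance: id, label, then the mean chunk embedding."""
    rows = []
    for w in utterances:
        chunks = chunk_waveform(w, chunk_s, shift_s)
        emb = model.embed_batch(chunks).mean(axis=0)
        rows.append((w.utterance_id, w.label, emb))
    dim = len(rows[0][2]) if rows else model.embed_dim
    data = {"utterance_id": [r[0] for r in rows], "label": [r[1] for r in rows]}
    mat = np.vstack([r[2] for r in rows]) if rows else np.empty((0, dim))
    for j in range(dim):
        data[f"e{j}"] = mat[:, j]
    return pd.DataFrame(data)


def tsne_scatter(embeddings: pd.DataFrame, perplexity: float = 30.0,
                 seed: int = 0, out_png=None) -> np.ndarray:
    """2-D t-SNE of utterance embeddings, optionally plotted by label.

    Perplexity is clamped to n/4 for small sets so the algorithm stays
    well-posed; coordinates are deterministic for a given seed.
    """
    from sklearn.manifold import TSNE

    feat_cols = [c for c in embeddings.columns if c.startswith("e")]
    x = embeddings[feat_cols].to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for t-SNE")
    eff = float(min(perplexity, max(1.0, n / 4.0), n - 2))
    coords = TSNE(n_components=2, perplexity=eff, random_state=seed,
                  init="pca").fit_transform(x)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lbl in dict.fromkeys(embeddings["label"]):
            m = embeddings["label"] == lbl
            ax.scatter(coords[m, 0], coords[m, 1], s=12, label=lbl)
        ax.legend()
        ax.set_title("t-SNE of utterance embeddings")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return coords
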