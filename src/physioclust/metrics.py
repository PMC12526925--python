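"""Clustering evaluation and descriptive signal features.

The clustering side reports normalized mutual information (NMI) between
partitions, the silhouette coefficient of the embedded layout, and —
after Hungarian alignment of cluster ids to ground-truth classes —
standard classification metrics (accuracy, macro precision/recall/F1,
confusion matrix).  The descriptive side summarizes each channel by its
mean, standard deviation and dominant periodogram frequency (DC bin
excluded), with group-level aggregation by activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.metrics import normalized_mutual_info_score

from .cohort import ChannelKind, Trial
from .clustering import hungarian_map


def nmi(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    Mutual information normalized by the arithmetic mean of the two
    entropies by default (``average_method="geometric"`` switches to the
    geometric mean).  1 for identical partitions up to relabeling, 0
    when either partition is a single cluster.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label lists must have equal length")
    if len(a) == 0:
        raise ValueError("label lists must be non-empty")
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


@dataclass(frozen=True)
class MetricsReport:
    nmi: float
    sc: float | None
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # rows = true classes, cols = mapped predicted
    classes: tuple
    task: str | None = None
    modality: str | None = None

    def to_dict(self) -> dict:
        return {
            "nmi": self.nmi,
            "sc": self.sc,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "task": self.task,
            "modality": self.modality,
        }


def classification_report(
    true_labels,
    pred_labels,
    sc: float | None = None,
    task: str | None = None,
    modality: str | None = None,
) -> MetricsReport:
    """Hungarian-aligned classification metrics for a clustering.

    Cluster ids are mapped one-to-one onto ground-truth classes so as to
    maximize total overlap; the confusion matrix and the accuracy /
    macro-averaged precision, recall and F1 are computed on the mapped
    labels.  Predicted clusters left unmatched by a rectangular
    assignment count as errors for every class.
    """
    true = np.asarray(true_labels)
    pred = np.asarray(pred_labels)
    if len(true) == 0 or len(true) != len(pred):
        raise ValueError("label lists must be non-empty and of equal length")
    mapping = hungarian_map(pred, true)
    classes = np.unique(true)
    t_index = {t: i for i, t in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), int)
    unmatched = 0
    mapped = np.empty(len(pred), object)
    for i, (p, t) in enumerate(zip(pred, true)):
        m = mapping.mapping.get(p.item() if isinstance(p, np.generic) else p)
        mapped[i] = m
        if m is None:
            unmatched += 1
            continue
        confusion[t_index[t], t_index[m]] += 1
    accuracy = float(np.trace(confusion)) / len(true)
    # per-class metrics on the mapped labels; a predicted cluster left
    # unmatched by a rectangular assignment counts against every class
    prec_c, rec_c, f1_c = [], [], []
    for c in classes:
        tp = confusion[t_index[c], t_index[c]]
        pred_c = int(np.sum(mapped == c))
        true_c = int(np.sum(true == c))
        p = tp / pred_c if pred_c else 0.0
        r = tp / true_c if true_c else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        prec_c.append(p)
        rec_c.append(r)
        f1_c.append(f)
    macro_p, macro_r, macro_f = (float(np.mean(v)) for v in (prec_c, rec_c, f1_c))
    return MetricsReport(
        nmi=nmi(true, pred),
        sc=sc,
        accuracy=accuracy,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        confusion=confusion,
        classes=tuple(classes),
        task=task,
        modality=modality,
    )


def dominant_frequency(samples: np.ndarray, rate: float) -> float:
    """Argmax of the periodogram excluding the DC bin; 0 for a channel
    with no spectral content above DC (e.g. a constant)."""
    x = np.asarray(samples, float)
    if np.ptp(x) == 0:
        return 0.0
    freqs, power = sps.periodogram(x, fs=rate)
    if len(freqs) < 2 or np.all(power[1:] == 0):
        return 0.0
    return float(freqs[1 + int(np.argmax(power[1:]))])


def feature_summary(trials: list[Trial]) -> pd.DataFrame:
    """Per-(trial, channel) mean, std and dominant frequency.

    Long-format frame with columns trial_id, subject_id, activity,
    channel, mean, std, dom_freq_hz.
    """
    rows = []
    for tr in trials:
        for kind in ChannelKind:
            ch = tr.channels[kind]
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "subject_id": tr.subject_id,
                    "activity": tr.activity.value,
                    "channel": kind.value,
                    "mean": float(np.mean(ch.samples)),
                    "std": float(np.std(ch.samples)),
                    "dom_freq_hz": dominant_frequency(ch.samples, ch.rate),
                }
            )
    return pd.DataFrame(rows)


def group_feature_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Group-level aggregation: feature means per (activity, channel)."""
    return (
        features.groupby(["activity", "channel"])[["mean", "std", "dom_freq_hz"]]
        .mean()
        .reset_index()
    )
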