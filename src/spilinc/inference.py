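"""Neuron tagging and spike-count inference for single liquids and ensembles.

After unsupervised training, each excitatory neuron is tagged with the class
(or the top two classes, for temporal tasks) of training inputs that drove it
to spike the most; neurons that never spiked stay untagged. A test pattern is
classified by the tag group with the highest average spike count; for an
ensemble, the per-liquid group averages are themselves averaged (every liquid
contributes, a liquid with no neurons carrying a tag contributes zero) before
the argmax. Argmax ties resolve to the lowest class index, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TagAssignment", "PredictionResult", "tag_neurons",
           "average_spike_count", "predict_single", "predict_ensemble",
           "confusion_and_rates", "accuracy"]


@dataclass
class TagAssignment:
    """Class-tag membership of the excitatory neurons of one liquid."""

    member: np.ndarray   # (n_neurons, n_classes) bool; row sums are n_tags
                         # for tagged neurons, 0 for silent (untagged) ones
    n_tags: int

    @property
    def n_classes(self) -> int:
        return self.member.shape[1]

    @property
    def group_sizes(self) -> np.ndarray:
        """n_j: number of neurons carrying each tag."""
        return self.member.sum(axis=0)

    def tags(self, neuron: int) -> set:
        return set(np.flatnonzero(self.member[neuron]).tolist())


@dataclass
class PredictionResult:
    """Per-class average spike counts (per liquid and ensemble-resultant)
    plus the predicted class."""

    avg_spike_count: np.ndarray       # (n_liquids, n_classes)
    res_avg_spike_count: np.ndarray   # (n_classes,)
    predicted_class: int


def tag_neurons(class_counts: np.ndarray, n_tags: int = 1) -> TagAssignment:
    """Tag each neuron with its ``n_tags`` most-active classes over training.

    ``class_counts`` is the (n_neurons, n_classes) cumulative training spike
    count matrix. Neurons with zero total training spikes are untagged and
    excluded from the tag groups. Count ties resolve to the lower class index.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("spike counts must be non-negative")
    n_neurons, n_classes = counts.shape
    if n_classes < n_tags:
        raise ValueError("need at least n_tags classes")
    # stable sort on descending count keeps the lower class index first on ties
    order = np.argsort(-counts, axis=1, kind="stable")
    member = np.zeros_like(counts, dtype=bool)
    rows = np.arange(n_neurons)[:, None]
    member[rows, order[:, :n_tags]] = True
    member[counts.sum(axis=1) == 0] = False
    return TagAssignment(member=member, n_tags=n_tags)


def average_spike_count(spike_counts: np.ndarray,
                        tags: TagAssignment) -> np.ndarray:
    """Mean test spike count of each tag group:
    avg(j) = (1/n_j) * sum over neurons tagged j of their spike count; a class
    with an empty group scores 0. A neuron carrying several tags contributes
    its full count to each of its groups."""
    counts = np.asarray(spike_counts, dtype=float)
    if counts.shape[0] != tags.member.shape[0]:
        raise ValueError("spike record does not cover all tagged neurons")
    sums = counts @ tags.member
    n_j = tags.group_sizes
    return np.divide(sums, n_j, out=np.zeros(tags.n_classes, dtype=float),
                     where=n_j > 0)


def _argmax_with_tie_warning(values: np.ndarray) -> int:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no classes to predict from")
    best = int(np.argmax(values))
    if np.count_nonzero(values == values[best]) > 1:
        logger.warning("argmax tie between classes %s; choosing lowest index",
                       np.flatnonzero(values == values[best]).tolist())
    return best


def predict_single(avg: np.ndarray) -> int:
    """Predicted class of a single liquid: argmax of the per-class average
    spike counts (ties -> lowest class index)."""
    return _argmax_with_tie_warning(avg)


def predict_ensemble(per_liquid_avgs) -> PredictionResult:
    """Combine per-liquid class averages into the ensemble-resultant average
    (plain mean over liquids) and take its argmax. With one liquid this
    reduces exactly to :func:`predict_single`."""
    avgs = [np.asarray(a, dtype=float) for a in per_liquid_avgs]
    if not avgs:
        raise ValueError("no liquids to combine")
    if len({a.shape for a in avgs}) != 1:
        raise ValueError("liquids report inconsistent class sets")
    stacked = np.vstack(avgs)
    res = stacked.mean(axis=0)
    return PredictionResult(avg_spike_count=stacked, res_avg_spike_count=res,
                            predicted_class=_argmax_with_tie_warning(res))


def confusion_and_rates(predictions, n_classes: int):
    """Confusion matrix (rows = predicted class, columns = actual class) and
    the per-class misprediction percentages.

    FN%(j): false negatives for actual class j — column sum minus the
    diagonal, as a percentage of the test samples of class j.
    FP%(j): false positives for predicted class j — row sum minus the
    diagonal, as a percentage of the test samples not of class j.
    """
    matrix = np.zeros((n_classes, n_classes), dtype=int)
    for actual, predicted in predictions:
        if not (0 <= actual < n_classes and 0 <= predicted < n_classes):
            raise ValueError("label out of range")
        matrix[predicted, actual] += 1
    total = matrix.sum()
    per_class = matrix.sum(axis=0)          # actual-class sample counts
    diag = np.diag(matrix)
    fn = np.divide(per_class - diag, per_class,
                   out=np.zeros(n_classes, dtype=float),
                   where=per_class > 0) * 100.0
    others = total - per_class
    fp = np.divide(matrix.sum(axis=1) - diag, others,
                   out=np.zeros(n_classes, dtype=float),
                   where=others > 0) * 100.0
    return matrix, fn, fp


def accuracy(predictions) -> float:
    """Percentage of correct (actual, predicted) pairs."""
    pairs = list(predictions)
    if not pairs:
        raise ValueError("empty prediction list")
    return 100.0 * sum(a == p for a, p in pairs) / len(pairs)


def results_frame(records) -> pd.DataFrame:
    """Tabulate per-sample results: actual, predicted and the per-class
    resultant averages (one column per class)."""
    rows = []
    for actual, pred in records:
        row = {"actual": actual, "predicted": pred.predicted_class}
        row.update({f"avg_class_{j}": v
                    for j, v in enumerate(pred.res_avg_spike_count)})
        rows.append(row)
    return pd.DataFrame(rows)
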