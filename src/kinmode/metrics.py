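"""Evaluation mathematics: MCC, balanced accuracy, entropy, Tanimoto distance.

Binary MCC and balanced accuracy follow the textbook confusion-count
formulas. For the three-class task, the global MCC is Gorodkin's R_K
statistic on the k x k contingency table and the global balanced accuracy is
the macro-average of per-class recall — the standard multi-class
generalizations that reduce to the binary formulas at k = 2. Per-class
values are computed one-vs-rest.

Conventions (documented, deliberate): an MCC whose denominator contains a
zero factor is 0 (no measurable association); the Tanimoto distance between
two all-zero fingerprints is 0 (identical objects); 0 * log 0 = 0 in the
entropy.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .modes import MODE_ORDER, BindingMode

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Binary (one-vs-rest) confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Global and per-class performance on one test set."""

    mcc: float
    ba: float
    per_class: Mapping[BindingMode, tuple[float, float]]  # mode -> (mcc, ba)
    n_test: int


def binary_mcc(cs: ConfusionSummary) -> float:
    """Matthews correlation coefficient from binary confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    factor of the denominator is zero the coefficient is reported as 0.
    """
    tp, tn, fp, fn = cs.tp, cs.tn, cs.fp, cs.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def balanced_accuracy(cs: ConfusionSummary) -> float:
    """Binary balanced accuracy: BA = (sensitivity + specificity) / 2."""
    if cs.n == 0:
        raise ValueError("empty test set")
    sens = cs.tp / (cs.tp + cs.fn) if (cs.tp + cs.fn) else 0.0
    spec = cs.tn / (cs.tn + cs.fp) if (cs.tn + cs.fp) else 0.0
    return 0.5 * (sens + spec)


def _contingency(y_true: Sequence, y_pred: Sequence) -> tuple[np.ndarray, list]:
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = sorted(set(y_true) | set(y_pred), key=lambda c: str(c))
    index = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        table[index[t], index[p]] += 1
    return table, classes


def multiclass_mcc(y_true: Sequence, y_pred: Sequence) -> float:
    """Gorodkin's R_K statistic on the k x k contingency table.

    Reduces to the binary MCC at k = 2. Degenerate cases (constant truth or
    constant prediction) are reported as 0.
    """
    table, _ = _contingency(y_true, y_pred)
    n = table.sum()
    t = table.sum(axis=1)  # true counts per class
    p = table.sum(axis=0)  # predicted counts per class
    correct = np.trace(table)
    cov_tp = correct * n - int(t @ p)
    cov_tt = n * n - int(t @ t)
    cov_pp = n * n - int(p @ p)
    if cov_tt == 0 or cov_pp == 0:
        return 0.0
    return cov_tp / math.sqrt(cov_tt * cov_pp)


def macro_balanced_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Multi-class balanced accuracy: macro-average of per-class recall."""
    table, _ = _contingency(y_true, y_pred)
    t = table.sum(axis=1)
    observed = t > 0
    if not observed.any():
        raise ValueError("empty test set")
    recalls = np.diag(table)[observed] / t[observed]
    return float(recalls.mean())


def _one_vs_rest(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionSummary:
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionSummary(tp, tn, fp, fn)


def per_class_evaluation(
    y_true: Sequence[BindingMode], y_pred: Sequence[BindingMode]
) -> dict[BindingMode, tuple[float, float]]:
    """One-vs-rest (MCC, BA) for every binding mode observed in y_true.

    A class absent from y_true gets ``(nan, nan)`` and a log message: its
    one-vs-rest confusion counts carry no positives, so the coefficient is
    undefined rather than zero.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    out: dict[BindingMode, tuple[float, float]] = {}
    for mode in MODE_ORDER:
        if mode not in y_true and mode not in y_pred:
            continue
        if mode not in y_true:
            logger.info("class %s absent from y_true; per-class MCC undefined", mode)
            out[mode] = (float("nan"), float("nan"))
            continue
        cs = _one_vs_rest(y_true, y_pred, mode)
        out[mode] = (binary_mcc(cs), balanced_accuracy(cs))
    return out


def evaluate(y_true: Sequence[BindingMode], y_pred: Sequence[BindingMode]) -> EvaluationResult:
    """Global multi-class MCC/BA plus per-class one-vs-rest values."""
    return EvaluationResult(
        mcc=multiclass_mcc(y_true, y_pred),
        ba=macro_balanced_accuracy(y_true, y_pred),
        per_class=per_class_evaluation(y_true, y_pred),
        n_test=len(y_true),
    )


def shannon_entropy(probs: Sequence[float]) -> float:
    """Shannon entropy H = -sum p_i log2 p_i, in bits (0 * log 0 = 0).

    ``probs`` must be a valid probability vector (non-negative, summing to 1
    within 1e-9).
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_per_row(prob_matrix: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy of a matrix of probability vectors."""
    p = np.asarray(prob_matrix, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def tanimoto_distance(a, b) -> float:
    """Tanimoto (Jaccard) distance 1 - |a&b| / |a|b| between binary vectors.

    Accepts Fingerprint objects or raw 0/1 vectors. Two all-zero vectors
    have distance 0.
    """
    va = np.asarray(getattr(a, "bits", a), dtype=bool)
    vb = np.asarray(getattr(b, "bits", b), dtype=bool)
    if va.shape != vb.shape:
        raise ValueError("fingerprint length mismatch")
    union = int((va | vb).sum())
    if union == 0:
        return 0.0
    inter = int((va & vb).sum())
    return 1.0 - inter / union


def distance_matrix(ds) -> np.ndarray:
    """Pairwise Tanimoto distance matrix of a FingerprintDataset.

    Returns an n x n symmetric matrix with zero diagonal and entries in
    [0, 1]; pairs of all-zero rows get distance 0.
    """
    x = np.asarray(ds.matrix if hasattr(ds, "matrix") else ds, dtype=np.float64)
    if x.shape[0] == 0:
        raise ValueError("empty dataset")
    inter = x @ x.T
    pop = x.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite floating point
    return (d + d.T) / 2.0
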