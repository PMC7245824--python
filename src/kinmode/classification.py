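"""Random-forest benchmarking: splits, trials, permutation test, importances.

The classifier is a 100-tree random forest with inverse-frequency
("balanced") class weights to compensate for the strong class imbalance of
the cohort (roughly 71/20/9 percent); all other hyperparameters are library
defaults. Probabilities are ensemble-averaged per-tree class probabilities;
argmax ties resolve to the earlier class in the canonical order
(I, I1/2, II).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .fingerprints import FingerprintDataset
from .metrics import EvaluationResult, evaluate, multiclass_mcc
from .modes import MODE_ORDER, BindingMode

logger = logging.getLogger(__name__)

N_TREES = 100


@dataclasses.dataclass(frozen=True)
class DataSplit:
    """A stratified compound-pool / test-set split.

    ``pool_indices`` are stored in a seeded-shuffled order; active-learning
    tie-breaks use ascending position in this order, which makes them
    deterministic without favoring any generation-order structure.
    """

    pool_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.pool_indices.tolist()) & set(self.test_indices.tolist()):
            raise ValueError("pool and test indices overlap")


@dataclasses.dataclass
class ClassifierModel:
    """Trained random-forest ensemble with a fixed class-probability order."""

    forest: RandomForestClassifier
    classes: tuple[BindingMode, ...]  # classes present in training, canonical order
    n_trees: int
    seed: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities over the full canonical mode order.

        Classes absent from the training set get probability 0, so entropy
        and argmax are always computed over the same three columns.
        """
        raw = self.forest.predict_proba(np.asarray(x))
        out = np.zeros((raw.shape[0], len(MODE_ORDER)))
        full_index = {m: i for i, m in enumerate(MODE_ORDER)}
        for j, code in enumerate(self.forest.classes_):
            out[:, full_index[MODE_ORDER[int(code)]]] = raw[:, j]
        return out

    def predict(self, x: np.ndarray) -> list[BindingMode]:
        """Argmax prediction; ties resolve to the earlier canonical class."""
        probs = self.predict_proba(x)
        return [MODE_ORDER[int(i)] for i in probs.argmax(axis=1)]


@dataclasses.dataclass
class PermutationTestResult:
    observed_mcc: float
    null_mccs: np.ndarray
    p_value: float


@dataclasses.dataclass
class ImportanceTrace:
    """Gini feature importances tracked over active-learning iterations."""

    matrix: np.ndarray  # (n_features, n_iterations)
    feature_names: list[str]
    training_sizes: list[int]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.feature_names), len(self.training_sizes)):
            raise ValueError("importance matrix not aligned with names/iterations")


def stratified_split(
    labels: Sequence[BindingMode],
    test_fraction: float = 0.1,
    seed: int = 0,
) -> DataSplit:
    """Stratified pool/test split carried out per binding-mode class.

    Each class contributes ``round(class_count * test_fraction)`` compounds
    to the test set, so the class distribution of pool and test match to
    within one compound per class.
    """
    labels = list(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test: list[int] = []
    pool: list[int] = []
    for mode in MODE_ORDER:
        members = np.flatnonzero(np.array([lab == mode for lab in labels]))
        if len(members) == 0:
            continue
        if len(members) < 2:
            raise ValueError(f"class {mode} has fewer than 2 members; cannot stratify")
        n_test = round(len(members) * test_fraction)
        if n_test == 0 or n_test == len(members):
            raise ValueError(
                f"test_fraction {test_fraction} gives a degenerate split for {mode}"
            )
        perm = rng.permutation(members)
        test.extend(perm[:n_test].tolist())
        pool.extend(perm[n_test:].tolist())
    pool_arr = np.array(pool, dtype=np.int64)
    rng.shuffle(pool_arr)  # seeded pool order for deterministic AL tie-breaks
    return DataSplit(
        pool_indices=pool_arr,
        test_indices=np.array(sorted(test), dtype=np.int64),
        test_fraction=test_fraction,
        seed=seed,
    )


def train_rf(x: np.ndarray, labels: Sequence[BindingMode], seed: int = 0) -> ClassifierModel:
    """Train the 100-tree balanced-class-weight random forest."""
    x = np.asarray(x)
    labels = list(labels)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    codes = np.array([MODE_ORDER.index(lab) for lab in labels], dtype=np.int64)
    forest = RandomForestClassifier(
        n_estimators=N_TREES,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, codes)
    present = tuple(MODE_ORDER[int(c)] for c in forest.classes_)
    return ClassifierModel(forest=forest, classes=present, n_trees=N_TREES, seed=seed)


def evaluate_split(
    ds: FingerprintDataset, split: DataSplit, seed: int = 0
) -> EvaluationResult:
    """Train on the pool, evaluate on the test set of one split."""
    model = train_rf(ds.matrix[split.pool_indices],
                     [ds.labels[i] for i in split.pool_indices], seed=seed)
    y_pred = model.predict(ds.matrix[split.test_indices])
    y_true = [ds.labels[i] for i in split.test_indices]
    return evaluate(y_true, y_pred)


def benchmark_trials(
    ds: FingerprintDataset,
    n_trials: int = 20,
    test_fraction: float = 0.1,
    base_seed: int = 0,
) -> list[EvaluationResult]:
    """The standard benchmark: independent stratified trials.

    Trial ``i`` uses split seed ``base_seed + i`` (and the same seed for
    the forest), trains one model on the pool and evaluates global and
    per-class metrics on the held-out test set.
    """
    results = []
    for i in range(n_trials):
        split = stratified_split(ds.labels, test_fraction=test_fraction, seed=base_seed + i)
        results.append(evaluate_split(ds, split, seed=base_seed + i))
    return results


def summarize_trials(results: Sequence[EvaluationResult]) -> dict[str, float]:
    """Median and quartiles of the trial MCC/BA distributions (boxplot stats)."""
    mccs = np.array([r.mcc for r in results])
    bas = np.array([r.ba for r in results])
    return {
        "mcc_median": float(np.median(mccs)),
        "mcc_q1": float(np.percentile(mccs, 25)),
        "mcc_q3": float(np.percentile(mccs, 75)),
        "ba_median": float(np.median(bas)),
        "ba_q1": float(np.percentile(bas, 25)),
        "ba_q3": float(np.percentile(bas, 75)),
    }


def per_class_medians(results: Sequence[EvaluationResult]) -> dict[BindingMode, float]:
    """Median one-vs-rest MCC per binding mode across trials."""
    out = {}
    for mode in MODE_ORDER:
        values = [r.per_class[mode][0] for r in results if mode in r.per_class]
        if values:
            out[mode] = float(np.median(values))
    return out


def permutation_test(
    ds: FingerprintDataset,
    split: DataSplit,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Label-permutation significance test on one pool/test split.

    The observed model is trained on the true pool labels. Each of the
    ``n_perm`` null models is trained on the pool with labels shuffled
    *within the pool* (test labels untouched; shuffle and forest seed for
    permutation ``i`` is ``seed + 1 + i``), and all models are scored by
    multi-class MCC on the fixed test set. The p-value is
    ``max(c, 1) / n_perm`` with ``c`` the number of null models performing
    at least as well as the observed one, so the smallest achievable
    p-value is ``1 / n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x_pool = ds.matrix[split.pool_indices]
    y_pool = [ds.labels[i] for i in split.pool_indices]
    x_test = ds.matrix[split.test_indices]
    y_test = [ds.labels[i] for i in split.test_indices]

    observed_model = train_rf(x_pool, y_pool, seed=seed)
    observed = multiclass_mcc(y_test, observed_model.predict(x_test))

    nulls = np.empty(n_perm)
    y_pool_arr = np.array([MODE_ORDER.index(lab) for lab in y_pool])
    for i in range(n_perm):
        perm_seed = seed + 1 + i
        rng = np.random.default_rng(perm_seed)
        shuffled = [MODE_ORDER[int(c)] for c in rng.permutation(y_pool_arr)]
        model = train_rf(x_pool, shuffled, seed=perm_seed)
        nulls[i] = multiclass_mcc(y_test, model.predict(x_test))
    c = int((nulls >= observed).sum())
    return PermutationTestResult(
        observed_mcc=observed,
        null_mccs=nulls,
        p_value=max(c, 1) / n_perm,
    )


def extract_importances(model: ClassifierModel, feature_names: Sequence[str]) -> np.ndarray:
    """Gini importances (mean impurity decrease), normalized to sum to 1."""
    if not hasattr(model.forest, "feature_importances_"):
        raise ValueError("model is not trained")
    imp = np.asarray(model.forest.feature_importances_, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("feature_names not aligned with model features")
    total = imp.sum()
    if total == 0:
        raise ValueError("all-zero importances (no split used any feature)")
    return imp / total


def filter_by_median_importance(trace: ImportanceTrace, fraction_of_max: float) -> list[str]:
    """Features whose median importance across iterations reaches a fraction
    of the maximum median importance."""
    if not 0.0 < fraction_of_max <= 1.0:
        raise ValueError("fraction_of_max must be in (0, 1]")
    if trace.matrix.size == 0:
        raise ValueError("empty importance trace")
    medians = np.median(trace.matrix, axis=1)
    threshold = fraction_of_max * medians.max()
    keep = medians >= threshold
    return [name for name, k in zip(trace.feature_names, keep) if k]
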