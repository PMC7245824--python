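"""Entropy-based active learning as a diagnostic of representation information.

The protocol: split the cohort 90/10 into a compound pool and a test set;
seed the training set with three randomly chosen pool compounds (one per
binding mode); then repeatedly (i) train the random forest on the current
training set, (ii) record its multi-class MCC/BA on the test set and MCC on
the compound pool, and (iii) move the N = 10 pool compounds whose predicted
class distributions have the largest Shannon entropy (or a random batch,
as control) into the training set, until the pool is exhausted.

A representation that is information-rich and redundant (interaction
fingerprints) produces accurate models from few, even randomly chosen,
training compounds; a sparser, weaker-signal representation
(atom-environment fingerprints) profits much more from entropy-guided
selection — visible as a larger peak in the entropy-minus-random MCC
difference curve.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

import numpy as np

from .classification import (
    ClassifierModel,
    DataSplit,
    ImportanceTrace,
    extract_importances,
    stratified_split,
    train_rf,
)
from .fingerprints import FingerprintDataset
from .metrics import entropy_per_row, macro_balanced_accuracy, multiclass_mcc
from .modes import MODE_ORDER, BindingMode

logger = logging.getLogger(__name__)

Strategy = Literal["entropy", "random"]


@dataclasses.dataclass(frozen=True)
class ActiveLearningConfig:
    """Protocol parameters. ``batch_size`` is the N of batch selection."""

    batch_size: int = 10
    initial_per_class: int = 1
    strategy: Strategy = "entropy"
    max_iterations: int | None = None  # None = run until the pool is empty
    seed: int = 0
    track_importances: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_per_class < 1:
            raise ValueError("initial_per_class must be >= 1")
        if self.strategy not in ("entropy", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclasses.dataclass
class ActiveLearningTrace:
    """Per-iteration record of one active-learning run.

    ``pool_mcc_remaining`` scores predictions of the compounds still in the
    pool at each iteration (nan once the pool is empty);
    ``pool_mcc_full`` scores predictions of the entire original pool
    (training compounds included), the default quantity for learning-curve
    plots.
    """

    strategy: Strategy
    training_sizes: list[int] = dataclasses.field(default_factory=list)
    selected_ids: list[list[int]] = dataclasses.field(default_factory=list)
    selection_entropies: list[np.ndarray] = dataclasses.field(default_factory=list)
    test_mcc: list[float] = dataclasses.field(default_factory=list)
    test_ba: list[float] = dataclasses.field(default_factory=list)
    pool_mcc_remaining: list[float] = dataclasses.field(default_factory=list)
    pool_mcc_full: list[float] = dataclasses.field(default_factory=list)
    importance_trace: ImportanceTrace | None = None


@dataclasses.dataclass
class AggregatedCurves:
    """Mean and standard deviation of trace metrics per training size."""

    training_sizes: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_traces: int


@dataclasses.dataclass
class DifferenceCurve:
    """Entropy-minus-random metric difference with propagated SD and peak."""

    training_sizes: np.ndarray
    mcc_difference: np.ndarray
    sd: np.ndarray
    peak_value: float
    peak_training_size: int


def initial_selection(
    pool_labels: Sequence[BindingMode], seed: int, per_class: int = 1
) -> list[int]:
    """Randomly pick ``per_class`` pool positions per binding mode (default:
    three compounds, one per class)."""
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for mode in MODE_ORDER:
        members = [i for i, lab in enumerate(pool_labels) if lab == mode]
        if len(members) < per_class:
            raise ValueError(f"class {mode} has fewer than {per_class} pool members")
        chosen.extend(rng.choice(members, size=per_class, replace=False).tolist())
    return chosen


def select_batch_entropy(
    model: ClassifierModel, pool_rows: np.ndarray, n: int
) -> tuple[list[int], np.ndarray]:
    """Positions (within the given pool order) of the n most uncertain
    compounds, plus their prediction entropies.

    Ties are broken by ascending pool position (the pool order was already
    shuffled once at split time, so this is deterministic yet unbiased).
    If fewer than n compounds remain, all are returned.
    """
    if pool_rows.shape[0] == 0:
        raise ValueError("empty pool")
    entropies = entropy_per_row(model.predict_proba(pool_rows))
    n_take = min(n, len(entropies))
    order = np.argsort(-entropies, kind="stable")  # stable: ties keep ascending position
    picked = order[:n_take]
    return picked.tolist(), entropies[picked]


def select_batch_random(n_pool: int, n: int, rng: np.random.Generator) -> list[int]:
    """n uniform draws without replacement from pool positions 0..n_pool-1."""
    if n_pool == 0:
        raise ValueError("empty pool")
    n_take = min(n, n_pool)
    return rng.choice(n_pool, size=n_take, replace=False).tolist()


def run_active_learning(
    ds: FingerprintDataset, split: DataSplit, config: ActiveLearningConfig
) -> ActiveLearningTrace:
    """One active-learning run on a fixed pool/test split.

    The forest is retrained from scratch each iteration with a seed fixed
    per run, so curve noise reflects instance selection rather than refit
    randomness. Selected instances are recorded as dataset row indices.
    """
    pool = list(split.pool_indices)  # dataset row indices, seeded order
    labels = ds.labels
    x_test = ds.matrix[split.test_indices]
    y_test = [labels[i] for i in split.test_indices]
    x_full_pool = ds.matrix[split.pool_indices]
    y_full_pool = [labels[i] for i in split.pool_indices]

    init_positions = initial_selection(
        [labels[i] for i in pool], seed=config.seed, per_class=config.initial_per_class
    )
    training = [pool[p] for p in init_positions]
    remaining = [idx for p, idx in enumerate(pool) if p not in set(init_positions)]

    trace = ActiveLearningTrace(strategy=config.strategy)
    trace.selected_ids.append(list(training))
    trace.selection_entropies.append(np.full(len(training), np.nan))
    rng = np.random.default_rng(config.seed + 7919)  # random-strategy draw stream
    importances: list[np.ndarray] = []

    iteration = 0
    while True:
        iteration += 1
        model = train_rf(
            ds.matrix[training], [labels[i] for i in training], seed=config.seed
        )
        trace.training_sizes.append(len(training))
        y_test_pred = model.predict(x_test)
        trace.test_mcc.append(multiclass_mcc(y_test, y_test_pred))
        trace.test_ba.append(macro_balanced_accuracy(y_test, y_test_pred))
        if remaining:
            x_rem = ds.matrix[remaining]
            y_rem = [labels[i] for i in remaining]
            trace.pool_mcc_remaining.append(multiclass_mcc(y_rem, model.predict(x_rem)))
        else:
            trace.pool_mcc_remaining.append(float("nan"))
        trace.pool_mcc_full.append(multiclass_mcc(y_full_pool, model.predict(x_full_pool)))
        if config.track_importances:
            importances.append(extract_importances(model, ds.feature_names))

        if not remaining:
            break
        if config.max_iterations is not None and iteration >= config.max_iterations:
            break

        if config.strategy == "entropy":
            positions, ent = select_batch_entropy(
                model, ds.matrix[remaining], config.batch_size
            )
        else:
            positions = select_batch_random(len(remaining), config.batch_size, rng)
            ent = entropy_per_row(model.predict_proba(ds.matrix[remaining]))[positions]
        batch = [remaining[p] for p in positions]
        trace.selected_ids.append(batch)
        trace.selection_entropies.append(np.asarray(ent))
        taken = set(positions)
        remaining = [idx for p, idx in enumerate(remaining) if p not in taken]
        training.extend(batch)

    if config.track_importances:
        trace.importance_trace = ImportanceTrace(
            matrix=np.column_stack(importances),
            feature_names=list(ds.feature_names),
            training_sizes=list(trace.training_sizes),
        )
    return trace


def aggregate_trials(traces: Sequence[ActiveLearningTrace]) -> AggregatedCurves:
    """Per-training-size mean and SD across trials (default design: six
    trials from two splits x three executions).

    Traces whose training-size grids differ are aligned on the common
    prefix, with a warning.
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    n_common = min(len(t.training_sizes) for t in traces)
    grids = {tuple(t.training_sizes[:n_common]) for t in traces}
    if len(grids) != 1:
        raise ValueError("traces have incompatible training-size grids")
    if any(len(t.training_sizes) != n_common for t in traces):
        logger.warning(
            "traces have unequal lengths; aggregating on the common prefix of %d iterations",
            n_common,
        )
    sizes = np.array(traces[0].training_sizes[:n_common])
    metrics = ["test_mcc", "test_ba", "pool_mcc_remaining", "pool_mcc_full"]
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for name in metrics:
        stack = np.array([getattr(t, name)[:n_common] for t in traces])
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=0)
    return AggregatedCurves(training_sizes=sizes, mean=mean, sd=sd, n_traces=len(traces))


def difference_curve(
    entropy_curves: AggregatedCurves,
    random_curves: AggregatedCurves,
    metric: str = "test_mcc",
) -> DifferenceCurve:
    """Pointwise entropy-minus-random difference with propagated SD.

    SDs add in quadrature; the peak is the maximum of the difference and
    the training size at which it occurs.
    """
    if not np.array_equal(entropy_curves.training_sizes, random_curves.training_sizes):
        raise ValueError("training-size grids do not match")
    diff = entropy_curves.mean[metric] - random_curves.mean[metric]
    sd = np.sqrt(entropy_curves.sd[metric] ** 2 + random_curves.sd[metric] ** 2)
    peak = int(np.argmax(diff))
    return DifferenceCurve(
        training_sizes=entropy_curves.training_sizes,
        mcc_difference=diff,
        sd=sd,
        peak_value=float(diff[peak]),
        peak_training_size=int(entropy_curves.training_sizes[peak]),
    )


def run_protocol(
    ds: FingerprintDataset,
    n_splits: int = 2,
    n_executions: int = 3,
    batch_size: int = 10,
    test_fraction: float = 0.1,
    base_seed: int = 0,
    max_iterations: int | None = None,
    strategies: Sequence[Strategy] = ("entropy", "random"),
    track_importances: bool = False,
) -> dict[Strategy, list[ActiveLearningTrace]]:
    """The full trial design: ``n_splits`` independent pool/test splits with
    ``n_executions`` runs each (default 2 x 3 = 6 trials per strategy).

    Entropy and random runs of the same (split, execution) pair share the
    same seed, hence the same initial three training compounds — pairing
    that reduces the variance of the difference curve.
    """
    out: dict[Strategy, list[ActiveLearningTrace]] = {s: [] for s in strategies}
    for s_idx in range(n_splits):
        split = stratified_split(ds.labels, test_fraction=test_fraction, seed=base_seed + s_idx)
        for e_idx in range(n_executions):
            run_seed = base_seed + 100 * s_idx + 10 * e_idx
            for strategy in strategies:
                config = ActiveLearningConfig(
                    batch_size=batch_size,
                    strategy=strategy,
                    seed=run_seed,
                    max_iterations=max_iterations,
                    track_importances=track_importances,
                )
                out[strategy].append(run_active_learning(ds, split, config))
    return out


def instances_to_reach(
    curves: AggregatedCurves, metric: str = "test_mcc", fraction: float = 0.95
) -> int:
    """Smallest training size whose mean metric reaches ``fraction`` of the
    final (pool-exhaustion) value — the plateau-onset summary."""
    values = curves.mean[metric]
    target = fraction * values[-1]
    reached = np.flatnonzero(values >= target)
    return int(curves.training_sizes[reached[0]])
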