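"""Shared fixtures: small cohorts and pre-computed expensive results.

Session-scoped fixtures hold the quarter-scale cohort and the experiment
results (benchmark trials, active-learning traces) that several test
modules examine, so each expensive computation runs once per session.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import kinmode as km
from kinmode.modes import BindingMode


@pytest.fixture(scope="session")
def quarter_config() -> km.SyntheticConfig:
    """Quarter-scale default cohort (502 inhibitors, same proportions)."""
    return km.scaled_config(0.25)


@pytest.fixture(scope="session")
def quarter_cohort(quarter_config) -> km.LabeledCohort:
    return km.generate_dataset(quarter_config, seed=11)


@pytest.fixture(scope="session")
def quarter_datasets(quarter_cohort) -> dict[str, km.FingerprintDataset]:
    ifp85, ifp595 = km.build_ifp_datasets(quarter_cohort)
    folded, unfolded = km.build_ecfp_datasets(quarter_cohort)
    return {
        "ifp85": ifp85,
        "ifp595": ifp595,
        "ecfp_folded": folded,
        "ecfp_unfolded": unfolded,
        "concat": km.concatenate(ifp595, folded),
    }


@pytest.fixture(scope="session")
def benchmark_results(quarter_datasets) -> dict[str, list[km.EvaluationResult]]:
    """20-trial benchmark for every representation on the quarter cohort."""
    return {
        name: km.benchmark_trials(ds, n_trials=20, base_seed=101)
        for name, ds in quarter_datasets.items()
    }


@pytest.fixture(scope="session")
def al_comparison(quarter_datasets):
    """Entropy-vs-random active learning run to pool exhaustion
    (2 splits x 3 executions) for an interaction-like and an
    atom-environment-like representation."""
    out = {}
    for name in ("ifp85", "ecfp_folded"):
        out[name] = km.run_protocol(quarter_datasets[name], n_splits=2,
                                    n_executions=3, base_seed=7)
    return out


@pytest.fixture(scope="session")
def al_peak_comparison():
    """Half-scale entropy-vs-random runs covering the early learning-curve
    region where the entropy-minus-random difference peaks (training sizes
    up to 293; the peak sits well below that for every representation)."""
    cohort = km.generate_dataset(km.scaled_config(0.5), seed=29)
    ifp85, _ = km.build_ifp_datasets(cohort)
    folded, _ = km.build_ecfp_datasets(cohort)
    out = {}
    for name, ds in (("ifp85", ifp85), ("ecfp_folded", folded)):
        out[name] = km.run_protocol(ds, n_splits=2, n_executions=3,
                                    base_seed=7, max_iterations=30)
    return out


@pytest.fixture(scope="session")
def tiny_separable_dataset() -> km.FingerprintDataset:
    """60 inhibitors, 3 classes, each class carrying a deterministic
    disjoint bit block — perfectly separable."""
    rng = np.random.default_rng(0)
    n_per = 20
    rows, labels, ids = [], [], []
    for k, mode in enumerate(km.MODE_ORDER):
        for i in range(n_per):
            row = (rng.random(30) < 0.05).astype(np.uint8)
            row[10 * k : 10 * k + 5] = 1
            rows.append(row)
            labels.append(mode)
            ids.append(f"T{k}_{i}")
    return km.FingerprintDataset(
        np.stack(rows), labels, ids,
        [f"f{j}" for j in range(30)], km.RepresentationTag.CONCAT,
    )


@pytest.fixture()
def tiny_config() -> km.SyntheticConfig:
    """Small configurable cohort used by generator unit tests."""
    return dataclasses.replace(
        km.default_config(),
        n_per_class={
            BindingMode.TYPE_I: 30,
            BindingMode.TYPE_I_HALF: 20,
            BindingMode.TYPE_II: 10,
        },
    )
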