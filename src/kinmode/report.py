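"""Consolidated figures and machine-readable summaries of all experiments.

Given whichever experiment results are available, one figure is written per
experiment (benchmark boxplots, permutation-null histogram, per-class
boxplots, learning curves, entropy-minus-random difference curves, feature
importance heatmap, t-SNE scatter) alongside a ``summary.json`` holding the
corresponding numeric summaries. Class colors are fixed throughout:
type I blue, type I1/2 orange, type II green.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .active_learning import AggregatedCurves, DifferenceCurve
from .classification import ImportanceTrace, PermutationTestResult
from .embedding import Embedding2D
from .metrics import EvaluationResult
from .modes import MODE_COLORS, MODE_ORDER

_KNOWN_KEYS = (
    "benchmark",
    "permutation",
    "learning_curves",
    "difference_curves",
    "importance",
    "embedding",
)


def render_report(results: Mapping, output_dir: str | Path) -> dict:
    """Render figures and a summary JSON for the supplied experiment results.

    ``results`` maps any subset of the known experiment keys to their
    result objects; an empty mapping is an error that lists the accepted
    keys. Returns the summary dictionary (also written to
    ``summary.json``). Re-rendering identical inputs yields an identical
    summary.
    """
    present = [k for k in _KNOWN_KEYS if k in results]
    if not present:
        raise ValueError(
            "no experiment results supplied; expected at least one of: "
            + ", ".join(_KNOWN_KEYS)
        )
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    if "benchmark" in results:
        summary["benchmark"] = _render_benchmark(results["benchmark"], out)
    if "permutation" in results:
        summary["permutation"] = _render_permutation(results["permutation"], out)
    if "learning_curves" in results:
        summary["learning_curves"] = _render_learning_curves(
            results["learning_curves"], out
        )
    if "difference_curves" in results:
        summary["difference_curves"] = _render_difference_curves(
            results["difference_curves"], out
        )
    if "importance" in results:
        summary["importance"] = _render_importance(results["importance"], out)
    if "embedding" in results:
        summary["embedding"] = _render_embedding(results["embedding"], out)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _render_benchmark(
    benchmark: Mapping[str, Sequence[EvaluationResult]], out: Path
) -> dict:
    tags = list(benchmark)
    fig, axes = plt.subplots(1, 2, figsize=(2.2 * len(tags) + 3, 4), sharey=False)
    for ax, metric in zip(axes, ("mcc", "ba")):
        data = [[getattr(r, metric) for r in benchmark[tag]] for tag in tags]
        ax.boxplot(data, tick_labels=tags, whis=1.5)
        ax.set_ylabel(metric.upper())
        ax.tick_params(axis="x", rotation=45)
    fig.suptitle("Benchmark performance by representation")
    fig.tight_layout()
    fig.savefig(out / "benchmark.png", dpi=150)
    plt.close(fig)

    # per-class boxplot for each representation
    fig, axes = plt.subplots(1, len(tags), figsize=(3 * len(tags), 4), squeeze=False)
    for ax, tag in zip(axes[0], tags):
        per_class = [
            [r.per_class[m][0] for r in benchmark[tag] if m in r.per_class]
            for m in MODE_ORDER
        ]
        box = ax.boxplot(per_class, tick_labels=[m.value for m in MODE_ORDER],
                         patch_artist=True, whis=1.5)
        for patch, mode in zip(box["boxes"], MODE_ORDER):
            patch.set_facecolor(MODE_COLORS[mode])
        ax.set_title(tag)
        ax.set_ylabel("per-class MCC")
    fig.tight_layout()
    fig.savefig(out / "per_class.png", dpi=150)
    plt.close(fig)

    summary = {}
    for tag in tags:
        mccs = np.array([r.mcc for r in benchmark[tag]])
        bas = np.array([r.ba for r in benchmark[tag]])
        summary[tag] = {
            "mcc_median": float(np.median(mccs)),
            "mcc_q1": float(np.percentile(mccs, 25)),
            "mcc_q3": float(np.percentile(mccs, 75)),
            "ba_median": float(np.median(bas)),
            "per_class_mcc_median": {
                m.value: float(
                    np.median([r.per_class[m][0] for r in benchmark[tag] if m in r.per_class])
                )
                for m in MODE_ORDER
            },
        }
    return summary


def _render_permutation(perm: PermutationTestResult, out: Path) -> dict:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(perm.null_mccs, bins=30, color="0.7")
    ax.axvline(0.0, color="k", linestyle="--", linewidth=1)
    ax.axvline(perm.observed_mcc, color="tab:red", linewidth=2,
               label=f"observed MCC = {perm.observed_mcc:.2f}")
    ax.set_xlabel("test-set MCC of label-shuffled models")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "permutation.png", dpi=150)
    plt.close(fig)
    return {
        "observed_mcc": float(perm.observed_mcc),
        "null_mcc_median": float(np.median(perm.null_mccs)),
        "p_value": float(perm.p_value),
        "n_perm": int(len(perm.null_mccs)),
    }


def _render_learning_curves(
    curves: Mapping[str, Mapping[str, AggregatedCurves]], out: Path
) -> dict:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    summary: dict = {}
    for tag, by_strategy in curves.items():
        for strategy, agg in by_strategy.items():
            for ax, metric in zip(axes, ("pool_mcc_full", "test_mcc")):
                mean, sd = agg.mean[metric], agg.sd[metric]
                style = "-" if strategy == "entropy" else "--"
                line, = ax.plot(agg.training_sizes, mean, style,
                                label=f"{tag} ({strategy})")
                ax.fill_between(agg.training_sizes, mean - sd, mean + sd,
                                alpha=0.15, color=line.get_color())
            summary.setdefault(tag, {})[strategy] = {
                "final_test_mcc": float(by_strategy[strategy].mean["test_mcc"][-1]),
                "final_test_mcc_sd": float(by_strategy[strategy].sd["test_mcc"][-1]),
                "n_traces": by_strategy[strategy].n_traces,
            }
    axes[0].set_title("compound pool")
    axes[1].set_title("test set")
    for ax in axes:
        ax.set_xlabel("training set size")
        ax.set_ylabel("MCC")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "learning_curves.png", dpi=150)
    plt.close(fig)
    return summary


def _render_difference_curves(diffs: Mapping[str, DifferenceCurve], out: Path) -> dict:
    fig, ax = plt.subplots(figsize=(6, 4))
    summary = {}
    for tag, curve in diffs.items():
        line, = ax.plot(curve.training_sizes, curve.mcc_difference, label=tag)
        ax.fill_between(
            curve.training_sizes,
            curve.mcc_difference - curve.sd,
            curve.mcc_difference + curve.sd,
            alpha=0.15,
            color=line.get_color(),
        )
        summary[tag] = {
            "peak_value": curve.peak_value,
            "peak_training_size": curve.peak_training_size,
        }
    ax.axhline(0.0, color="k", linewidth=0.8)
    ax.set_xlabel("training set size")
    ax.set_ylabel("MCC difference (entropy - random)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "difference_curves.png", dpi=150)
    plt.close(fig)
    return summary


def _render_importance(trace: ImportanceTrace, out: Path, top: int = 30) -> dict:
    medians = np.median(trace.matrix, axis=1)
    order = np.argsort(-medians)[:top]
    fig, ax = plt.subplots(figsize=(8, 0.25 * len(order) + 2))
    im = ax.imshow(trace.matrix[order], aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([trace.feature_names[i] for i in order], fontsize=6)
    ax.set_xticks(range(len(trace.training_sizes)))
    ax.set_xticklabels(trace.training_sizes, fontsize=6, rotation=90)
    ax.set_xlabel("training set size")
    fig.colorbar(im, ax=ax, label="Gini importance")
    fig.tight_layout()
    fig.savefig(out / "importance.png", dpi=150)
    plt.close(fig)
    return {
        "top_features": [trace.feature_names[i] for i in order[:10]],
        "max_median_importance": float(medians.max()),
    }


def _render_embedding(embeddings: Mapping[str, Embedding2D], out: Path) -> dict:
    from .embedding import embedding_silhouette

    n = len(embeddings)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4.5), squeeze=False)
    summary = {}
    for ax, (tag, emb) in zip(axes[0], embeddings.items()):
        for mode in MODE_ORDER:
            mask = np.array([lab == mode for lab in emb.labels])
            if mask.any():
                ax.scatter(
                    emb.coordinates[mask, 0],
                    emb.coordinates[mask, 1],
                    s=6,
                    color=MODE_COLORS[mode],
                    label=mode.value,
                )
        ax.set_title(tag)
        ax.legend(markerscale=2)
        ax.set_xticks([])
        ax.set_yticks([])
        summary[tag] = {
            "silhouette": embedding_silhouette(emb) if emb.labels else None,
            "n": len(emb.inhibitor_ids),
        }
    fig.tight_layout()
    fig.savefig(out / "embedding.png", dpi=150)
    plt.close(fig)
    return summary
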