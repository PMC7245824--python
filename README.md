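# kinmode

Multi-class prediction of kinase inhibitor binding modes (type I / I1/2 /
II) from two fundamentally different molecular representations, and a
diagnostic for *why* one outperforms the other.

Kinase inhibitors are classified crystallographically by the conformation
they bind: type I (active, DFG-in/alphaC-in), type I1/2 (intermediate,
DFG-in/alphaC-out) and type II (inactive, DFG-out). `kinmode` compares

* **interaction fingerprints (IFP)** — binary vectors over 85 standardized
  binding-site residue positions (85-bit), expanded to 595 bits by seven
  interaction categories per position, with a majority-vote consensus rule
  across multiple complex structures per inhibitor (ties set "on"); and
* **atom-environment fingerprints (ECFP4-like)** — hashed circular
  substructure identifiers of the ligand alone, used either folded to 1024
  bits by modulo mapping or unfolded as a variable-size feature set,

as inputs to 100-tree class-weighted random forests. Evaluation uses the
Matthews correlation coefficient (Gorodkin's R_K for three classes) and
balanced accuracy (macro recall), globally and one-vs-rest per class:

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    BA  = ½·(TP/(TP+FN) + TN/(TN+FP))
    H   = − Σᵢ pᵢ log₂ pᵢ

Significance comes from a 1000-model label-permutation test. The
information content of each representation is probed with pool-based
active learning: starting from three training compounds (one per class),
each iteration adds the N = 10 pool compounds whose predicted class
distribution has maximal Shannon entropy H (or a random batch, as
control). A representation that is information-rich and redundant yields
accurate models even from randomly selected compounds; a weak-signal,
high-dimensional representation needs entropy-guided selection — visible
as a peak in the entropy-minus-random MCC difference curve. Tanimoto
(Jaccard) distance t-SNE maps visualize both representation spaces.

A synthetic cohort generator emulates the statistical structure of the
KLIFS-derived study cohort (2008 inhibitors: 1424 type I, 394 type I1/2,
190 type II; class-conditional sparse interaction patterns with redundant
correlated copies; weak diffuse atom-environment signal; multiple noisy
structures per inhibitor), so the complete pipeline runs and is tested
offline. Adapters read real KLIFS-style 595-bit strings and SMILES files
(via RDKit) when real data are available. See `docs/methods.md` for the
model and every numerical choice.

## Worked example

```python
import numpy as np
import kinmode as km

cohort = km.generate_dataset(km.default_config(), seed=1)   # 2008 inhibitors
ifp85, ifp595 = km.build_ifp_datasets(cohort)               # consensus IFPs
folded, unfolded = km.build_ecfp_datasets(cohort)           # ECFP4-like

for name, ds in [("IFP_85", ifp85), ("IFP_595", ifp595),
                 ("ECFP4_folded", folded), ("ECFP4_unfolded", unfolded),
                 ("IFP+ECFP", km.concatenate(ifp595, folded))]:
    stats = km.summarize_trials(km.benchmark_trials(ds, n_trials=20, base_seed=1))
    print(f"{name:14s} median MCC {stats['mcc_median']:.2f}  "
          f"median BA {stats['ba_median']:.2f}")
```

prints

```
IFP_85         median MCC 0.77  median BA 0.89
IFP_595        median MCC 0.86  median BA 0.94
ECFP4_folded   median MCC 0.51  median BA 0.68
ECFP4_unfolded median MCC 0.61  median BA 0.73
IFP+ECFP       median MCC 0.88  median BA 0.95
```

Interaction fingerprints clearly out-predict ligand-structure fingerprints
(the extra 0.09 MCC of IFP_595 over IFP_85 is the value of resolving
interaction *types*), and concatenating ECFP4 onto the IFP changes
essentially nothing (+0.02) — the interaction information subsumes the
structural signal. The active-learning diagnostic explains the gap:

```python
from kinmode.active_learning import aggregate_trials, difference_curve

half = km.generate_dataset(km.scaled_config(0.5), seed=1)
ds, _ = km.build_ifp_datasets(half)
traces = km.run_protocol(ds, n_splits=2, n_executions=3, base_seed=1,
                         max_iterations=30)
diff = difference_curve(aggregate_trials(traces["entropy"]),
                        aggregate_trials(traces["random"]))
print(f"peak entropy-minus-random MCC difference {diff.peak_value:.2f} "
      f"at {diff.peak_training_size} training compounds")
```

```
peak entropy-minus-random MCC difference 0.08 at 133 training compounds
```

For the atom-environment representation the same run peaks at 0.17: picking
informative compounds matters twice as much when the representation itself
carries less redundant signal, whereas IFP models are accurate even with
randomly chosen small training sets.

A command-line interface mirrors the library
(`kinmode generate | featurize | benchmark | permtest | active-learn |
embed`); figures for every experiment come from `kinmode.render_report`.

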