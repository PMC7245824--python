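"""Synthetic kinase-inhibitor cohort generator.

Emulates the statistical structure of a KLIFS-style binding-mode cohort so
that every downstream stage (fingerprint construction, random-forest
benchmarking, permutation tests, active learning, embedding) can run without
any external download:

* three imbalanced binding-mode classes (default composition
  1424 type I / 394 type I1/2 / 190 type II = 2008 inhibitors);
* per-structure residue interaction records (85 binding-site positions x
  7 interaction categories) drawn from class-conditional Bernoulli patterns
  with *redundant* correlated copies of each signature interaction — the
  mechanism that makes the interaction-fingerprint representation
  information-rich but highly redundant;
* sparse, high-dimensional, weak-signal integer feature sets emulating
  hashed atom-environment (ECFP4-like) fingerprints;
* several structures per inhibitor with independent bit-flip noise, so the
  per-inhibitor consensus rule is exercised.

All randomness flows from a single master seed through fixed sub-seed
offsets, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .modes import MODE_ORDER, BindingMode, mode_from_label

# Fixed sub-seed offsets: interaction records and structural feature sets are
# generated from independent streams derived from the master seed.
_INTERACTION_SEED_OFFSET = 101
_STRUCTURAL_SEED_OFFSET = 202
_SEED_MODULUS = 2**31 - 1


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    n_per_class
        Exact number of inhibitors per binding mode. Labels are assigned by
        count, not sampled, so the class composition is reproduced exactly.
    n_positions, n_categories
        Interaction-record geometry: binding-site residue positions (85 in
        the KLIFS numbering scheme) times interaction categories (7).
    signature_bits
        Class-conditional signature interactions: for each binding mode, a
        list of ``(position, category, on_probability)`` triples (1-based
        position/category). Members of the class carry each signature cell
        ON with its ``on_probability``; for non-members the cell is ordinary
        background. A cell may appear in several classes' signatures with
        different probabilities (partially shared interaction patterns).
    background_on_probability
        ON-rate of all non-signature cells.
    redundancy_factor
        Number of correlated copies written for every signature cell, at
        reserved cells allocated from the high end of the position grid.
        Copies duplicate the parent draw exactly and then receive the same
        independent per-structure noise as every other cell, which is what
        makes the interaction representation redundant.
    structures_per_inhibitor, structure_noise
        Each inhibitor has this many simulated complex structures; each
        structure is the inhibitor's base pattern with independent per-cell
        bit flips at rate ``structure_noise``.
    ecfp_vocab_size, ecfp_signal_features_per_class, ecfp_signal_strength,
    ecfp_background_rate
        Atom-environment-like feature sets: a vocabulary of hashed integer
        identifiers; each class reserves a block of signal identifiers that
        members include with probability ``background + signal_strength``
        and non-members with the background rate; all other identifiers are
        included at the background rate. Defaults give a sparser,
        higher-dimensional, weaker-signal representation than the
        interaction records.
    seed
        Master seed; sub-seeds for the two generators are derived from it
        by fixed offsets.
    """

    n_per_class: Mapping[BindingMode, int]
    n_positions: int = 85
    n_categories: int = 7
    signature_bits: Mapping[BindingMode, Sequence[tuple[int, int, float]]] = (
        dataclasses.field(default_factory=dict)
    )
    background_on_probability: float = 0.02
    redundancy_factor: int = 3
    structures_per_inhibitor: int = 3
    structure_noise: float = 0.03
    ecfp_vocab_size: int = 2000
    ecfp_signal_features_per_class: int = 30
    ecfp_signal_strength: float = 0.05
    ecfp_background_rate: float = 0.008
    seed: int = 0

    def validate(self) -> None:
        for mode, count in self.n_per_class.items():
            if count <= 0:
                raise ConfigurationError(f"count for {mode} must be positive")
        for p in (
            self.background_on_probability,
            self.structure_noise,
            self.ecfp_background_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.ecfp_background_rate + self.ecfp_signal_strength <= 1.0:
            raise ConfigurationError("ecfp background + signal strength outside [0, 1]")
        if self.redundancy_factor < 0:
            raise ConfigurationError("redundancy_factor must be >= 0")
        if self.structures_per_inhibitor < 1:
            raise ConfigurationError("structures_per_inhibitor must be >= 1")
        for mode, bits in self.signature_bits.items():
            for pos, cat, p in bits:
                if not (1 <= pos <= self.n_positions and 1 <= cat <= self.n_categories):
                    raise ConfigurationError(
                        f"signature cell ({pos}, {cat}) for {mode} outside the "
                        f"{self.n_positions} x {self.n_categories} grid"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"on_probability {p} outside [0, 1]")
        if 3 * self.ecfp_signal_features_per_class > self.ecfp_vocab_size:
            raise ConfigurationError("class signal features exceed the ECFP vocabulary")
        # copy layout feasibility is checked by _copy_layout
        _copy_layout(self)


def _signature_cells(config: SyntheticConfig) -> list[tuple[int, int]]:
    """Sorted unique (position, category) cells appearing in any signature."""
    cells = {
        (pos, cat)
        for bits in config.signature_bits.values()
        for (pos, cat, _p) in bits
    }
    return sorted(cells)


def _copy_layout(config: SyntheticConfig) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Reserved cells holding the redundant copies of each signature cell.

    Copies are allocated from the high end of the grid (position descending,
    category descending), skipping signature cells, in sorted parent order.
    The layout depends only on the configuration, so the same cell always
    duplicates the same parent across the whole cohort.
    """
    parents = _signature_cells(config)
    parent_set = set(parents)
    free = (
        (pos, cat)
        for pos in range(config.n_positions, 0, -1)
        for cat in range(config.n_categories, 0, -1)
        if (pos, cat) not in parent_set
    )
    layout: dict[tuple[int, int], list[tuple[int, int]]] = {}
    try:
        for parent in parents:
            layout[parent] = [next(free) for _ in range(config.redundancy_factor)]
    except StopIteration:
        raise ConfigurationError(
            "redundancy_factor too large: copies do not fit in the "
            f"{config.n_positions} x {config.n_categories} grid"
        ) from None
    return layout


def default_config() -> SyntheticConfig:
    """Default synthetic cohort matching the study's class composition.

    Class counts are 1424 / 394 / 190 (2008 inhibitors total). Signature
    interactions are laid out so that type II inhibitors carry a strong,
    nearly unique back-pocket pattern (easiest class), while types I and
    I1/2 share partially overlapping hinge-region patterns with shifted
    probabilities (the intermediate I1/2 mode is hardest to separate from
    type I). See ``docs/methods.md`` for the calibration rationale.
    """
    sig: dict[BindingMode, list[tuple[int, int, float]]] = {
        # hinge-like contacts: present in both I and I1/2, stronger in I
        BindingMode.TYPE_I: [(pos, 1, 0.62) for pos in range(5, 11)]
        + [(pos, 2, 0.12) for pos in range(11, 15)],
        BindingMode.TYPE_I_HALF: [(pos, 1, 0.28) for pos in range(5, 11)]
        + [(pos, 2, 0.55) for pos in range(11, 15)]
        + [(pos, 3, 0.15) for pos in range(15, 21)],
        # back-pocket contacts: near-unique to DFG-out binders
        BindingMode.TYPE_II: [(pos, 3, 0.85) for pos in range(15, 21)],
    }
    return SyntheticConfig(
        n_per_class={
            BindingMode.TYPE_I: 1424,
            BindingMode.TYPE_I_HALF: 394,
            BindingMode.TYPE_II: 190,
        },
        signature_bits=sig,
    )


def scaled_config(fraction: float, base: SyntheticConfig | None = None) -> SyntheticConfig:
    """Down-scaled cohort with the same class proportions and signal model.

    Useful for fast experiments: class counts are scaled by ``fraction``
    (minimum 2 per class so stratified splitting stays possible).
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must be in (0, 1]")
    base = base if base is not None else default_config()
    counts = {
        mode: max(2, round(count * fraction))
        for mode, count in base.n_per_class.items()
    }
    return dataclasses.replace(base, n_per_class=counts)


def null_config(base: SyntheticConfig | None = None) -> SyntheticConfig:
    """Configuration with no class-dependent signal (label-independent data)."""
    base = base if base is not None else default_config()
    return dataclasses.replace(base, signature_bits={}, ecfp_signal_strength=0.0)


@dataclasses.dataclass
class LabeledCohort:
    """A generated cohort: identifiers, labels and both raw representations."""

    inhibitor_ids: list[str]
    labels: list[BindingMode]
    #: inhibitor_id -> one interaction record per simulated structure
    interaction_records: dict[str, list["ResidueInteractionRecord"]]
    #: inhibitor_id -> set of integer atom-environment feature identifiers
    structural_features: dict[str, set[int]]

    def __post_init__(self) -> None:
        if len(self.inhibitor_ids) != len(self.labels):
            raise ValueError("labels not aligned with inhibitor_ids")
        for inh in self.inhibitor_ids:
            if not self.interaction_records.get(inh):
                raise ValueError(f"inhibitor {inh} has no interaction record")

    def __len__(self) -> int:
        return len(self.inhibitor_ids)


def _inhibitor_ids(n: int) -> list[str]:
    return [f"INH{i:05d}" for i in range(n)]


def make_labels(config: SyntheticConfig) -> list[BindingMode]:
    """Deterministic label vector with exact per-class counts, in canonical order."""
    labels: list[BindingMode] = []
    for mode in MODE_ORDER:
        labels.extend([mode] * config.n_per_class.get(mode, 0))
    return labels


def generate_interaction_profiles(
    config: SyntheticConfig,
    labels: Sequence[BindingMode],
    rng_seed: int,
) -> dict[str, list["ResidueInteractionRecord"]]:
    """Simulate per-structure residue interaction records for each inhibitor.

    For each inhibitor: signature cells of its class are drawn ON with their
    configured probabilities, each drawn value is duplicated at its reserved
    copy cells, all remaining cells are ON at the background rate, and then
    every structure is an independent noisy read of that base pattern
    (per-cell flips at ``structure_noise``).
    """
    from .fingerprints import ResidueInteractionRecord

    config.validate()
    layout = _copy_layout(config)
    rng = np.random.default_rng(rng_seed)
    ids = _inhibitor_ids(len(labels))
    out: dict[str, list[ResidueInteractionRecord]] = {}
    for inh, mode in zip(ids, labels):
        base = rng.random((config.n_positions, config.n_categories)) < (
            config.background_on_probability
        )
        for pos, cat, p in config.signature_bits.get(mode, ()):
            value = rng.random() < p
            base[pos - 1, cat - 1] = value
            for cpos, ccat in layout[(pos, cat)]:
                base[cpos - 1, ccat - 1] = value
        records = []
        for s in range(config.structures_per_inhibitor):
            flips = rng.random(base.shape) < config.structure_noise
            records.append(
                ResidueInteractionRecord(
                    structure_id=f"{inh}_s{s}",
                    inhibitor_id=inh,
                    cells=base ^ flips,
                )
            )
        out[inh] = records
    return out


def generate_structural_features(
    config: SyntheticConfig,
    labels: Sequence[BindingMode],
    rng_seed: int,
) -> dict[str, set[int]]:
    """Simulate hashed atom-environment feature sets for each inhibitor.

    Class ``k`` (canonical order) reserves identifiers
    ``[k * m, (k + 1) * m)`` with ``m = ecfp_signal_features_per_class``;
    members include each of them with probability ``background + signal``,
    everything else is included at the background rate.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    ids = _inhibitor_ids(len(labels))
    m = config.ecfp_signal_features_per_class
    mode_index = {mode: k for k, mode in enumerate(MODE_ORDER)}
    out: dict[str, set[int]] = {}
    for inh, mode in zip(ids, labels):
        draws = rng.random(config.ecfp_vocab_size)
        prob = np.full(config.ecfp_vocab_size, config.ecfp_background_rate)
        k = mode_index[mode]
        prob[k * m : (k + 1) * m] += config.ecfp_signal_strength
        out[inh] = set(np.flatnonzero(draws < prob).tolist())
    return out


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> LabeledCohort:
    """Generate a full labeled cohort (labels, interaction records, feature sets)."""
    config.validate()
    master = config.seed if seed is None else seed
    labels = make_labels(config)
    records = generate_interaction_profiles(
        config, labels, (master + _INTERACTION_SEED_OFFSET) % _SEED_MODULUS
    )
    features = generate_structural_features(
        config, labels, (master + _STRUCTURAL_SEED_OFFSET) % _SEED_MODULUS
    )
    return LabeledCohort(
        inhibitor_ids=_inhibitor_ids(len(labels)),
        labels=labels,
        interaction_records=records,
        structural_features=features,
    )


# ---------------------------------------------------------------------------
# configuration and cohort serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_per_class"] = {mode.value: c for mode, c in config.n_per_class.items()}
    d["signature_bits"] = {
        mode.value: [list(t) for t in bits]
        for mode, bits in config.signature_bits.items()
    }
    return d


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    d["n_per_class"] = {
        mode_from_label(k): int(v) for k, v in d["n_per_class"].items()
    }
    d["signature_bits"] = {
        mode_from_label(k): [tuple(t) for t in bits]
        for k, bits in d.get("signature_bits", {}).items()
    }
    return SyntheticConfig(**d)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    """Write a configuration as YAML (or JSON, by file suffix)."""
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> SyntheticConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(d)


def save_cohort(cohort: LabeledCohort, output_dir: str | Path) -> None:
    """Serialize a cohort as plain-text tables.

    ``labels.tsv``
        inhibitor_id and binding-mode label.
    ``interactions.tsv``
        structure_id, inhibitor_id and the 595-character 0/1 bitstring of
        the record in position-major order.
    ``structural_features.txt``
        one line per inhibitor: inhibitor_id then space-separated integer
        feature identifiers.
    """
    from .fingerprints import write_klifs_bitstrings

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.tsv", "w") as fh:
        fh.write("inhibitor_id\tbinding_mode\n")
        for inh, mode in zip(cohort.inhibitor_ids, cohort.labels):
            fh.write(f"{inh}\t{mode.value}\n")
    records = [r for inh in cohort.inhibitor_ids for r in cohort.interaction_records[inh]]
    write_klifs_bitstrings(records, out / "interactions.tsv")
    with open(out / "structural_features.txt", "w") as fh:
        for inh in cohort.inhibitor_ids:
            feats = " ".join(str(f) for f in sorted(cohort.structural_features[inh]))
            fh.write(f"{inh} {feats}\n".rstrip() + "\n")


def load_cohort(input_dir: str | Path) -> LabeledCohort:
    """Read a cohort previously written by :func:`save_cohort`."""
    from .fingerprints import read_klifs_bitstrings

    src = Path(input_dir)
    inhibitor_ids: list[str] = []
    labels: list[BindingMode] = []
    with open(src / "labels.tsv") as fh:
        next(fh)  # header
        for line in fh:
            inh, label = line.rstrip("\n").split("\t")
            inhibitor_ids.append(inh)
            labels.append(mode_from_label(label))
    records = read_klifs_bitstrings(src / "interactions.tsv")
    by_inh: dict[str, list] = {}
    for rec in records:
        by_inh.setdefault(rec.inhibitor_id, []).append(rec)
    features: dict[str, set[int]] = {}
    with open(src / "structural_features.txt") as fh:
        for line in fh:
            parts = line.split()
            features[parts[0]] = {int(x) for x in parts[1:]}
    return LabeledCohort(
        inhibitor_ids=inhibitor_ids,
        labels=labels,
        interaction_records=by_inh,
        structural_features=features,
    )
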