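"""Fingerprint representations of kinase-inhibitor complexes.

Four binary representations are supported:

* ``IFP_85`` — one bit per binding-site residue position (85 positions in
  the standardized KLIFS numbering), recording whether the ligand interacts
  with that position at all;
* ``IFP_595`` — the expansion to 85 x 7 bits, one per (position,
  interaction-category) pair, permitting multiple interactions per residue;
* ``ECFP4_folded`` — hashed atom-environment identifiers folded to a fixed
  1024-bit vector by modulo mapping;
* ``ECFP4_unfolded`` — the variable-size feature set, one column per
  identifier observed anywhere in the dataset.

Bit indexing is 1-based in file formats and documentation, 0-based
internally; the 595-bit flattening is position-major (the seven category
bits of position p occupy characters 7(p-1)+1 .. 7(p-1)+7).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .modes import BindingMode

logger = logging.getLogger(__name__)

N_POSITIONS = 85
N_CATEGORIES = 7
IFP595_LENGTH = N_POSITIONS * N_CATEGORIES  # 595
ECFP_FOLDED_WIDTH = 1024

#: Ordered labels for the seven interaction categories (KLIFS convention).
#: The pipeline treats them as opaque categories 1-7; the names only affect
#: feature naming in reports.
CATEGORY_NAMES: tuple[str, ...] = (
    "hydrophobic",
    "aromatic_face",
    "aromatic_edge",
    "hbond_donor",
    "hbond_acceptor",
    "cationic",
    "anionic",
)


class RepresentationTag(str, enum.Enum):
    IFP_85 = "IFP_85"
    IFP_595 = "IFP_595"
    ECFP4_FOLDED = "ECFP4_folded"
    ECFP4_UNFOLDED = "ECFP4_unfolded"
    CONCAT = "CONCAT"

    def __str__(self) -> str:
        return self.value


@dataclasses.dataclass
class ResidueInteractionRecord:
    """Boolean interaction matrix of one complex structure (85 x 7 cells)."""

    structure_id: str
    inhibitor_id: str
    cells: np.ndarray  # bool, shape (85, 7)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (N_POSITIONS, N_CATEGORIES):
            raise ValueError(
                f"interaction record must be {N_POSITIONS} x {N_CATEGORIES}, "
                f"got {self.cells.shape}"
            )


@dataclasses.dataclass
class Fingerprint:
    """A named binary feature vector with its representation tag."""

    representation_tag: RepresentationTag
    bits: np.ndarray  # uint8 0/1 vector
    feature_names: list[str]

    # folded width is a parameter (default 1024), so only the IFP
    # geometries are structurally fixed
    _EXPECTED_LENGTHS = {
        RepresentationTag.IFP_85: N_POSITIONS,
        RepresentationTag.IFP_595: IFP595_LENGTH,
    }

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if len(self.bits) != len(self.feature_names):
            raise ValueError("feature_names must align with bits")
        expected = self._EXPECTED_LENGTHS.get(self.representation_tag)
        if expected is not None and len(self.bits) != expected:
            raise ValueError(
                f"{self.representation_tag} fingerprint must have {expected} bits, "
                f"got {len(self.bits)}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclasses.dataclass
class FingerprintDataset:
    """Row-aligned binary matrix with binding-mode labels."""

    matrix: np.ndarray  # uint8, (n_inhibitors, n_features)
    labels: list[BindingMode]
    inhibitor_ids: list[str]
    feature_names: list[str]
    representation_tag: RepresentationTag

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        n, d = self.matrix.shape
        if len(self.labels) != n or len(self.inhibitor_ids) != n:
            raise ValueError("labels and inhibitor_ids must align with matrix rows")
        if len(self.feature_names) != d:
            raise ValueError("feature_names must align with matrix columns")
        if len(set(self.inhibitor_ids)) != n:
            raise ValueError("duplicate inhibitor_ids")

    @property
    def n_inhibitors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def label_codes(self) -> np.ndarray:
        """Integer class codes 0/1/2 in canonical mode order."""
        from .modes import labels_to_codes

        return np.asarray(labels_to_codes(self.labels), dtype=np.int64)

    def row_fingerprint(self, i: int) -> Fingerprint:
        return Fingerprint(self.representation_tag, self.matrix[i], self.feature_names)


# ---------------------------------------------------------------------------
# IFP construction
# ---------------------------------------------------------------------------

def _ifp595_feature_names() -> list[str]:
    return [
        f"pos{p}:{CATEGORY_NAMES[c]}"
        for p in range(1, N_POSITIONS + 1)
        for c in range(N_CATEGORIES)
    ]


def _ifp85_feature_names() -> list[str]:
    return [f"pos{p}" for p in range(1, N_POSITIONS + 1)]


def build_ifp595(record: ResidueInteractionRecord) -> Fingerprint:
    """Flatten an interaction record into the 595-bit fingerprint (position-major)."""
    return Fingerprint(
        RepresentationTag.IFP_595,
        record.cells.reshape(-1).astype(np.uint8),
        _ifp595_feature_names(),
    )


def collapse_to_ifp85(ifp595: Fingerprint) -> Fingerprint:
    """Collapse a 595-bit fingerprint to 85 bits: bit p = OR over the 7
    category bits of position p."""
    if ifp595.representation_tag is not RepresentationTag.IFP_595:
        raise ValueError(f"expected an IFP_595 fingerprint, got {ifp595.representation_tag}")
    cells = ifp595.bits.reshape(N_POSITIONS, N_CATEGORIES)
    return Fingerprint(
        RepresentationTag.IFP_85,
        cells.any(axis=1).astype(np.uint8),
        _ifp85_feature_names(),
    )


def consensus_fingerprint(fps: Sequence[Fingerprint]) -> Fingerprint:
    """Per-bit majority vote over fingerprints of the same representation.

    An exact tie is resolved ON (an interaction observed in half of the
    structures is retained).
    """
    if len(fps) == 0:
        raise ValueError("consensus of an empty fingerprint list")
    tag = fps[0].representation_tag
    length = len(fps[0].bits)
    for fp in fps[1:]:
        if fp.representation_tag is not tag or len(fp.bits) != length:
            raise ValueError("consensus requires fingerprints of identical representation")
    stack = np.stack([fp.bits for fp in fps])
    # majority with tie -> ON: ON count * 2 >= number of fingerprints
    consensus = (2 * stack.sum(axis=0) >= len(fps)).astype(np.uint8)
    return Fingerprint(tag, consensus, list(fps[0].feature_names))


def build_ifp_datasets(cohort) -> tuple[FingerprintDataset, FingerprintDataset]:
    """Per-inhibitor consensus IFP_85 and IFP_595 datasets from a cohort.

    Each inhibitor's structures are flattened to 595-bit fingerprints; the
    85-bit fingerprints are collapsed per structure; if an inhibitor has
    several structures the consensus rule is applied independently for the
    two representations (so, under ties, the consensus 85-bit fingerprint
    is not necessarily the collapse of the consensus 595-bit fingerprint).
    """
    rows595 = []
    rows85 = []
    for inh in cohort.inhibitor_ids:
        records = cohort.interaction_records.get(inh)
        if not records:
            raise ValueError(f"inhibitor {inh} has no interaction records")
        fps595 = [build_ifp595(r) for r in records]
        fps85 = [collapse_to_ifp85(fp) for fp in fps595]
        rows595.append(consensus_fingerprint(fps595).bits if len(fps595) > 1 else fps595[0].bits)
        rows85.append(consensus_fingerprint(fps85).bits if len(fps85) > 1 else fps85[0].bits)
    ds85 = FingerprintDataset(
        np.stack(rows85),
        list(cohort.labels),
        list(cohort.inhibitor_ids),
        _ifp85_feature_names(),
        RepresentationTag.IFP_85,
    )
    ds595 = FingerprintDataset(
        np.stack(rows595),
        list(cohort.labels),
        list(cohort.inhibitor_ids),
        _ifp595_feature_names(),
        RepresentationTag.IFP_595,
    )
    return ds85, ds595


# ---------------------------------------------------------------------------
# atom-environment (ECFP-like) construction
# ---------------------------------------------------------------------------

def fold_features(feature_ids: Iterable[int], width: int = ECFP_FOLDED_WIDTH) -> Fingerprint:
    """Fold integer feature identifiers to a fixed-width bit vector.

    Bit ``j`` is set iff some identifier maps to it under modulo-``width``
    hashing; collisions simply OR together.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    bits = np.zeros(width, dtype=np.uint8)
    for fid in feature_ids:
        if fid < 0:
            raise ValueError(f"negative feature identifier {fid}")
        bits[fid % width] = 1
    names = [f"bit{j}" for j in range(width)]
    return Fingerprint(RepresentationTag.ECFP4_FOLDED, bits, names)


def build_folded_matrix(
    feature_sets: Mapping[str, set[int]],
    labels: Sequence[BindingMode],
    width: int = ECFP_FOLDED_WIDTH,
) -> FingerprintDataset:
    """Row-aligned dataset of modulo-folded fingerprints."""
    if not feature_sets:
        raise ValueError("empty feature-set mapping")
    ids = list(feature_sets)
    rows = np.zeros((len(ids), width), dtype=np.uint8)
    for i, inh in enumerate(ids):
        for fid in feature_sets[inh]:
            if fid < 0:
                raise ValueError(f"negative feature identifier {fid}")
            rows[i, fid % width] = 1
    return FingerprintDataset(
        rows,
        list(labels),
        ids,
        [f"bit{j}" for j in range(width)],
        RepresentationTag.ECFP4_FOLDED,
    )


def build_unfolded_matrix(
    feature_sets: Mapping[str, set[int]],
    labels: Sequence[BindingMode],
) -> FingerprintDataset:
    """Dataset over the unfolded (variable-size) feature vocabulary.

    The vocabulary is the sorted union of all identifiers across the
    dataset, fixed once before any splitting.
    """
    if not feature_sets:
        raise ValueError("empty feature-set mapping")
    ids = list(feature_sets)
    vocab = sorted(set().union(*feature_sets.values())) if any(feature_sets.values()) else []
    col = {fid: j for j, fid in enumerate(vocab)}
    rows = np.zeros((len(ids), len(vocab)), dtype=np.uint8)
    for i, inh in enumerate(ids):
        for fid in feature_sets[inh]:
            rows[i, col[fid]] = 1
    return FingerprintDataset(
        rows,
        list(labels),
        ids,
        [f"id{fid}" for fid in vocab],
        RepresentationTag.ECFP4_UNFOLDED,
    )


def build_ecfp_datasets(cohort, width: int = ECFP_FOLDED_WIDTH):
    """Folded and unfolded atom-environment datasets from a cohort."""
    sets = {inh: cohort.structural_features[inh] for inh in cohort.inhibitor_ids}
    folded = build_folded_matrix(sets, cohort.labels, width=width)
    unfolded = build_unfolded_matrix(sets, cohort.labels)
    return folded, unfolded


def concatenate(a: FingerprintDataset, b: FingerprintDataset) -> FingerprintDataset:
    """Column-wise concatenation of two row-aligned datasets."""
    if a.inhibitor_ids != b.inhibitor_ids:
        raise ValueError("datasets are not aligned on the same inhibitors")
    names = [f"{a.representation_tag}:{n}" for n in a.feature_names] + [
        f"{b.representation_tag}:{n}" for n in b.feature_names
    ]
    return FingerprintDataset(
        np.hstack([a.matrix, b.matrix]),
        list(a.labels),
        list(a.inhibitor_ids),
        names,
        RepresentationTag.CONCAT,
    )


# ---------------------------------------------------------------------------
# KLIFS-style bitstring I/O
# ---------------------------------------------------------------------------

class BitstringParseError(ValueError):
    pass


def read_klifs_bitstrings(path: str | Path) -> list[ResidueInteractionRecord]:
    """Read interaction records from a KLIFS-style TSV.

    Each data row holds ``structure_id``, ``inhibitor_id`` and a 595-character
    0/1 string in position-major order: characters 7(p-1)+1 .. 7(p-1)+7 are
    interaction categories 1..7 of position p.
    """
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("structure_id"):
            raise BitstringParseError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise BitstringParseError(f"{path}:{lineno}: expected 3 columns")
            structure_id, inhibitor_id, bitstring = parts
            if len(bitstring) != IFP595_LENGTH:
                raise BitstringParseError(
                    f"{path}:{lineno}: bitstring length {len(bitstring)} != {IFP595_LENGTH}"
                )
            if set(bitstring) - {"0", "1"}:
                raise BitstringParseError(f"{path}:{lineno}: non-0/1 character in bitstring")
            cells = (
                np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0")
            ).reshape(N_POSITIONS, N_CATEGORIES).astype(bool)
            records.append(ResidueInteractionRecord(structure_id, inhibitor_id, cells))
    return records


def write_klifs_bitstrings(
    records: Iterable[ResidueInteractionRecord], path: str | Path
) -> None:
    """Write interaction records in the KLIFS-style TSV format."""
    with open(path, "w") as fh:
        fh.write("structure_id\tinhibitor_id\tifp\n")
        for rec in records:
            bitstring = "".join(
                "1" if v else "0" for v in rec.cells.reshape(-1)
            )
            fh.write(f"{rec.structure_id}\t{rec.inhibitor_id}\t{bitstring}\n")


# ---------------------------------------------------------------------------
# dataset serialization (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def save_dataset(ds: FingerprintDataset, output_dir: str | Path) -> None:
    import scipy.io
    import scipy.sparse

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.csr_matrix(ds.matrix))
    with open(out / "rows.tsv", "w") as fh:
        fh.write("inhibitor_id\tbinding_mode\n")
        for inh, mode in zip(ds.inhibitor_ids, ds.labels):
            fh.write(f"{inh}\t{mode.value}\n")
    (out / "features.txt").write_text("\n".join(ds.feature_names) + "\n")
    (out / "representation.txt").write_text(ds.representation_tag.value + "\n")


def load_dataset(input_dir: str | Path) -> FingerprintDataset:
    import scipy.io

    from .modes import mode_from_label

    src = Path(input_dir)
    matrix = np.asarray(scipy.io.mmread(src / "matrix.mtx").todense(), dtype=np.uint8)
    ids, labels = [], []
    with open(src / "rows.tsv") as fh:
        next(fh)
        for line in fh:
            inh, label = line.rstrip("\n").split("\t")
            ids.append(inh)
            labels.append(mode_from_label(label))
    names = (src / "features.txt").read_text().splitlines()
    tag = RepresentationTag((src / "representation.txt").read_text().strip())
    return FingerprintDataset(matrix, labels, ids, names, tag)


# ---------------------------------------------------------------------------
# optional SMILES -> ECFP4 adapter
# ---------------------------------------------------------------------------

def compute_ecfp4(smiles_records: Iterable[tuple[str, str]]) -> dict[str, set[int]]:
    """Compute unfolded ECFP4 feature-identifier sets from SMILES.

    ``smiles_records`` yields ``(smiles, inhibitor_id)`` pairs. Atom
    environments of bond diameter 4 (Morgan radius 2) are enumerated and
    hashed by RDKit; the raw integer identifiers are returned. Unparsable
    SMILES are skipped with a warning and the skip count is logged.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
    out: dict[str, set[int]] = {}
    skipped = 0
    for smiles, inhibitor_id in smiles_records:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            logger.warning("unparsable SMILES for %s: %r", inhibitor_id, smiles)
            skipped += 1
            continue
        sparse = gen.GetSparseCountFingerprint(mol)
        out[inhibitor_id] = set(sparse.GetNonzeroElements())
    if skipped:
        logger.warning("skipped %d unparsable SMILES records", skipped)
    return out


def read_smiles_file(path: str | Path):
    """Yield (smiles, inhibitor_id, label) from a SMILES TSV."""
    from .modes import mode_from_label

    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            smiles, inhibitor_id, label = line.rstrip("\n").split("\t")
            yield smiles, inhibitor_id, mode_from_label(label)
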