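"""Fingerprint algebra: flattening, collapse, consensus, folding, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinmode as km
from kinmode.fingerprints import (
    IFP595_LENGTH,
    N_CATEGORIES,
    N_POSITIONS,
    BitstringParseError,
    Fingerprint,
    RepresentationTag,
    ResidueInteractionRecord,
    build_folded_matrix,
    build_ifp595,
    build_unfolded_matrix,
    load_dataset,
    read_klifs_bitstrings,
    save_dataset,
    write_klifs_bitstrings,
)
from kinmode.modes import BindingMode


def record_from_cells(cells, structure_id="s1", inhibitor_id="i1"):
    return ResidueInteractionRecord(structure_id, inhibitor_id, cells)


def random_record(seed, density=0.2):
    rng = np.random.default_rng(seed)
    return record_from_cells(rng.random((N_POSITIONS, N_CATEGORIES)) < density)


class TestIfp595:
    def test_all_false_gives_zeros(self):
        fp = build_ifp595(record_from_cells(np.zeros((85, 7), dtype=bool)))
        assert fp.popcount() == 0
        assert len(fp.bits) == IFP595_LENGTH

    def test_position_major_flattening(self):
        # categories {2, 5} at position 10 -> 1-based bits 7*9+2 and 7*9+5
        cells = np.zeros((85, 7), dtype=bool)
        cells[9, 1] = cells[9, 4] = True
        fp = build_ifp595(record_from_cells(cells))
        assert set(np.flatnonzero(fp.bits) + 1) == {7 * 9 + 2, 7 * 9 + 5}

    @pytest.mark.parametrize("seed", range(5))
    def test_popcount_equals_true_cells(self, seed):
        rec = random_record(seed)
        assert build_ifp595(rec).popcount() == rec.cells.sum()


class TestCollapse:
    def test_zeros_collapse_to_zeros(self):
        fp = build_ifp595(record_from_cells(np.zeros((85, 7), dtype=bool)))
        assert km.collapse_to_ifp85(fp).popcount() == 0

    def test_single_category_sets_single_position(self):
        cells = np.zeros((85, 7), dtype=bool)
        cells[41, 3] = True
        fp85 = km.collapse_to_ifp85(build_ifp595(record_from_cells(cells)))
        assert set(np.flatnonzero(fp85.bits) + 1) == {42}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_or_reduce_oracle(self, seed):
        rec = random_record(seed)
        fp85 = km.collapse_to_ifp85(build_ifp595(rec))
        # independent oracle: direct row-wise OR over the record cells
        oracle = np.array(
            [any(rec.cells[p, c] for c in range(7)) for p in range(85)], dtype=np.uint8
        )
        np.testing.assert_array_equal(fp85.bits, oracle)

    def test_wrong_tag_rejected(self):
        fp = Fingerprint(RepresentationTag.IFP_85, np.zeros(85, np.uint8),
                         [f"p{i}" for i in range(85)])
        with pytest.raises(ValueError):
            km.collapse_to_ifp85(fp)


def _fp(bits):
    bits = np.asarray(bits, dtype=np.uint8)
    return Fingerprint(RepresentationTag.CONCAT, bits,
                       [f"f{i}" for i in range(len(bits))])


class TestConsensus:
    def test_tie_is_set_on(self):
        out = km.consensus_fingerprint([_fp([1, 0]), _fp([0, 0])])
        np.testing.assert_array_equal(out.bits, [1, 0])

    def test_majority_wins(self):
        on = km.consensus_fingerprint([_fp([1]), _fp([1]), _fp([0])])
        off = km.consensus_fingerprint([_fp([0]), _fp([0]), _fp([1])])
        assert on.bits[0] == 1 and off.bits[0] == 0

    def test_single_input_is_identity(self):
        fp = _fp([1, 0, 1, 1])
        np.testing.assert_array_equal(km.consensus_fingerprint([fp]).bits, fp.bits)

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            km.consensus_fingerprint([])
        fp85 = Fingerprint(RepresentationTag.IFP_85, np.zeros(85, np.uint8),
                           [f"p{i}" for i in range(85)])
        with pytest.raises(ValueError):
            km.consensus_fingerprint([fp85, _fp([0] * 85)])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(0, 1), min_size=6, max_size=6),
            min_size=1,
            max_size=7,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_replication_idempotence(self, rows, rnd):
        fps = [_fp(r) for r in rows]
        base = km.consensus_fingerprint(fps).bits
        shuffled = list(fps)
        rnd.shuffle(shuffled)
        np.testing.assert_array_equal(km.consensus_fingerprint(shuffled).bits, base)
        np.testing.assert_array_equal(km.consensus_fingerprint(fps * 3).bits, base)


class TestFolding:
    def test_modulo_collision(self):
        fp = km.fold_features({6, 1030}, width=1024)
        assert set(np.flatnonzero(fp.bits)) == {6}

    def test_empty_set_folds_to_zeros(self):
        assert km.fold_features(set(), width=1024).popcount() == 0

    def test_boundary_identifiers(self):
        fp = km.fold_features({0, 1023, 1024}, width=1024)
        assert set(np.flatnonzero(fp.bits)) == {0, 1023}

    def test_negative_id_rejected(self):
        with pytest.raises(ValueError):
            km.fold_features({-1})

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.integers(0, 5000), max_size=40),
        st.sets(st.integers(0, 5000), max_size=40),
    )
    def test_fold_of_union_is_or_of_folds(self, s, t):
        width = 64
        union = km.fold_features(s | t, width).bits
        ored = km.fold_features(s, width).bits | km.fold_features(t, width).bits
        np.testing.assert_array_equal(union, ored)


class TestMatrices:
    def test_unfolded_vocabulary_and_rows(self):
        ds = build_unfolded_matrix(
            {"a": {1, 2}, "b": {2, 3}},
            [BindingMode.TYPE_I, BindingMode.TYPE_II],
        )
        assert ds.feature_names == ["id1", "id2", "id3"]
        np.testing.assert_array_equal(ds.matrix, [[1, 1, 0], [0, 1, 1]])

    def test_row_sums_equal_set_sizes(self):
        rng = np.random.default_rng(0)
        sets = {f"i{k}": set(rng.choice(500, rng.integers(0, 60), replace=False).tolist())
                for k in range(20)}
        ds = build_unfolded_matrix(sets, [BindingMode.TYPE_I] * 20)
        for k, inh in enumerate(ds.inhibitor_ids):
            assert ds.matrix[k].sum() == len(sets[inh])

    def test_identical_sets_identical_rows(self):
        ds = build_unfolded_matrix(
            {"a": {5, 9}, "b": {5, 9}}, [BindingMode.TYPE_I, BindingMode.TYPE_I]
        )
        np.testing.assert_array_equal(ds.matrix[0], ds.matrix[1])

    def test_folded_matrix_matches_fold_features(self):
        sets = {"a": {6, 1030, 77}, "b": {2048}}
        ds = build_folded_matrix(sets, [BindingMode.TYPE_I, BindingMode.TYPE_II])
        for i, inh in enumerate(ds.inhibitor_ids):
            np.testing.assert_array_equal(ds.matrix[i], km.fold_features(sets[inh]).bits)

    def test_concatenate_shapes_and_popcounts(self, quarter_datasets):
        a, b = quarter_datasets["ifp85"], quarter_datasets["ecfp_folded"]
        cat = km.concatenate(a, b)
        assert cat.n_features == a.n_features + b.n_features == 85 + 1024
        np.testing.assert_array_equal(
            cat.matrix.sum(axis=1), a.matrix.sum(axis=1) + b.matrix.sum(axis=1)
        )
        assert cat.representation_tag is RepresentationTag.CONCAT

    def test_concatenate_misaligned_rejected(self, quarter_datasets):
        a = quarter_datasets["ifp85"]
        b = quarter_datasets["ecfp_folded"]
        flipped = km.FingerprintDataset(
            b.matrix[::-1].copy(), list(reversed(b.labels)),
            list(reversed(b.inhibitor_ids)), b.feature_names, b.representation_tag,
        )
        with pytest.raises(ValueError):
            km.concatenate(a, flipped)


class TestCohortDatasets:
    def test_single_structure_rows_equal_fingerprints(self, tiny_config):
        import dataclasses

        config = dataclasses.replace(tiny_config, structures_per_inhibitor=1)
        cohort = km.generate_dataset(config, seed=3)
        ds85, ds595 = km.build_ifp_datasets(cohort)
        for i, inh in enumerate(cohort.inhibitor_ids):
            rec = cohort.interaction_records[inh][0]
            np.testing.assert_array_equal(ds595.matrix[i], build_ifp595(rec).bits)
        assert ds85.n_inhibitors == len(cohort)

    def test_no_noise_consensus_equals_single_structure(self, tiny_config):
        import dataclasses

        config = dataclasses.replace(tiny_config, structure_noise=0.0)
        cohort = km.generate_dataset(config, seed=4)
        ds85, ds595 = km.build_ifp_datasets(cohort)
        for i, inh in enumerate(cohort.inhibitor_ids):
            rec = cohort.interaction_records[inh][0]
            fp595 = build_ifp595(rec)
            np.testing.assert_array_equal(ds595.matrix[i], fp595.bits)
            np.testing.assert_array_equal(
                ds85.matrix[i], km.collapse_to_ifp85(fp595).bits
            )


class TestKlifsBitstrings:
    def test_round_trip(self, tmp_path, tiny_config):
        cohort = km.generate_dataset(tiny_config, seed=8)
        records = [r for inh in cohort.inhibitor_ids
                   for r in cohort.interaction_records[inh]]
        path = tmp_path / "ifp.tsv"
        write_klifs_bitstrings(records, path)
        loaded = read_klifs_bitstrings(path)
        assert len(loaded) == len(records)
        for a, b in zip(records, loaded):
            assert (a.structure_id, a.inhibitor_id) == (b.structure_id, b.inhibitor_id)
            np.testing.assert_array_equal(a.cells, b.cells)

    def test_first_character_is_position1_category1(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text(
            "structure_id\tinhibitor_id\tifp\ns\ti\t" + "1" + "0" * 594 + "\n"
        )
        (rec,) = read_klifs_bitstrings(path)
        assert rec.cells[0, 0]
        assert rec.cells.sum() == 1

    @pytest.mark.parametrize(
        "bitstring", ["0" * 594, "0" * 596, "0" * 594 + "2"],
        ids=["too-short", "too-long", "bad-char"],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, bitstring):
        path = tmp_path / "bad.tsv"
        path.write_text(f"structure_id\tinhibitor_id\tifp\ns\ti\t{bitstring}\n")
        with pytest.raises(BitstringParseError, match=":2"):
            read_klifs_bitstrings(path)


class TestDatasetSerialization:
    def test_mtx_round_trip(self, tmp_path, quarter_datasets):
        ds = quarter_datasets["ifp85"]
        save_dataset(ds, tmp_path)
        loaded = load_dataset(tmp_path)
        np.testing.assert_array_equal(loaded.matrix, ds.matrix)
        assert loaded.labels == ds.labels
        assert loaded.inhibitor_ids == ds.inhibitor_ids
        assert loaded.representation_tag is ds.representation_tag


class TestEcfpAdapter:
    def test_known_molecules(self):
        pytest.importorskip("rdkit")
        out = km.fingerprints.compute_ecfp4(
            [("C", "methane"), ("CCO", "ethanol"), ("CCO", "ethanol2")]
        )
        assert len(out["methane"]) >= 1
        assert out["ethanol"] == out["ethanol2"]

    def test_unparsable_smiles_skipped(self):
        pytest.importorskip("rdkit")
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
        out = km.fingerprints.compute_ecfp4([("not_a_smiles((", "bad"), ("CCO", "ok")])
        assert set(out) == {"ok"}

    def test_empty_input(self):
        pytest.importorskip("rdkit")
        assert km.fingerprints.compute_ecfp4([]) == {}
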