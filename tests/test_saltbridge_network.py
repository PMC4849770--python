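import numpy as np
import pytest

from pmhcdyn import (
    BridgeSchedule,
    SaltBridgeMatrix,
    SyntheticSpec,
    adjacency_matrix,
    align_matrices,
    count_bridges,
    distance_series,
    find_candidate_pairs,
    frobenius_distance,
    frobenius_inner,
    generate_ensemble,
    intermolecular_submatrix,
    toy_complex_topology,
)
from pmhcdyn.io_model import AtomRecord, Ensemble, Topology


def _two_residue_system(on_distance: float, od2_extra: float = 2.0) -> Ensemble:
    """One Asp and one Lys with OD1 placed `on_distance` Å from NZ."""
    atoms = [
        AtomRecord(1, "CB", "ASP", 1, "A", "C", 12.011),
        AtomRecord(2, "OD1", "ASP", 1, "A", "O", 15.999),
        AtomRecord(3, "OD2", "ASP", 1, "A", "O", 15.999),
        AtomRecord(4, "CB", "LYS", 2, "A", "C", 12.011),
        AtomRecord(5, "NZ", "LYS", 2, "A", "N", 14.007),
    ]
    coords = np.array(
        [
            [
                [-1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, od2_extra, 0.0],  # OD2 farther from NZ
                [on_distance + 1.0, 0.0, 0.0],
                [on_distance, 0.0, 0.0],
            ]
        ]
    )
    return Ensemble(topology=Topology(atoms), coordinates=coords)


def _random_matrix(rng, n=5, m=5) -> SaltBridgeMatrix:
    return SaltBridgeMatrix(
        row_labels=tuple(f"A:ASP{i}" for i in range(n)),
        col_labels=tuple(f"A:LYS{j}" for j in range(m)),
        weights=rng.uniform(0, 0.35, size=(n, m)),
    )


class TestFindCandidatePairs:
    def test_pair_within_cutoff_detected(self):
        ens = _two_residue_system(3.0)
        pairs = find_candidate_pairs(ens)
        assert len(pairs) == 1
        assert pairs[0].acidic.residue_name == "ASP"
        assert pairs[0].basic.residue_name == "LYS"

    def test_pair_beyond_cutoff_excluded(self):
        assert find_candidate_pairs(_two_residue_system(9.0)) == []
        assert len(find_candidate_pairs(_two_residue_system(8.0))) == 1  # boundary inclusive

    def test_no_charged_residues_empty(self):
        atoms = [AtomRecord(1, "CA", "ALA", 1, "A", "C", 12.011)]
        ens = Ensemble(topology=Topology(atoms), coordinates=np.zeros((1, 1, 3)))
        assert find_candidate_pairs(ens) == []

    def test_matches_exhaustive_all_pairs_scan(self):
        topo, mean = toy_complex_topology(6, 2, 5, charged_fraction=1.0, seed=3)
        spec = SyntheticSpec(topology=topo, mean_coordinates=mean, n_frames=5,
                             noise_sigma=0.3, seed=4)
        ens = generate_ensemble(spec)
        pairs = find_candidate_pairs(ens, cutoff=8.0)
        got = {(p.acidic.residue_key, p.basic.residue_key) for p in pairs}
        # brute force: all acidic x basic groups, all frames, all member atoms
        expected = set()
        acidics = [g for g in topo.charged_groups if g.polarity == "acidic"]
        basics = [g for g in topo.charged_groups if g.polarity == "basic"]
        for ag in acidics:
            for bg in basics:
                dmin = np.inf
                for t in range(ens.n_frames):
                    for i in ag.atom_indices:
                        for j in bg.atom_indices:
                            dmin = min(dmin, np.linalg.norm(
                                ens.coordinates[t, i] - ens.coordinates[t, j]))
                if dmin <= 8.0:
                    expected.add((ag.residue_key, bg.residue_key))
        assert got == expected


class TestDistanceSeries:
    def test_min_rule_over_member_atoms(self):
        ens = _two_residue_system(3.0, od2_extra=4.0)
        (pair,) = find_candidate_pairs(ens)
        ser = distance_series(ens, pair)
        assert ser.values[0] == pytest.approx(3.0)

    def test_schedule_reproduced(self):
        topo, mean = toy_complex_topology(6, 2, 5, charged_fraction=1.0, seed=3)
        acid = next(g for g in topo.charged_groups if g.polarity == "acidic")
        base = next(g for g in topo.charged_groups
                    if g.polarity == "basic" and g.chain_id != acid.chain_id)
        sched = BridgeSchedule(acidic_key=acid.residue_key, basic_key=base.residue_key,
                               formed_distance=2.8, broken_distance=6.0,
                               formed_fraction=0.5, pattern="block")
        spec = SyntheticSpec(topology=topo, mean_coordinates=mean, n_frames=8,
                             schedules=[sched], seed=5)
        ens = generate_ensemble(spec)
        pair = next(p for p in find_candidate_pairs(ens)
                    if p.acidic.residue_key == acid.residue_key
                    and p.basic.residue_key == base.residue_key)
        ser = distance_series(ens, pair)
        np.testing.assert_allclose(ser.values[:4], 2.8, atol=1e-10)
        np.testing.assert_allclose(ser.values[4:], 6.0, atol=1e-10)

    def test_single_frame_series(self):
        ens = _two_residue_system(3.5)
        (pair,) = find_candidate_pairs(ens)
        assert len(distance_series(ens, pair).values) == 1


class TestAdjacencyMatrix:
    def test_constant_distance_inverse(self):
        ens = _two_residue_system(4.0)
        pairs = find_candidate_pairs(ens)
        m = adjacency_matrix(ens, pairs)
        assert m.weights[0, 0] == pytest.approx(0.25)
        assert not m.normalized

    def test_tight_contact_reaches_scale_cap(self):
        """A permanent 2.86 Å contact weighs ≈0.35 1/Å, the top of the
        conventional grey scale for these matrices."""
        ens = _two_residue_system(2.86)
        m = adjacency_matrix(ens, find_candidate_pairs(ens))
        assert m.weights[0, 0] == pytest.approx(0.35, abs=0.005)

    def test_matches_brute_force_mean_of_reciprocals(self):
        topo, mean = toy_complex_topology(6, 2, 5, charged_fraction=1.0, seed=6)
        spec = SyntheticSpec(topology=topo, mean_coordinates=mean, n_frames=20,
                             noise_sigma=0.2, seed=7)
        ens = generate_ensemble(spec)
        pairs = find_candidate_pairs(ens)
        m = adjacency_matrix(ens, pairs)
        df = m.to_dataframe()
        for p in pairs:
            ser = distance_series(ens, p)
            expected = np.mean([1.0 / d for d in ser.values])
            assert df.loc[p.acidic.label, p.basic.label] == pytest.approx(expected, rel=1e-12)

    def test_normalization_recorded(self):
        ens = _two_residue_system(2.8)
        m = adjacency_matrix(ens, find_candidate_pairs(ens), normalize=True)
        assert m.normalized
        assert m.weights[0, 0] == pytest.approx(1.0)
        assert m.normalization_constant == pytest.approx(1 / 2.8)


class TestFrobenius:
    def test_inner_product_identity(self):
        eye = SaltBridgeMatrix(("r1", "r2"), ("c1", "c2"), np.eye(2))
        assert frobenius_inner(eye, eye) == pytest.approx(2.0)

    def test_inner_product_orthogonal_supports(self):
        a = SaltBridgeMatrix(("r1", "r2"), ("c1", "c2"), np.array([[1.0, 0], [0, 0]]))
        b = SaltBridgeMatrix(("r1", "r2"), ("c1", "c2"), np.array([[0, 0], [0, 2.0]]))
        assert frobenius_inner(a, b) == 0.0

    def test_inner_matches_double_loop(self):
        rng = np.random.default_rng(12)
        a, b = _random_matrix(rng), _random_matrix(rng)
        expected = sum(
            a.weights[i, j] * b.weights[i, j] for i in range(5) for j in range(5)
        )
        assert frobenius_inner(a, b) == pytest.approx(expected, rel=1e-12)

    def test_self_distance_zero(self):
        rng = np.random.default_rng(13)
        m = _random_matrix(rng)
        assert frobenius_distance(m, m) == 0.0

    def test_orthogonal_unit_matrices_sqrt2(self):
        a = SaltBridgeMatrix(("r1", "r2"), ("c1", "c2"), np.array([[3.0, 0], [0, 0]]))
        b = SaltBridgeMatrix(("r1", "r2"), ("c1", "c2"), np.array([[0, 0], [0, 5.0]]))
        assert frobenius_distance(a, b) == pytest.approx(np.sqrt(2.0))

    def test_scale_invariance_of_normalized_distance(self):
        rng = np.random.default_rng(14)
        a, b = _random_matrix(rng), _random_matrix(rng)
        scaled = SaltBridgeMatrix(a.row_labels, a.col_labels, 7.3 * a.weights)
        assert frobenius_distance(scaled, b) == pytest.approx(frobenius_distance(a, b), rel=1e-12)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(15)
        for _ in range(200):
            a, b, c = (_random_matrix(rng) for _ in range(3))
            dab = frobenius_distance(a, b)
            assert dab == pytest.approx(frobenius_distance(b, a), rel=1e-12)
            assert dab + frobenius_distance(b, c) >= frobenius_distance(a, c) - 1e-12

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(16)
        a = _random_matrix(rng, 2, 2)
        b = SaltBridgeMatrix(("X:GLU1",), ("X:ARG2",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="align"):
            frobenius_distance(a, b)

    def test_both_zero_matrices_distance_zero(self):
        z = SaltBridgeMatrix(("r1",), ("c1",), np.zeros((1, 1)))
        assert frobenius_distance(z, z) == 0.0

    def test_invariant_under_common_permutation(self):
        rng = np.random.default_rng(17)
        a, b = _random_matrix(rng), _random_matrix(rng)
        perm_r = rng.permutation(5)
        perm_c = rng.permutation(5)

        def permute(m):
            return SaltBridgeMatrix(
                tuple(m.row_labels[i] for i in perm_r),
                tuple(m.col_labels[j] for j in perm_c),
                m.weights[np.ix_(perm_r, perm_c)],
            )

        assert frobenius_distance(permute(a), permute(b)) == pytest.approx(
            frobenius_distance(a, b), rel=1e-12
        )


class TestAlignMatrices:
    def test_identical_labels_unchanged(self):
        rng = np.random.default_rng(18)
        a, b = _random_matrix(rng), _random_matrix(rng)
        aa, bb = align_matrices(a, b)
        np.testing.assert_array_equal(aa.weights, a.weights)
        np.testing.assert_array_equal(bb.weights, b.weights)

    def test_disjoint_labels_block_padded(self):
        a = SaltBridgeMatrix(("r1",), ("c1",), np.array([[1.0]]))
        b = SaltBridgeMatrix(("r2",), ("c2",), np.array([[2.0]]))
        aa, bb = align_matrices(a, b)
        assert aa.row_labels == ("r1", "r2")
        np.testing.assert_array_equal(aa.weights, [[1.0, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(bb.weights, [[0.0, 0.0], [0.0, 2.0]])

    def test_partial_overlap_union_dimension(self):
        a = SaltBridgeMatrix(("r1", "r2"), ("c1",), np.ones((2, 1)))
        b = SaltBridgeMatrix(("r2", "r3"), ("c1", "c2"), np.ones((2, 2)))
        aa, bb = align_matrices(a, b)
        assert aa.weights.shape == (3, 2)
        assert set(aa.row_labels) == {"r1", "r2", "r3"}


class TestIntermolecular:
    def _mixed_matrix_and_topology(self):
        topo, mean = toy_complex_topology(6, 2, 5, charged_fraction=1.0, seed=19)
        spec = SyntheticSpec(topology=topo, mean_coordinates=mean, n_frames=3,
                             noise_sigma=0.1, seed=20)
        ens = generate_ensemble(spec)
        pairs = find_candidate_pairs(ens, cutoff=20.0)  # wide: include A-C pairs
        return topo, ens, pairs

    def test_only_interface_entries_survive(self):
        topo, ens, pairs = self._mixed_matrix_and_topology()
        m = adjacency_matrix(ens, pairs)
        inter = intermolecular_submatrix(m, topo)
        df_full, df_inter = m.to_dataframe(), inter.to_dataframe()
        role = topo.chain_roles
        for r in df_full.index:
            for c in df_full.columns:
                chains = {r.split(":")[0], c.split(":")[0]}
                spans = any(role[ch] in ("receptor_alpha", "receptor_beta") for ch in chains) and any(
                    role[ch] in ("presenter", "peptide") for ch in chains
                )
                if spans:
                    assert df_inter.loc[r, c] == df_full.loc[r, c]
                else:
                    assert df_inter.loc[r, c] == 0.0

    def test_intramolecular_only_matrix_zeroed(self):
        topo, ens, pairs = self._mixed_matrix_and_topology()
        intra = [p for p in pairs if not p.intermolecular]
        m = adjacency_matrix(ens, intra)
        inter = intermolecular_submatrix(m, topo)
        np.testing.assert_array_equal(inter.weights, 0.0)

    def test_unresolvable_label_rejected(self):
        topo, _, _ = self._mixed_matrix_and_topology()
        m = SaltBridgeMatrix(("Z:ASP1",), ("A:LYS2",), np.array([[0.1]]))
        with pytest.raises(ValueError, match="unknown chain"):
            intermolecular_submatrix(m, topo)


class TestCountBridges:
    def test_permanent_contact_counted(self):
        ens = _two_residue_system(2.8)
        pairs = find_candidate_pairs(ens)
        n, occ = count_bridges(ens, pairs)
        assert n == 1
        assert list(occ.values()) == [1.0]

    def test_contact_above_cutoff_not_counted(self):
        ens = _two_residue_system(3.3)
        pairs = find_candidate_pairs(ens)
        n, occ = count_bridges(ens, pairs)
        assert n == 0
        assert list(occ.values()) == [0.0]

    def test_scheduled_occupancy_exact(self):
        topo, mean = toy_complex_topology(6, 2, 5, charged_fraction=1.0, seed=21)
        acid = next(g for g in topo.charged_groups if g.polarity == "acidic")
        base = next(g for g in topo.charged_groups
                    if g.polarity == "basic" and g.residue_key != acid.residue_key)
        sched = BridgeSchedule(acidic_key=acid.residue_key, basic_key=base.residue_key,
                               formed_fraction=0.6, pattern="block")
        spec = SyntheticSpec(topology=topo, mean_coordinates=mean, n_frames=10,
                             schedules=[sched], seed=22)
        ens = generate_ensemble(spec)
        pair = next(p for p in find_candidate_pairs(ens)
                    if p.acidic.residue_key == acid.residue_key
                    and p.basic.residue_key == base.residue_key)
        n, occ = count_bridges(ens, [pair])
        assert occ[pair.label] == pytest.approx(0.6)
        assert n == 1
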