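"""Composition arithmetic and minimum-distance aggregation networks."""

import numpy as np
import pytest

from sugarcg import aggregation as agg
from sugarcg.synthetic_fixtures import gen_clustered_config
from sugarcg.traj_project import Trajectory


class TestComposition:
    def test_printed_system_evaluates_to_50_g_per_l(self):
        conc = agg.concentration_of(20, 342.30, 7609, 18.015)
        assert round(conc) == 50

    def test_water_bead_mapping(self):
        assert agg.cg_water_beads(7609) == 1902
        assert agg.cg_water_beads(0) == 0
        for k in (1, 17, 475):
            assert agg.cg_water_beads(4 * k) == k

    def test_inversion_gives_7600ish(self):
        waters = agg.waters_for_concentration(20, 342.30, 50.0, 18.015)
        assert abs(waters - 7600) <= 1

    def test_scale_invariance(self):
        a = agg.concentration_of(20, 342.30, 7609)
        b = agg.concentration_of(40, 342.30, 15218)
        assert a == pytest.approx(b)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            agg.concentration_of(0, 342.30, 7609)
        with pytest.raises(ValueError):
            agg.waters_for_concentration(20, -1.0, 50.0)

    def test_composition_spec_helper(self):
        spec = agg.CompositionSpec.for_concentration(20)
        assert spec.cg_beads == spec.aa_waters // 4
        assert round(agg.concentration_of(20, spec.mw_solute, spec.aa_waters)) == 50


class TestMinImageDistance:
    def test_plain_pair(self):
        d = agg.min_intermolecular_distance(
            np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 0.3]]), (10, 10, 10))
        assert d == pytest.approx(0.3)

    def test_across_periodic_boundary(self):
        d = agg.min_intermolecular_distance(
            np.array([[0.05, 0, 0]]), np.array([[4.95, 0, 0]]), (5, 5, 5))
        assert d == pytest.approx(0.1)

    def test_matches_27_image_brute_force(self, rng):
        box = np.array([3.0, 4.0, 5.0])
        a = rng.uniform(0, box, size=(6, 3))
        b = rng.uniform(0, box, size=(8, 3))
        got = agg.min_intermolecular_distance(a, b, box)
        best = np.inf
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    shift = box * np.array([sx, sy, sz])
                    d = np.linalg.norm(a[:, None] - (b + shift)[None], axis=-1).min()
                    best = min(best, d)
        assert got == pytest.approx(best, abs=1e-12)

    def test_matches_mdanalysis_distance_array(self, rng):
        from MDAnalysis.lib.distances import distance_array

        box = np.array([4.0, 4.0, 4.0])
        a = rng.uniform(0, 4, size=(5, 3))
        b = rng.uniform(0, 4, size=(7, 3))
        got = agg.min_intermolecular_distance(a, b, box)
        mda_box = np.array([4.0, 4.0, 4.0, 90.0, 90.0, 90.0], dtype=np.float32)
        want = distance_array(a.astype(np.float32), b.astype(np.float32),
                              box=mda_box).min()
        assert got == pytest.approx(want, abs=1e-5)

    def test_triclinic_rejected(self):
        with pytest.raises(ValueError, match="orthorhombic"):
            agg.min_intermolecular_distance(
                np.zeros((1, 3)), np.ones((1, 3)), np.eye(3))

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            agg.min_intermolecular_distance(np.zeros((0, 3)), np.ones((1, 3)),
                                            (5, 5, 5))


class TestAggregateSizes:
    def test_all_far_apart_gives_singletons(self):
        mols, box = gen_clustered_config(20, [1] * 20, gap=1.0, box=(10.0,) * 3)
        rec = agg.aggregate_sizes(mols, box)
        assert rec.sizes == (1,) * 20

    def test_chain_is_transitively_connected(self):
        # A-B-C chain where A and C are beyond the cutoff from each other
        mols = [np.array([[0.0, 0, 0]]), np.array([[0.4, 0, 0]]),
                np.array([[0.8, 0, 0]])]
        rec = agg.aggregate_sizes(mols, (10, 10, 10))
        assert rec.sizes == (3,)

    @pytest.mark.parametrize("planted", [[5, 15], [9, 11], [2] * 10])
    def test_planted_partitions_recovered(self, planted):
        mols, box = gen_clustered_config(sum(planted), planted, gap=1.0,
                                         box=(8.0,) * 3, seed=7)
        rec = agg.aggregate_sizes(mols, box)
        assert rec.sizes == tuple(sorted(planted, reverse=True))

    def test_sizes_sum_to_molecule_count(self, rng):
        mols = [rng.uniform(0, 5, size=(3, 3)) for _ in range(20)]
        rec = agg.aggregate_sizes(mols, (5, 5, 5))
        assert rec.n_molecules == 20

    def test_aggregate_count_monotone_in_cutoff(self, rng):
        mols = [rng.uniform(0, 6, size=(2, 3)) for _ in range(15)]
        box = (6.0, 6.0, 6.0)
        prev = None
        for cutoff in np.linspace(0.3, 1.0, 8):
            n = len(agg.aggregate_sizes(mols, box, cutoff=cutoff).sizes)
            if prev is not None:
                assert n <= prev
            prev = n

    def test_edges_are_exactly_the_below_cutoff_pairs(self, rng):
        mols = [rng.uniform(0, 4, size=(2, 3)) for _ in range(10)]
        box = np.array([4.0, 4.0, 4.0])
        g = agg.distance_network(mols, box, cutoff=0.9)
        for i in range(10):
            for j in range(i + 1, 10):
                d = agg.min_intermolecular_distance(mols[i], mols[j], box)
                assert g.has_edge(i, j) == (d <= 0.9), (i, j, d)


def _static_traj(mols, box, n_frames=6, dt=100.0):
    coords = np.concatenate([m for m in mols], axis=0)
    sizes = [len(m) for m in mols]
    starts = np.cumsum([0] + sizes[:-1])
    groups = [np.arange(s, s + k) for s, k in zip(starts, sizes)]
    traj = Trajectory(coords=np.repeat(coords[None], n_frames, axis=0),
                      box=np.asarray(box, float),
                      times=np.arange(n_frames) * dt)
    return traj, groups


class TestDistributionsAndEvolution:
    def test_static_fixture_is_point_mass(self):
        mols, box = gen_clustered_config(20, [9, 11], gap=1.0, box=(8.0,) * 3)
        traj, groups = _static_traj(mols, box)
        records = agg.aggregate_records(traj, groups)
        hist = agg.size_distribution(records)
        assert hist.loc[9] == 6 and hist.loc[11] == 6
        assert hist.drop([9, 11]).sum() == 0

    def test_window_and_stride_selection(self):
        mols, box = gen_clustered_config(4, [2, 2], gap=1.0, box=(6.0,) * 3)
        traj, groups = _static_traj(mols, box, n_frames=11, dt=100.0)
        records = agg.aggregate_records(traj, groups)
        # last 500 ps at 100 ps stride -> 6 frames, two dimers each
        hist = agg.size_distribution(records, window_ps=500.0, stride_ps=100.0)
        assert hist.loc[2] == 12
        with pytest.raises(ValueError, match="window"):
            agg.size_distribution(records, window_ps=5000.0)

    def test_replica_pooling_adds_counts(self):
        mols, box = gen_clustered_config(6, [3, 3], gap=1.0, box=(6.0,) * 3)
        traj, groups = _static_traj(mols, box, n_frames=4)
        records = agg.aggregate_records(traj, groups)
        single = agg.size_distribution(records)
        pooled = agg.size_distribution([records, records, records])
        assert (pooled == 3 * single).all()

    def test_time_evolution_series(self):
        mols, box = gen_clustered_config(20, [20], gap=1.0, box=(8.0,) * 3)
        traj, groups = _static_traj(mols, box, n_frames=5)
        ev = agg.time_evolution(agg.aggregate_records(traj, groups))
        assert len(ev) == 5
        assert (ev["largest"] == 20).all()
        assert (ev["n_aggregates"] == 1).all()
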