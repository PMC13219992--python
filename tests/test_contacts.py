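import numpy as np
import pytest

import posestab as ps
from posestab.errors import NoNativeContactsError, WindowError
from tests.conftest import make_pair_topology, random_system


def _structure(topo, coords):
    return ps.Structure(topo, np.asarray(coords, dtype=float))


def _sels(topo):
    return (
        ps.select_atoms(topo, "protein and heavy"),
        ps.select_atoms(topo, "ligand and heavy"),
    )


class TestIdentifyNativeContacts:
    def test_single_pair_stores_r0(self):
        topo = make_pair_topology(1, 1)
        s = _structure(topo, [[0, 0, 0], [3.0, 0, 0]])
        cs = ps.identify_native_contacts(s, *_sels(topo))
        assert cs.n_contacts == 1
        assert cs.pairs[0].r0 == pytest.approx(3.0)

    def test_cutoff_is_strict(self):
        topo = make_pair_topology(1, 1)
        s = _structure(topo, [[0, 0, 0], [4.5, 0, 0]])
        with pytest.raises(NoNativeContactsError):
            ps.identify_native_contacts(s, *_sels(topo))

    def test_all_pairs_brute_force(self):
        # 3 protein x 2 ligand atoms all within 4.0 A -> 6 sorted pairs
        rng = np.random.default_rng(1)
        topo = make_pair_topology(3, 2)
        coords = np.vstack([rng.uniform(0, 1.5, (3, 3)), rng.uniform(1.0, 2.5, (2, 3))])
        s = _structure(topo, coords)
        cs = ps.identify_native_contacts(s, *_sels(topo))
        # independent brute force
        expected = []
        for i in range(3):
            for j in range(3, 5):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d < 4.5:
                    expected.append((i, j, d))
        assert len(cs.pairs) == len(expected) == 6
        got = [(p.protein_atom, p.ligand_atom, p.r0) for p in cs.pairs]
        for g, e in zip(got, sorted(expected)):
            assert g[:2] == e[:2]
            assert g[2] == pytest.approx(e[2], abs=1e-12)

    def test_sorted_canonically_under_relabeling(self, toy_complex, toy_selections):
        cs = ps.identify_native_contacts(toy_complex, *toy_selections)
        keys = [(p.protein_atom, p.ligand_atom) for p in cs.pairs]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)


class TestApplyWindow:
    def _traj(self, n_frames, n_replicas=1):
        topo = make_pair_topology(1, 1)
        coords = np.zeros((n_frames * n_replicas, 2, 3))
        coords[:, 1, 0] = 3.0
        return ps.Trajectory(
            topo,
            coords,
            replica_ids=np.repeat(np.arange(n_replicas), n_frames),
            times=np.tile(np.arange(n_frames, dtype=float), n_replicas),
            frame_indices=np.tile(np.arange(n_frames), n_replicas),
        )

    def test_discard_60_of_100_keeps_frames_60_to_99(self):
        w = ps.apply_window(self._traj(100), ps.AnalysisWindow(0.6))
        assert w.n_frames == 40
        assert w.frame_indices.tolist() == list(range(60, 100))

    def test_discard_zero_is_identity(self):
        t = self._traj(7)
        w = ps.apply_window(t, ps.AnalysisWindow(0.0))
        assert np.array_equal(w.coords, t.coords)
        assert np.array_equal(w.frame_indices, t.frame_indices)

    def test_two_replicas_pool_in_replica_order(self):
        w = ps.apply_window(self._traj(10, n_replicas=2), ps.AnalysisWindow(0.5))
        assert w.n_frames == 10
        assert w.replica_ids.tolist() == [0] * 5 + [1] * 5
        assert w.frame_indices.tolist() == list(range(5, 10)) * 2

    def test_idempotent_with_discard_zero_on_own_output(self):
        w = ps.apply_window(self._traj(10), ps.AnalysisWindow(0.6))
        w2 = ps.apply_window(w, ps.AnalysisWindow(0.0))
        assert np.array_equal(w.coords, w2.coords)

    def test_discard_fraction_must_be_below_one(self):
        with pytest.raises(WindowError):
            ps.AnalysisWindow(1.0)
        with pytest.raises(WindowError):
            ps.AnalysisWindow(-0.1)


class TestDistanceSeries:
    def test_static_trajectory_columns_equal_r0(self, toy_complex, toy_selections, toy_contacts):
        coords = np.repeat(toy_complex.coords[None], 4, axis=0)
        traj = ps.Trajectory(
            toy_complex.topology, coords, np.zeros(4, dtype=int), np.arange(4.0)
        )
        series = ps.compute_distance_series(traj, toy_contacts)
        np.testing.assert_allclose(
            series.values, np.tile(toy_contacts.r0, (4, 1)), atol=1e-12
        )

    def test_axial_translation_adds_exactly(self):
        topo = make_pair_topology(1, 1)
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 3.0
        coords[1, 1, 0] += 1.0  # ligand moved +1 A along the pair axis
        traj = ps.Trajectory(topo, coords, np.zeros(2, dtype=int), np.arange(2.0))
        series = ps.compute_distance_series(traj, [(0, 1)])
        np.testing.assert_allclose(series.values[:, 0], [3.0, 4.0], atol=1e-12)

    def test_matches_naive_per_frame_loop(self):
        rng = np.random.default_rng(7)
        topo, ref, traj = random_system(rng)
        psel, lsel = _sels(topo)
        cs = ps.identify_native_contacts(ref, psel, lsel)
        series = ps.compute_distance_series(traj, cs)
        for f in range(traj.n_frames):
            for k, p in enumerate(cs.pairs):
                d = np.linalg.norm(
                    traj.coords[f, p.protein_atom] - traj.coords[f, p.ligand_atom]
                )
                assert series.values[f, k] == pytest.approx(d, abs=1e-12)


class TestEnsembleMatrix:
    def _traj_with_pair_series(self, values):
        """1 protein + 1 ligand atom; pair distance follows ``values``."""
        topo = make_pair_topology(1, 1)
        n = len(values)
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = values
        return topo, ps.Trajectory(topo, coords, np.zeros(n, dtype=int), np.arange(float(n)))

    def test_mean_at_retention_boundary_is_retained(self):
        topo, traj = self._traj_with_pair_series([6.75, 6.75])
        m = ps.ensemble_contact_matrix(traj, *_sels(topo))
        assert m.retained_mask.tolist() == [True]

    def test_alternating_5_and_9_mean_7_dropped(self):
        topo, traj = self._traj_with_pair_series([5.0, 9.0, 5.0, 9.0])
        with pytest.raises(NoNativeContactsError):
            ps.ensemble_contact_matrix(traj, *_sels(topo))

    def test_means_match_hand_computation(self):
        rng = np.random.default_rng(2)
        topo = make_pair_topology(2, 2)
        coords = rng.uniform(0, 5, (6, 4, 3))
        traj = ps.Trajectory(topo, coords, np.zeros(6, dtype=int), np.arange(6.0))
        m = ps.ensemble_contact_matrix(traj, *_sels(topo), retention_cutoff=100.0)
        for k, (i, j) in enumerate(m.candidate_pairs):
            hand = np.mean(
                [np.linalg.norm(coords[f, i] - coords[f, j]) for f in range(6)]
            )
            assert m.mean_distance[k] == pytest.approx(hand, abs=1e-12)

    def test_retained_set_monotone_in_cutoff(self, toy_complex, toy_selections):
        coords = np.repeat(toy_complex.coords[None], 3, axis=0)
        traj = ps.Trajectory(
            toy_complex.topology, coords, np.zeros(3, dtype=int), np.arange(3.0)
        )
        sizes = []
        for cutoff in (8.0, 6.75, 5.0, 4.0):
            m = ps.ensemble_contact_matrix(traj, *toy_selections, retention_cutoff=cutoff)
            sizes.append(int(m.retained_mask.sum()))
        assert sizes == sorted(sizes, reverse=True)


class TestRepresentative:
    def test_all_identical_frames_tie_breaks_to_frame_0(self, toy_complex, toy_selections):
        coords = np.repeat(toy_complex.coords[None], 5, axis=0)
        traj = ps.Trajectory(
            toy_complex.topology, coords, np.zeros(5, dtype=int), np.arange(5.0)
        )
        m = ps.ensemble_contact_matrix(traj, *toy_selections)
        rep = ps.select_representative(traj, m)
        assert rep.frame_global_index == 0
        assert rep.euclidean_distance == pytest.approx(0.0, abs=1e-12)

    def test_three_frame_single_pair_example(self):
        # distances {3.0, 5.0, 4.1}, mean 4.0333... -> frame 2 is closest
        topo = make_pair_topology(1, 1)
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = [3.0, 5.0, 4.1]
        traj = ps.Trajectory(topo, coords, np.zeros(3, dtype=int), np.arange(3.0))
        m = ps.ensemble_contact_matrix(
            traj, ps.select_atoms(topo, "protein"), ps.select_atoms(topo, "ligand")
        )
        rep = ps.select_representative(traj, m)
        assert rep.frame_global_index == 2
        assert rep.euclidean_distance == pytest.approx(abs(4.1 - 4.1 / 3 - 8.0 / 3), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        topo, ref, traj = random_system(rng, max_frames=20)
        psel = ps.select_atoms(topo, "protein and heavy")
        lsel = ps.select_atoms(topo, "ligand and heavy")
        m = ps.ensemble_contact_matrix(traj, psel, lsel, retention_cutoff=10.0)
        rep = ps.select_representative(traj, m)
        # exhaustive O(F*K) oracle
        pairs = m.retained_pairs
        best, best_d = None, np.inf
        for f in range(traj.n_frames):
            vec = [
                np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) for i, j in pairs
            ]
            d = np.sqrt(np.sum((np.array(vec) - m.mean_vector) ** 2))
            if d < best_d:
                best, best_d = f, d
        assert rep.frame_global_index == best
        assert rep.euclidean_distance == pytest.approx(best_d, rel=1e-10)
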