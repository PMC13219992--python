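import math

import numpy as np
import pytest

import posestab as ps
from posestab.errors import ComparabilityError, DomainError, NoNativeContactsError
from tests.conftest import make_pair_topology, random_system

PARAMS = ps.ContactModelParams()


def naive_r_trajectory(values, r0, beta=5.0, lam=1.8):
    """Independent double-loop evaluation of the contact-persistence score."""
    n_frames, n_pairs = values.shape
    per_frame = []
    for f in range(n_frames):
        total = 0.0
        for k in range(n_pairs):
            x = beta * (values[f, k] - lam * r0[k])
            if x > 700:
                term = 0.0
            else:
                term = 1.0 / (1.0 + math.exp(x))
            total += term
        per_frame.append(total / n_pairs)
    return sum(per_frame) / n_frames, per_frame


def _series_from_values(values, contacts):
    values = np.asarray(values, dtype=float)
    return ps.DistanceSeries(
        contacts.pair_indices,
        values,
        np.zeros(values.shape[0], dtype=int),
        np.arange(float(values.shape[0])),
    )


def _single_contact_set(r0=3.0):
    topo = make_pair_topology(1, 1)
    s = ps.Structure(topo, np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]))
    return ps.identify_native_contacts(
        s, ps.select_atoms(topo, "protein"), ps.select_atoms(topo, "ligand")
    )


class TestContactTerm:
    @pytest.mark.parametrize("r0", [0.5, 2.0, 3.7])
    def test_half_at_switching_point(self, r0):
        assert ps.contact_term(PARAMS.lam * r0, r0) == pytest.approx(0.5, abs=1e-12)

    def test_far_distance_underflows_to_zero(self):
        assert ps.contact_term(1e6, 3.0) == 0.0

    def test_hand_evaluated_sigmoid(self):
        # rX = r0 = 3.0: exponent = 5.0*(3.0 - 1.8*3.0) = -12
        expected = 1.0 / (1.0 + math.exp(-12.0))
        assert ps.contact_term(3.0, 3.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            ps.contact_term(-1.0, 3.0)
        with pytest.raises(DomainError):
            ps.contact_term(3.0, 0.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        terms = ps.contact_term(rng.uniform(0.1, 30, 200), rng.uniform(0.5, 5, 200))
        assert np.all(terms >= 0) and np.all(terms <= 1)


class TestRValueFrame:
    def test_mean_of_terms(self):
        topo = make_pair_topology(2, 1)
        s = ps.Structure(topo, np.array([[0, 0, 0], [0, 2.0, 0], [3.0, 0, 0]], dtype=float))
        cs = ps.identify_native_contacts(
            s, ps.select_atoms(topo, "protein"), ps.select_atoms(topo, "ligand")
        )
        # distances chosen so terms are 0.5 and ~1.0
        d = np.array([PARAMS.lam * cs.pairs[0].r0, cs.pairs[1].r0])
        terms = [ps.contact_term(d[k], cs.pairs[k].r0) for k in range(2)]
        assert ps.r_value_frame(d, cs) == pytest.approx(np.mean(terms), abs=1e-12)

    def test_single_contact_at_switching_point(self):
        cs = _single_contact_set(3.0)
        assert ps.r_value_frame([PARAMS.lam * 3.0], cs) == pytest.approx(0.5, abs=1e-12)

    def test_empty_contacts_raise(self):
        cs = _single_contact_set()
        empty = ps.ContactSet((), cs.reference_mode, cs.cutoff, cs.reference_structure)
        with pytest.raises(NoNativeContactsError):
            ps.r_value_frame(np.array([]), empty)


class TestRValueTrajectory:
    def test_self_reference_is_nearly_one(self, toy_complex, toy_selections, toy_contacts):
        assert toy_contacts.r0.min() >= 2.0
        values = np.tile(toy_contacts.r0, (5, 1))
        res = ps.r_value_trajectory(_series_from_values(values, toy_contacts), toy_contacts)
        assert res.r_global >= 0.999

    def test_alternating_bound_unbound_is_half(self, toy_contacts):
        r0 = toy_contacts.r0
        bound = r0
        unbound = 3.0 * PARAMS.lam * r0
        values = np.stack([bound, unbound] * 5)
        res = ps.r_value_trajectory(_series_from_values(values, toy_contacts), toy_contacts)
        # oracle: mean of the two per-frame values
        rb, _ = naive_r_trajectory(bound[None, :], r0)
        ru, _ = naive_r_trajectory(unbound[None, :], r0)
        assert res.r_global == pytest.approx(0.5 * (rb + ru), rel=1e-10)
        assert res.r_global == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_systems(self, seed):
        """Vectorized pipeline == naive double loop on random toy systems."""
        rng = np.random.default_rng(seed)
        topo, ref, traj = random_system(rng, max_atoms=30, max_frames=20)
        psel = ps.select_atoms(topo, "protein and heavy")
        lsel = ps.select_atoms(topo, "ligand and heavy")
        try:
            cs = ps.identify_native_contacts(ref, psel, lsel)
        except NoNativeContactsError:
            pytest.skip("random cloud produced no native contact")
        series = ps.compute_distance_series(traj, cs)
        res = ps.r_value_trajectory(series, cs)
        expected_global, expected_frames = naive_r_trajectory(series.values, cs.r0)
        assert res.r_global == pytest.approx(expected_global, rel=1e-10)
        np.testing.assert_allclose(res.per_frame_r, expected_frames, rtol=1e-10)

    def test_global_is_mean_of_per_frame(self, toy_contacts):
        rng = np.random.default_rng(4)
        values = np.abs(rng.normal(4.0, 1.0, (8, toy_contacts.n_contacts))) + 0.1
        res = ps.r_value_trajectory(_series_from_values(values, toy_contacts), toy_contacts)
        assert res.r_global == pytest.approx(float(res.per_frame_r.mean()), abs=1e-14)
        assert 0 < res.r_global < 1

    def test_scaling_distances_up_decreases_r(self, toy_contacts):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(4.0, 0.5, (6, toy_contacts.n_contacts))) + 0.5
        base = ps.r_value_trajectory(_series_from_values(values, toy_contacts), toy_contacts)
        scaled = ps.r_value_trajectory(
            _series_from_values(values * 1.5, toy_contacts), toy_contacts
        )
        assert scaled.r_global < base.r_global


class TestResidueMap:
    def test_single_residue_owns_100_percent(self):
        cs = _single_contact_set()
        values = np.tile(cs.r0, (3, 1))
        m = ps.residue_stability_map(
            _series_from_values(values, cs), cs, PARAMS, cs.reference_structure.topology
        )
        assert m.table.pct_contribution.tolist() == [100.0]

    def test_two_residue_arithmetic_example(self):
        # residue A: 1 contact with term 1.0; residue B: 3 contacts with term 0.5
        topo = ps.Topology(
            names=np.array(["CA", "CA", "CB", "CG", "C1", "C2"], dtype="U6"),
            elements=np.full(6, "C", dtype="U2"),
            res_names=np.array(["ALA", "GLY", "GLY", "GLY", "LIG", "LIG"], dtype="U5"),
            res_seqs=np.array([1, 2, 2, 2, 1, 1], dtype=np.intp),
            ins_codes=np.full(6, "", dtype="U1"),
            chain_ids=np.array(["A", "A", "A", "A", "L", "L"], dtype="U4"),
            is_ligand=np.array([False] * 4 + [True] * 2, dtype=bool),
            is_hydrogen=np.zeros(6, dtype=bool),
        )
        pairs = (
            ps.ContactPair(0, 4, 3.0),
            ps.ContactPair(1, 4, 3.0),
            ps.ContactPair(2, 5, 3.0),
            ps.ContactPair(3, 5, 3.0),
        )
        ref = ps.Structure(topo, np.zeros((6, 3)) + np.arange(6)[:, None])
        cs = ps.ContactSet(pairs, ps.ReferenceMode.EXP, 4.5, ref)
        # choose distances producing exactly term 1.0 (impossible) -> use the
        # switching point for B (term 0.5) and a saturating distance for A
        d_A = 1e-6  # term -> 1.0 at double precision
        d_B = PARAMS.lam * 3.0
        values = np.tile([d_A, d_B, d_B, d_B], (4, 1))
        m = ps.residue_stability_map(_series_from_values(values, cs), cs, PARAMS, topo)
        t = m.table.set_index("resseq")
        assert t.loc[1, "contribution"] == pytest.approx(1.0, abs=1e-9)
        assert t.loc[2, "contribution"] == pytest.approx(1.5, abs=1e-9)
        assert t.loc[1, "pct_contribution"] == pytest.approx(40.0, abs=1e-6)
        assert t.loc[2, "pct_contribution"] == pytest.approx(60.0, abs=1e-6)
        assert m.table.contribution.sum() == pytest.approx(4 * 0.625, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_decomposition_identity_random(self, seed, toy_complex, toy_selections, toy_contacts):
        rng = np.random.default_rng(seed)
        values = np.abs(rng.normal(4.0, 1.5, (7, toy_contacts.n_contacts))) + 0.1
        series = _series_from_values(values, toy_contacts)
        res = ps.r_value_trajectory(series, toy_contacts)
        m = ps.residue_stability_map(series, toy_contacts, PARAMS, toy_complex.topology)
        assert m.table.contribution.sum() == pytest.approx(
            toy_contacts.n_contacts * res.r_global, abs=1e-9
        )
        assert m.table.pct_contribution.sum() == pytest.approx(100.0, abs=1e-9)

    def test_averaging_order_commutes(self, toy_contacts):
        rng = np.random.default_rng(11)
        values = np.abs(rng.normal(4.0, 1.0, (9, toy_contacts.n_contacts))) + 0.1
        series = _series_from_values(values, toy_contacts)
        res = ps.r_value_trajectory(series, toy_contacts)
        terms = ps.contact_term(values, toy_contacts.r0[None, :])
        assert res.r_global == pytest.approx(float(terms.mean()), abs=1e-12)


class TestAtomMap:
    def test_categories(self, toy_complex, toy_selections, toy_contacts):
        values = np.tile(toy_contacts.r0, (4, 1))  # all terms ~1 -> stable
        m = ps.atom_stability_map(
            _series_from_values(values, toy_contacts),
            toy_contacts,
            PARAMS,
            toy_complex.topology,
        )
        contacted = m.table[m.table.contact_count > 0]
        assert (contacted.category == "stable").all()

    def test_uncontacted_atom_is_no_contact_with_null_r(self):
        topo = make_pair_topology(1, 2)
        s = ps.Structure(
            topo, np.array([[0, 0, 0], [3.0, 0, 0], [40.0, 0, 0]], dtype=float)
        )
        cs = ps.identify_native_contacts(
            s, ps.select_atoms(topo, "protein"), ps.select_atoms(topo, "ligand")
        )
        values = np.tile(cs.r0, (2, 1))
        m = ps.atom_stability_map(_series_from_values(values, cs), cs, PARAMS, topo)
        far = m.table.set_index("atom_index").loc[2]
        assert far.category == "no_contact"
        assert np.isnan(far.r_atom)

    def test_constant_term_075_is_less_stable(self):
        cs = _single_contact_set(3.0)
        # solve for distance giving term exactly 0.75
        d = PARAMS.lam * 3.0 - math.log(3.0) / PARAMS.beta
        assert ps.contact_term(d, 3.0) == pytest.approx(0.75, rel=1e-12)
        values = np.full((3, 1), d)
        m = ps.atom_stability_map(
            _series_from_values(values, cs), cs, PARAMS, cs.reference_structure.topology
        )
        assert m.table.category.tolist() == ["less_stable"]


class TestDeltaR:
    def _result(self, r, params=PARAMS):
        return ps.RValueResult(r, np.array([r]), 1, ps.ReferenceMode.EXP, params)

    def test_identical_results_zero(self):
        assert ps.delta_r(self._result(0.9), self._result(0.9)) == 0.0

    def test_subtraction_and_antisymmetry(self):
        a, b = self._result(0.97), self._result(0.85)
        assert ps.delta_r(a, b) == pytest.approx(0.12, abs=1e-12)
        assert ps.delta_r(a, b) == pytest.approx(-ps.delta_r(b, a), abs=1e-15)

    def test_param_mismatch_rejected(self):
        other = ps.ContactModelParams(beta=4.0)
        with pytest.raises(ComparabilityError):
            ps.delta_r(self._result(0.9), self._result(0.8, other))
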