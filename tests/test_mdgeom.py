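"""Trajectory geometry: H-bond occupancy, contacts, arm distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucfret import ValidationError
from nucfret.mdgeom import (AtomSelection, DistanceSeries, SegmentPairSpec,
                            Trajectory, arm_segment_distances,
                            contact_probability, count_contacts,
                            hbond_occupancy, running_average)
from nucfret.synthetic import (TrajectoryScript, duplex_toy, hbond_toy,
                               make_toy_trajectory, random_walk_toy)


def rigid_transform(traj, seed=0):
    """Apply a random rotation+translation to every frame."""
    rng = np.random.default_rng(seed)
    coords = traj.coords_nm.copy()
    for fi in range(traj.n_frames):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-5, 5, size=3)
        coords[fi] = coords[fi] @ rot.T + shift
    return Trajectory(structure=traj.structure, times_ps=traj.times_ps,
                      coords_nm=coords)


def simple_pair_traj(distances_nm, with_hydrogen=True):
    """Two single-atom residues separated by a scripted distance series."""
    atoms = [("N", "N", 14.0, "DON", 1, "X"),
             ("O", "O", 16.0, "ACC", 2, "Y")]
    if with_hydrogen:
        atoms.insert(1, ("H", "H", 1.0, "DON", 1, "X"))
    n = len(distances_nm)
    coords = np.zeros((n, len(atoms), 3))
    if with_hydrogen:
        coords[:, 1] = [0.10, 0.0, 0.0]
    coords[:, -1, 0] = distances_nm
    times = 100.0 * np.arange(n)
    return make_toy_trajectory(TrajectoryScript(atoms, times, coords))


class TestHbondOccupancy:
    def test_scripted_fraction_recovered(self):
        traj, truth = hbond_toy(n_frames=100, bound_fraction=0.37, seed=1)
        occ = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                              AtomSelection(chains=("Y",)),
                              t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        assert occ.iloc[0]["occupancy"] == pytest.approx(truth["occupancy"])

    def test_always_beyond_cutoff_is_zero(self):
        traj = simple_pair_traj([0.8] * 20)  # > 2 x 0.35 nm
        occ = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                              AtomSelection(chains=("Y",)),
                              t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        assert occ.iloc[0]["occupancy"] == 0.0

    def test_rigid_bond_all_frames_is_one(self):
        traj = simple_pair_traj([0.30] * 20)
        occ = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                              AtomSelection(chains=("Y",)),
                              t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        assert occ.iloc[0]["occupancy"] == 1.0

    def test_angle_criterion_enforced(self):
        # acceptor at criterion distance but perpendicular to the N-H axis
        atoms = [("N", "N", 14.0, "DON", 1, "X"),
                 ("H", "H", 1.0, "DON", 1, "X"),
                 ("O", "O", 16.0, "ACC", 2, "Y")]
        coords = np.zeros((5, 3, 3))
        coords[:, 1] = [0.10, 0.0, 0.0]
        coords[:, 2] = [0.0, 0.30, 0.0]   # 90 deg H-D-A angle
        traj = make_toy_trajectory(
            TrajectoryScript(atoms, 100.0 * np.arange(5), coords))
        occ = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                              AtomSelection(chains=("Y",)),
                              t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        assert occ.iloc[0]["occupancy"] == 0.0

    def test_analysis_window_restricts_frames(self):
        # bonded in the first half only; window over the second half
        traj = simple_pair_traj([0.30] * 10 + [0.8] * 10)
        occ = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                              AtomSelection(chains=("Y",)),
                              t_start_ps=1000.0, t_end_ps=1900.0)
        assert occ.iloc[0]["occupancy"] == 0.0

    def test_empty_selection_named_in_error(self):
        traj = simple_pair_traj([0.3] * 5)
        with pytest.raises(ValidationError, match="donor"):
            hbond_occupancy(traj, AtomSelection(chains=("Z",)),
                            AtomSelection(chains=("Y",)),
                            t_start_ps=0.0, t_end_ps=traj.times_ps[-1])

    def test_window_outside_span_rejected(self):
        traj = simple_pair_traj([0.3] * 5)
        with pytest.raises(ValidationError, match="window"):
            hbond_occupancy(traj, AtomSelection(chains=("X",)),
                            AtomSelection(chains=("Y",)),
                            t_start_ps=0.0, t_end_ps=1e9)

    def test_rigid_motion_invariance(self):
        traj, _ = hbond_toy(n_frames=50, bound_fraction=0.5, seed=4)
        occ1 = hbond_occupancy(traj, AtomSelection(chains=("X",)),
                               AtomSelection(chains=("Y",)),
                               t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        occ2 = hbond_occupancy(rigid_transform(traj),
                               AtomSelection(chains=("X",)),
                               AtomSelection(chains=("Y",)),
                               t_start_ps=0.0, t_end_ps=traj.times_ps[-1])
        assert occ1["occupancy"].tolist() == occ2["occupancy"].tolist()


class TestCountContacts:
    @pytest.mark.parametrize("dist, expected", [
        (0.34, 1),
        (0.35, 0),  # strictly less than the cutoff
    ])
    def test_cutoff_strictness(self, dist, expected):
        traj = simple_pair_traj([dist], with_hydrogen=False)
        counts = count_contacts(traj, AtomSelection(chains=("X",)),
                                AtomSelection(chains=("Y",)))
        assert counts[0] == expected

    def test_hydrogens_excluded(self):
        traj = simple_pair_traj([0.3] * 3, with_hydrogen=True)
        counts = count_contacts(traj, AtomSelection(chains=("X",)),
                                AtomSelection(chains=("Y",)))
        assert np.all(counts == 1)  # N-O only; H does not pair

    def test_brute_force_oracle_on_random_walk(self):
        traj = random_walk_toy(n_atoms=20, n_frames=50, seed=11)
        sel_a = AtomSelection(chains=("A",))
        sel_b = AtomSelection(chains=("B",))
        counts = count_contacts(traj, sel_a, sel_b)
        s = traj.structure
        ia = np.flatnonzero(s.chain_ids == "A")
        ib = np.flatnonzero(s.chain_ids == "B")
        for fi in range(traj.n_frames):
            ref = sum(1 for i in ia for j in ib
                      if np.linalg.norm(traj.coords_nm[fi, i]
                                        - traj.coords_nm[fi, j]) < 0.35)
            assert counts[fi] == ref

    def test_symmetry(self):
        traj = random_walk_toy(n_atoms=16, n_frames=20, seed=3)
        a = AtomSelection(chains=("A",))
        b = AtomSelection(chains=("B",))
        assert np.array_equal(count_contacts(traj, a, b),
                              count_contacts(traj, b, a))

    def test_empty_group_gives_zeros(self):
        traj = random_walk_toy(n_atoms=10, n_frames=5, seed=0)
        counts = count_contacts(traj, AtomSelection(chains=("A",)),
                                AtomSelection(chains=("Q",)))
        assert np.all(counts == 0)

    def test_overlapping_selections_warn_and_exclude_self_pairs(self):
        traj = random_walk_toy(n_atoms=10, n_frames=5, seed=0)
        everything = AtomSelection()
        with pytest.warns(UserWarning, match="overlap"):
            counts = count_contacts(traj, everything, everything)
        # self pairs excluded -> even counts (each pair counted twice)
        assert np.all(counts % 2 == 0)

    def test_rigid_motion_invariance(self):
        traj = random_walk_toy(n_atoms=20, n_frames=20, seed=5)
        a = AtomSelection(chains=("A",))
        b = AtomSelection(chains=("B",))
        assert np.array_equal(count_contacts(traj, a, b),
                              count_contacts(rigid_transform(traj), a, b))

    def test_cross_check_against_mdanalysis_distances(self):
        """Independent distance engine agrees with our contact counts."""
        from MDAnalysis.lib.distances import distance_array
        traj = random_walk_toy(n_atoms=20, n_frames=10, seed=17)
        s = traj.structure
        ia = np.flatnonzero(s.chain_ids == "A")
        ib = np.flatnonzero(s.chain_ids == "B")
        counts = count_contacts(traj, AtomSelection(chains=("A",)),
                                AtomSelection(chains=("B",)))
        for fi in range(traj.n_frames):
            # MDAnalysis works in Angstrom
            d = distance_array(traj.coords_nm[fi, ia] * 10.0,
                               traj.coords_nm[fi, ib] * 10.0)
            assert counts[fi] == int((d < 3.5).sum())


class TestArmSegmentDistances:
    def test_constructed_geometry(self):
        traj, truth = duplex_toy()
        series = arm_segment_distances(traj)
        for label, expected in truth.items():
            assert np.all(np.abs(series[label].values - expected) < 1e-9)

    def test_translation_invariance(self):
        traj, _ = duplex_toy()
        shifted = Trajectory(structure=traj.structure,
                             times_ps=traj.times_ps,
                             coords_nm=traj.coords_nm + [1.0, -2.0, 3.0])
        s1 = arm_segment_distances(traj)
        s2 = arm_segment_distances(shifted)
        for label in s1:
            assert np.allclose(s1[label].values, s2[label].values,
                               atol=1e-12)

    def test_mass_scale_invariance(self):
        import dataclasses
        traj, _ = duplex_toy()
        s1 = arm_segment_distances(traj)
        doubled = dataclasses.replace(traj.structure,
                                      masses=traj.structure.masses * 2.0)
        heavy = Trajectory(structure=doubled, times_ps=traj.times_ps,
                           coords_nm=traj.coords_nm)
        s2 = arm_segment_distances(heavy)
        for label in s1:
            assert np.allclose(s1[label].values, s2[label].values)

    def test_rigid_motion_invariance(self):
        traj, _ = duplex_toy()
        s1 = arm_segment_distances(traj)
        s2 = arm_segment_distances(rigid_transform(traj, seed=2))
        for label in s1:
            assert np.allclose(s1[label].values, s2[label].values,
                               atol=1e-9)

    def test_missing_chain_reported(self):
        traj, _ = duplex_toy()
        with pytest.raises(ValidationError, match="chain"):
            arm_segment_distances(traj, SegmentPairSpec(strand1_chain="Q"))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError):
            SegmentPairSpec(windows=((1, 5), (4, 10)))


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        s = DistanceSeries(100.0 * np.arange(20), np.full(20, 3.3))
        out = running_average(s, 200.0)
        assert np.allclose(out.values, 3.3)
        assert np.array_equal(out.times_ps, s.times_ps)

    def test_alternating_series_half(self):
        s = DistanceSeries(100.0 * np.arange(10),
                           np.array([0.0, 1.0] * 5))
        out = running_average(s, 200.0)
        assert np.allclose(out.values[1:], 0.5)

    def test_window_not_exceeding_spacing_rejected(self):
        s = DistanceSeries(100.0 * np.arange(10), np.zeros(10))
        with pytest.raises(ValidationError):
            running_average(s, 50.0)

    def test_single_frame_identity_with_warning(self):
        s = DistanceSeries(np.array([0.0]), np.array([1.0]))
        with pytest.warns(UserWarning):
            out = running_average(s, 200.0)
        assert out.values.tolist() == [1.0]

    def test_mean_preserved_on_stationary_signal(self, rng):
        v = rng.normal(2.0, 0.3, size=400)
        s = DistanceSeries(50.0 * np.arange(400), v)
        out = running_average(s, 200.0)
        assert np.mean(out.values) == pytest.approx(np.mean(v), abs=0.05)


class TestContactProbability:
    def test_scripted_half_contact(self):
        dists = [0.3] * 50 + [0.8] * 50
        traj = simple_pair_traj(dists, with_hydrogen=False)
        table = contact_probability(traj, ("X", 1),
                                    AtomSelection(chains=("Y",)))
        assert table.iloc[0]["probability"] == pytest.approx(0.5)

    def test_self_residue_excluded(self):
        traj = simple_pair_traj([0.3] * 5, with_hydrogen=False)
        table = contact_probability(traj, ("X", 1), AtomSelection())
        assert not ((table["chain"] == "X") & (table["resid"] == 1)).any()

    def test_never_contacting_zero(self):
        traj = simple_pair_traj([2.0] * 10, with_hydrogen=False)
        table = contact_probability(traj, ("X", 1),
                                    AtomSelection(chains=("Y",)))
        assert table.iloc[0]["probability"] == 0.0


class TestAtomSelection:
    def test_parse_grammar(self):
        sel = AtomSelection.parse("chain C and resid 81 and heavy")
        assert sel.chains == ("C",) and sel.res_ids == (81,)
        assert sel.heavy_only

    def test_parse_resid_range(self):
        sel = AtomSelection.parse("resid 10:13")
        assert sel.res_ids == (10, 11, 12, 13)

    def test_unknown_term_rejected(self):
        with pytest.raises(ValidationError):
            AtomSelection.parse("spam 42")

    def test_indices_order_stable(self):
        traj, _ = duplex_toy()
        sel = AtomSelection(chains=("I",))
        idx1 = sel.indices(traj.structure)
        idx2 = sel.indices(traj.structure)
        assert np.array_equal(idx1, idx2)
        assert np.all(np.diff(idx1) > 0)
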