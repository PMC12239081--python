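"""Bilayer structural metrics on analytically known toy membranes."""
import math

import numpy as np
import pytest

from scperm.core import Snapshot, Trajectory
from scperm.structure import (
    HBondCriteria,
    HBondGroup,
    StructureError,
    area_per_lipid,
    chain_distance_distribution,
    count_hbonds,
    density_profile,
    membrane_thickness,
    order_parameter,
)
from scperm.synthetic import generate_toy_membrane


def single_atom_snapshot(z=0.0, name="N", box=(4.0, 5.0, 10.0)):
    return Snapshot(resids=[1], resnames=["CER"], names=[name],
                    positions=[[1.0, 1.0, z]], box=list(box))


class TestDensity:
    def test_single_atom_occupies_one_bin_at_mass_over_volume(self):
        traj = Trajectory([single_atom_snapshot()])
        prof = density_profile(traj, "name N", bin_width=0.1)
        occupied = np.flatnonzero(prof.density["selection"])
        assert len(occupied) == 1
        vol = 0.1 * 4.0 * 5.0
        assert prof.density["selection"][occupied[0]] == pytest.approx(14.007 / vol)
        # the atom sits at the bilayer center, i.e. the z = 0 bin
        assert prof.z[occupied[0]] == pytest.approx(0.0, abs=1e-12)

    def test_toy_membrane_markers_peak_symmetrically(self):
        traj = generate_toy_membrane(49, thickness=5.0)
        prof = density_profile(traj, "name N", bin_width=0.1)
        dens = prof.density["selection"]
        peaks = prof.z[dens > 0.5 * dens.max()]
        assert peaks.min() == pytest.approx(-2.5, abs=0.1)
        assert peaks.max() == pytest.approx(2.5, abs=0.1)

    def test_mass_closure(self):
        """Integrated density x box area equals the selected mass."""
        traj = generate_toy_membrane(25, jitter=0.03, n_frames=4, seed=2)
        prof = density_profile(traj, {"markers": "name N", "chains": "name CS1 CF1"})
        assert prof.total_mass("markers") == pytest.approx(2 * 25 * 14.007, rel=1e-6)
        assert prof.total_mass("chains") == pytest.approx(2 * 25 * 2 * 12.011, rel=1e-6)

    def test_empty_selection_is_an_error(self):
        traj = Trajectory([single_atom_snapshot()])
        with pytest.raises(StructureError):
            density_profile(traj, "name XX")


class TestThickness:
    def test_noiseless_fixture_is_exact_with_zero_error(self):
        traj = generate_toy_membrane(36, thickness=5.0, n_frames=6)
        thick, se = membrane_thickness(traj, "name N", n_blocks=6)
        assert thick == pytest.approx(5.0, abs=1e-9)
        assert se == 0.0

    def test_jittered_fixture_recovered_within_one_bin(self):
        traj = generate_toy_membrane(100, thickness=4.96, jitter=0.05,
                                     n_frames=24, seed=7)
        thick, se = membrane_thickness(traj, "name N", n_blocks=6, bin_width=0.02)
        assert abs(thick - 4.96) < 0.02
        assert se > 0

    def test_identical_blocks_have_zero_se(self):
        traj = generate_toy_membrane(16, thickness=5.0, n_frames=6)
        _, se = membrane_thickness(traj, "name N", n_blocks=6)
        assert se == 0.0

    def test_empty_leaflet_is_an_error(self):
        snap = single_atom_snapshot(z=2.0)
        snap2 = single_atom_snapshot(z=2.2)
        frames = Trajectory([snap, snap2])
        with pytest.raises(StructureError):
            membrane_thickness(frames, "name N", center_selection="name N")


class TestAreaPerLipid:
    def test_exact_arithmetic(self):
        snap = single_atom_snapshot(box=(6.0, 4.0, 10.0))
        apl, err = area_per_lipid(Trajectory([snap]), 75)
        assert apl == pytest.approx(0.32, rel=1e-12)
        assert err == 0.0

    def test_constant_box_has_zero_error(self):
        snap = single_atom_snapshot()
        apl, err = area_per_lipid(Trajectory([snap, snap, snap]), 10)
        assert err == 0.0

    def test_fixture_apl_recovered(self):
        traj = generate_toy_membrane(75, apl=0.322)
        apl, _ = area_per_lipid(traj, 75)
        assert apl == pytest.approx(0.322, rel=1e-12)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(StructureError):
            area_per_lipid(Trajectory([single_atom_snapshot()]), 0)


CHAIN = [f"CS{i}" for i in range(1, 9)]


class TestOrderParameter:
    def test_chains_along_the_normal_have_sz_one(self):
        traj = generate_toy_membrane(9, chain_tilt=0.0)
        prof = order_parameter(traj, CHAIN)
        np.testing.assert_allclose(prof.S_z, 1.0, atol=1e-12)

    def test_chains_in_plane_have_sz_minus_half(self):
        # built by hand: tilt 90 degrees is outside the generator's domain
        n = 5
        pos = [[0.5 + 0.1 * k, 1.0, 2.0] for k in range(n)]
        snap = Snapshot(resids=[1] * n, resnames=["CER"] * n,
                        names=CHAIN[:n], positions=pos, box=[4.0, 4.0, 8.0])
        prof = order_parameter(Trajectory([snap]), CHAIN[:n])
        np.testing.assert_allclose(prof.S_z, -0.5, atol=1e-12)

    def test_45_degree_tilt_gives_one_quarter(self):
        traj = generate_toy_membrane(9, chain_tilt=45.0)
        prof = order_parameter(traj, CHAIN)
        np.testing.assert_allclose(prof.S_z, 0.25, atol=1e-12)

    def test_missing_chain_atom_names_the_residue(self):
        traj = generate_toy_membrane(4)
        with pytest.raises(StructureError, match="CS99"):
            order_parameter(traj, ["CS1", "CS99", "CS3"])

    def test_rotation_about_z_is_invariant(self):
        traj = generate_toy_membrane(9, chain_tilt=30.0)
        prof0 = order_parameter(traj, CHAIN)
        th = 1.1
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        frames = []
        for fr in traj:
            frames.append(Snapshot(resids=fr.resids, resnames=fr.resnames,
                                   names=fr.names,
                                   positions=fr.positions @ rot.T,
                                   box=fr.box, time=fr.time))
        prof1 = order_parameter(Trajectory(frames), CHAIN)
        np.testing.assert_allclose(prof1.S_z, prof0.S_z, atol=1e-12)


class TestChainDistance:
    def test_fixed_separation_has_a_single_mode_there(self):
        traj = generate_toy_membrane(16, chain_sep=0.5)
        dist = chain_distance_distribution(traj, "CS1", "CF1", bandwidth=0.05)
        assert len(dist.modes) == 1
        assert dist.modes[0] == pytest.approx(0.5, abs=0.01)

    def test_bimodal_mixture_resolves_both_modes(self):
        """Half the pairs at 0.5 nm, half at 1.0 nm: two modes recovered."""
        a = generate_toy_membrane(8, chain_sep=0.5)
        b = generate_toy_membrane(8, chain_sep=1.0)
        snap_a, snap_b = a[0], b[0]
        merged = Snapshot(
            resids=np.concatenate([snap_a.resids, snap_b.resids + 100]),
            resnames=np.concatenate([snap_a.resnames, snap_b.resnames]),
            names=np.concatenate([snap_a.names, snap_b.names]),
            positions=np.vstack([snap_a.positions, snap_b.positions]),
            box=np.maximum(snap_a.box, snap_b.box) * 2,
        )
        dist = chain_distance_distribution(Trajectory([merged]), "CS1", "CF1",
                                           bandwidth=0.05)
        assert len(dist.modes) == 2
        np.testing.assert_allclose(sorted(dist.modes), [0.5, 1.0], atol=0.02)

    def test_density_normalizes_to_one(self):
        traj = generate_toy_membrane(16, jitter=0.02, seed=5)
        dist = chain_distance_distribution(traj, "CS1", "CF1")
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_bandwidth_rejected(self):
        traj = generate_toy_membrane(4)
        with pytest.raises(StructureError):
            chain_distance_distribution(traj, "CS1", "CF1", bandwidth=0.0)

    def test_lateral_vs_3d_modes_differ_for_tilted_chains(self):
        traj = generate_toy_membrane(16, chain_sep=0.5)
        lat = chain_distance_distribution(traj, "CS1", "CF8", lateral=True)
        full = chain_distance_distribution(traj, "CS1", "CF8", lateral=False)
        assert full.distances.mean() > lat.distances.mean()


def water_dimer(o_o=0.28, h_angle_deg=0.0):
    """Donor water (O1-H1) pointing at acceptor O2 along +x; the hydrogen
    is rotated off the O-O axis by h_angle_deg."""
    a = math.radians(h_angle_deg)
    return Snapshot(
        resids=[1, 1, 2],
        resnames=["SOL", "SOL", "SOL"],
        names=["O1", "H1", "O2"],
        positions=[[1.0, 1.0, 1.0],
                   [1.0 + 0.1 * math.cos(a), 1.0 + 0.1 * math.sin(a), 1.0],
                   [1.0 + o_o, 1.0, 1.0]],
        box=[3.0, 3.0, 3.0],
    )


DONOR = HBondGroup("don", "name O1", "name H1")
ACCEPTOR = HBondGroup("acc", "name O2")


class TestHBonds:
    def count(self, snap, criteria=HBondCriteria()):
        rep = count_hbonds(Trajectory([snap]), [DONOR], [ACCEPTOR], criteria)
        return rep.entries[("don", "acc")].mean_per_frame

    def test_ideal_dimer_is_one_bond(self):
        assert self.count(water_dimer(0.28, 0.0)) == 1.0

    def test_stretched_dimer_is_no_bond(self):
        assert self.count(water_dimer(0.40, 0.0)) == 0.0

    def test_bent_hydrogen_beyond_cutoff_is_no_bond(self):
        assert self.count(water_dimer(0.28, 45.0)) == 0.0
        assert self.count(water_dimer(0.28, 25.0)) == 1.0

    def test_donor_without_hydrogen_is_a_definition_error(self):
        snap = water_dimer()
        bad = HBondGroup("don", "name O1", "name HX")
        with pytest.raises(StructureError):
            count_hbonds(Trajectory([snap]), [bad], [ACCEPTOR])

    def test_minimum_image_bonds_across_the_boundary(self):
        snap = water_dimer()
        # acceptor wrapped across x: direct distance huge, minimum image 0.28,
        # but the hydrogen then points away from the image (angle 180)
        pos_wrapped = snap.positions.copy()
        pos_wrapped[2, 0] = pos_wrapped[0, 0] - 0.28 + 3.0
        snap2 = Snapshot(resids=snap.resids, resnames=snap.resnames,
                         names=snap.names, positions=pos_wrapped, box=snap.box)
        assert self.count(snap2) == 0.0
        # flipping the hydrogen toward the image restores the bond
        pos_flipped = pos_wrapped.copy()
        pos_flipped[1, 0] = pos_flipped[0, 0] - 0.1
        snap3 = Snapshot(resids=snap.resids, resnames=snap.resnames,
                         names=snap.names, positions=pos_flipped, box=snap.box)
        assert self.count(snap3) == 1.0

    def test_fixture_counts_match_brute_force_oracle(self):
        """Seeded toy membrane with per-lipid donor/acceptor triplets: the
        pairwise scan equals an independent triple-loop enumeration."""
        traj = generate_toy_membrane(10, hbond_geometry=(0.30, 20.0),
                                     jitter=0.02, n_frames=2, seed=21)
        donor = HBondGroup("NH", "name N", "name H")
        acceptor = HBondGroup("O", "name O")
        crit = HBondCriteria(0.35, 30.0)
        rep = count_hbonds(traj, [donor], [acceptor], crit, normalizer=20)

        def brute(snap):
            d_idx = np.flatnonzero(snap.names == "N")
            h_idx = np.flatnonzero(snap.names == "H")
            a_idx = np.flatnonzero(snap.names == "O")
            box = snap.box
            n = 0
            for d in d_idx:
                hs = [h for h in h_idx if snap.resids[h] == snap.resids[d]]
                for a in a_idx:
                    if a == d:
                        continue
                    da = snap.positions[a] - snap.positions[d]
                    da -= box * np.round(da / box)
                    if np.linalg.norm(da) > crit.max_da_distance:
                        continue
                    for h in hs:
                        dh = snap.positions[h] - snap.positions[d]
                        dh -= box * np.round(dh / box)
                        cosang = np.dot(da, dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) <= crit.max_hda_angle:
                            n += 1
            return n

        expected = np.mean([brute(fr) for fr in traj])
        assert expected > 0  # the geometry really produces bonds
        assert rep.entries[("NH", "O")].mean_per_frame == pytest.approx(expected)
        assert rep.entries[("NH", "O")].per_lipid == pytest.approx(expected / 20)


class TestRigidMotionInvariance:
    def test_translation_leaves_all_metrics_unchanged(self):
        traj = generate_toy_membrane(16, thickness=4.8, chain_tilt=20.0,
                                     jitter=0.02, n_frames=3, seed=9)
        moved = traj.translated([0.7, -0.3, 1.9])
        t0 = membrane_thickness(traj, "name N")[0]
        t1 = membrane_thickness(moved, "name N")[0]
        assert t1 == pytest.approx(t0, abs=1e-12)
        s0 = order_parameter(traj, CHAIN).S_z
        s1 = order_parameter(moved, CHAIN).S_z
        np.testing.assert_allclose(s1, s0, atol=1e-12)
        d0 = chain_distance_distribution(traj, "CS1", "CF1").distances
        d1 = chain_distance_distribution(moved, "CS1", "CF1").distances
        np.testing.assert_allclose(d1, d0, atol=1e-12)
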