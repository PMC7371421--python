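"""Tyr-membrane anchoring metrics against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bklinker.anchor import (AnchorProfile, InteractionCriteria,
                             aggregate_replicas, contact_probability_map,
                             count_cc_contacts, count_hbonds, count_pi_cation,
                             lipid_burial_sasa, membrane_frames,
                             pore_water_count)
from bklinker.sasa import VDW_RADII, shrake_rupley
from bklinker.synth import ToyMembraneSpec, gen_membrane_toy
from bklinker.traj import DegenerateSelectionError, Selection
from conftest import make_traj


RING_SEL = Selection(chain_id="A", atom_names=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])
CHOLINE_SEL = Selection(segment_class="lipid", atom_names=["N"])
TAIL_SEL = Selection(segment_class="lipid",
                     atom_names=[f"C2{i}" for i in range(2, 9)])
OH_SEL = Selection(chain_id="A", atom_names=["OH"])
ACCEPTOR_SEL = Selection(segment_class="lipid", atom_names=["N", "P"])


def hbond_traj(da_distance, angle_deg):
    """One O-H donor and one acceptor O at a chosen D-A distance and D-H-A angle."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([0.97, 0.0, 0.0])
    # place acceptor at distance da from donor, such that angle D-H-A = angle_deg
    theta = np.deg2rad(180.0 - angle_deg)
    # acceptor direction from H chosen in the xz plane
    ha_dir = np.array([np.cos(theta), 0.0, np.sin(theta)])
    # solve for |HA| so that |DA| = da_distance
    from scipy.optimize import brentq
    f = lambda r: np.linalg.norm(h + r * ha_dir - d) - da_distance
    r = brentq(f, 1e-3, 10.0)
    a = h + r * ha_dir
    coords = np.stack([d, h, a])[None]
    return make_traj(coords, names=["OH", "HH", "P"],
                     elements=["O", "H", "P"],
                     resids=[1, 1, 2], resnames=["TYR", "TYR", "POPC"],
                     chains=["A", "A", "L"],
                     segclass=["protein", "protein", "lipid"])


class TestHBonds:
    def test_collinear_short_bond_counts(self):
        traj = hbond_traj(2.8, 180.0)
        assert count_hbonds(traj, OH_SEL, ACCEPTOR_SEL)[0] == 1

    def test_long_distance_fails(self):
        traj = hbond_traj(3.2, 180.0)
        assert count_hbonds(traj, OH_SEL, ACCEPTOR_SEL)[0] == 0

    def test_bent_geometry_fails(self):
        traj = hbond_traj(2.8, 120.0)
        assert count_hbonds(traj, OH_SEL, ACCEPTOR_SEL)[0] == 0

    def test_angle_threshold_boundary(self):
        assert count_hbonds(hbond_traj(2.8, 150.0), OH_SEL, ACCEPTOR_SEL)[0] == 1
        assert count_hbonds(hbond_traj(2.8, 149.0), OH_SEL, ACCEPTOR_SEL)[0] == 0

    def test_donor_without_hydrogen_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)) + [[0, 0, 0], [2.8, 0, 0]],
                         names=["OH", "P"], elements=["O", "P"],
                         resids=[1, 2], resnames=["TYR", "POPC"],
                         chains=["A", "L"], segclass=["protein", "lipid"])
        with pytest.raises(DegenerateSelectionError, match="OH"):
            count_hbonds(traj, OH_SEL, ACCEPTOR_SEL)

    def test_matches_brute_force_on_toy_lattice(self, rng):
        """Exhaustive pair scan over a random acceptor cloud around one OH."""
        n_acc = 30
        acc = rng.uniform(-5, 5, (n_acc, 3))
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([0.97, 0.0, 0.0])
        coords = np.vstack([d, h, acc])[None]
        traj = make_traj(
            coords, names=["OH", "HH"] + [f"P" for _ in range(n_acc)],
            elements=["O", "H"] + ["P"] * n_acc,
            resids=[1, 1] + list(range(2, n_acc + 2)),
            resnames=["TYR"] * 2 + ["POPC"] * n_acc,
            chains=["A", "A"] + ["L"] * n_acc,
            segclass=["protein"] * 2 + ["lipid"] * n_acc)
        got = count_hbonds(traj, OH_SEL, ACCEPTOR_SEL)[0]
        oracle = 0
        for a in acc:
            if np.linalg.norm(a - d) > 3.0:
                continue
            cosang = np.dot(d - h, a - h) / (
                np.linalg.norm(d - h) * np.linalg.norm(a - h))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 150.0:
                oracle += 1
        assert got == oracle


def probe_with_cations(cation_offsets):
    """Tyr ring at origin plus choline N atoms at given offsets from the centroid."""
    angles = np.deg2rad(np.arange(0, 360, 60))
    ring = 1.39 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
    cats = np.asarray(cation_offsets, dtype=float).reshape(-1, 3)
    coords = np.vstack([ring, cats])[None]
    n_c = len(cats)
    return make_traj(
        coords,
        names=["CG", "CD1", "CE1", "CZ", "CE2", "CD2"] + ["N"] * n_c,
        elements=["C"] * 6 + ["N"] * n_c,
        resids=[1] * 6 + list(range(2, n_c + 2)),
        resnames=["TYR"] * 6 + ["POPC"] * n_c,
        chains=["A"] * 6 + ["L"] * n_c,
        segclass=["protein"] * 6 + ["lipid"] * n_c)


class TestPiCation:
    def test_cutoff_boundary_inclusive(self):
        assert count_pi_cation(probe_with_cations([[0, 0, 4.9]]),
                               RING_SEL, CHOLINE_SEL)[0] == 1
        assert count_pi_cation(probe_with_cations([[0, 0, 5.0]]),
                               RING_SEL, CHOLINE_SEL)[0] == 1  # "no greater than"
        assert count_pi_cation(probe_with_cations([[0, 0, 5.1]]),
                               RING_SEL, CHOLINE_SEL)[0] == 0

    def test_two_cations_additive(self):
        traj = probe_with_cations([[0, 0, 4.0], [0, 0, -4.0]])
        assert count_pi_cation(traj, RING_SEL, CHOLINE_SEL)[0] == 2

    def test_wrong_ring_size_rejected(self):
        traj = probe_with_cations([[0, 0, 4.0]])
        bad = Selection(chain_id="A", atom_names=["CG", "CD1", "CD2"])
        with pytest.raises(DegenerateSelectionError, match="3 atoms"):
            count_pi_cation(traj, bad, CHOLINE_SEL)

    def test_matches_brute_force_on_jittered_membrane(self, rng):
        traj, _truth = gen_membrane_toy(
            ToyMembraneSpec(probe_z=17.0, jitter_sd=0.5, n_frames=3, seed=5))
        got = count_pi_cation(traj, RING_SEL, CHOLINE_SEL)
        top = traj.topology
        ring_idx = RING_SEL.indices(top)
        n_idx = CHOLINE_SEL.indices(top)
        for f in range(3):
            centroid = traj.coords[f][ring_idx].mean(axis=0)  # equal masses
            d = np.linalg.norm(traj.coords[f][n_idx] - centroid, axis=1)
            assert got[f] == int(np.sum(d <= 5.0))


class TestCCContacts:
    def test_exact_cutoff_counts(self):
        ring = probe_with_cations([])
        tail = np.array([[1.39 + 4.5, 0.0, 0.0]])
        coords = np.concatenate([ring.coords[0], tail])[None]
        traj = make_traj(
            coords,
            names=list(ring.topology.atom_name) + ["C22"],
            elements=list(ring.topology.element) + ["C"],
            resids=list(ring.topology.residue_id) + [99],
            resnames=list(ring.topology.residue_name) + ["POPC"],
            chains=list(ring.topology.chain_id) + ["L"],
            segclass=list(ring.topology.segment_class) + ["lipid"])
        # exactly 4.5 A from CG: inclusive boundary -> 1 contact
        assert count_cc_contacts(traj, RING_SEL, TAIL_SEL)[0] == 1

    def test_distant_tails_zero(self):
        # probe in bulk water, all tail carbons > 10 A away
        traj, _ = gen_membrane_toy(ToyMembraneSpec(probe_z=28.0))
        assert count_cc_contacts(traj, RING_SEL, TAIL_SEL)[0] == 0

    def test_non_carbon_selection_rejected(self):
        traj, _ = gen_membrane_toy(ToyMembraneSpec())
        with pytest.raises(DegenerateSelectionError, match="non-carbon"):
            count_cc_contacts(traj, RING_SEL,
                              Selection(segment_class="lipid", atom_names=["P"]))

    def test_matches_all_pairs_oracle(self, rng):
        traj, _ = gen_membrane_toy(
            ToyMembraneSpec(probe_z=12.0, jitter_sd=0.4, n_frames=3, seed=11))
        got = count_cc_contacts(traj, RING_SEL, TAIL_SEL)
        top = traj.topology
        ring_idx = RING_SEL.indices(top)
        tail_idx = TAIL_SEL.indices(top)
        for f in range(3):
            d = np.linalg.norm(traj.coords[f][ring_idx][:, None]
                               - traj.coords[f][tail_idx][None], axis=-1)
            assert got[f] == int(np.sum(d <= 4.5))


class TestSASA:
    def test_isolated_atom_closed_form(self):
        for r in (1.52, 1.7, 1.8):
            area = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=1.4)
            assert area[0] == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=0.01)

    def test_buried_atom_zero(self):
        # center atom fully enclosed by a tight shell of large spheres
        from bklinker.sasa import sphere_points
        shell = 2.0 * sphere_points(40)
        coords = np.vstack([[0.0, 0, 0], shell])
        radii = np.full(len(coords), 1.7)
        area = shrake_rupley(coords, radii, probe=1.4)
        assert area[0] == 0.0

    def test_two_spheres_match_analytic_cap(self):
        """Two equal spheres: hidden area equals the spherical-cap formula."""
        r, probe, d = 1.7, 1.4, 2.0
        R = r + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        area = shrake_rupley(coords, np.full(2, r), probe=probe, n_points=8000)
        cap_height = R - d / 2.0
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * cap_height
        assert area[0] == pytest.approx(expected, rel=0.01)

    def test_agrees_with_mdtraj_oracle(self):
        """Independent Shrake-Rupley (mdtraj) on the same ring geometry."""
        mdtraj = pytest.importorskip("mdtraj")
        angles = np.deg2rad(np.arange(0, 360, 60))
        ring = 1.39 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        top = mdtraj.Topology()
        ch = top.add_chain()
        res = top.add_residue("TYR", ch)
        for i in range(6):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(ring[None] / 10.0, top)  # nm
        # use mdtraj's carbon radius so the comparison isolates the algorithm
        ref = mdtraj.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960)[0] * 100.0
        mine = shrake_rupley(ring, np.full(6, 1.7), probe=1.4, n_points=960)
        assert np.allclose(mine, ref, rtol=0.03)

    def test_burial_zero_without_nearby_lipids(self):
        traj, _ = gen_membrane_toy(ToyMembraneSpec(probe_z=28.0))
        side = Selection(chain_id="A")
        burial = lipid_burial_sasa(traj, side, TAIL_SEL)
        assert burial[0] == 0.0

    def test_burial_monotone_on_approach(self):
        """Burial grows monotonically as a tail carbon approaches the ring."""
        angles = np.deg2rad(np.arange(0, 360, 60))
        ring = 1.39 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        burials = []
        for dz in (8.0, 6.0, 5.0, 4.0, 3.4):
            coords = np.vstack([ring, [0.0, 0.0, dz]])[None]
            traj = make_traj(
                coords,
                names=["CG", "CD1", "CE1", "CZ", "CE2", "CD2", "C22"],
                elements=["C"] * 7,
                resids=[1] * 6 + [2], resnames=["TYR"] * 6 + ["POPC"],
                chains=["A"] * 6 + ["L"],
                segclass=["protein"] * 6 + ["lipid"])
            burials.append(lipid_burial_sasa(
                traj, Selection(chain_id="A"), TAIL_SEL, n_points=1500)[0])
        assert burials[0] == 0.0
        assert all(b1 <= b2 + 1e-9 for b1, b2 in zip(burials, burials[1:]))
        assert burials[-1] > 0.0

    def test_tangent_carbon_matches_fine_grid_oracle(self):
        """Default quadrature agrees with a 10x finer grid within 2%."""
        angles = np.deg2rad(np.arange(0, 360, 60))
        ring = 1.39 * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        coords = np.vstack([ring, [0.0, 0.0, 3.4]])[None]
        traj = make_traj(coords,
                         names=["CG", "CD1", "CE1", "CZ", "CE2", "CD2", "C22"],
                         elements=["C"] * 7,
                         resids=[1] * 6 + [2], resnames=["TYR"] * 6 + ["POPC"],
                         chains=["A"] * 6 + ["L"],
                         segclass=["protein"] * 6 + ["lipid"])
        side = Selection(chain_id="A")
        coarse = lipid_burial_sasa(traj, side, TAIL_SEL, n_points=960)[0]
        fine = lipid_burial_sasa(traj, side, TAIL_SEL, n_points=9600)[0]
        assert coarse == pytest.approx(fine, rel=0.02)


class TestRigidInvariance:
    def test_counts_invariant_under_rigid_motion(self, rng):
        traj, _ = gen_membrane_toy(
            ToyMembraneSpec(probe_z=16.0, jitter_sd=0.3, n_frames=1, seed=2))
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = traj.with_coords(traj.coords @ R.T + t)
        for counter, args in [
            (count_pi_cation, (RING_SEL, CHOLINE_SEL)),
            (count_cc_contacts, (RING_SEL, TAIL_SEL)),
        ]:
            assert counter(traj, *args)[0] == counter(moved, *args)[0]


class TestContactMap:
    def test_bonded_neighbors_probability_one(self, rng):
        coords = rng.normal(0, 0.05, (10, 2, 3)) + np.array([[0, 0, 0], [3.8, 0, 0]])
        traj = make_traj(coords)
        cmap = contact_probability_map(traj, Selection(residue_ids=[1]),
                                       Selection(residue_ids=[2]))
        assert cmap.iloc[0, 0] == 1.0

    def test_never_in_contact_zero(self, rng):
        coords = rng.normal(0, 0.05, (10, 2, 3)) + np.array([[0, 0, 0], [30, 0, 0]])
        cmap = contact_probability_map(make_traj(coords), Selection(residue_ids=[1]),
                                       Selection(residue_ids=[2]))
        assert cmap.iloc[0, 0] == 0.0

    def test_planted_intermittent_contact_fraction(self):
        d = np.full(100, 8.0)
        d[:60] = 4.0
        coords = np.zeros((100, 2, 3))
        coords[:, 1, 0] = d
        cmap = contact_probability_map(make_traj(coords), Selection(residue_ids=[1]),
                                       Selection(residue_ids=[2]), cutoff=5.0)
        assert cmap.iloc[0, 0] == pytest.approx(0.60)

    def test_empty_window_rejected(self, rng):
        traj = make_traj(rng.normal(0, 1, (5, 2, 3)))
        with pytest.raises(ValueError, match="window"):
            contact_probability_map(traj, Selection(residue_ids=[1]),
                                    Selection(residue_ids=[2]), frames=[])


def water_system(water_xyz, upper_z=10.0, lower_z=-10.0):
    planes = np.array([[0.0, 0.0, upper_z], [0.0, 0.0, lower_z]])
    waters = np.asarray(water_xyz, dtype=float).reshape(-1, 3)
    coords = np.vstack([planes, waters])[None]
    nw = len(waters)
    return make_traj(
        coords, names=["CA", "CA"] + ["OH2"] * nw,
        elements=["C", "C"] + ["O"] * nw,
        resids=[1, 2] + list(range(3, nw + 3)),
        resnames=["GLY", "GLY"] + ["TIP3"] * nw,
        chains=["A", "A"] + ["W"] * nw,
        segclass=["protein", "protein"] + ["water"] * nw)


class TestPoreWater:
    UPPER = Selection(chain_id="A", residue_ids=[1])
    LOWER = Selection(chain_id="A", residue_ids=[2])

    def test_waters_inside_cylinder_counted(self):
        traj = water_system([[0, 0, 0], [3, 0, 5], [12, 0, 0], [0, 0, 15]])
        n = pore_water_count(traj, self.UPPER, self.LOWER, radius=10.0)
        assert n[0] == 2  # the off-axis (r=12) and above-plane waters excluded

    def test_dewetted_pore_zero(self):
        traj = water_system([[0, 0, 50], [40, 40, 0]])
        assert pore_water_count(traj, self.UPPER, self.LOWER, radius=10.0)[0] == 0

    def test_matches_point_in_cylinder_oracle(self, rng):
        waters = rng.uniform(-20, 20, (200, 3))
        traj = water_system(waters)
        got = pore_water_count(traj, self.UPPER, self.LOWER, radius=10.0)[0]
        inside = ((np.abs(waters[:, 2]) <= 10.0)
                  & (waters[:, 0] ** 2 + waters[:, 1] ** 2 <= 100.0))
        assert got == int(inside.sum())

    def test_inverted_planes_rejected(self):
        traj = water_system([[0, 0, 0]])
        with pytest.raises(ValueError, match="[Ii]nverted"):
            pore_water_count(traj, self.LOWER, self.UPPER, radius=10.0)


class TestMembraneFrames:
    def test_center_and_leaflets(self):
        traj, _ = gen_membrane_toy(ToyMembraneSpec(interface_z=18.0))
        mf = membrane_frames(traj)[0]
        assert mf.center_z == pytest.approx(0.0, abs=1e-9)
        assert mf.upper_interface_z == pytest.approx(18.0)
        assert mf.lower_interface_z == pytest.approx(-18.0)
        assert set(mf.leaflet.values()) == {"upper", "lower"}


class TestAggregateReplicas:
    def test_identical_replicas_zero_sem(self):
        p = AnchorProfile(n_hbond=np.array([2, 2, 2]))
        agg = aggregate_replicas([p, p, p])
        assert agg.mean["n_hbond"] == 2.0
        assert agg.sem["n_hbond"] == 0.0

    def test_closed_form_sem(self):
        reps = [AnchorProfile(n_cc=np.array([v], dtype=float)) for v in (1, 2, 3)]
        agg = aggregate_replicas(reps)
        assert agg.mean["n_cc"] == pytest.approx(2.0)
        assert agg.sem["n_cc"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-9)

    def test_single_replica_sem_undefined(self):
        with pytest.warns(UserWarning, match="single replica"):
            agg = aggregate_replicas([AnchorProfile(n_hbond=np.array([1, 2]))])
        assert np.isnan(agg.sem["n_hbond"])

    def test_poisson_replicas_match_analytic_sem(self, rng):
        """SEM of time-averaged Poisson counts ~ sqrt(lam/M)/sqrt(n)."""
        lam, M, n = 4.0, 200, 50
        reps = [AnchorProfile(n_pication=rng.poisson(lam, M).astype(float))
                for _ in range(n)]
        agg = aggregate_replicas(reps)
        expected = np.sqrt(lam / M) / np.sqrt(n)
        assert agg.sem["n_pication"] == pytest.approx(expected, rel=0.20)

    def test_window_restricts_time_average(self):
        p1 = AnchorProfile(n_cc=np.array([0.0, 0.0, 10.0, 10.0]))
        p2 = AnchorProfile(n_cc=np.array([0.0, 0.0, 20.0, 20.0]))
        agg = aggregate_replicas([p1, p2], window=slice(2, None))
        assert agg.mean["n_cc"] == pytest.approx(15.0)
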