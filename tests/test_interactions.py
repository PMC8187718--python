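"""Contacts, salt bridges, and residue-pair interaction energies."""

import numpy as np
import pytest

from allotrace.interactions import (
    ParameterTable, contact_scan, interaction_energy, load_default_parameters,
    pair_profile, salt_bridge_classify, salt_bridge_occupancy,
)
from allotrace.structure_io import AtomRecord, Structure, Trajectory
from allotrace.synthetic import StateSpec, SyntheticSpec, generate_trajectory


@pytest.fixture(scope="module")
def point_charges():
    """Two single-atom ±1e residues 3 Å apart, LJ disabled via ε = 0."""
    atoms = [
        AtomRecord(1, "NZ", "LYS", 1, "A", np.zeros(3), "N"),
        AtomRecord(2, "OE1", "GLU", 2, "A", np.array([3.0, 0.0, 0.0]), "O"),
    ]
    table = ParameterTable({("LYS", "NZ"): (1.0, 3.0, 0.0),
                            ("GLU", "OE1"): (-1.0, 3.0, 0.0)})
    return Structure(atoms), table


class TestParameterTable:
    def test_default_table_side_chain_net_charges(self):
        table = load_default_parameters()
        assert table.side_chain_charge("GLU") == pytest.approx(-1.0, abs=1e-6)
        assert table.side_chain_charge("ASP") == pytest.approx(-1.0, abs=1e-6)
        for basic in ("ARG", "LYS", "HIS"):
            assert table.side_chain_charge(basic) == pytest.approx(1.0, abs=1e-6)

    def test_backbone_fallback_and_missing_atom(self):
        table = load_default_parameters()
        q, _, _ = table.lookup("GLY", "CA")
        assert isinstance(q, float)
        with pytest.raises(KeyError, match="XX"):
            table.lookup("GLU", "XX")


class TestInteractionEnergy:
    def test_hand_computed_coulomb_pair(self, point_charges):
        # f·q₁q₂/(ε·r) = 138.935 × (−1) / (20 × 0.3 nm) = −23.16 kJ/mol
        s, table = point_charges
        e = interaction_energy(s.coordinates, s, 1, 2, table, dielectric=20,
                               include_lj=False)
        assert e == pytest.approx(-23.156, abs=0.01)

    def test_screening_linearity(self, point_charges):
        s, table = point_charges
        e20 = interaction_energy(s.coordinates, s, 1, 2, table, dielectric=20)
        e1 = interaction_energy(s.coordinates, s, 1, 2, table, dielectric=1)
        assert e1 / e20 == pytest.approx(20.0, rel=1e-10)

    def test_like_charges_repulsive(self, point_charges):
        s, _ = point_charges
        table = ParameterTable({("LYS", "NZ"): (1.0, 3.0, 0.0),
                                ("GLU", "OE1"): (1.0, 3.0, 0.0)})
        assert interaction_energy(s.coordinates, s, 1, 2, table) > 0

    def test_symmetric_in_pair_swap(self, single_state_traj):
        traj, _ = single_state_traj
        table = load_default_parameters()
        e_ab = interaction_energy(traj.frames[0], traj.topology, 521, 1364, table)
        e_ba = interaction_energy(traj.frames[0], traj.topology, 1364, 521, table)
        assert e_ab == pytest.approx(e_ba, abs=1e-10)

    def test_coulomb_antisymmetric_in_charge_flip(self, point_charges):
        s, table = point_charges
        flipped = ParameterTable({("LYS", "NZ"): (1.0, 3.0, 0.0),
                                  ("GLU", "OE1"): (1.0, 3.0, 0.0)})
        e = interaction_energy(s.coordinates, s, 1, 2, table, include_lj=False)
        e_flip = interaction_energy(s.coordinates, s, 1, 2, flipped, include_lj=False)
        assert e_flip == pytest.approx(-e, abs=1e-10)

    def test_magnitude_decreases_with_distance(self, point_charges):
        _, table = point_charges
        energies = []
        for r in (3.0, 4.0, 6.0, 9.0):
            atoms = [AtomRecord(1, "NZ", "LYS", 1, "A", np.zeros(3), "N"),
                     AtomRecord(2, "OE1", "GLU", 2, "A", np.array([r, 0, 0]), "O")]
            s = Structure(atoms)
            energies.append(abs(interaction_energy(s.coordinates, s, 1, 2, table,
                                                   include_lj=False)))
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_clash_guard(self, point_charges):
        _, table = point_charges
        atoms = [AtomRecord(1, "NZ", "LYS", 1, "A", np.zeros(3), "N"),
                 AtomRecord(2, "OE1", "GLU", 2, "A", np.array([0.3, 0, 0]), "O")]
        s = Structure(atoms)
        with pytest.raises(ValueError, match="clash"):
            interaction_energy(s.coordinates, s, 1, 2, table)

    def test_unparameterised_atom_named(self, single_state_traj):
        traj, _ = single_state_traj
        table = ParameterTable({})
        with pytest.raises(KeyError):
            interaction_energy(traj.frames[0], traj.topology, 521, 1364, table)


class TestSaltBridge:
    def test_wt_his_distance_bridged(self):
        assert salt_bridge_classify(2.4, "HIS", "GLU")

    def test_mutant_his_distance_not_bridged(self):
        assert not salt_bridge_classify(5.9, "HIS", "GLU")

    def test_boundary_inclusive_at_4A(self):
        assert salt_bridge_classify(4.0, "ARG", "GLU")
        assert not salt_bridge_classify(4.0 + 1e-9, "ARG", "GLU")

    def test_non_ionizable_pair_rejected(self):
        with pytest.raises(ValueError, match="salt bridge"):
            salt_bridge_classify(3.0, "GLY", "GLU")
        with pytest.raises(ValueError):
            salt_bridge_classify(3.0, "ARG", "LYS")  # like charges

    def test_occupancy_over_series(self):
        occ = salt_bridge_occupancy([2.5, 3.9, 4.1, 7.0], "HIS", "GLU")
        assert occ == pytest.approx(0.5)


class TestContactScan:
    def test_distant_groups_empty(self, single_state_traj):
        traj, _ = single_state_traj
        # helix-11 midsection is tens of Å from the Walker-A analogue helix
        hits = contact_scan(traj, [585, 586], [1330, 1331], mean_cutoff=3.0)
        assert hits == []

    def test_planted_pair_found(self, single_state_traj):
        traj, _ = single_state_traj
        hits = contact_scan(traj, [521], list(range(1358, 1372)), mean_cutoff=3.0)
        assert [(a, b) for a, b, _ in hits] == [(521, 1364)]

    def test_infinite_cutoff_returns_all_pairs_sorted(self, single_state_traj):
        traj, _ = single_state_traj
        ga, gb = [521, 522], [1364, 1367]
        hits = contact_scan(traj, ga, gb, mean_cutoff=np.inf)
        assert len(hits) == 4
        dists = [d for _, _, d in hits]
        assert dists == sorted(dists)

    def test_matches_brute_force_filter(self, single_state_traj):
        from allotrace.geometry import min_residue_distance
        traj, _ = single_state_traj
        ga, gb = [521, 523], [1364, 1367, 1369]
        cutoff = 10.0
        brute = []
        for a in ga:
            for b in gb:
                m = np.mean([min_residue_distance(traj.frames[f], traj.topology, a, b,
                                                  "heavy")
                             for f in range(traj.n_frames)])
                if m < cutoff:
                    brute.append((a, b, m))
        brute.sort(key=lambda t: t[2])
        ours = contact_scan(traj, ga, gb, cutoff)
        assert [(a, b) for a, b, _ in ours] == [(a, b) for a, b, _ in brute]
        assert np.allclose([d for _, _, d in ours], [d for _, _, d in brute])

    def test_group_validation(self, single_state_traj):
        traj, _ = single_state_traj
        with pytest.raises(ValueError, match="non-empty"):
            contact_scan(traj, [], [1364])
        with pytest.raises(ValueError, match="disjoint"):
            contact_scan(traj, [521], [521, 1364])


class TestPairProfile:
    def test_stable_bridge_full_occupancy_negative_energy(self):
        spec = SyntheticSpec(states=[StateSpec(1.0, bridge_distances={"HIS": 3.0,
                                                                      "ARG": 3.0})],
                             n_frames=10, seed=3, noise_sigma=0.05)
        traj, _ = generate_trajectory(spec)
        prof = pair_profile([traj], (521, 1364))
        assert prof.occupancy == 1.0
        assert prof.bonded
        assert prof.mean_energy < 0

    def test_broken_pair_zero_occupancy_weaker_energy(self):
        near, _ = generate_trajectory(SyntheticSpec(
            states=[StateSpec(1.0, bridge_distances={"HIS": 3.0, "ARG": 3.0})],
            n_frames=10, seed=3, noise_sigma=0.05))
        far, _ = generate_trajectory(SyntheticSpec(
            states=[StateSpec(1.0, bridge_distances={"HIS": 6.0, "ARG": 6.0})],
            n_frames=10, seed=3, noise_sigma=0.05))
        p_near = pair_profile([near], (521, 1364))
        p_far = pair_profile([far], (521, 1364))
        assert p_far.occupancy == 0.0
        assert not p_far.bonded
        assert abs(p_far.mean_energy) < abs(p_near.mean_energy)

    def test_wt_vs_mutant_style_ordering(self):
        from allotrace.synthetic import paper_scenario
        wt = [paper_scenario("wt", seed=s, n_frames=16)[0] for s in (1, 2)]
        mu = [paper_scenario("mutant", seed=s, n_frames=16)[0] for s in (4, 5)]
        p_wt = pair_profile(wt, (521, 1364))
        p_mu = pair_profile(mu, (521, 1364))
        assert p_wt.mean_energy < p_mu.mean_energy  # WT more negative
        assert p_wt.bonded and not p_mu.bonded

    def test_non_ionizable_pair_rejected(self, single_state_traj):
        traj, _ = single_state_traj
        with pytest.raises(ValueError):
            pair_profile([traj], (522, 1364))  # GLY–HIS


def test_end_to_end_discovery_of_planted_communication_pairs():
    """Scan → classify → profile finds exactly the planted triplet."""
    from allotrace.synthetic import paper_scenario
    traj, _ = paper_scenario("wt", seed=1, n_frames=16)
    hits = contact_scan(traj, [521], list(range(1358, 1372)), mean_cutoff=3.5)
    assert {(a, b) for a, b, _ in hits} == {(521, 1364), (521, 1367)}
    for _, b, _ in hits:
        prof = pair_profile([traj], (521, b))
        assert prof.bonded
        assert prof.mean_energy < 0
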