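import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camdyn import energy, fixtures, structure
from camdyn.constants import EPSILON_KCAL, R_KCAL, bjerrum_length, debye_length
from camdyn.energy import ElectrostaticsParams, EnergyBreakdown, System

from conftest import naive_total_energy


def two_bead_topology(r0=1.5, k=100.0):
    return structure.Topology(
        kind=np.array(["CA", "CA"], dtype=object),
        res_id=np.array([1, 2]),
        res_name=np.array(["ALA", "ALA"], dtype=object),
        positions=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        sigma=np.full(2, 3.8), mass=np.ones(2), charge=np.zeros(2),
        bonds=np.array([[0, 1]]), bond_r0=np.array([r0]), bond_k=np.array([k]),
        angles=np.empty((0, 3), int), angle_theta0=np.empty(0), angle_k=np.empty(0),
        dihedrals=np.empty((0, 4), int), dihedral_phi0=np.empty(0),
        dihedral_k1=np.empty(0), dihedral_k3=np.empty(0),
        dihedral_enabled=np.empty(0, bool),
    )


class TestBondedTerms:
    def test_bond_stretched_tenth_angstrom_costs_one_epsilon(self):
        top = two_bead_topology(r0=1.5)
        pos = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        assert energy.bond_energy(top, pos) == pytest.approx(1.0, rel=1e-12)

    def test_angle_displaced_tenth_radian(self, helix_topology):
        top = helix_topology
        i, j, k = top.angles[0]
        pos = top.positions.copy()
        # rotate bead i around j by 0.1 rad in the plane of the angle
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        axis = np.cross(u, v)
        axis /= np.linalg.norm(axis)
        c, s = math.cos(0.1), math.sin(0.1)
        K = np.array([
            [0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        single = structure.Topology.from_dict(top.to_dict())
        single.angles = top.angles[:1]
        single.angle_theta0 = top.angle_theta0[:1]
        single.angle_k = top.angle_k[:1]
        pos[i] = pos[j] + R @ u
        # moving bead i may perturb no other term in this isolated evaluation
        assert energy.angle_energy(single, pos) == pytest.approx(
            20.0 * 0.01, rel=1e-6
        )

    def test_collinear_angle_is_finite(self):
        top = two_bead_topology()
        top.angles = np.array([[0, 1, 0]])  # degenerate on purpose
        top.angle_theta0 = np.array([1.0])
        top.angle_k = np.array([20.0])
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert np.isfinite(energy.angle_energy(top, pos))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, efhand_system, seed):
        rng = np.random.default_rng(seed)
        pos = efhand_system.topology.positions + rng.normal(0, 0.1, efhand_system.topology.positions.shape)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = pos @ R.T + rng.normal(0, 10, 3)
        e1 = efhand_system.potential_energy(pos)
        e2 = efhand_system.potential_energy(moved)
        assert e2 == pytest.approx(e1, rel=1e-8)


class TestRepulsive:
    def test_contact_at_sigma_bar_costs_one_epsilon(self):
        pos = np.array([[0.0, 0, 0], [0.9 * 3.8, 0, 0]])
        pairs = np.array([[0, 1]])
        sigma = np.full(2, 3.8)
        assert energy.repulsive_energy(pos, pairs, sigma) == pytest.approx(1.0)

    def test_double_distance_gives_two_to_minus_twelve(self):
        pos = np.array([[0.0, 0, 0], [2 * 0.9 * 3.8, 0, 0]])
        e = energy.repulsive_energy(pos, np.array([[0, 1]]), np.full(2, 3.8))
        assert e == pytest.approx(2.0**-12, rel=1e-12)

    def test_strictly_decreasing_on_grid(self):
        sigma = np.full(2, 5.0)
        rs = np.linspace(2.0, 20.0, 50)
        es = [
            energy.repulsive_energy(
                np.array([[0.0, 0, 0], [r, 0, 0]]), np.array([[0, 1]]), sigma
            )
            for r in rs
        ]
        assert np.all(np.diff(es) < 0)

    def test_coincident_beads_capped_with_warning(self):
        pos = np.zeros((2, 3))
        with pytest.warns(RuntimeWarning):
            e = energy.repulsive_energy(pos, np.array([[0, 1]]), np.full(2, 3.8))
        assert np.isfinite(e)


class TestNativeWell:
    def test_minimum_is_minus_depth_at_native_distance(self):
        pairs = np.array([[0, 1]])
        r0 = np.array([5.0])
        depth = np.array([1.3])
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert energy.native_energy(pos, pairs, r0, depth) == pytest.approx(-1.3)

    def test_vanishes_at_long_range(self):
        pos = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        e = energy.native_energy(pos, np.array([[0, 1]]), np.array([5.0]), np.array([1.0]))
        assert abs(e) < 1e-8

    def test_numeric_minimum_located_at_native_distance(self):
        rs = np.linspace(3.0, 12.0, 2000)
        es = [
            energy.native_energy(
                np.array([[0.0, 0, 0], [r, 0, 0]]),
                np.array([[0, 1]]), np.array([5.0]), np.array([1.0]),
            )
            for r in rs
        ]
        assert rs[int(np.argmin(es))] == pytest.approx(5.0, abs=0.01)


class TestDebyeHuckel:
    def test_unit_charges_at_bjerrum_length_cost_one_kT(self):
        params = ElectrostaticsParams(ionic_strength_M=0.0)
        lb = bjerrum_length(80.0, 298.0)
        assert lb == pytest.approx(7.01, abs=0.03)  # frozen closed-form value
        pos = np.array([[0.0, 0, 0], [lb, 0, 0]])
        charge = np.array([1.0, 1.0])
        e_eps = energy.debye_huckel_energy(pos, np.array([[0, 1]]), charge, params)
        kT_eps = R_KCAL * 298.0 / EPSILON_KCAL
        assert e_eps == pytest.approx(kT_eps, rel=1e-10)

    def test_debye_lengths_match_closed_form(self):
        assert debye_length(0.1) == pytest.approx(9.71, abs=0.02)
        assert debye_length(0.5) == pytest.approx(4.34, abs=0.02)

    def test_sign_convention(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        params = ElectrostaticsParams(0.1)
        pair = np.array([[0, 1]])
        assert energy.debye_huckel_energy(pos, pair, np.array([1.0, -1.0]), params) < 0
        assert energy.debye_huckel_energy(pos, pair, np.array([1.0, 1.0]), params) > 0

    def test_coulomb_limit_at_vanishing_ionic_strength(self):
        pos = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        pair = np.array([[0, 1]])
        charge = np.array([1.0, -1.0])
        e_dh = energy.debye_huckel_energy(
            pos, pair, charge, ElectrostaticsParams(1e-13)
        )
        e_coul = energy.debye_huckel_energy(
            pos, pair, charge, ElectrostaticsParams(0.0)
        )
        assert e_dh == pytest.approx(e_coul, rel=1e-6)

    def test_screening_monotone_in_ionic_strength(self):
        pos = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        pair = np.array([[0, 1]])
        charge = np.array([1.0, 1.0])
        mags = [
            abs(energy.debye_huckel_energy(pos, pair, charge, ElectrostaticsParams(i)))
            for i in (0.01, 0.05, 0.1, 0.5, 1.0, 2.0)
        ]
        assert np.all(np.diff(mags) < 0)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            ElectrostaticsParams(-0.1)


class TestCrowderTerm:
    def test_no_crowders_is_zero(self, helix_topology):
        sys_ = System(helix_topology, box=1140.0)
        assert sys_.energy(sys_.initial_positions()).crowder_crowder == 0.0

    def test_two_crowders_at_contact_distance(self, helix_topology):
        sys_ = System(
            helix_topology, box=1140.0,
            crowder_positions=np.array([[500.0, 500, 500], [610.0, 500, 500]]),
        )
        e = sys_.energy(sys_.initial_positions())
        assert e.crowder_crowder == pytest.approx(0.9**12, rel=1e-10)

    def test_periodic_translation_invariance(self, helix_topology):
        crowders = np.array([[100.0, 100, 100], [1100.0, 1100, 1100]])
        sys_ = System(helix_topology, box=1140.0, crowder_positions=crowders)
        pos = sys_.initial_positions()
        shifted = pos + np.array([1140.0, 2 * 1140.0, -1140.0])
        assert sys_.potential_energy(shifted) == pytest.approx(
            sys_.potential_energy(pos), rel=1e-10
        )


class TestTotalEnergy:
    def test_breakdown_total_is_sum_of_components(self, efhand_system):
        br = efhand_system.energy(efhand_system.initial_positions())
        comp_sum = sum(
            getattr(br, n)
            for n in (
                "bond", "angle", "dihedral", "native_attractive",
                "nonnative_repulsive", "debye_huckel",
                "crowder_protein", "crowder_crowder",
            )
        )
        assert br.total == pytest.approx(comp_sum, rel=1e-12)

    def test_reference_state_bonded_zero_native_full(self, efhand_system):
        br = efhand_system.energy(efhand_system.initial_positions())
        assert br.bond < 1e-12 and br.angle < 1e-12
        depths = efhand_system.topology.contact_depth
        assert br.native_attractive == pytest.approx(-depths.sum(), rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_term_matches_naive_double_loop(self, efhand_system, seed):
        rng = np.random.default_rng(seed)
        pos = efhand_system.topology.positions + rng.normal(
            0, 0.25, efhand_system.topology.positions.shape
        )
        br = efhand_system.energy(pos)
        naive = naive_total_energy(efhand_system, pos)
        for term, value in naive.items():
            got = getattr(br, term)
            assert got == pytest.approx(value, rel=1e-10, abs=1e-12), term

    def test_forces_match_finite_differences(self, efhand_system):
        rng = np.random.default_rng(7)
        pos = efhand_system.topology.positions + rng.normal(
            0, 0.15, efhand_system.topology.positions.shape
        )
        f = efhand_system.forces(pos)
        h = 1e-5
        for _ in range(60):
            i = rng.integers(0, len(pos))
            a = rng.integers(0, 3)
            p1, p2 = pos.copy(), pos.copy()
            p1[i, a] += h
            p2[i, a] -= h
            fd = -(
                efhand_system.potential_energy(p1)
                - efhand_system.potential_energy(p2)
            ) / (2 * h)
            assert f[i, a] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_screening_never_raises_dh_magnitude(self, efhand):
        top = structure.coarse_grain(efhand.record_set)
        # charge a few residues so nonbonded charged pairs exist
        top.charge[top.kind == "SC"] = np.resize(
            [1.0, -1.0, 0.0], int(np.sum(top.kind == "SC"))
        )
        mags = []
        for i_strength in (0.05, 0.1, 0.3, 0.6):
            sys_ = System(top, electrostatics=ElectrostaticsParams(i_strength))
            mags.append(abs(sys_.energy(top.positions).debye_huckel))
        assert np.all(np.diff(mags) <= 0)
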