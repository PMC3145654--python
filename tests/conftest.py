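import numpy as np
import pytest

from camdyn import energy, fixtures, structure


@pytest.fixture(scope="session")
def helix_record_set():
    return fixtures.make_ideal_helix(12)


@pytest.fixture(scope="session")
def helix_topology(helix_record_set):
    return structure.coarse_grain(helix_record_set)


@pytest.fixture(scope="session")
def efhand():
    return fixtures.make_mini_efhand(100.0)


@pytest.fixture(scope="session")
def efhand_system(efhand):
    """Fully built holo-style system: calcium, charges, native contacts."""
    top = structure.coarse_grain(efhand.record_set)
    top = structure.attach_calcium(top, efhand.record_set, efhand.connectivity)
    top = structure.assign_charges(top)
    top = structure.build_native_contacts(efhand.record_set, top, cutoff=6.5)
    return energy.System(top, electrostatics=energy.ElectrostaticsParams(0.1))


def naive_total_energy(system, positions):
    """Independent single-loop evaluation of every Hamiltonian term."""
    import math

    from camdyn.constants import COULOMB_KCAL_ANG, EPSILON_KCAL
    from camdyn.structure import angle_between, dihedral_angle

    top = system.topology
    box = system.box
    cut = system.cutoff

    def dist(i, j):
        d = positions[i] - positions[j]
        if box is not None:
            d = d - box * np.round(d / box)
        return float(np.linalg.norm(d))

    e = {}
    e["bond"] = sum(
        k * (dist(i, j) - r0) ** 2
        for (i, j), r0, k in zip(top.bonds, top.bond_r0, top.bond_k)
    )
    e["angle"] = sum(
        ka * (angle_between(positions[i], positions[j], positions[kk]) - t0) ** 2
        for (i, j, kk), t0, ka in zip(top.angles, top.angle_theta0, top.angle_k)
    )
    e["dihedral"] = 0.0
    for quad, p0, k1, k3, en in zip(
        top.dihedrals, top.dihedral_phi0, top.dihedral_k1,
        top.dihedral_k3, top.dihedral_enabled,
    ):
        if not en:
            continue
        phi = dihedral_angle(*(positions[q] for q in quad))
        e["dihedral"] += k1 * (1 - math.cos(phi - p0)) + k3 * (
            1 - math.cos(3 * (phi - p0))
        )
    e["native_attractive"] = 0.0
    for (i, j), r0, d in zip(top.contacts, top.contact_r0, top.contact_depth):
        r = dist(i, j)
        if cut is not None and r >= cut:
            continue
        e["native_attractive"] += d * (5 * (r0 / r) ** 12 - 6 * (r0 / r) ** 10)

    def rep(pairs):
        total = 0.0
        for i, j in pairs:
            r = dist(i, j)
            if cut is not None and r >= cut:
                continue
            sb = 0.9 * 0.5 * (system.sigma[i] + system.sigma[j])
            total += (sb / max(r, 0.05 * sb)) ** 12
        return total

    e["nonnative_repulsive"] = rep(system.repulsive_pairs)
    e["crowder_protein"] = rep(system.crowder_protein_pairs)
    e["crowder_crowder"] = rep(system.crowder_crowder_pairs)
    e["debye_huckel"] = 0.0
    if system.electrostatics is not None:
        es = system.electrostatics
        kappa = es.kappa
        pref = COULOMB_KCAL_ANG / (es.eps_r * EPSILON_KCAL)
        dh_cut = cut if cut is not None else es.cutoff
        for i, j in system.dh_pairs:
            r = dist(i, j)
            if dh_cut is not None and r >= dh_cut:
                continue
            e["debye_huckel"] += (
                pref * system.charge[i] * system.charge[j] * math.exp(-kappa * r) / r
            )
    return e
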