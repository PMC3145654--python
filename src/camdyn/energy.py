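"""Hamiltonian of the coarse-grained model, term by term, with forces.

All energies are returned in reduced units of epsilon (0.6 kcal/mol).
Bonded terms use the no-half-prefactor convention k (x - x0)^2.  Nonbonded
terms: a strictly repulsive (sigma_bar/r)^12 steric wall with
sigma_bar = f (sigma_i + sigma_j)/2, f = 0.9; a 12-10 attractive well on
native contacts; and a Debye-Hückel screened Coulomb term between partial
charges, evaluated in physical units and converted to epsilon.  Forces are
analytic gradients of every term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .constants import (
    COULOMB_KCAL_ANG,
    EPSILON_KCAL,
    R_KCAL,
    SIGMA_CROWDER,
    STERIC_SCALING,
    debye_kappa,
)
from .structure import KIND_CALCIUM, KIND_CROWDER, Topology

# Distances below this fraction of sigma_bar are clamped so the steric wall
# stays finite at r -> 0 (overlapping beads are unphysical but must not NaN).
_R_FLOOR_FRACTION = 0.05


@dataclass
class ElectrostaticsParams:
    """Solution conditions entering the screened Coulomb term."""

    ionic_strength_M: float = 0.1
    eps_r: float = 80.0
    temperature_K: float = 298.0
    cutoff: float | None = None

    def __post_init__(self):
        if self.ionic_strength_M < 0:
            raise ValueError("ionic strength must be >= 0")
        if self.eps_r <= 0:
            raise ValueError("relative dielectric must be > 0")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength_M, self.eps_r, self.temperature_K)


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    native_attractive: float = 0.0
    nonnative_repulsive: float = 0.0
    debye_huckel: float = 0.0
    crowder_protein: float = 0.0
    crowder_crowder: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f.name) for f in fields(self)))

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d


def _pair_vectors(positions, pairs, box=None):
    d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    if box is not None:
        d = d - box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    return d, r


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------

def bond_energy(topology: Topology, positions: np.ndarray) -> float:
    """Sum of k_b (r - r0)^2 over bonds, epsilon units."""
    if len(topology.bonds) == 0:
        return 0.0
    _, r = _pair_vectors(positions, topology.bonds)
    return float(np.sum(topology.bond_k * (r - topology.bond_r0) ** 2))


def bond_forces(topology: Topology, positions: np.ndarray, out: np.ndarray) -> None:
    if len(topology.bonds) == 0:
        return
    d, r = _pair_vectors(positions, topology.bonds)
    r = np.maximum(r, 1e-12)
    dudr = 2.0 * topology.bond_k * (r - topology.bond_r0)
    fpair = -(dudr / r)[:, None] * d  # force on bead i
    np.add.at(out, topology.bonds[:, 0], fpair)
    np.add.at(out, topology.bonds[:, 1], -fpair)


def _angle_geometry(topology, positions):
    i, j, k = topology.angles.T
    u = positions[i] - positions[j]
    v = positions[k] - positions[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    return u, v, nu, nv, c, theta


def angle_energy(topology: Topology, positions: np.ndarray) -> float:
    """Sum of k_theta (theta - theta0)^2, radians, epsilon units."""
    if len(topology.angles) == 0:
        return 0.0
    *_, theta = _angle_geometry(topology, positions)
    return float(np.sum(topology.angle_k * (theta - topology.angle_theta0) ** 2))


def angle_forces(topology: Topology, positions: np.ndarray, out: np.ndarray) -> None:
    if len(topology.angles) == 0:
        return
    u, v, nu, nv, c, theta = _angle_geometry(topology, positions)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
    dudtheta = 2.0 * topology.angle_k * (theta - topology.angle_theta0)
    uhat = u / nu[:, None]
    vhat = v / nv[:, None]
    dth_di = (c[:, None] * uhat - vhat) / (nu * s)[:, None]
    dth_dk = (c[:, None] * vhat - uhat) / (nv * s)[:, None]
    fi = -dudtheta[:, None] * dth_di
    fk = -dudtheta[:, None] * dth_dk
    i, j, k = topology.angles.T
    np.add.at(out, i, fi)
    np.add.at(out, k, fk)
    np.add.at(out, j, -(fi + fk))


def _dihedral_geometry(topology, positions):
    p = positions[topology.dihedrals]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / np.maximum(nb2, 1e-12)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    return b1, b2, b3, n1, n2, nb2, phi


def dihedral_energy(topology: Topology, positions: np.ndarray) -> float:
    """1-fold + 3-fold cosine series anchored at the native torsion."""
    if len(topology.dihedrals) == 0:
        return 0.0
    *_, phi = _dihedral_geometry(topology, positions)
    dphi = phi - topology.dihedral_phi0
    e = topology.dihedral_k1 * (1.0 - np.cos(dphi)) + topology.dihedral_k3 * (
        1.0 - np.cos(3.0 * dphi)
    )
    return float(np.sum(e[topology.dihedral_enabled]))


def dihedral_forces(topology: Topology, positions: np.ndarray, out: np.ndarray) -> None:
    if len(topology.dihedrals) == 0 or not topology.dihedral_enabled.any():
        return
    b1, b2, b3, n1, n2, nb2, phi = _dihedral_geometry(topology, positions)
    dphi = phi - topology.dihedral_phi0
    dudphi = topology.dihedral_k1 * np.sin(dphi) + 3.0 * topology.dihedral_k3 * np.sin(
        3.0 * dphi
    )
    dudphi = np.where(topology.dihedral_enabled, dudphi, 0.0)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # collinear quads have an undefined torsion axis; their torque is dropped
    singular = (n1sq < 1e-8) | (n2sq < 1e-8)
    dudphi = np.where(singular, 0.0, dudphi)
    n1sq = np.maximum(n1sq, 1e-8)
    n2sq = np.maximum(n2sq, 1e-8)
    dphi_d1 = (nb2 / n1sq)[:, None] * n1
    dphi_d4 = -(nb2 / n2sq)[:, None] * n2
    t = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
    s = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
    dphi_d2 = -(1.0 + t) * dphi_d1 + s * dphi_d4
    dphi_d3 = t * dphi_d1 - (1.0 + s) * dphi_d4
    g = dudphi[:, None]
    quads = topology.dihedrals
    np.add.at(out, quads[:, 0], -g * dphi_d1)
    np.add.at(out, quads[:, 1], -g * dphi_d2)
    np.add.at(out, quads[:, 2], -g * dphi_d3)
    np.add.at(out, quads[:, 3], -g * dphi_d4)


# ---------------------------------------------------------------------------
# Nonbonded pair terms
# ---------------------------------------------------------------------------

def repulsive_energy(
    positions: np.ndarray,
    pairs: np.ndarray,
    sigma: np.ndarray,
    f: float = STERIC_SCALING,
    box: float | None = None,
    cutoff: float | None = None,
) -> float:
    """Strictly repulsive steric term: sum eps (sigma_bar / r)^12."""
    e, _ = _repulsive_terms(positions, pairs, sigma, f, box, cutoff)
    return float(e.sum())


def _repulsive_terms(positions, pairs, sigma, f, box, cutoff, with_force=False):
    if len(pairs) == 0:
        z = np.zeros(0)
        return z, None
    d, r = _pair_vectors(positions, pairs, box)
    sbar = f * 0.5 * (sigma[pairs[:, 0]] + sigma[pairs[:, 1]])
    floor = _R_FLOOR_FRACTION * sbar
    clamped = r < floor
    if np.any(clamped):
        warnings.warn(
            "bead overlap below the clamping floor; repulsive energy capped",
            RuntimeWarning,
            stacklevel=3,
        )
    rc = np.maximum(r, floor)
    e = (sbar / rc) ** 12
    if cutoff is not None:
        e = np.where(r < cutoff, e, 0.0)
    force = None
    if with_force:
        dudr = -12.0 * e / rc
        if cutoff is not None:
            dudr = np.where(r < cutoff, dudr, 0.0)
        force = -(dudr / np.maximum(r, 1e-12))[:, None] * d
    return e, force


def native_energy(
    positions: np.ndarray,
    pairs: np.ndarray,
    r0: np.ndarray,
    depth: np.ndarray,
    box: float | None = None,
    cutoff: float | None = None,
) -> float:
    """12-10 attractive well per native contact, minimum -depth at r0."""
    e, _ = _native_terms(positions, pairs, r0, depth, box, cutoff)
    return float(e.sum())


def _native_terms(positions, pairs, r0, depth, box, cutoff, with_force=False):
    if len(pairs) == 0:
        return np.zeros(0), None
    d, r = _pair_vectors(positions, pairs, box)
    rc = np.maximum(r, 0.05 * r0)
    q10 = (r0 / rc) ** 10
    q12 = q10 * (r0 / rc) ** 2
    e = depth * (5.0 * q12 - 6.0 * q10)
    if cutoff is not None:
        e = np.where(r < cutoff, e, 0.0)
    force = None
    if with_force:
        dudr = (60.0 * depth / rc) * (q10 - q12)
        if cutoff is not None:
            dudr = np.where(r < cutoff, dudr, 0.0)
        force = -(dudr / np.maximum(r, 1e-12))[:, None] * d
    return e, force


def debye_huckel_energy(
    positions: np.ndarray,
    pairs: np.ndarray,
    charge: np.ndarray,
    params: ElectrostaticsParams,
    box: float | None = None,
    cutoff: float | None = None,
) -> float:
    """Screened Coulomb energy over the given pairs, epsilon units.

    V_ij = Z_i Z_j e^2 exp(-kappa r) / (4 pi eps0 eps_r r); evaluated in
    kcal/mol via the Coulomb prefactor and divided by epsilon = 0.6.
    """
    e, _ = _dh_terms(positions, pairs, charge, params, box, cutoff)
    return float(e.sum())


def _dh_terms(positions, pairs, charge, params, box, cutoff, with_force=False):
    if len(pairs) == 0:
        return np.zeros(0), None
    d, r = _pair_vectors(positions, pairs, box)
    rc = np.maximum(r, 1e-3)
    qq = charge[pairs[:, 0]] * charge[pairs[:, 1]]
    kappa = params.kappa
    pref = COULOMB_KCAL_ANG / (params.eps_r * EPSILON_KCAL)
    e = pref * qq * np.exp(-kappa * rc) / rc
    cut = cutoff if cutoff is not None else params.cutoff
    if cut is not None:
        e = np.where(r < cut, e, 0.0)
    force = None
    if with_force:
        dudr = -e * (kappa + 1.0 / rc)
        if cut is not None:
            dudr = np.where(r < cut, dudr, 0.0)
        force = -(dudr / np.maximum(r, 1e-12))[:, None] * d
    return e, force


def thermal_energy_kT(params: ElectrostaticsParams) -> float:
    """k_B T at the electrostatics temperature, in epsilon units."""
    return R_KCAL * params.temperature_K / EPSILON_KCAL


# ---------------------------------------------------------------------------
# The assembled system
# ---------------------------------------------------------------------------

class System:
    """A topology plus solution conditions, crowders, and a periodic box.

    Builds the pair bookkeeping once: bonded (1-2) and angle (1-3) pairs are
    excluded from all nonbonded terms; native contacts attract; every other
    protein pair (and anything involving a calcium bead) is strictly
    repulsive; charged pairs additionally feel the screened Coulomb term
    (calcium beads carry no screened-Coulomb charge); crowders interact
    with everything through the steric wall only.  With a box, nonbonded
    interactions use the minimum image and a half-box cutoff.
    """

    def __init__(
        self,
        topology: Topology,
        electrostatics: ElectrostaticsParams | None = None,
        box: float | None = None,
        crowder_positions: np.ndarray | None = None,
        crowder_mass: float = 10.0,
        crowder_sigma: float = SIGMA_CROWDER,
    ):
        self.topology = topology
        self.electrostatics = electrostatics
        self.box = box
        n_p = topology.n_beads
        self.n_protein = n_p

        if crowder_positions is not None and len(crowder_positions):
            crowder_positions = np.asarray(crowder_positions, float).reshape(-1, 3)
            n_c = len(crowder_positions)
        else:
            crowder_positions = np.empty((0, 3))
            n_c = 0
        self.n_crowders = n_c
        self.reference_positions = np.vstack([topology.positions, crowder_positions])

        self.sigma = np.concatenate([topology.sigma, np.full(n_c, crowder_sigma)])
        self.mass = np.concatenate([topology.mass, np.full(n_c, crowder_mass)])
        self.charge = np.concatenate([topology.charge, np.zeros(n_c)])
        self.kind = np.concatenate(
            [topology.kind, np.array([KIND_CROWDER] * n_c, dtype=object)]
        )

        excluded = {frozenset(b) for b in topology.bonds.tolist()}
        for i, j, k in topology.angles.tolist():
            excluded.add(frozenset((i, k)))
        native = {frozenset(p) for p in topology.contacts.tolist()}

        rep, dh = [], []
        is_cal = topology.kind == KIND_CALCIUM
        for i in range(n_p):
            for j in range(i + 1, n_p):
                key = frozenset((i, j))
                if key in excluded:
                    continue
                if key not in native:
                    rep.append((i, j))
                if (
                    topology.charge[i] * topology.charge[j] != 0.0
                    and not (is_cal[i] or is_cal[j])
                ):
                    dh.append((i, j))
        self.repulsive_pairs = np.asarray(rep, int).reshape(-1, 2)
        self.dh_pairs = np.asarray(dh, int).reshape(-1, 2)

        if n_c:
            ci = np.arange(n_p, n_p + n_c)
            cp = np.stack(
                np.meshgrid(np.arange(n_p), ci, indexing="ij"), axis=-1
            ).reshape(-1, 2)
            cc = np.array(
                [(a, b) for ai, a in enumerate(ci) for b in ci[ai + 1:]], int
            ).reshape(-1, 2)
        else:
            cp = np.empty((0, 2), int)
            cc = np.empty((0, 2), int)
        self.crowder_protein_pairs = cp
        self.crowder_crowder_pairs = cc

    # ------------------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.n_protein + self.n_crowders

    @property
    def cutoff(self) -> float | None:
        """Half-box nonbonded cutoff when periodic, else none."""
        return 0.5 * self.box if self.box else None

    def initial_positions(self) -> np.ndarray:
        return self.reference_positions.copy()

    def energy(self, positions: np.ndarray) -> EnergyBreakdown:
        top = self.topology
        cut = self.cutoff
        box = self.box
        br = EnergyBreakdown(
            bond=bond_energy(top, positions),
            angle=angle_energy(top, positions),
            dihedral=dihedral_energy(top, positions),
            native_attractive=native_energy(
                positions, top.contacts, top.contact_r0, top.contact_depth,
                box=box, cutoff=cut,
            ),
            nonnative_repulsive=repulsive_energy(
                positions, self.repulsive_pairs, self.sigma, box=box, cutoff=cut
            ),
            crowder_protein=repulsive_energy(
                positions, self.crowder_protein_pairs, self.sigma,
                box=box, cutoff=cut,
            ),
            crowder_crowder=repulsive_energy(
                positions, self.crowder_crowder_pairs, self.sigma,
                box=box, cutoff=cut,
            ),
        )
        if self.electrostatics is not None:
            br.debye_huckel = debye_huckel_energy(
                positions, self.dh_pairs, self.charge, self.electrostatics,
                box=box, cutoff=cut,
            )
        return br

    def potential_energy(self, positions: np.ndarray) -> float:
        return self.energy(positions).total

    def forces(self, positions: np.ndarray) -> np.ndarray:
        top = self.topology
        out = np.zeros_like(positions)
        bond_forces(top, positions, out)
        angle_forces(top, positions, out)
        dihedral_forces(top, positions, out)
        cut = self.cutoff
        box = self.box
        for pairs in (
            self.repulsive_pairs,
            self.crowder_protein_pairs,
            self.crowder_crowder_pairs,
        ):
            _, f = _repulsive_terms(
                positions, pairs, self.sigma, STERIC_SCALING, box, cut,
                with_force=True,
            )
            if f is not None:
                np.add.at(out, pairs[:, 0], f)
                np.add.at(out, pairs[:, 1], -f)
        _, f = _native_terms(
            positions, top.contacts, top.contact_r0, top.contact_depth,
            box, cut, with_force=True,
        )
        if f is not None:
            np.add.at(out, top.contacts[:, 0], f)
            np.add.at(out, top.contacts[:, 1], -f)
        if self.electrostatics is not None:
            _, f = _dh_terms(
                positions, self.dh_pairs, self.charge, self.electrostatics,
                box, cut, with_force=True,
            )
            if f is not None:
                np.add.at(out, self.dh_pairs[:, 0], f)
                np.add.at(out, self.dh_pairs[:, 1], -f)
        return out
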