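"""Synthetic inputs: toy structures, perturbed ensembles, harmonic benchmarks.

Everything every other module needs for testing is generated here
deterministically, with no downloads: ideal helices and extended chains
written as valid PDB, a desk-scale helix-loop-helix calcium-binding motif,
Gaussian-perturbed reference ensembles, and independent harmonic wells with
closed-form thermodynamics for validating the sampler and WHAM.

Helix geometry constants: 100 degrees of turn and 1.5 A rise per residue at
2.3 A radius, giving the realistic ~3.8 A C-alpha spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .structure import AtomRecordSet, HelixRecord

HELIX_TURN_DEG = 100.0
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
SIDECHAIN_OFFSET = 1.5   # radial displacement of the pseudo side-chain atom
EXTENDED_SPACING = 3.8


@dataclass
class FixtureSpec:
    kind: str                      # ideal_helix | helix_loop_helix | mini_efhand
    #                              # | extended_chain | harmonic_oscillator
    #                              # | reference_ensemble
    size: int = 10
    angle_deg: float = 90.0
    perturbation_sd: float = 0.0
    n_frames: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _atom_array(records):
    """Build a biotite AtomArray from (res_id, res_name, atom_name, element,
    hetero, xyz) tuples."""
    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r[5] for r in records], dtype=np.float32)
    arr.chain_id = np.full(len(records), "A")
    arr.res_id = np.array([r[0] for r in records], dtype=int)
    arr.res_name = np.array([r[1] for r in records])
    arr.atom_name = np.array([r[2] for r in records])
    arr.element = np.array([r[3] for r in records])
    arr.hetero = np.array([r[4] for r in records], dtype=bool)
    arr.set_annotation("occupancy", np.ones(len(records), dtype=np.float32))
    arr.set_annotation("b_factor", np.zeros(len(records), dtype=np.float32))
    return arr


def _helix_coords(n: int, phase_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha and pseudo side-chain coordinates of an ideal helix on +z."""
    k = np.arange(n)
    # negative sense gives the right-handed twist of a natural alpha-helix
    theta = -np.radians(HELIX_TURN_DEG * k + phase_deg)
    ca = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * k],
        axis=1,
    )
    r_sc = HELIX_RADIUS + SIDECHAIN_OFFSET
    sc = np.stack(
        [r_sc * np.cos(theta), r_sc * np.sin(theta), HELIX_RISE * k], axis=1
    )
    return ca, sc


def _build_record_set(ca, sc, res_names, start_res_id=1, helices=None,
                      hetero_records=()):
    records = []
    for i, name in enumerate(res_names):
        rid = start_res_id + i
        records.append((rid, name, "CA", "C", False, ca[i]))
        if name != "GLY" and sc[i] is not None:
            records.append((rid, name, "CB", "C", False, sc[i]))
    records.extend(hetero_records)
    return AtomRecordSet(atoms=_atom_array(records), helices=list(helices or []))


def make_ideal_helix(n_residues: int, res_names=None) -> AtomRecordSet:
    """Ideal alpha-helix-like C-alpha trace with radial pseudo side chains."""
    if n_residues < 5:
        raise ValueError("an ideal helix needs at least five residues")
    ca, sc = _helix_coords(n_residues)
    names = list(res_names) if res_names else ["ALA"] * n_residues
    if len(names) != n_residues:
        raise ValueError("residue name list length mismatch")
    helices = [HelixRecord("H1", "A", 1, n_residues)]
    return _build_record_set(ca, sc, names, helices=helices)


def make_extended_chain(n_residues: int, res_names=None) -> AtomRecordSet:
    """Fully extended chain: C-alphas on a line at 3.8 A spacing."""
    if n_residues < 2:
        raise ValueError("need at least two residues")
    k = np.arange(n_residues)
    ca = np.stack([EXTENDED_SPACING * k, np.zeros(n_residues), np.zeros(n_residues)], 1)
    sc = np.stack(
        [EXTENDED_SPACING * k, np.full(n_residues, 2.5), np.zeros(n_residues)], 1
    )
    names = list(res_names) if res_names else ["ALA"] * n_residues
    return _build_record_set(ca, sc, names)


def _rotation_to_angle(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an axis perpendicular to v, by angle_deg."""
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, v)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v, helper)
    axis /= np.linalg.norm(axis)
    a = math.radians(angle_deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


@dataclass
class MiniEFHand:
    record_set: AtomRecordSet
    calcium_position: np.ndarray
    connectivity: dict[int, list[int]]
    helix_residues: tuple[tuple[int, int], tuple[int, int]]


def make_mini_efhand(
    interhelix_angle_deg: float = 90.0,
    helix_len: int = 10,
    loop_len: int = 5,
) -> MiniEFHand:
    """Desk-scale helix-loop-helix calcium-binding motif.

    Two ideal helices joined by a loop, oriented so the angle between their
    endpoint vectors equals the request (the second helix is rotated by
    exactly that angle about an axis perpendicular to the first helix's
    endpoint vector).  A calcium ion sits at the loop centroid with three
    acidic loop residues as its ligands.
    """
    if not (0.0 < interhelix_angle_deg < 180.0):
        raise ValueError("interhelix angle must be in (0, 180) degrees")
    ca1, sc1 = _helix_coords(helix_len)
    v1 = ca1[-4:].mean(axis=0) - ca1[:4].mean(axis=0)
    rot = _rotation_to_angle(v1, interhelix_angle_deg)
    ca2 = (rot @ ca1.T).T
    sc2 = (rot @ sc1.T).T
    # loop runs from helix 1's end along helix 2's direction at C-alpha
    # spacing; helix 2 then continues outward, so the helices cannot clash
    gap_dir = rot @ (v1 / np.linalg.norm(v1))
    loop_normal = np.cross(gap_dir, np.array([0.1, 1.0, 0.2]))
    if np.linalg.norm(loop_normal) < 1e-6:
        loop_normal = np.cross(gap_dir, np.array([1.0, 0.0, 0.0]))
    loop_normal = loop_normal / np.linalg.norm(loop_normal)
    loop_ca = np.array(
        [
            ca1[-1]
            + gap_dir * EXTENDED_SPACING * k
            + 2.5 * math.sin(math.pi * k / (loop_len + 1)) * loop_normal
            for k in range(1, loop_len + 1)
        ]
    )
    shift = (loop_ca[-1] + gap_dir * EXTENDED_SPACING) - ca2[0]
    ca2 = ca2 + shift
    sc2 = sc2 + shift
    loop_sc = loop_ca + 2.0 * loop_normal

    ca = np.vstack([ca1, loop_ca, ca2])
    sc = np.vstack([sc1, loop_sc, sc2])
    n_total = len(ca)
    names = ["ALA"] * n_total
    loop_start = helix_len + 1  # 1-based residue ids
    ligand_residues = [loop_start, loop_start + 1, loop_start + loop_len - 1]
    for rid in ligand_residues:
        names[rid - 1] = "ASP"

    ligand_sc = loop_sc[[0, 1, loop_len - 1]]
    calcium = ligand_sc.mean(axis=0) + 2.5 * loop_normal
    het = [(900, "CA", "CA", "CA", True, calcium)]
    helices = [
        HelixRecord("H1", "A", 1, helix_len),
        HelixRecord("H2", "A", helix_len + loop_len + 1, n_total),
    ]
    rs = _build_record_set(ca, sc, names, helices=helices, hetero_records=het)
    return MiniEFHand(
        record_set=rs,
        calcium_position=np.asarray(calcium),
        connectivity={1: ligand_residues},
        helix_residues=((1, helix_len), (helix_len + loop_len + 1, n_total)),
    )


def make_helix_coil_helix(
    helix1: int = 12, coil: int = 7, helix2: int = 12
) -> np.ndarray:
    """C-alpha trace: helix, extended coil, helix — for helicity estimators."""
    ca1, _ = _helix_coords(helix1)
    d = np.array([1.0, 0.0, 0.6])
    d /= np.linalg.norm(d)
    coil_ca = ca1[-1] + d * EXTENDED_SPACING * np.arange(1, coil + 1)[:, None]
    ca2, _ = _helix_coords(helix2)
    ca2 = ca2 + (coil_ca[-1] + d * EXTENDED_SPACING) - ca2[0]
    return np.vstack([ca1, coil_ca, ca2])


def make_reference_ensemble(
    reference: np.ndarray, n_frames: int, perturbation_sd: float, seed: int = 0
) -> list[np.ndarray]:
    """Gaussian-perturbed copies of a reference conformation."""
    if perturbation_sd < 0:
        raise ValueError("perturbation sd must be >= 0")
    ref = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    return [
        ref + rng.normal(0.0, perturbation_sd, size=ref.shape)
        for _ in range(n_frames)
    ]


class HarmonicSystem:
    """Independent 3-D harmonic wells with closed-form thermodynamics.

    U = (k/2) sum_i |x_i - x0_i|^2, so <U> = (3/2) N k_BT at temperature T
    and the configurational partition function scales as beta^(-3N/2) —
    the oracle for validating the Langevin sampler and WHAM reweighting.
    """

    def __init__(self, n_particles: int, spring_constant: float = 1.0):
        if n_particles < 1:
            raise ValueError("need at least one particle")
        self.n_particles = n_particles
        self.k = spring_constant
        self.mass = np.ones(n_particles)
        self.n_protein = 0
        self.sigma = None
        self.centers = np.zeros((n_particles, 3))

    def initial_positions(self) -> np.ndarray:
        return self.centers.copy()

    def potential_energy(self, positions: np.ndarray) -> float:
        d = positions - self.centers
        return float(0.5 * self.k * np.sum(d * d))

    def forces(self, positions: np.ndarray) -> np.ndarray:
        return -self.k * (positions - self.centers)

    def mean_potential_energy(self, temperature: float) -> float:
        return 1.5 * self.n_particles * temperature

    def log_partition_ratio(self, t_a: float, t_b: float) -> float:
        """ln[Z(t_b)/Z(t_a)] of the configurational partition function."""
        return 1.5 * 3 * self.n_particles / 3 * math.log(t_b / t_a)


def make_harmonic_system(n_particles: int, spring_constant: float = 1.0) -> HarmonicSystem:
    return HarmonicSystem(n_particles, spring_constant)


def make_fixture(spec: FixtureSpec):
    """Dispatch on the fixture kind; deterministic per (spec, seed)."""
    if spec.kind == "ideal_helix":
        return make_ideal_helix(spec.size)
    if spec.kind == "extended_chain":
        return make_extended_chain(spec.size)
    if spec.kind in ("mini_efhand", "helix_loop_helix"):
        return make_mini_efhand(spec.angle_deg, helix_len=spec.size)
    if spec.kind == "harmonic_oscillator":
        return make_harmonic_system(spec.size, spec.extra.get("spring_constant", 1.0))
    if spec.kind == "reference_ensemble":
        ref = spec.extra["reference"]
        return make_reference_ensemble(
            ref, spec.n_frames, spec.perturbation_sd, spec.seed
        )
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
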