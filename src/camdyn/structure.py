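"""Structure ingestion and coarse-graining into the two-bead-per-residue model.

A protein is reduced to one backbone bead per residue (at the C-alpha
position) and one side-chain bead at the side-chain heavy-atom centroid
(glycine contributes no side-chain bead).  Bound calcium ions become
explicit beads tethered by stiff springs to the side-chain beads of their
coordinating acidic residues.  Bonded reference geometry (bond lengths,
angles, dihedrals) is measured from the input structure so the reference
conformation has zero bonded energy.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .constants import (
    K_ANGLE,
    K_BOND,
    SIGMA_BACKBONE,
    SIGMA_CALCIUM,
)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: vdW diameters (Angstrom) of the side-chain beads, by residue, scaled to
#: side-chain heavy-atom volume; overridable via the ``radii`` argument.
SIDECHAIN_SIGMA = {
    "ALA": 5.0, "ARG": 6.6, "ASN": 5.7, "ASP": 5.6, "CYS": 5.5,
    "GLN": 6.0, "GLU": 6.0, "GLY": 0.0, "HIS": 6.1, "ILE": 6.2,
    "LEU": 6.2, "LYS": 6.4, "MET": 6.2, "PHE": 6.4, "PRO": 5.6,
    "SER": 5.2, "THR": 5.6, "TRP": 6.8, "TYR": 6.5, "VAL": 5.9,
}

#: Calcium-to-residue connectivity of holo calmodulin: each of the four
#: bound ions is tethered to the side chains of the listed residues.
CAM_CALCIUM_CONNECTIVITY = {
    1: [20, 22, 24, 31],
    2: [56, 58, 64, 67],
    3: [93, 95, 104],
    4: [129, 131, 133, 140],
}

KIND_CA = "CA"
KIND_SC = "SC"
KIND_CALCIUM = "CALCIUM"
KIND_CROWDER = "CROWDER"


class StructureError(ValueError):
    """Raised when an input structure violates the model's assumptions."""


@dataclass
class HelixRecord:
    helix_id: str
    chain: str
    start: int
    end: int


@dataclass
class AtomRecordSet:
    """Heavy atoms of one model, plus HELIX annotations."""

    atoms: struc.AtomArray
    helices: list[HelixRecord] = field(default_factory=list)

    def amino_atoms(self) -> struc.AtomArray:
        """Polymer atoms: non-hetero residues that carry a C-alpha atom."""
        at = self.atoms
        has_ca = np.isin(
            at.res_id, np.unique(at.res_id[(at.atom_name == "CA") & ~at.hetero])
        )
        return at[~at.hetero & has_ca]

    def residue_ids(self) -> np.ndarray:
        aa = self.amino_atoms()
        return np.unique(aa.res_id)

    def calcium_positions(self) -> np.ndarray:
        """Coordinates of non-polymer calcium ions, in file order."""
        at = self.atoms
        mask = (at.res_name == "CA") | (
            (np.char.upper(at.element) == "CA") & at.hetero
        )
        return np.asarray(at.coord[mask], dtype=float)


@dataclass
class ChargeTable:
    """Per-residue backbone/side-chain partial charges, elementary units."""

    charges: dict[int, tuple[float, float]]
    provenance: str = "user"

    def total_charge(self) -> float:
        return float(sum(qb + qs for qb, qs in self.charges.values()))


def read_charge_table(text: str, provenance: str = "file") -> ChargeTable:
    """Parse a tab/space-delimited table: resnum resname q_backbone q_sidechain."""
    charges: dict[int, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 4:
            raise StructureError(f"malformed charge-table line: {line!r}")
        resnum = int(fields[0])
        charges[resnum] = (float(fields[2]), float(fields[3]))
    if not charges:
        raise StructureError("charge table contains no entries")
    return ChargeTable(charges, provenance)


def write_charge_table(table: ChargeTable, resnames: dict[int, str] | None = None) -> str:
    lines = ["# resnum\tresname\tq_backbone\tq_sidechain"]
    for resnum in sorted(table.charges):
        qb, qs = table.charges[resnum]
        name = (resnames or {}).get(resnum, "UNK")
        lines.append(f"{resnum}\t{name}\t{qb:.6f}\t{qs:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def parse_structure(pdb_text: str) -> AtomRecordSet:
    """Read a PDB character stream into an :class:`AtomRecordSet`.

    Only the first model is used; alternate locations are resolved to the
    highest-occupancy conformer; hydrogens are dropped; HELIX records are
    retained as annotations.  Residues with insertion codes are rejected,
    and every amino-acid residue must carry a C-alpha atom.
    """
    if not pdb_text.strip():
        raise StructureError("empty PDB input")
    pdb_file = pdbio.PDBFile.read(io.StringIO(pdb_text))
    if pdb_file.get_model_count() < 1:
        raise StructureError("PDB input contains no coordinate model")
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    if np.any(atoms.ins_code != ""):
        bad = atoms.res_id[atoms.ins_code != ""][0]
        raise StructureError(
            f"insertion codes are not supported (residue {bad})"
        )
    atoms = atoms[np.char.upper(atoms.element) != "H"]
    if not np.all(np.isfinite(atoms.coord)):
        raise StructureError("non-finite coordinates in PDB input")

    chain = atoms[~atoms.hetero & (atoms.res_name != "HOH")]
    for res_id in np.unique(chain.res_id):
        res = chain[chain.res_id == res_id]
        if not np.any(res.atom_name == "CA"):
            name = res.res_name[0]
            raise StructureError(f"residue {name}{res_id} has no C-alpha atom")

    helices = []
    for line in pdb_text.splitlines():
        if line.startswith("HELIX"):
            helices.append(
                HelixRecord(
                    helix_id=line[11:14].strip(),
                    chain=line[19:20].strip(),
                    start=int(line[21:25]),
                    end=int(line[33:37]),
                )
            )
    return AtomRecordSet(atoms=atoms, helices=helices)


def to_pdb_text(record_set: AtomRecordSet) -> str:
    """Serialize an :class:`AtomRecordSet` back to PDB text."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(record_set.atoms)
    body = "\n".join(pdb_file.lines) + "\n"
    helix_lines = []
    for i, h in enumerate(record_set.helices, start=1):
        helix_lines.append(
            f"HELIX  {i:>3} {h.helix_id:>3} XXX {h.chain:1}{h.start:>5} "
            f"XXX {h.chain:1}{h.end:>5} {1:>2}{'':30s}{h.end - h.start + 1:>5}"
        )
    header = ("\n".join(helix_lines) + "\n") if helix_lines else ""
    return header + body


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Bead:
    index: int
    kind: str
    res_name: str
    res_id: int
    position: np.ndarray
    sigma: float
    mass: float
    charge: float


@dataclass
class Topology:
    """Beads plus bonded terms and the native-contact list.

    Array-of-struct layout: parallel numpy arrays indexed by bead.  ``sigma``
    is the vdW diameter entering the repulsive term's sigma_bar.
    """

    kind: np.ndarray              # (N,) str
    res_id: np.ndarray            # (N,) int, 0 for crowders
    res_name: np.ndarray          # (N,) str
    positions: np.ndarray         # (N,3) reference coordinates, Angstrom
    sigma: np.ndarray             # (N,) vdW diameter, Angstrom
    mass: np.ndarray              # (N,) reduced units
    charge: np.ndarray            # (N,) elementary units

    bonds: np.ndarray             # (M,2) int
    bond_r0: np.ndarray           # (M,)
    bond_k: np.ndarray            # (M,) in epsilon
    angles: np.ndarray            # (K,3) int
    angle_theta0: np.ndarray      # (K,) radians
    angle_k: np.ndarray           # (K,)
    dihedrals: np.ndarray         # (L,4) int
    dihedral_phi0: np.ndarray     # (L,) radians
    dihedral_k1: np.ndarray       # (L,)
    dihedral_k3: np.ndarray       # (L,)
    dihedral_enabled: np.ndarray  # (L,) bool

    contacts: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    contact_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    contact_depth: np.ndarray = field(default_factory=lambda: np.empty(0))
    contact_residues: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), int)
    )
    calcium_attachments: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.kind)

    @property
    def n_residues(self) -> int:
        return int(np.sum(self.kind == KIND_CA))

    def beads(self) -> list[Bead]:
        return [
            Bead(
                i,
                str(self.kind[i]),
                str(self.res_name[i]),
                int(self.res_id[i]),
                self.positions[i].copy(),
                float(self.sigma[i]),
                float(self.mass[i]),
                float(self.charge[i]),
            )
            for i in range(self.n_beads)
        ]

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kind == KIND_CA)

    def sc_index_of(self, res_id: int) -> int:
        """Side-chain bead of a residue, or its CA bead for glycine."""
        hits = np.flatnonzero((self.kind == KIND_SC) & (self.res_id == res_id))
        if hits.size:
            return int(hits[0])
        hits = np.flatnonzero((self.kind == KIND_CA) & (self.res_id == res_id))
        if not hits.size:
            raise StructureError(f"residue {res_id} not in topology")
        return int(hits[0])

    def ca_index_of(self, res_id: int) -> int:
        hits = np.flatnonzero((self.kind == KIND_CA) & (self.res_id == res_id))
        if not hits.size:
            raise StructureError(f"residue {res_id} not in topology")
        return int(hits[0])

    def total_charge(self) -> float:
        return float(self.charge.sum())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "kind": arr(self.kind), "res_id": arr(self.res_id),
            "res_name": arr(self.res_name), "positions": arr(self.positions),
            "sigma": arr(self.sigma), "mass": arr(self.mass),
            "charge": arr(self.charge),
            "bonds": arr(self.bonds), "bond_r0": arr(self.bond_r0),
            "bond_k": arr(self.bond_k),
            "angles": arr(self.angles), "angle_theta0": arr(self.angle_theta0),
            "angle_k": arr(self.angle_k),
            "dihedrals": arr(self.dihedrals),
            "dihedral_phi0": arr(self.dihedral_phi0),
            "dihedral_k1": arr(self.dihedral_k1),
            "dihedral_k3": arr(self.dihedral_k3),
            "dihedral_enabled": arr(self.dihedral_enabled),
            "contacts": arr(self.contacts), "contact_r0": arr(self.contact_r0),
            "contact_depth": arr(self.contact_depth),
            "contact_residues": arr(self.contact_residues),
            "calcium_attachments": {
                str(k): v for k, v in self.calcium_attachments.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            kind=np.array(d["kind"], dtype=object),
            res_id=np.asarray(d["res_id"], dtype=int),
            res_name=np.array(d["res_name"], dtype=object),
            positions=np.asarray(d["positions"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            mass=np.asarray(d["mass"], dtype=float),
            charge=np.asarray(d["charge"], dtype=float),
            bonds=np.asarray(d["bonds"], dtype=int).reshape(-1, 2),
            bond_r0=np.asarray(d["bond_r0"], dtype=float),
            bond_k=np.asarray(d["bond_k"], dtype=float),
            angles=np.asarray(d["angles"], dtype=int).reshape(-1, 3),
            angle_theta0=np.asarray(d["angle_theta0"], dtype=float),
            angle_k=np.asarray(d["angle_k"], dtype=float),
            dihedrals=np.asarray(d["dihedrals"], dtype=int).reshape(-1, 4),
            dihedral_phi0=np.asarray(d["dihedral_phi0"], dtype=float),
            dihedral_k1=np.asarray(d["dihedral_k1"], dtype=float),
            dihedral_k3=np.asarray(d["dihedral_k3"], dtype=float),
            dihedral_enabled=np.asarray(d["dihedral_enabled"], dtype=bool),
            contacts=np.asarray(d["contacts"], dtype=int).reshape(-1, 2),
            contact_r0=np.asarray(d["contact_r0"], dtype=float),
            contact_depth=np.asarray(d["contact_depth"], dtype=float),
            contact_residues=np.asarray(
                d["contact_residues"], dtype=int
            ).reshape(-1, 2),
            calcium_attachments={
                int(k): list(v) for k, v in d["calcium_attachments"].items()
            },
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "Topology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Geometry helpers (shared with the energy module)
# ---------------------------------------------------------------------------

def angle_between(p_i, p_j, p_k) -> float:
    """Angle at the middle vertex, radians, with clamped arccos."""
    u = np.asarray(p_i) - np.asarray(p_j)
    v = np.asarray(p_k) - np.asarray(p_j)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(math.acos(min(1.0, max(-1.0, c))))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle, radians in (-pi, pi]."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


# ---------------------------------------------------------------------------
# Coarse-graining
# ---------------------------------------------------------------------------

def coarse_grain(
    record_set: AtomRecordSet,
    radii: dict[str, float] | None = None,
    dihedral_disabled_residues: set[int] | frozenset[int] = frozenset(),
    dihedral_k1: float = 1.0,
    dihedral_k3: float = 0.5,
) -> Topology:
    """Reduce a structure to the two-bead model with reference geometry.

    Bonds CA(i)-CA(i+1) and CA(i)-SC(i) use the measured distances as rest
    lengths with k_b = 100 epsilon; angles over consecutive bead triples use
    measured angles with k_theta = 20 epsilon; backbone dihedrals get a
    1-fold + 3-fold cosine series anchored at the measured torsion, and can
    be disabled per residue (e.g. modelled-in terminal residues).
    """
    sigma_table = dict(SIDECHAIN_SIGMA)
    if radii:
        sigma_table.update(radii)

    aa = record_set.amino_atoms()
    res_ids = np.unique(aa.res_id)

    kinds, rids, rnames, pos, sigmas = [], [], [], [], []
    ca_of_res: dict[int, int] = {}
    sc_of_res: dict[int, int] = {}
    for rid in res_ids:
        res = aa[aa.res_id == rid]
        name = str(res.res_name[0])
        ca_xyz = res.coord[res.atom_name == "CA"][0]
        ca_of_res[int(rid)] = len(kinds)
        kinds.append(KIND_CA)
        rids.append(int(rid))
        rnames.append(name)
        pos.append(np.asarray(ca_xyz, dtype=float))
        sigmas.append(SIGMA_BACKBONE)
        if name == "GLY":
            continue
        side_mask = ~np.isin(res.atom_name, list(BACKBONE_ATOMS))
        if not np.any(side_mask):
            continue  # side chain unresolved: backbone bead only
        if name not in sigma_table:
            raise StructureError(f"no vdW radius entry for residue {name}")
        sc_of_res[int(rid)] = len(kinds)
        kinds.append(KIND_SC)
        rids.append(int(rid))
        rnames.append(name)
        pos.append(np.mean(res.coord[side_mask], axis=0).astype(float))
        sigmas.append(sigma_table[name])

    positions = np.asarray(pos)
    n = len(kinds)

    bonds, bond_r0 = [], []
    ordered = [int(r) for r in res_ids]
    for a, b in zip(ordered[:-1], ordered[1:]):
        i, j = ca_of_res[a], ca_of_res[b]
        bonds.append((i, j))
        bond_r0.append(np.linalg.norm(positions[i] - positions[j]))
    for rid, sc in sc_of_res.items():
        i = ca_of_res[rid]
        bonds.append((i, sc))
        bond_r0.append(np.linalg.norm(positions[i] - positions[sc]))

    angles, theta0 = [], []

    def add_angle(i, j, k):
        angles.append((i, j, k))
        theta0.append(angle_between(positions[i], positions[j], positions[k]))

    for a, b, c in zip(ordered[:-2], ordered[1:-1], ordered[2:]):
        add_angle(ca_of_res[a], ca_of_res[b], ca_of_res[c])
    for rid, sc in sc_of_res.items():
        idx = ordered.index(rid)
        if idx + 1 < len(ordered):
            add_angle(sc, ca_of_res[rid], ca_of_res[ordered[idx + 1]])
        if idx - 1 >= 0:
            add_angle(sc, ca_of_res[rid], ca_of_res[ordered[idx - 1]])

    dihedrals, phi0, enabled = [], [], []
    for a, b, c, d in zip(ordered[:-3], ordered[1:-2], ordered[2:-1], ordered[3:]):
        quad = (ca_of_res[a], ca_of_res[b], ca_of_res[c], ca_of_res[d])
        dihedrals.append(quad)
        phi0.append(dihedral_angle(*(positions[q] for q in quad)))
        enabled.append(
            not any(r in dihedral_disabled_residues for r in (a, b, c, d))
        )

    L = len(dihedrals)
    return Topology(
        kind=np.array(kinds, dtype=object),
        res_id=np.asarray(rids, dtype=int),
        res_name=np.array(rnames, dtype=object),
        positions=positions,
        sigma=np.asarray(sigmas, dtype=float),
        mass=np.ones(n),
        charge=np.zeros(n),
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.asarray(bond_r0, dtype=float),
        bond_k=np.full(len(bonds), K_BOND),
        angles=np.asarray(angles, dtype=int).reshape(-1, 3),
        angle_theta0=np.asarray(theta0, dtype=float),
        angle_k=np.full(len(angles), K_ANGLE),
        dihedrals=np.asarray(dihedrals, dtype=int).reshape(-1, 4),
        dihedral_phi0=np.asarray(phi0, dtype=float),
        dihedral_k1=np.full(L, dihedral_k1),
        dihedral_k3=np.full(L, dihedral_k3),
        dihedral_enabled=np.asarray(enabled, dtype=bool),
    )


def infer_calcium_connectivity(
    record_set: AtomRecordSet,
    topology: Topology,
    cutoff: float = 6.0,
) -> dict[int, list[int]]:
    """Derive a calcium-to-residue map from geometry: each ion is attached
    to the acidic residues (Asp/Glu) whose side-chain bead lies within
    ``cutoff`` Angstrom of it."""
    acidic = {"ASP", "GLU"}
    out: dict[int, list[int]] = {}
    for m, xyz in enumerate(record_set.calcium_positions(), start=1):
        ligands = []
        for i in np.flatnonzero(topology.kind == KIND_SC):
            if str(topology.res_name[i]) not in acidic:
                continue
            if np.linalg.norm(topology.positions[i] - xyz) < cutoff:
                ligands.append(int(topology.res_id[i]))
        if not ligands:
            raise StructureError(
                f"no acidic side chains within {cutoff} A of calcium {m}"
            )
        out[m] = ligands
    return out


def attach_calcium(
    topology: Topology,
    record_set: AtomRecordSet | None = None,
    connectivity: dict[int, list[int]] | None = None,
    calcium_positions: np.ndarray | None = None,
    calcium_mass: float = 1.0,
) -> Topology:
    """Add calcium beads tethered to their coordinating side chains.

    Each ion gains spring bonds (k_b = 100 eps) to the side-chain beads of
    the residues in ``connectivity`` and angle terms (k_theta = 20 eps) over
    every (SC_i, ion, SC_j) pair, with rest geometry from the reference
    coordinates.  Calcium nonbonded interactions are strictly repulsive.
    """
    connectivity = connectivity or CAM_CALCIUM_CONNECTIVITY
    if calcium_positions is None:
        if record_set is None:
            raise StructureError("need a structure or explicit calcium positions")
        calcium_positions = record_set.calcium_positions()
    calcium_positions = np.asarray(calcium_positions, dtype=float).reshape(-1, 3)
    if len(calcium_positions) < len(connectivity):
        raise StructureError(
            f"found {len(calcium_positions)} calcium ions, "
            f"connectivity lists {len(connectivity)}"
        )

    top = Topology.from_dict(topology.to_dict())  # deep copy
    known = set(int(r) for r in top.res_id)
    for residues in connectivity.values():
        for r in residues:
            if r not in known:
                raise StructureError(f"calcium ligand residue {r} not in sequence")

    new_bonds, new_r0, new_angles, new_theta0 = [], [], [], []
    positions = top.positions
    attachments: dict[int, list[int]] = {}
    n0 = top.n_beads
    cal_pos = []
    for slot, (label, residues) in enumerate(sorted(connectivity.items())):
        ca_idx = n0 + slot
        xyz = calcium_positions[slot]
        cal_pos.append(xyz)
        sc_beads = [top.sc_index_of(r) for r in residues]
        attachments[ca_idx] = sc_beads
        for sc in sc_beads:
            new_bonds.append((ca_idx, sc))
            new_r0.append(np.linalg.norm(xyz - positions[sc]))
        for a in range(len(sc_beads)):
            for b in range(a + 1, len(sc_beads)):
                i, j = sc_beads[a], sc_beads[b]
                new_angles.append((i, ca_idx, j))
                new_theta0.append(angle_between(positions[i], xyz, positions[j]))

    m = len(connectivity)
    top.kind = np.append(top.kind, np.array([KIND_CALCIUM] * m, dtype=object))
    top.res_id = np.append(top.res_id, np.zeros(m, dtype=int))
    top.res_name = np.append(top.res_name, np.array(["CAL"] * m, dtype=object))
    top.positions = np.vstack([top.positions, np.asarray(cal_pos)])
    top.sigma = np.append(top.sigma, np.full(m, SIGMA_CALCIUM))
    top.mass = np.append(top.mass, np.full(m, calcium_mass))
    top.charge = np.append(top.charge, np.zeros(m))
    top.bonds = np.vstack(
        [top.bonds, np.asarray(new_bonds, dtype=int).reshape(-1, 2)]
    )
    top.bond_r0 = np.append(top.bond_r0, new_r0)
    top.bond_k = np.append(top.bond_k, np.full(len(new_bonds), K_BOND))
    top.angles = np.vstack(
        [top.angles, np.asarray(new_angles, dtype=int).reshape(-1, 3)]
    )
    top.angle_theta0 = np.append(top.angle_theta0, new_theta0)
    top.angle_k = np.append(top.angle_k, np.full(len(new_angles), K_ANGLE))
    top.calcium_attachments = attachments
    return top


#: Fallback formal charges of the side-chain bead, elementary units.
FALLBACK_SC_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}


def assign_charges(topology: Topology, table: ChargeTable | None = None) -> Topology:
    """Attach partial charges to every bead.

    With a :class:`ChargeTable` the tabulated backbone/side-chain charges
    are used (every protein residue must be covered).  Without one, formal
    fallback charges apply: Asp/Glu side chains -1, Lys/Arg +1, all other
    beads neutral (capped termini carry no formal charge).
    """
    top = Topology.from_dict(topology.to_dict())
    protein = (top.kind == KIND_CA) | (top.kind == KIND_SC)
    if table is None:
        charges = np.zeros(top.n_beads)
        sc = top.kind == KIND_SC
        for name, q in FALLBACK_SC_CHARGE.items():
            charges[sc & (top.res_name == name)] = q
        top.charge = charges
        return top

    residues = set(int(r) for r in top.res_id[protein])
    missing = residues - set(table.charges)
    if missing:
        raise StructureError(
            f"charge table does not cover residues {sorted(missing)[:5]}..."
            if len(missing) > 5
            else f"charge table does not cover residues {sorted(missing)}"
        )
    charges = np.zeros(top.n_beads)
    for i in range(top.n_beads):
        if not protein[i]:
            continue
        qb, qs = table.charges[int(top.res_id[i])]
        charges[i] = qb if top.kind[i] == KIND_CA else qs
    top.charge = charges
    return top


def build_native_contacts(
    record_set: AtomRecordSet,
    topology: Topology,
    cutoff: float = 4.5,
    depth_model="uniform",
    min_separation: int = 3,
) -> Topology:
    """Build the native-contact list from heavy-atom proximity.

    Residue pairs at sequence separation >= ``min_separation`` whose
    minimum heavy-atom distance in the reference structure is below
    ``cutoff`` become attractive contacts between their side-chain beads
    (C-alpha for glycine), storing the native bead-bead distance and a well
    depth from ``depth_model`` ("uniform" -> 1 epsilon, or a
    ``{(resname_a, resname_b): depth}`` mapping / callable).
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    top = Topology.from_dict(topology.to_dict())
    aa = record_set.amino_atoms()
    res_ids = [int(r) for r in np.unique(aa.res_id)]
    coords = {r: aa.coord[aa.res_id == r] for r in res_ids}
    names = {r: str(aa.res_name[aa.res_id == r][0]) for r in res_ids}

    def depth_of(ra, rb):
        if depth_model == "uniform" or depth_model is None:
            return 1.0
        if callable(depth_model):
            return float(depth_model(names[ra], names[rb]))
        key = (names[ra], names[rb])
        return float(depth_model.get(key, depth_model.get(key[::-1], 1.0)))

    bonded = {frozenset(b) for b in topology.bonds.tolist()}
    pairs, r0s, depths, res_pairs = [], [], [], []
    for a_pos, ra in enumerate(res_ids):
        for rb in res_ids[a_pos + 1:]:
            if abs(res_ids.index(rb) - a_pos) < min_separation:
                continue
            diff = coords[ra][:, None, :] - coords[rb][None, :, :]
            dmin = np.sqrt((diff**2).sum(-1)).min()
            if dmin >= cutoff:
                continue
            i, j = top.sc_index_of(ra), top.sc_index_of(rb)
            if frozenset((i, j)) in bonded or i == j:
                continue
            pairs.append((i, j))
            r0s.append(np.linalg.norm(top.positions[i] - top.positions[j]))
            depths.append(depth_of(ra, rb))
            res_pairs.append((ra, rb))

    top.contacts = np.asarray(pairs, dtype=int).reshape(-1, 2)
    top.contact_r0 = np.asarray(r0s, dtype=float)
    top.contact_depth = np.asarray(depths, dtype=float)
    top.contact_residues = np.asarray(res_pairs, dtype=int).reshape(-1, 2)
    return top
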