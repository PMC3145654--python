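"""Ensemble analysis: order parameters, WHAM reweighting, contact statistics.

Order parameters follow the conventions used for shape and similarity
analysis of coarse-grained protein ensembles: mass-weighted radius of
gyration; asphericity Delta from the gyration-tensor eigenvalues (0 =
sphere, 1 = rod); the pair-distance overlap function chi (0 = identical to
the reference, 1 = fully dissimilar); a helicity estimator on the C-alpha
trace; and inter-helix angles from helix endpoint vectors.  Multi-
temperature ensembles are combined with the weighted histogram analysis
method in its binless (pooled-sample) self-consistent form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .structure import HelixRecord, KIND_SC, Topology


# ---------------------------------------------------------------------------
# Per-frame order parameters
# ---------------------------------------------------------------------------

def radius_of_gyration(positions: np.ndarray, mass: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, Angstrom."""
    x = np.asarray(positions, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two beads")
    m = np.ones(len(x)) if mass is None else np.asarray(mass, dtype=float)
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt(np.average(((x - com) ** 2).sum(axis=1), weights=m)))


def gyration_tensor(positions: np.ndarray, mass: np.ndarray | None = None) -> np.ndarray:
    x = np.asarray(positions, dtype=float)
    m = np.ones(len(x)) if mass is None else np.asarray(mass, dtype=float)
    com = np.average(x, axis=0, weights=m)
    d = x - com
    return np.einsum("i,ij,ik->jk", m, d, d) / m.sum()


def asphericity(positions: np.ndarray, mass: np.ndarray | None = None) -> float:
    """Shape parameter Delta in [0, 1]: 0 for a sphere, 1 for a rod.

    Delta = (3/2) sum_i (lambda_i - mean)^2 / (sum_i lambda_i)^2 from the
    gyration-tensor eigenvalues.
    """
    if len(positions) < 3:
        raise ValueError("need at least three beads")
    lam = np.linalg.eigvalsh(gyration_tensor(positions, mass))
    tr = lam.sum()
    if tr == 0:
        return 0.0
    return float(1.5 * np.sum((lam - lam.mean()) ** 2) / tr**2)


def overlap_chi(
    positions: np.ndarray,
    reference: np.ndarray,
    res_id: np.ndarray | None = None,
    tolerance: float = 2.0,
    min_residue_separation: int = 2,
) -> float:
    """Structural dissimilarity to a reference: fraction of pairs whose
    distance deviates from the reference by more than ``tolerance``.

    Pairs at residue separation >= ``min_residue_separation`` are counted;
    without residue labels, bead indices stand in for residue numbers.
    """
    x = np.asarray(positions, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("frame and reference bead counts differ")
    n = len(x)
    rid = np.arange(n) if res_id is None else np.asarray(res_id)
    iu, ju = np.triu_indices(n, k=1)
    mask = np.abs(rid[iu] - rid[ju]) >= min_residue_separation
    iu, ju = iu[mask], ju[mask]
    if iu.size == 0:
        raise ValueError("no eligible pairs for the overlap function")
    d = np.linalg.norm(x[iu] - x[ju], axis=1)
    dref = np.linalg.norm(ref[iu] - ref[ju], axis=1)
    return float(np.mean(np.abs(d - dref) >= tolerance))


def helicity(
    ca_positions: np.ndarray,
    dihedral_window_deg: tuple[float, float] = (30.0, 80.0),
    distance_cutoff: float = 6.5,
) -> float:
    """Fraction of assessable residues in a helical local geometry.

    Residue i is helical when the C-alpha virtual torsion over
    (i-1, i, i+1, i+2) falls in the helical window and the
    C-alpha(i)-C-alpha(i+4) distance is below the cutoff.  Residues where
    either test is undefined (chain ends) are excluded from the denominator.
    """
    x = np.asarray(ca_positions, dtype=float)
    n = len(x)
    if n < 6:
        raise ValueError("need at least six residues for the helicity estimator")
    lo, hi = dihedral_window_deg
    count = 0
    total = 0
    from .structure import dihedral_angle

    for i in range(1, n - 4):
        total += 1
        phi = math.degrees(dihedral_angle(x[i - 1], x[i], x[i + 1], x[i + 2]))
        if not (lo <= phi <= hi):
            continue
        if np.linalg.norm(x[i] - x[i + 4]) < distance_cutoff:
            count += 1
    return count / total


def helix_vector(ca_positions: np.ndarray) -> np.ndarray:
    """Endpoint vector of a helix: mean of the last four C-alphas minus the
    mean of the first four."""
    x = np.asarray(ca_positions, dtype=float)
    if len(x) < 4:
        raise ValueError("helix must have at least four residues")
    v = x[-4:].mean(axis=0) - x[:4].mean(axis=0)
    if np.linalg.norm(v) == 0:
        raise ValueError("zero-length helix vector")
    return v


def ef_hand_angle(ca_i: np.ndarray, ca_j: np.ndarray) -> float:
    """Angle between the endpoint vectors of two helices, degrees [0, 180]."""
    vi = helix_vector(ca_i)
    vj = helix_vector(ca_j)
    c = np.dot(vi, vj) / (np.linalg.norm(vi) * np.linalg.norm(vj))
    return float(math.degrees(math.acos(min(1.0, max(-1.0, c)))))


@dataclass
class HelixAnnotation:
    """Helix residue ranges (by residue id, inclusive) and EF-hand pairing."""

    ranges: dict[str, tuple[int, int]]
    pairing: tuple[tuple[str, str], ...] = (
        ("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"),
    )

    def __post_init__(self):
        spans = sorted(self.ranges.values())
        for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
            if s2 <= e1:
                raise ValueError("helix ranges overlap")

    @classmethod
    def from_helix_records(cls, records: list[HelixRecord]) -> "HelixAnnotation":
        ordered = sorted(records, key=lambda h: h.start)
        labels = [chr(ord("A") + i) for i in range(len(ordered))]
        return cls({lab: (h.start, h.end) for lab, h in zip(labels, ordered)})

    def ca_slice(self, topology: Topology, helix: str, positions: np.ndarray):
        start, end = self.ranges[helix]
        idx = [
            topology.ca_index_of(r)
            for r in range(start, end + 1)
            if r in set(int(v) for v in topology.res_id)
        ]
        return positions[idx]

    def ef_hand_angles(self, topology: Topology, positions: np.ndarray) -> dict:
        out = {}
        for a, b in self.pairing:
            out[a + b] = ef_hand_angle(
                self.ca_slice(topology, a, positions),
                self.ca_slice(topology, b, positions),
            )
        return out


# ---------------------------------------------------------------------------
# Contact statistics
# ---------------------------------------------------------------------------

@dataclass
class ContactDefinitions:
    """Native contacts (formed below a factor of the native distance) and
    candidate nonnative pairs (formed below an absolute cutoff)."""

    native_pairs: np.ndarray           # (Cn, 2) bead indices
    native_r0: np.ndarray              # (Cn,)
    native_residues: np.ndarray        # (Cn, 2)
    nonnative_pairs: np.ndarray        # (Cm, 2)
    nonnative_residues: np.ndarray     # (Cm, 2)
    native_factor: float = 1.2
    nonnative_cutoff: float = 8.0

    @property
    def n_contacts(self) -> int:
        return len(self.native_pairs) + len(self.nonnative_pairs)

    def labels(self) -> list[str]:
        return ["native"] * len(self.native_pairs) + (
            ["nonnative"] * len(self.nonnative_pairs)
        )

    @classmethod
    def from_topology(
        cls,
        topology: Topology,
        min_separation: int = 3,
        residue_filter=None,
        native_factor: float = 1.2,
        nonnative_cutoff: float = 8.0,
    ) -> "ContactDefinitions":
        """Native pairs from the topology's contact list; nonnative
        candidates are all other side-chain pairs at the same minimum
        sequence separation (optionally restricted by ``residue_filter``,
        a predicate on residue name)."""
        native_set = {frozenset(p) for p in topology.contacts.tolist()}
        sc = np.flatnonzero(topology.kind == KIND_SC)
        nn_pairs, nn_res = [], []
        for a_pos, i in enumerate(sc):
            for j in sc[a_pos + 1:]:
                ra, rb = int(topology.res_id[i]), int(topology.res_id[j])
                if abs(rb - ra) < min_separation:
                    continue
                if frozenset((int(i), int(j))) in native_set:
                    continue
                if residue_filter is not None and not (
                    residue_filter(str(topology.res_name[i]))
                    and residue_filter(str(topology.res_name[j]))
                ):
                    continue
                nn_pairs.append((int(i), int(j)))
                nn_res.append((ra, rb))
        return cls(
            native_pairs=topology.contacts.copy(),
            native_r0=topology.contact_r0.copy(),
            native_residues=topology.contact_residues.copy(),
            nonnative_pairs=np.asarray(nn_pairs, int).reshape(-1, 2),
            nonnative_residues=np.asarray(nn_res, int).reshape(-1, 2),
            native_factor=native_factor,
            nonnative_cutoff=nonnative_cutoff,
        )


def contact_states(positions: np.ndarray, defs: ContactDefinitions) -> np.ndarray:
    """Binary formation indicator per contact: native below
    factor * native distance, nonnative below the absolute cutoff."""
    x = np.asarray(positions, dtype=float)
    out = np.zeros(defs.n_contacts, dtype=int)
    if len(defs.native_pairs):
        d = np.linalg.norm(
            x[defs.native_pairs[:, 0]] - x[defs.native_pairs[:, 1]], axis=1
        )
        out[: len(defs.native_pairs)] = d < defs.native_factor * defs.native_r0
    if len(defs.nonnative_pairs):
        d = np.linalg.norm(
            x[defs.nonnative_pairs[:, 0]] - x[defs.nonnative_pairs[:, 1]], axis=1
        )
        out[len(defs.native_pairs):] = d < defs.nonnative_cutoff
    return out


@dataclass
class ContactMatrices:
    """Contact-pair index table, formation probabilities and covariance."""

    cpi: list[tuple[int, int, int, str]]     # (cpi, bead_i, bead_j, class)
    probabilities: np.ndarray                # per contact, [0, 1]
    covariance: np.ndarray                   # Pearson, nan where undefined
    residue_matrix: np.ndarray               # native upper / nonnative lower

    def to_cpi_table(self) -> str:
        lines = ["# cpi\tbead_i\tbead_j\tclass"]
        for cpi, i, j, label in self.cpi:
            lines.append(f"{cpi}\t{i}\t{j}\t{label}")
        return "\n".join(lines) + "\n"


def contact_probability_matrix(
    q_frames: np.ndarray, defs: ContactDefinitions, weights=None
) -> ContactMatrices:
    """Mean contact formation over frames plus the per-pair covariance.

    ``q_frames`` is (frames, contacts).  The residue-pair matrix places
    native contacts in the upper triangle and nonnative contacts in the
    lower triangle, the convention used for contact-probability maps.
    """
    q = np.asarray(q_frames, dtype=float)
    if q.ndim != 2 or q.shape[0] < 1:
        raise ValueError("need at least one frame of contact states")
    w = None if weights is None else np.asarray(weights, dtype=float)
    p = np.average(q, axis=0, weights=w)
    cov = contact_covariance(q, weights=w) if q.shape[0] >= 2 else np.full(
        (q.shape[1], q.shape[1]), np.nan
    )

    all_res = np.vstack([defs.native_residues, defs.nonnative_residues])
    n_res = int(all_res.max()) + 1 if len(all_res) else 0
    mat = np.full((n_res, n_res), np.nan)
    labels = defs.labels()
    for idx, (ra, rb) in enumerate(all_res):
        lo, hi = min(ra, rb), max(ra, rb)
        if labels[idx] == "native":
            mat[lo, hi] = p[idx]
        else:
            mat[hi, lo] = p[idx]

    pairs = np.vstack([defs.native_pairs, defs.nonnative_pairs]) if defs.n_contacts else np.empty((0, 2), int)
    cpi = [
        (k + 1, int(pairs[k, 0]), int(pairs[k, 1]), labels[k])
        for k in range(defs.n_contacts)
    ]
    return ContactMatrices(cpi=cpi, probabilities=p, covariance=cov, residue_matrix=mat)


def contact_covariance(q_frames: np.ndarray, weights=None) -> np.ndarray:
    """Pearson-normalized covariance of contact indicators, in [-1, 1].

    Entries involving a zero-variance (always/never formed) contact are
    flagged as nan; the diagonal is 1 for non-constant contacts.
    """
    q = np.asarray(q_frames, dtype=float)
    if q.shape[0] < 2:
        raise ValueError("need at least two frames")
    if weights is None:
        w = np.full(q.shape[0], 1.0 / q.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mean = w @ q
    dq = q - mean
    cov = np.einsum("f,fi,fj->ij", w, dq, dq)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.isinf(corr)] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr, where=~np.isnan(corr))


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

class WHAMConvergenceError(RuntimeError):
    pass


@dataclass
class WHAMResult:
    """Self-consistent multi-temperature reweighting of pooled samples."""

    temperatures: np.ndarray      # k_BT/epsilon per simulated ladder rung
    free_energies: np.ndarray     # dimensionless -ln(Z_k/Z_0)
    pooled_energies: np.ndarray   # (N,)
    sample_counts: np.ndarray     # (K,)
    iterations: int = 0

    def log_weights(self, temperature: float) -> np.ndarray:
        """Normalized log sample weights at an arbitrary temperature."""
        betas = 1.0 / self.temperatures
        log_m = logsumexp(
            np.log(self.sample_counts)[:, None]
            + self.free_energies[:, None]
            - betas[:, None] * self.pooled_energies[None, :],
            axis=0,
        )
        logw = -self.pooled_energies / temperature - log_m
        return logw - logsumexp(logw)

    def weights(self, temperature: float) -> np.ndarray:
        return np.exp(self.log_weights(temperature))

    def expectation(self, values: np.ndarray, temperature: float) -> float:
        """Reweighted ensemble average of a pooled per-frame observable."""
        values = np.asarray(values, dtype=float)
        if len(values) != len(self.pooled_energies):
            raise ValueError("observable length must match the pooled samples")
        return float(np.sum(self.weights(temperature) * values))


def wham(
    energies_by_temperature: list[np.ndarray],
    temperatures,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> WHAMResult:
    """Solve the WHAM self-consistency equations on pooled samples.

    Iterates f_k = -ln sum_n exp(-beta_k E_n) / sum_l N_l exp(f_l - beta_l E_n)
    until the largest free-energy increment falls below ``tol``.  Adjacent
    temperatures must produce overlapping energy distributions; a gross
    overlap failure is reported with a diagnostic.
    """
    temps = np.asarray(list(temperatures), dtype=float)
    series = [np.asarray(e, dtype=float) for e in energies_by_temperature]
    if len(series) != len(temps):
        raise ValueError("one energy series per temperature required")
    counts = np.array([len(e) for e in series], dtype=float)
    if np.any(counts == 0):
        raise ValueError("empty energy series")
    pooled = np.concatenate(series)
    betas = 1.0 / temps

    for k in range(len(temps) - 1):
        lo_hi = max(series[k].min(), series[k + 1].min())
        hi_lo = min(series[k].max(), series[k + 1].max())
        if lo_hi > hi_lo:
            raise WHAMConvergenceError(
                f"no energy overlap between temperatures {temps[k]:.4g} and "
                f"{temps[k + 1]:.4g}: ranges "
                f"[{series[k].min():.4g}, {series[k].max():.4g}] vs "
                f"[{series[k + 1].min():.4g}, {series[k + 1].max():.4g}]"
            )

    neg_be = -betas[:, None] * pooled[None, :]  # (K, N)
    log_counts = np.log(counts)
    f = np.zeros(len(temps))
    it = 0
    for it in range(1, max_iter + 1):
        log_m = logsumexp(log_counts[:, None] + f[:, None] + neg_be, axis=0)
        f_new = -logsumexp(neg_be - log_m[None, :], axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise WHAMConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (delta={delta:.3g})"
        )
    return WHAMResult(
        temperatures=temps,
        free_energies=f,
        pooled_energies=pooled,
        sample_counts=counts,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Free-energy surface and basins
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """-k_BT ln P over a (chi, Delta) grid, minimum shifted to zero."""

    chi_edges: np.ndarray
    delta_edges: np.ndarray
    free_energy: np.ndarray       # (bins, bins), nan for empty bins
    counts: np.ndarray
    temperature: float

    def to_text(self) -> str:
        lines = [
            f"# free-energy surface at T = {self.temperature:.6g} (epsilon units)",
            "# chi_center delta_center free_energy count",
        ]
        cx = 0.5 * (self.chi_edges[:-1] + self.chi_edges[1:])
        cy = 0.5 * (self.delta_edges[:-1] + self.delta_edges[1:])
        for i, x in enumerate(cx):
            for j, y in enumerate(cy):
                fe = self.free_energy[i, j]
                fe_s = "nan" if np.isnan(fe) else f"{fe:.6f}"
                lines.append(f"{x:.4f} {y:.4f} {fe_s} {self.counts[i, j]:.6g}")
        return "\n".join(lines) + "\n"


def free_energy_surface(
    chi: np.ndarray,
    delta: np.ndarray,
    temperature: float,
    weights: np.ndarray | None = None,
    bins: int = 50,
    ranges=((0.0, 1.0), (0.0, 1.0)),
) -> FreeEnergySurface:
    """Bin (possibly reweighted) frames into F(chi, Delta) = -k_BT ln P."""
    chi = np.asarray(chi, dtype=float)
    delta = np.asarray(delta, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    h, xe, ye = np.histogram2d(chi, delta, bins=bins, range=ranges, weights=w)
    total = h.sum()
    if total <= 0:
        raise ValueError("no samples fall inside the surface range")
    p = h / total
    with np.errstate(divide="ignore"):
        fe = np.where(p > 0, -temperature * np.log(p), np.nan)
    fe = fe - np.nanmin(fe)
    return FreeEnergySurface(
        chi_edges=xe, delta_edges=ye, free_energy=fe, counts=h,
        temperature=temperature,
    )


@dataclass
class BasinDefinition:
    name: str
    chi_range: tuple[float, float]
    delta_range: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.chi_range, self.delta_range):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("basin bounds must satisfy 0 <= lo < hi <= 1")

    def contains(self, chi, delta) -> np.ndarray:
        chi = np.asarray(chi)
        delta = np.asarray(delta)
        return (
            (chi >= self.chi_range[0]) & (chi < self.chi_range[1])
            & (delta >= self.delta_range[0]) & (delta < self.delta_range[1])
        )


#: Basin rectangles of the calmodulin (chi, Delta) landscape: M1 extended
#: apo, M2 collapsed apo, M3 compact holo.
BASIN_M1 = BasinDefinition("M1", (0.1, 0.3), (0.28, 0.3))
BASIN_M2 = BasinDefinition("M2", (0.3, 0.4), (0.03, 0.15))
BASIN_M3 = BasinDefinition("M3", (0.38, 0.45), (0.01, 0.1))


def basin_population(
    chi: np.ndarray,
    delta: np.ndarray,
    basin: BasinDefinition,
    weights: np.ndarray | None = None,
) -> float:
    """Probability mass inside the basin rectangle (closed-open bounds)."""
    chi = np.asarray(chi, dtype=float)
    if chi.size == 0:
        raise ValueError("empty ensemble")
    inside = basin.contains(chi, delta)
    if weights is None:
        return float(np.mean(inside))
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w[inside]) / np.sum(w))


# ---------------------------------------------------------------------------
# Synthetic CD spectrum
# ---------------------------------------------------------------------------

DEFAULT_WAVELENGTHS = np.arange(190.0, 251.0, 1.0)

# Gaussian band parameters (amplitude deg cm^2/dmol, center nm, width nm) of
# the synthetic secondary-structure basis spectra.  These reproduce the
# canonical band positions of poly-amino-acid reference spectra (helix:
# positive 192, negative 208/222; sheet: positive 196, negative 217; coil:
# negative 198) but the amplitudes are a synthetic stand-in, swappable via
# the ``basis`` argument.
_CD_BANDS = {
    "helix": [(65000.0, 192.0, 5.0), (-31000.0, 208.0, 5.5), (-33000.0, 222.0, 6.5)],
    "sheet": [(30000.0, 196.0, 5.0), (-14000.0, 217.0, 6.0)],
    "coil": [(-40000.0, 198.0, 6.0), (2500.0, 220.0, 8.0)],
}


def cd_basis(wavelengths: np.ndarray = DEFAULT_WAVELENGTHS) -> dict[str, np.ndarray]:
    """Synthetic helix/sheet/coil mean-residue-ellipticity basis spectra."""
    wl = np.asarray(wavelengths, dtype=float)
    out = {}
    for name, bands in _CD_BANDS.items():
        spec = np.zeros_like(wl)
        for amp, center, width in bands:
            spec += amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        out[name] = spec
    return out


def synthesize_cd_spectrum(
    f_helix: float,
    f_beta: float,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    basis: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-residue ellipticity as a linear combination of reference spectra:
    theta(lambda) = f_H B_H + f_beta B_beta + (1 - f_H - f_beta) B_coil."""
    if f_helix < 0 or f_beta < 0 or f_helix + f_beta > 1.0 + 1e-12:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    wl = np.asarray(wavelengths, dtype=float)
    b = basis if basis is not None else cd_basis(wl)
    theta = (
        f_helix * b["helix"]
        + f_beta * b["sheet"]
        + (1.0 - f_helix - f_beta) * b["coil"]
    )
    return wl, theta
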