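"""Low-friction Langevin propagation and temperature replica exchange.

Reduced units throughout: k_B = 1, energies in epsilon, temperatures in
k_B T / epsilon, time in tau_L, friction in m / tau_L.  The integrator is
a velocity-Verlet scheme with explicit friction and a fluctuation-
dissipation-balanced random force (variance 2 zeta k_B T / h per degree of
freedom); with zero friction it reduces exactly to velocity Verlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CROWDER_RADIUS


class CrowderPackingError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


def default_temperature_ladder(
    n: int = 18, t_min: float = 1.0, t_max: float = 1.63
) -> tuple[float, ...]:
    """Geometrically spaced replica temperatures, k_BT/epsilon."""
    return tuple(np.geomspace(t_min, t_max, n).tolist())


@dataclass
class SimulationConfig:
    timestep: float = 0.005            # tau_L
    friction: float = 0.05             # m / tau_L
    temperatures: tuple = field(default_factory=default_temperature_ladder)
    box: float | None = 1140.0         # Angstrom
    phi_c: float = 0.0                 # crowder volume fraction
    exchange_interval: float = 400.0   # tau_L between exchange attempts
    sample_interval: int = 1000        # integration steps between samples
    seed: int = 0
    n_steps: int = 100_000
    store_positions: bool = True

    def __post_init__(self):
        temps = tuple(self.temperatures)
        if len(temps) >= 2 and not all(
            a < b for a, b in zip(temps[:-1], temps[1:])
        ):
            raise ValueError("temperature ladder must be strictly increasing")
        if not (0.0 <= self.phi_c < 0.55):
            raise ValueError("crowder volume fraction must be in [0, 0.55)")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        self.temperatures = temps


# ---------------------------------------------------------------------------
# Crowder placement
# ---------------------------------------------------------------------------

def crowder_count(phi_c: float, box: float, radius: float = CROWDER_RADIUS) -> int:
    """Number of hard spheres realizing volume fraction phi_c in a cubic box."""
    return int(math.floor(phi_c * box**3 / (4.0 / 3.0 * math.pi * radius**3)))


def _min_image_dist(points, x, box):
    d = points - x
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=1))


def place_crowders(
    phi_c: float,
    box: float,
    radius: float = CROWDER_RADIUS,
    seed: int = 0,
    max_attempts_per_sphere: int = 2000,
    method: str = "auto",
) -> np.ndarray:
    """Place non-overlapping hard spheres under periodic minimum image.

    Random sequential insertion first; at volume fractions near or beyond
    its saturation limit (~0.38) the "auto" method falls back to a seeded
    jittered cubic lattice, which is still exactly overlap-free and
    deterministic per seed.
    """
    n = crowder_count(phi_c, box, radius)
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 3))
    if method in ("auto", "rsa"):
        points = np.empty((n, 3))
        placed = 0
        failed = False
        for i in range(n):
            for _ in range(max_attempts_per_sphere):
                x = rng.uniform(0.0, box, size=3)
                if placed == 0 or np.all(
                    _min_image_dist(points[:placed], x, box) >= 2.0 * radius
                ):
                    points[placed] = x
                    placed += 1
                    break
            else:
                failed = True
                break
        if not failed:
            return points
        if method == "rsa":
            raise CrowderPackingError(
                f"could not insert sphere {placed + 1}/{n} after "
                f"{max_attempts_per_sphere} attempts; lower phi_c "
                f"(requested {phi_c})"
            )
    # Jittered cubic lattice fallback (or method == "lattice").
    cells = int(math.ceil(n ** (1.0 / 3.0)))
    spacing = box / cells
    if spacing < 2.0 * radius:
        raise CrowderPackingError(
            f"phi_c = {phi_c} cannot be packed even on a cubic lattice "
            f"(lattice spacing {spacing:.1f} A < diameter {2 * radius:.1f} A)"
        )
    jitter_max = max(0.0, (spacing - 2.0 * radius) / (2.0 * math.sqrt(3.0)))
    grid = (np.arange(cells) + 0.5) * spacing
    sites = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), -1).reshape(-1, 3)
    order = rng.permutation(len(sites))[:n]
    points = sites[order] + rng.uniform(-jitter_max, jitter_max, size=(n, 3))
    return np.mod(points, box)


# ---------------------------------------------------------------------------
# Langevin integration
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    step: int = 0


def maxwell_velocities(rng, mass, temperature):
    scale = np.sqrt(temperature / mass)[:, None]
    return rng.normal(size=(len(mass), 3)) * scale


class LangevinIntegrator:
    """Velocity Verlet with friction and thermal noise on a force provider.

    ``system`` needs ``forces(positions)``, ``potential_energy(positions)``
    and a ``mass`` array; an optional ``sigma`` array sets the per-step
    displacement sanity limit (half the smallest bead diameter).
    """

    def __init__(self, system, temperature: float, config: SimulationConfig, rng):
        self.system = system
        self.temperature = temperature
        self.h = config.timestep
        self.zeta = config.friction
        self.rng = rng
        self.mass = np.asarray(system.mass, dtype=float)
        sigma = getattr(system, "sigma", None)
        if sigma is not None and np.any(np.asarray(sigma) > 0):
            s = np.asarray(sigma)
            self.max_displacement = 0.5 * float(s[s > 0].min())
        else:
            self.max_displacement = None

    def initial_state(self, positions: np.ndarray) -> ParticleState:
        v = maxwell_velocities(self.rng, self.mass, self.temperature)
        return ParticleState(
            positions=np.array(positions, dtype=float, copy=True),
            velocities=v,
            forces=self.system.forces(positions),
        )

    def _noise(self, shape):
        if self.zeta == 0.0:
            return 0.0
        sd = math.sqrt(2.0 * self.zeta * self.temperature / self.h)
        return self.rng.normal(0.0, sd, size=shape)

    def step(self, state: ParticleState) -> ParticleState:
        h, zeta, m = self.h, self.zeta, self.mass[:, None]
        x, v, f = state.positions, state.velocities, state.forces
        noise = self._noise(x.shape)
        a = (f + noise - zeta * v) / m
        v_half = v + 0.5 * h * a
        dx = h * v_half
        if self.max_displacement is not None:
            dmax = float(np.abs(dx).max())
            if dmax > self.max_displacement:
                raise IntegrationError(
                    f"step displacement {dmax:.3g} A exceeds half the "
                    f"smallest bead diameter; reduce the timestep "
                    f"(h = {h})"
                )
        x_new = x + dx
        f_new = self.system.forces(x_new)
        a_new = (f_new + noise - zeta * v_half) / m
        v_new = v_half + 0.5 * h * a_new
        return ParticleState(x_new, v_new, f_new, state.step + 1)


def langevin_step(state: ParticleState, system, temperature, config, rng):
    """One integration step; convenience wrapper over the integrator."""
    integ = LangevinIntegrator(system, temperature, config, rng)
    return integ.step(state)


# ---------------------------------------------------------------------------
# Replica exchange
# ---------------------------------------------------------------------------

def exchange_probability(beta_i, beta_j, e_i, e_j) -> float:
    """Metropolis probability min(1, exp[(beta_i - beta_j)(E_i - E_j)])."""
    return min(1.0, math.exp(min(700.0, (beta_i - beta_j) * (e_i - e_j))))


def attempt_exchange(beta_i, beta_j, e_i, e_j, rng) -> bool:
    return rng.random() < exchange_probability(beta_i, beta_j, e_i, e_j)


@dataclass
class Frame:
    step: int
    temperature_index: int
    potential_energy: float
    positions: np.ndarray | None = None
    order_parameters: dict = field(default_factory=dict)


@dataclass
class ReplicaEnsemble:
    temperatures: tuple
    frames: list[list[Frame]]            # per temperature slot
    exchange_attempts: np.ndarray        # per neighbor pair
    exchange_accepts: np.ndarray

    def energies(self, t_index: int) -> np.ndarray:
        return np.array([f.potential_energy for f in self.frames[t_index]])

    def positions(self, t_index: int) -> list[np.ndarray]:
        return [f.positions for f in self.frames[t_index]]

    def acceptance_ratios(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.exchange_attempts > 0,
                self.exchange_accepts / np.maximum(self.exchange_attempts, 1),
                np.nan,
            )

    def autocorrelation_times(self) -> list[float]:
        return [
            integrated_autocorrelation_time(self.energies(k))
            for k in range(len(self.temperatures))
        ]


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Self-consistent window estimate of the integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return 1.0
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.var(x) * n)
    tau = 1.0
    for window in range(1, n):
        tau = 1.0 + 2.0 * np.sum(acf[1 : window + 1])
        if window >= c * tau:
            break
    return float(max(tau, 1.0))


def _wrap_frame(positions, n_protein, box):
    """Wrap crowders bead-wise and the protein rigidly into the primary box."""
    if box is None:
        return positions
    out = positions.copy()
    if n_protein:
        centroid = out[:n_protein].mean(axis=0)
        out[:n_protein] -= box * np.floor(centroid / box)
    out[n_protein:] = np.mod(out[n_protein:], box)
    return out


def run_rem(system, config: SimulationConfig) -> ReplicaEnsemble:
    """Temperature replica-exchange Langevin sampling.

    Every replica is propagated at its ladder temperature; exchanges are
    attempted every ``exchange_interval`` tau_L between alternating
    even/odd neighbor pairs, with velocities rescaled by sqrt(T_new/T_old)
    on acceptance; frames are recorded every ``sample_interval`` steps.
    All randomness derives from the single config seed.
    """
    temps = config.temperatures
    n_rep = len(temps)
    rng = np.random.default_rng(config.seed)
    n_protein = getattr(system, "n_protein", 0)

    integrators = [
        LangevinIntegrator(system, t, config, rng) for t in temps
    ]
    x0 = system.initial_positions()
    states = [integ.initial_state(x0) for integ in integrators]
    energies = [system.potential_energy(s.positions) for s in states]

    steps_per_exchange = max(1, int(round(config.exchange_interval / config.timestep)))
    attempts = np.zeros(max(n_rep - 1, 0))
    accepts = np.zeros(max(n_rep - 1, 0))
    frames: list[list[Frame]] = [[] for _ in range(n_rep)]

    def maybe_sample(k, state, energy):
        if state.step % config.sample_interval == 0:
            frames[k].append(
                Frame(
                    step=state.step,
                    temperature_index=k,
                    potential_energy=energy,
                    positions=_wrap_frame(state.positions, n_protein, config.box)
                    if config.store_positions
                    else None,
                )
            )

    total = 0
    parity = 0
    while total < config.n_steps:
        block = min(steps_per_exchange, config.n_steps - total)
        for k in range(n_rep):
            state = states[k]
            for _ in range(block):
                state = integrators[k].step(state)
                if state.step % config.sample_interval == 0:
                    e = system.potential_energy(state.positions)
                    if not math.isfinite(e):
                        raise RuntimeError(
                            f"non-finite energy at step {state.step}, "
                            f"replica {k} (T = {temps[k]})"
                        )
                    maybe_sample(k, state, e)
            states[k] = state
            energies[k] = system.potential_energy(state.positions)
        total += block
        # alternating even/odd neighbor pairs
        for i in range(parity, n_rep - 1, 2):
            j = i + 1
            attempts[i] += 1
            if attempt_exchange(
                1.0 / temps[i], 1.0 / temps[j], energies[i], energies[j], rng
            ):
                accepts[i] += 1
                si, sj = states[i], states[j]
                scale_ij = math.sqrt(temps[i] / temps[j])
                si_new = ParticleState(
                    sj.positions, sj.velocities * scale_ij, sj.forces, si.step
                )
                sj_new = ParticleState(
                    si.positions, si.velocities / scale_ij, si.forces, sj.step
                )
                states[i], states[j] = si_new, sj_new
                energies[i], energies[j] = energies[j], energies[i]
        parity ^= 1

    return ReplicaEnsemble(
        temperatures=tuple(temps),
        frames=frames,
        exchange_attempts=attempts,
        exchange_accepts=accepts,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def save_trajectory_xyz(path, ensemble: ReplicaEnsemble, t_index: int, labels=None):
    """Multi-frame XYZ with step/T/E metadata on the comment line."""
    frames = ensemble.frames[t_index]
    temp = ensemble.temperatures[t_index]
    with open(path, "w") as fh:
        for fr in frames:
            if fr.positions is None:
                continue
            n = len(fr.positions)
            fh.write(f"{n}\n")
            fh.write(
                f"step={fr.step} T={temp:.6g} E={fr.potential_energy:.10g}\n"
            )
            for i, xyz in enumerate(fr.positions):
                lab = labels[i] if labels is not None else "X"
                fh.write(
                    f"{lab:<4s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}\n"
                )


def load_trajectory_xyz(path):
    """Read frames back as (positions, metadata-dict) pairs."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        meta = dict(
            kv.split("=", 1) for kv in lines[i + 1].split() if "=" in kv
        )
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in lines[i + 2 : i + 2 + n]]
        )
        out.append((coords, meta))
        i += 2 + n
    return out


def save_energy_table(path, ensemble: ReplicaEnsemble):
    """Per-frame delimited energy table: one row per frame."""
    with open(path, "w") as fh:
        fh.write("# t_index temperature step potential_energy\n")
        for k, temp in enumerate(ensemble.temperatures):
            for fr in ensemble.frames[k]:
                fh.write(
                    f"{k} {temp:.6g} {fr.step} {fr.potential_energy:.10g}\n"
                )
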