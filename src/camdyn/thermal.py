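"""Thermal-unfolding analysis of CD melting curves.

Raw ellipticity (millidegrees) is converted to mean residue ellipticity,
and temperature series at 222 nm are fit to two-state (N <-> U) or
sequential three-state (N <-> I <-> U) unfolding models.  Each transition
is parameterized by its midpoint T_m, van't Hoff enthalpy dH_m, and an
optionally fixed heat-capacity change dC_p through the modified
Gibbs-Helmholtz equation

    dG(T) = dH_m (1 - T/T_m) + dC_p [(T - T_m) - T ln(T/T_m)],

with K = exp(-dG/RT) so dG vanishes at T_m and the unfolded state is
favored above it.  Each state contributes a linear baseline I + S*T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL


#: Temperature grid of a synthetic thermal melt: 5-90 C ramp sampled every
#: 0.2 K, matching a slow-ramp CD acquisition.
DEFAULT_MELT_GRID = np.arange(278.15, 363.15, 0.2)
#: Gaussian noise of a synthetic melt on the mean-residue-ellipticity scale
#: (deg cm^2/dmol), the scatter of an averaged 222 nm melt.
DEFAULT_MELT_NOISE_SD = 50.0


@dataclass
class MeltingCurve:
    """Temperature vs CD signal series (mean residue ellipticity, 222 nm)."""

    temperature: np.ndarray     # strictly increasing
    signal: np.ndarray
    temperature_unit: str = "K"    # "K" or "C"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_unit not in ("K", "C"):
            raise ValueError("temperature unit must be 'K' or 'C'")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(self.temperature) != len(self.signal):
            raise ValueError("temperature and signal lengths differ")

    def in_kelvin(self) -> np.ndarray:
        if self.temperature_unit == "K":
            return self.temperature
        return self.temperature + 273.15

    def to_text(self) -> str:
        lines = [f"# unit={self.temperature_unit}"]
        for k, v in self.metadata.items():
            lines.append(f"# {k}={v}")
        for t, y in zip(self.temperature, self.signal):
            lines.append(f"{t:.6g}\t{y:.6g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MeltingCurve":
        unit = "K"
        meta = {}
        temps, sigs = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    if k.strip() == "unit":
                        unit = v.strip()
                    else:
                        meta[k.strip()] = v.strip()
                continue
            t, y = line.split()[:2]
            temps.append(float(t))
            sigs.append(float(y))
        return cls(np.array(temps), np.array(sigs), unit, meta)


def mdeg_to_mre(
    signal_mdeg,
    molecular_weight: float,
    pathlength_mm: float,
    conc_mg_ml: float,
    n_residues: int,
):
    """Millidegrees to mean residue ellipticity, deg cm^2/dmol:
    [theta] = mdeg * MW / (path_mm * conc_mg/ml * n_residues)."""
    denom = pathlength_mm * conc_mg_ml * n_residues
    if molecular_weight <= 0 or denom <= 0:
        raise ValueError("molecular weight, path, concentration and residue "
                         "count must all be positive")
    return np.asarray(signal_mdeg, dtype=float) * molecular_weight / denom


def mre_to_mdeg(mre, molecular_weight, pathlength_mm, conc_mg_ml, n_residues):
    """Exact inverse of :func:`mdeg_to_mre`."""
    denom = pathlength_mm * conc_mg_ml * n_residues
    if molecular_weight <= 0 or denom <= 0:
        raise ValueError("conversion constants must be positive")
    return np.asarray(mre, dtype=float) * denom / molecular_weight


def gibbs_helmholtz(T, T_m: float, dH_m: float, dC_p: float = 0.0):
    """Unfolding free energy dG(T), kcal/mol; zero at T_m, positive below."""
    T = np.asarray(T, dtype=float)
    if T_m <= 0 or np.any(T <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    return dH_m * (1.0 - T / T_m) + dC_p * ((T - T_m) - T * np.log(T / T_m))


def _equilibrium_K(T, T_m, dH_m, dC_p):
    dG = gibbs_helmholtz(T, T_m, dH_m, dC_p)
    return np.exp(np.clip(-dG / (R_KCAL * np.asarray(T, float)), -500, 500))


@dataclass
class TransitionParams:
    T_m: float                  # K
    dH_m: float                 # kcal/mol
    dC_p: float = 0.0           # kcal/(mol K)


@dataclass
class TwoStateParams:
    transition: TransitionParams
    native_baseline: tuple[float, float]    # (intercept, slope per K)
    unfolded_baseline: tuple[float, float]


@dataclass
class ThreeStateParams:
    transition_ni: TransitionParams
    transition_iu: TransitionParams
    native_baseline: tuple[float, float]
    intermediate_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]


def two_state_signal(T, params: TwoStateParams):
    """y = f_N (I_N + S_N T) + f_U (I_U + S_U T), f_U = K/(1+K)."""
    T = np.asarray(T, dtype=float)
    tr = params.transition
    K = _equilibrium_K(T, tr.T_m, tr.dH_m, tr.dC_p)
    f_u = K / (1.0 + K)
    i_n, s_n = params.native_baseline
    i_u, s_u = params.unfolded_baseline
    return (1.0 - f_u) * (i_n + s_n * T) + f_u * (i_u + s_u * T)


def three_state_populations(T, p: ThreeStateParams):
    """Sequential N <-> I <-> U populations: f_N = 1/(1 + K1 + K1 K2)."""
    T = np.asarray(T, dtype=float)
    k1 = _equilibrium_K(T, p.transition_ni.T_m, p.transition_ni.dH_m, p.transition_ni.dC_p)
    k2 = _equilibrium_K(T, p.transition_iu.T_m, p.transition_iu.dH_m, p.transition_iu.dC_p)
    f_n = 1.0 / (1.0 + k1 + k1 * k2)
    return f_n, k1 * f_n, k1 * k2 * f_n


def three_state_signal(T, params: ThreeStateParams):
    T = np.asarray(T, dtype=float)
    f_n, f_i, f_u = three_state_populations(T, params)
    i_n, s_n = params.native_baseline
    i_i, s_i = params.intermediate_baseline
    i_u, s_u = params.unfolded_baseline
    return f_n * (i_n + s_n * T) + f_i * (i_i + s_i * T) + f_u * (i_u + s_u * T)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class FitError(RuntimeError):
    pass


@dataclass
class UnfoldFitResult:
    model: str                               # "two_state" | "three_state"
    params: TwoStateParams | ThreeStateParams
    standard_errors: dict[str, float]
    covariance: np.ndarray | None
    residual_rms: float
    fixed: dict[str, float]
    ill_conditioned: bool = False
    message: str = ""

    def transitions(self) -> list[TransitionParams]:
        if self.model == "two_state":
            return [self.params.transition]
        return [self.params.transition_ni, self.params.transition_iu]


def fit_unfolding(
    curve: MeltingCurve,
    model: str = "three_state",
    fix_dCp: float | None = 0.0,
    max_starts: int = 4,
    seed: int = 0,
) -> UnfoldFitResult:
    """Bounded nonlinear least-squares fit with multi-start initialization.

    ``fix_dCp`` pins the heat-capacity change (None lets it vary).
    Midpoints are started from temperature quantiles of the data;
    baselines from linear regressions on the curve edges; the trust-region
    solver keeps T_m near the observed range and dH_m positive.  Returns
    estimates with asymptotic standard errors from the Jacobian; a fit
    whose transitions collapse onto each other, or whose midpoint is
    unconstrained by the data (e.g. a pure straight line), is flagged
    ill-conditioned.
    """
    T = curve.in_kelvin()
    y = curve.signal
    if model == "three_state" and len(T) < 15:
        raise FitError("three-state fits need at least 15 points")
    if model not in ("two_state", "three_state"):
        raise ValueError(f"unknown model {model!r}")

    free_dcp = fix_dCp is None
    n_trans = 1 if model == "two_state" else 2
    n_edge = max(3, len(T) // 10)
    base_n = np.polyfit(T[:n_edge], y[:n_edge], 1)       # (slope, intercept)
    base_u = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
    t_mid = float(T.mean())
    mid_i = 0.5 * (np.polyval(base_n, t_mid) + np.polyval(base_u, t_mid))

    def pack_names():
        names = []
        for t in range(n_trans):
            names += [f"T_m{t + 1}", f"dH_m{t + 1}"]
            if free_dcp:
                names += [f"dC_p{t + 1}"]
        if model == "two_state":
            names += ["I_N", "S_N", "I_U", "S_U"]
        else:
            names += ["I_N", "S_N", "I_I", "S_I", "I_U", "S_U"]
        return names

    def unpack(theta):
        idx = 0
        trans = []
        for _ in range(n_trans):
            tm, dh = theta[idx], theta[idx + 1]
            idx += 2
            dcp = theta[idx] if free_dcp else fix_dCp
            if free_dcp:
                idx += 1
            trans.append(TransitionParams(tm, dh, dcp))
        base = theta[idx:]
        if model == "two_state":
            return TwoStateParams(trans[0], (base[0], base[1]), (base[2], base[3]))
        return ThreeStateParams(
            trans[0], trans[1],
            (base[0], base[1]), (base[2], base[3]), (base[4], base[5]),
        )

    def resid(theta):
        p = unpack(theta)
        model_y = (
            two_state_signal(T, p) if model == "two_state" else three_state_signal(T, p)
        )
        return model_y - y

    per_trans_lo = [T[0] - 20.0, 1.0] + ([-5.0] if free_dcp else [])
    per_trans_hi = [T[-1] + 30.0, 300.0] + ([5.0] if free_dcp else [])
    n_base = 4 if model == "two_state" else 6
    lo = np.array(per_trans_lo * n_trans + [-np.inf] * n_base)
    hi = np.array(per_trans_hi * n_trans + [np.inf] * n_base)

    per_trans_scale = [10.0, 20.0] + ([0.5] if free_dcp else [])
    base_scale = [abs(base_n[1]) + 1.0, 5.0]
    if model == "three_state":
        base_scale += [abs(mid_i) + 1.0, 5.0]
    base_scale += [abs(base_u[1]) + 1.0, 5.0]
    x_scale = np.array(per_trans_scale * n_trans + base_scale)

    if n_trans == 1:
        q = np.quantile(T, [0.5])
        tm_starts = [(q[0],), (t_mid - 10.0,), (t_mid + 10.0,), (q[0] + 5.0,)]
    else:
        q = np.quantile(T, [0.3, 0.7])
        tm_starts = [
            (q[0], q[1]),
            (t_mid - 12.0, t_mid + 8.0),
            (q[0] - 8.0, q[1] - 8.0),
            (q[0] + 8.0, q[1] + 8.0),
        ]
    starts = []
    for tms in tm_starts[:max_starts]:
        for dh in (25.0, 45.0):
            theta = []
            for tm in tms:
                theta += [tm, dh] + ([0.0] if free_dcp else [])
            if model == "two_state":
                theta += [base_n[1], base_n[0], base_u[1], base_u[0]]
            else:
                theta += [
                    base_n[1], base_n[0],
                    mid_i, 0.5 * (base_n[0] + base_u[0]),
                    base_u[1], base_u[0],
                ]
            starts.append(np.array(theta, dtype=float))

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                resid, theta0, bounds=(lo, hi), method="trf",
                x_scale=x_scale, max_nfev=3000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("unfolding fit did not converge from any start")

    names = pack_names()
    dof = max(len(y) - len(best.x), 1)
    s_sq = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    ill = False
    try:
        cov = np.linalg.inv(jtj) * s_sq
        se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        cov = None
        se = {n: float("nan") for n in names}
        ill = True

    params = unpack(best.x)
    trans = (
        [params.transition] if model == "two_state"
        else [params.transition_ni, params.transition_iu]
    )
    if any(t.T_m <= 0 for t in trans):
        ill = True
    if n_trans == 2 and abs(trans[0].T_m - trans[1].T_m) < 2.0:
        ill = True
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    if se.get("T_m1", float("inf")) > 0.5 * (T[-1] - T[0]):
        ill = True
    # a transition must change the signal by more than the residual scatter,
    # otherwise the data (e.g. a pure straight line) do not constrain it
    if model == "two_state":
        i_n, s_n = params.native_baseline
        i_u, s_u = params.unfolded_baseline
        amp = abs((i_n + s_n * trans[0].T_m) - (i_u + s_u * trans[0].T_m))
        if amp < max(10.0 * rms, 1e-9):
            ill = True

    return UnfoldFitResult(
        model=model,
        params=params,
        standard_errors=se,
        covariance=cov,
        residual_rms=rms,
        fixed={} if free_dcp else {"dC_p": fix_dCp},
        ill_conditioned=ill,
        message="ill-conditioned fit" if ill else "converged",
    )


def generate_melting_curve(
    params: TwoStateParams | ThreeStateParams,
    temperature_K: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> MeltingCurve:
    """Synthetic melting curve: model signal plus Gaussian noise.

    Deterministic per seed; the generating truth is recorded in the
    metadata for recovery studies.
    """
    T = np.asarray(temperature_K, dtype=float)
    if isinstance(params, TwoStateParams):
        y = two_state_signal(T, params)
        truth = {"model": "two_state", "T_m1": params.transition.T_m,
                 "dH_m1": params.transition.dH_m}
    else:
        y = three_state_signal(T, params)
        truth = {
            "model": "three_state",
            "T_m1": params.transition_ni.T_m, "dH_m1": params.transition_ni.dH_m,
            "T_m2": params.transition_iu.T_m, "dH_m2": params.transition_iu.dH_m,
        }
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(T))
    meta = dict(truth)
    meta["noise_sd"] = noise_sd
    meta["seed"] = seed
    if metadata:
        meta.update(metadata)
    return MeltingCurve(T, y, "K", meta)
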