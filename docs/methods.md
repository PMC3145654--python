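# Methods

## Model

`camdyn` implements a structure-based (Go-type) side-chain/Cα protein model.
Every residue contributes a backbone bead at its Cα position and, except for
glycine, a side-chain bead at the side-chain heavy-atom centroid. Reference
geometry — bond lengths, angles, backbone torsions, native-contact distances —
is measured from the input structure, so the reference conformation has zero
bonded energy and sits at the bottom of every native well.

Energies are reduced by ε = 0.6 kcal/mol; lengths are in Å, masses in bead
units, time in τ_L = σ√(m/ε), and k_B = 1 so temperature is quoted in k_BT/ε.

Hamiltonian terms:

| term | form | parameters |
|---|---|---|
| bond | k_b (r − r⁰)² | k_b = 100ε |
| angle | k_θ (θ − θ⁰)² | k_θ = 20ε, clamped arccos at collinearity |
| torsion | k₁[1 − cos(φ−φ⁰)] + k₃[1 − cos 3(φ−φ⁰)] | k₁ = 1ε, k₃ = 0.5ε |
| native contact | D[5(r⁰/r)¹² − 6(r⁰/r)¹⁰] | depth D from the depth model |
| steric | ε (σ̄/r)¹², σ̄ = f(σᵢ+σⱼ)/2 | f = 0.9 |
| screened Coulomb | ZᵢZⱼe² exp(−κr)/(4πε₀ε_r r) | ε_r = 80, κ from ionic strength |

The torsion series is anchored at the measured native torsion (minimum at
φ⁰), with a per-residue disable list for modelled-in terminal residues whose
torsional stiffness should not be imposed. No ½ prefactor is used in the
bond/angle terms; the spring constants above absorb it.

Conventions that were genuinely open and are fixed here:

- **σ is a diameter.** The `sigma` stored on beads is the length parameter of
  the steric term. A crowder of hard-core *radius* 55 Å therefore carries
  σ = 110 Å, which makes two crowders at contact (center distance 110 Å) cost
  exactly ε·0.9¹² — the consistent reading of the repulsion formula.
- **Native contacts** are residue pairs at sequence separation ≥ 3 whose
  minimum heavy-atom distance in the reference structure is below a 4.5 Å
  cutoff (configurable); the contact acts between side-chain beads (Cα for
  glycine). Well depths default to uniform ε; a per-residue-pair mapping or
  callable can supply statistical-potential depths. The numeric
  Betancourt–Thirumalai matrix is not redistributed here; the depth model is
  the plug-in point for it.
- **Exclusions.** Bonded (1–2) and angle (1–3) pairs are excluded from all
  nonbonded terms. Calcium beads interact only sterically beyond their
  tethers and carry no screened-Coulomb charge. Nonnative side-chain pairs
  are repulsive-only.
- **Charges.** A charge table (tab-delimited: resnum, resname, backbone
  charge, side-chain charge) assigns per-bead partial charges; without one,
  fallback formal charges apply (Asp/Glu side chain −1, Lys/Arg +1,
  everything else 0, termini neutral as for capped termini). Charge
  assignment conserves the table total exactly.
- **Electrostatics units.** The screened Coulomb term is the only place
  physical constants enter: it is evaluated in kcal/mol via
  e²N_A/4πε₀ = 332.06 kcal·Å/mol and divided by ε on return. With CODATA
  constants the Debye length at (0.1 M, ε_r = 80, 298 K) is 9.71 Å and the
  Bjerrum length 7.01 Å; tests freeze those values.

## Sampling

The integrator is velocity Verlet with explicit friction and a per-step
random force of variance 2ζk_BT/h per degree of freedom
(fluctuation–dissipation); at ζ = 0 it reduces exactly to velocity Verlet,
which the energy-conservation test exploits. Defaults: h = 0.005 τ_L,
ζ = 0.05 m/τ_L (low-friction regime); a step that would move any bead by
more than half the smallest bead diameter raises an instability error.
Replica exchange uses a geometric ladder (default 18 rungs, 1.0–1.63
k_BT/ε), Metropolis acceptance min(1, exp[(βᵢ−βⱼ)(Eᵢ−Eⱼ)]) on alternating
even/odd neighbor pairs every 400 τ_L, velocity rescaling by √(T_new/T_old)
on acceptance, and a single seeded generator for all randomness, so runs are
bit-reproducible per seed.

Crowders are mobile particles (mass 10 bead units so their time scale stays
within reach of the bead timestep; a mass ∝ σ³ would freeze them).
Placement is random sequential insertion under periodic minimum image;
because RSA saturates near volume fraction 0.38, the 0.40 condition falls
back to a seeded, jittered cubic lattice that is still exactly
non-overlapping and deterministic. Placement does not know about the
protein; a protein at the box center may overlap a crowder at t = 0 and is
pushed off by the steric wall within the first few steps. Stored frames wrap
crowders bead-wise and the protein rigidly (by centroid), keeping bonded
geometry intact across the boundary.

## Analysis

- **χ (overlap function):** fraction of bead pairs (residue separation ≥ 2)
  whose distance deviates from the reference by ≥ 2.0 Å. 0 = reference-like,
  1 = fully dissimilar.
- **Δ (asphericity):** (3/2)Σ(λᵢ−λ̄)²/(Σλᵢ)² from gyration-tensor
  eigenvalues; 0 = sphere, 1 = rod.
- **Helicity:** residue i is helical when the Cα virtual torsion over
  (i−1…i+2) lies in [30°, 80°] and d(Cαᵢ, Cαᵢ₊₄) < 6.5 Å; chain ends where
  either test is undefined are excluded from the denominator. The window and
  cutoff are configurable — the estimator itself is a design choice.
- **EF-hand angle Θ:** angle between helix endpoint vectors, each from the
  mean of a helix's first four Cα positions to the mean of its last four.
- **Contacts:** a native contact is formed below 1.2 × its native distance;
  a nonnative candidate below 8 Å (both configurable, logged in the
  definitions object). Contact covariance is the Pearson-normalized
  covariance of the per-frame indicators; constant contacts are flagged
  as undefined rather than zero-filled.
- **WHAM** is solved in binless form on the pooled samples:
  f_k = −ln Σ_n exp(−β_k E_n)/Σ_l N_l exp(f_l − β_l E_n), iterated to a
  1e-7 increment (cap 1e5 iterations), with adjacent-temperature overlap
  checked up front. Reweighted surfaces bin (χ, Δ) on a 50×50 grid over
  [0,1]²; F = −k_BT ln P with the minimum shifted to 0 and empty bins
  flagged, not zero-filled. Basin rectangles use closed-open bounds.
- **CD synthesis:** θ(λ) = f_H·B_H + f_β·B_β + (1−f_H−f_β)·B_C. The packaged
  basis spectra are a *synthetic* Gaussian-band construction reproducing the
  canonical band positions of poly-amino-acid reference spectra (helix
  192+/208−/222−, sheet 196+/217−, coil 198−); amplitudes are plausible but
  not digitized from any instrument, and the basis is swappable via an
  argument. Computed spectra capture secondary-structure content only — not
  tertiary effects such as helix reorientation.

## Thermal-unfolding fits

Signals are mean residue ellipticity: [θ] = mdeg·MW/(path_mm · conc_mg/ml ·
N_res), exactly invertible. Unfolding uses K = exp(−ΔG/RT) with ΔG from the
modified Gibbs–Helmholtz equation, ΔG(T_m) = 0 and unfolded favored above
T_m. The three-state scheme is sequential (N↔I↔U) with
f_N = 1/(1+K₁+K₁K₂); each state has a free linear baseline (the intermediate
baseline can be pinned by fixing its slope start, default free). The
two-state model is the K₂→0 limit of the three-state model to 1e-10.

Fitting is bounded trust-region least squares with multi-start midpoint
initialization (temperature quantiles), baselines initialized by linear
regression on the curve edges, and parameter scaling for conditioning.
T_m is bounded near the observed range and ΔH_m to (1, 300) kcal/mol.
ΔC_p can be fixed (the three-state default is 0, the choice that makes the
two-transition fit identifiable). Standard errors are asymptotic (from
JᵀJ); fits are flagged ill-conditioned when the two midpoints collapse
within 2 K, the Jacobian is rank-deficient, the T_m standard error exceeds
half the temperature range, or the fitted transition amplitude is below the
residual scatter (a straight line).

Two identifiability limits are worth knowing. With ΔC_p free, the
Gibbs–Helmholtz curve can have two roots, so distinct (T_m, ΔH_m, ΔC_p)
triples reproduce the same curve over a finite range — fits with free ΔC_p
report *a* valid parameterization, not necessarily the generating one.
And a broad first transition (ΔH ~ 27 kcal/mol) overlapping a second one is
only resolvable with densely sampled, low-noise data.

## Synthetic data

The fixtures module generates every test input deterministically:
ideal helices (100°/residue turn, right-handed, 1.5 Å rise, 2.3 Å radius →
3.83 Å Cα spacing, virtual torsion ≈ 50°), extended chains, a desk-scale
helix-loop-helix calcium motif whose inter-helix angle is set exactly by
construction (the second helix is rotated about an axis perpendicular to the
first helix's endpoint vector), Gaussian-perturbed reference ensembles,
independent 3-D harmonic wells with closed-form thermodynamics
(⟨E_pot⟩ = (3/2)Nk_BT, Z ∝ β^(−3N/2)), and synthetic melting curves.

Synthetic melting curves default to a 278.15–363.15 K grid at 0.2 K pitch
with Gaussian noise of 50 deg·cm²/dmol — the sampling density and scatter of
a slow-ramp, averaged 222 nm acquisition. Recovery statistics in the tests
(midpoints within 2%, enthalpies within 10% over 100 replicates, midpoint
bias under 1 K) are statements about these conditions; sparser or noisier
data degrade the recovery of the broad first transition well before the
second.

What the fixtures do *not* emulate: real CaM geometry (the motif is a
geometric stand-in), sequence-specific contact energetics, solvent
structure, or instrument drift. Passing tests therefore demonstrate the
correctness of the machinery — energies, forces, sampling, reweighting,
estimators, fits — not agreement with any particular experimental ensemble.

## Problem sizes

The validation suite runs at desk scale by design: oracle systems of ≤ 30
beads, harmonic benchmarks of 5 particles × 4 replicas × 8×10⁴ steps, and
100-replicate fit-recovery studies. Production-scale runs (full CaM, 18
replicas, ≥ 4×10⁷ steps, hundreds of crowders) use the same code paths with
larger configuration values.

## Known limitations

- Dispersion and screened-Coulomb interactions between charged residues are
  both counted; no correction for this double counting is applied.
- Nonnative attraction is off by default (repulsive-only nonnative pairs);
  enabling a statistical-potential attractive mode requires supplying the
  depth model.
- WHAM error bars are limited to autocorrelation-deflated standard errors;
  no bootstrap machinery is included.
- The O(N²) pair evaluation is appropriate for coarse-grained systems of
  10²–10³ beads; there are no neighbor lists or GPU kernels.
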