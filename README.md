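# camdyn

Coarse-grained simulation and analysis of calmodulin conformational dynamics
under ionic strength, calcium binding, and macromolecular crowding — plus the
circular-dichroism (CD) thermal-unfolding fitting machinery used to interpret
the corresponding experiments.

Calmodulin (CaM) is a highly acidic, two-lobed calcium sensor whose ensemble
shifts between an extended dumbbell and collapsed compact forms depending on
salt, bound calcium, and the crowdedness of its surroundings. `camdyn`
implements a side-chain/Cα (two beads per residue, none for glycine's side
chain) structure-based model of this problem:

- **Hamiltonian.** Bonds `k_b (r − r⁰)²` with `k_b = 100ε`, angles
  `k_θ (θ − θ⁰)²` with `k_θ = 20ε` (`ε = 0.6 kcal/mol`), a 1-fold + 3-fold
  backbone torsion series, 12–10 attractive wells on native contacts,
  a strictly repulsive steric wall `ε (σ̄ᵢⱼ/r)¹²` with
  `σ̄ᵢⱼ = 0.9 (σᵢ + σⱼ)/2`, and a Debye–Hückel screened Coulomb term
  `V = Zᵢ Zⱼ e² exp(−κr) / (4π ε₀ ε_r r)` with
  `κ² = 2 N_A e² I·10³ / (ε₀ ε_r k_B T)`, `ε_r = 80`.
- **Calcium.** Each bound ion is an explicit bead tethered by stiff springs
  and angle terms to the side chains of its coordinating acidic residues
  (4 ions, 15 tethers for holo CaM); its other interactions are purely steric.
- **Crowders.** Ficoll-70-like hard spheres of radius 55 Å in a periodic
  1140 Å box with a half-box nonbonded cutoff.
- **Sampling.** Low-friction Langevin dynamics with temperature replica
  exchange (default: 18 temperatures, 1.0–1.63 k_BT/ε).
- **Analysis.** Radius of gyration, overlap function χ, asphericity Δ,
  helicity, EF-hand inter-helix angles Θ, native/nonnative
  contact-probability matrices and contact covariance, WHAM reweighting and
  F(χ, Δ) = −k_BT ln P free-energy surfaces, basin populations
  (M1/M2/M3 rectangles), and CD spectra synthesized from secondary-structure
  content.
- **Thermal fits.** Mean-residue-ellipticity conversion and two-state /
  sequential three-state unfolding fits through the modified Gibbs–Helmholtz
  equation `ΔG(T) = ΔH_m (1 − T/T_m) + ΔC_p [(T − T_m) − T ln(T/T_m)]`.

## Worked example

Fitting a synthetic 222 nm melting curve (two transitions with midpoints and
van't Hoff enthalpies at the magnitudes measured for apo CaM at 100 mM KCl,
Gaussian noise of 50 deg·cm²/dmol) with the three-state model, ΔC_p fixed
at 0:

```sh
$ python examples/fit_melting_curve.py
transition  T_m fit (C)  T_m true  dH fit  dH true
       N-I         47.9      46.6    27.2     27.2
       I-U         60.9      61.3    43.2     43.0
residual rms: 48 deg cm^2/dmol (noise sd 50)
T_m standard errors: 3.99, 1.16 K
```

Both midpoints come back within ~1.3 °C of the generating truth and both
enthalpies within 0.5 kcal/mol; the residual rms equal to the injected noise
indicates the model neither over- nor under-fits.

The other scripts in `examples/` each demonstrate one capability: topology
construction with calcium and charges (`build_topology.py`), Debye screening
across the experimental KCl range (`electrostatic_screening.py`),
replica-exchange sampling validated against a closed-form benchmark
(`replica_exchange_wham.py`), (χ, Δ) free-energy surfaces and basin
populations (`free_energy_landscape.py`), and CD-spectrum synthesis
(`cd_spectrum.py`). A thin `camdyn` CLI wraps the same API
(`camdyn topology|simulate|analyze|fitcd|fixtures --help`).

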