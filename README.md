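# llpsmd

Coarse-grained molecular simulation and analysis of liquid–liquid phase
separation (LLPS) of RNA-binding proteins and poly-U RNA.

Biomolecular condensates formed by proteins such as FUS, hnRNPA1 and TDP-43
assemble and dissolve in response to RNA: low RNA concentration stabilizes
the droplets, high concentration dissolves them (reentrant behavior), and
RNA length tunes droplet viscosity. `llpsmd` implements a residue-resolution
model and the full analysis chain needed to study these effects on a single
workstation: sequence-dependent pair potentials, a direct-coexistence
Langevin simulator, and estimators for phase diagrams, critical points,
surface tensions, contact statistics, conformational ensembles, shear
viscosity and diffusion. It is aimed at computational biophysicists who
want a transparent, fully testable implementation of this methodology.

## Model

One bead per amino acid (or uridine nucleotide), implicit solvent. The
potential energy is a sum of four terms:

* **Bonds** — harmonic, `U_b(r) = k (r − r0)²` between consecutive beads
  (prefactor convention configurable).
* **Hydrophobicity (Ashbaugh–Hatch)** — a λ-scaled Lennard-Jones form
  encoding each residue pair's hydropathy λij = (λi + λj)/2:

  `U_AH = LJ(r) + (1 − λij) ε` for `r ≤ 2^(1/6) σij`, `λij · LJ(r)` beyond,

  with `LJ(r) = 4ε[(σij/r)¹² − (σij/r)⁶]`. Residues buried inside
  structured domains (RRMs, zinc fingers, the TDP-43 helix) carry a 0.7
  interaction scale, entering λij multiplicatively.
* **Electrostatics (Debye–Hückel / Yukawa)** —
  `U_DH = (qi qj / 4πε0εr) · exp(−r/λD)/r`, with λD set by the ionic
  strength (≈ 0.8 nm at the physiological 150 mM).
* **Cation-π** — an extra Lennard-Jones well for (R,K) × (F,W,Y) pairs
  with tabulated depths.

All numeric parameters (masses, charges, σ, λ, cation-π depths, the RNA
bead) are read from editable TSV tables under `src/llpsmd/data/`. The
packaged FASTA file carries the public FUS, hnRNPA1 (isoform A1-B) and
TDP-43 sequences with domain annotations.

Phase diagrams come from direct-coexistence (slab) trajectories: tanh fits
of the density profile give the coexisting densities, closed with the
critical-exponent and rectilinear-diameter laws
`ρh − ρl = d (1 − T/Tc)^β` (β = 0.325) and
`(ρh + ρl)/2 = ρc + s (Tc − T)`. Surface tension uses the pressure-tensor
anisotropy `γ = (Lz/2)⟨Pzz − (Pxx + Pyy)/2⟩` and scales as
`γ ∝ (Tc − T)^1.26`. Viscosity is the Green–Kubo time integral of the shear
relaxation modulus `G(t)`, evaluated as `η = Σ Gi τi` after a Maxwell-mode
fit; diffusion coefficients come from center-of-mass mean-squared
displacements.

## Worked example

```python
from llpsmd import sequences as sq
from llpsmd.forcefield import default_params, debye_length
from llpsmd.fixtures import synthetic_binodal
from llpsmd.phase_analysis import fit_critical_point

params = default_params()
fus = sq.load_reference_proteins()["FUS"]
print(f"FUS: {len(fus)} residues, glycine fraction "
      f"{sq.composition(fus)['G']:.3f}")
print(f"FUS net charge: {sq.net_charge(fus, params):+.0f} e")
ratio = sq.electroneutral_mass_ratio(fus, sq.make_polyU(250), params)
print(f"electroneutral poly-U/FUS mass ratio: {ratio:.4f} mg RNA / mg protein")
print(f"Debye length (150 mM, 300 K): {debye_length(150.0, 300.0):.3f} nm")

points = synthetic_binodal(tc=400.0, rho_c=0.30, noise=0.01, n_points=6,
                           seed=11)
d = fit_critical_point(points, seed=11)
print(f"fitted Tc = {d.tc:.1f} +/- {d.tc_err:.1f} K, "
      f"rho_c = {d.rho_c:.3f} +/- {d.rho_c_err:.3f} g/cm^3")
```

prints

```
FUS: 526 residues, glycine fraction 0.289
FUS net charge: +14 e
electroneutral poly-U/FUS mass ratio: 0.0803 mg RNA / mg protein
Debye length (150 mM, 300 K): 0.795 nm
fitted Tc = 399.2 +/- 2.5 K, rho_c = 0.300 +/- 0.002 g/cm^3
```

Glycine is indeed nearly 30% of FUS; the +14 e net charge fixes the RNA
mass fraction at which a poly-U/FUS mixture is electroneutral — the regime
where RNA most enhances phase separation; and the critical-point fit
recovers a known synthetic binodal to well under a percent with a
bootstrapped uncertainty.

A command-line interface mirrors the library
(`llpsmd simulate|phase-diagram|surface-tension|contacts|rheology|make-fixture|report`);
`llpsmd report --config pipeline.yml` runs a whole staged pipeline with
provenance manifests.

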