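# Methods

## Model

`llpsmd` implements a hydropathy-scale (HPS-family) coarse-grained model:
one spherical bead per amino acid or nucleotide, implicit solvent, real
units (nm, ps, K, g/mol, kJ/mol — a consistent set, so kinetic energy in
kJ/mol is `½ m v²` with m in g/mol and v in nm/ps).

Interaction terms and their assumptions:

* **Harmonic bonds**, `U = k (r − r0)²` with k = 8033 kJ/mol/nm² and
  r0 = 0.38 nm (protein) / 0.50 nm (RNA). Both the `k` and the `k/2`
  prefactor conventions occur in the literature of this model family; the
  convention is a `BondParams` field and is recorded in run configs.
* **Ashbaugh–Hatch** pair term with a single global energy scale
  ε = 0.8368 kJ/mol (0.2 kcal/mol) and per-residue hydropathies λ ∈ [0, 1];
  combining rules are arithmetic means for both σij and λij. Residues
  flagged *buried* (structured RRM/ZF/helix regions, from annotation files,
  never inferred from sequence) carry `interaction_scale = 0.7`, and λij is
  multiplied by the product of the two bead scales — a 30% scale-down of
  buried-residue short-range attraction.
* **Debye–Hückel** screened electrostatics. The screening length is always
  derived from (ionic strength, temperature, εr) via the closed form; at
  150 mM, 300 K, εr = 80 it is 0.795 nm. Histidine is uncharged at
  physiological pH (a table entry, overridable). The RNA bead (uridine)
  carries −1 e.
* **Cation-π** extra Lennard-Jones wells for (R,K) × (F,W,Y) with depths
  from their own table (shipped default: 12.552 kJ/mol for all six pairs).

All short-range terms are truncated **and shifted** at 3.5 σij, the
electrostatics at 3.5 nm. Shifted truncation keeps the energy continuous at
the cutoff (the force retains the — negligible at 3.5 σ — tail value),
which is what stable weak-friction Langevin dynamics needs. Forces are
analytic gradients; the test suite verifies them against centered finite
differences to ≤ 1e−5 relative for every term.

Parameter values live in TSV tables (`src/llpsmd/data/*.tsv`), not in code.
The shipped tables carry the published values of this model family
(HPS-style amino-acid set, uniform cation-π depths, a Regy-style uridine
bead); anyone with a different SI table can swap the files without touching
code.

### What the model does not contain

No RNA secondary or tertiary structure, no sequence-specific RRM–RNA
recognition, no explicit ions or pH titration, no PTMs. Poly-U is a
homopolymer of identical −1 e beads. Absolute temperatures of an implicit
solvent model are not physical; only renormalized temperatures (T/Tc) carry
meaning, and reports expose both.

## Simulator

BAOAB-splitting Langevin dynamics; at zero friction it reduces exactly to
velocity Verlet (verified by an energy-conservation test). Defaults:
timestep 10 fs, friction 0.01 ps⁻¹ — standard for one-bead-per-residue
models. All randomness (initial Maxwell–Boltzmann velocities, thermostat
noise, slab construction) flows from one seeded `numpy` generator per run;
identical seeds give bit-identical trajectories.

Direct-coexistence (slab) initial states place chains as self-avoiding
random walks (no pair closer than 0.7 σij) inside a central cube spanning
x,y whose edge is set by the requested slab density; the box is elongated
along z (aspect 3:1 by default), so interfaces are normal to z. Builder
configurations are intentionally rough; a displacement-capped steepest
descent (`minimize_energy`) plus a short strongly coupled equilibration
(friction 1 ps⁻¹) precede weak-friction production — without this the
overlap energy thermalizes into a large temperature transient.

Structured regions can optionally be kept rigid by an elastic network:
harmonic restraints between all template pairs within 1 nm of an ideal
α-helix template (0.23 nm radius, 0.15 nm rise, 100°/residue), in addition
to the buried λ scale-down.

Positions are integrated unwrapped (periodicity enters through
minimum-image distances and the periodic k-d-tree neighbor search), so Rg
and MSD need no unwrapping pass; wrapped views are produced on demand.
Neighbor lists (cutoff + 0.4 nm skin) are rebuilt when any displacement
since the last build exceeds half the skin. Pair kernels are numba-compiled
and accumulate per-term energies and the full virial tensor; saved frames
carry instantaneous pressure tensors `(Σ m v⊗v + Σ r⊗f)/V`.

Trajectories are in-memory arrays with plain-text extended-XYZ export
(time, box and pressure tensor in the comment line) and PDB snapshots for
visualization. A binary container was deliberately not added: every
analysis in scope reads the in-memory form or the text format.

## Analyses

**Density profiles** are histogrammed along z after recentering each frame
on the slab's mass-weighted *circular mean* (the center of mass computed on
the unit circle θ = 2πz/Lz). This is equivalent to a largest-cluster
recentering for slab geometries, cheap, and immune to slabs crossing the
periodic boundary; for a homogeneous system it centers on the largest
density fluctuation, which only inflates the apparent central density
within counting noise.

**Coexisting densities** come from a four-parameter fit of
ρ(z) = (ρh+ρl)/2 − (ρh−ρl)/2 · tanh((|z|−z0)/w). The fit refuses to report
coexistence when the plateau separation is below 3× the residual noise.

**Critical points**: joint least squares of the width law
(ρh − ρl) = d (1 − T/Tc)^β and the rectilinear diameter
(ρh + ρl)/2 = ρc + s (Tc − T), initialized by linearizing the width law in
(ρh − ρl)^(1/β). β defaults to 0.325 (3D Ising) and is configurable, since
the governing equations admit either the universal or a fitted exponent.
Uncertainties are bootstrap over binodal points (200 resamples). On
synthetic binodals with 1% multiplicative noise the fit recovers Tc to
≈0.25% on average and the 95% bootstrap CI covers the truth in ≳90/100
repeats (both recomputed by `scripts/acceptance.py`).

**Surface tension**: γ = (Lz/2)⟨Pzz − (Pxx+Pyy)/2⟩, block-averaged over 5
blocks; γ(T) is fitted with the exponent fixed at 1.26 (one free
amplitude), so γ extrapolates to zero exactly at Tc.

**Contacts**: a pair of beads on different chains is a contact when its
minimum-image distance is ≤ 1.2 × 2^(1/6) σij (boundary inclusive) — a
cutoff placed just beyond the attractive minimum of the hydropathy term;
the 1.2 factor is exposed in configs and recorded in output metadata.
Position maps report the percentage of (frame, ordered-chain-pair)
observations in contact, so co-located chains read 100 and values are
bounded by 100. Type-pair counts can be renormalized by abundance,
`raw / (f_a f_b (2 − δab))`, which converts frequencies into per-pair
propensities — the transformation under which rare-but-sticky pairs (R-Y)
outrank abundant ones (G-G). Domain aggregation sums map blocks over
annotated intervals (uncovered positions pool into `other`, preserving the
grand total).

**Rheology**: G(t) = V/(kBT)·⟨Pαβ(0)Pαβ(t)⟩ averaged over the five
independent traceless components (xy, xz, yz, (Pxx−Pyy)/2, (Pyy−Pzz)/2),
FFT time-origin averaging, mean removed per component. Maxwell fits run
non-negative least squares on a log-spaced τ grid (2×frame spacing to
≈2.5× the longest lag, 60 points), prune zero modes, keep at most
`n_modes` (default 8) by Gi·τi, then refine (Gi, τi) jointly with bound
least squares. η = Σ Gi τi; when the fit starts after lag 0 the raw
short-time segment is integrated by trapezoid. Uncertainty propagates from
the fit covariance.

**Diffusion**: chain-center-of-mass MSD with FFT time-origin averaging and
optional per-frame system-drift removal. The diffusive window is detected
by a local log-log slope within 1 ± 0.1 and capped at the first fifth of
the series — longer lags average too few origins for a stable slope (an
effect visible as seed-to-seed scatter when fitted further out). D =
slope/6; errors from 5 trajectory blocks.

## Synthetic fixtures and what passing tests mean

The fixture generators produce inputs with *exactly known* structure: toy
sequences (maximum-hydropathy homopolymer, K/D diblock, shuffled control),
binodal point sets generated from the two scaling laws, tanh slab profiles,
and pressure-tensor series built from Ornstein–Uhlenbeck modes whose
autocovariance is Σ Gi exp(−t/τi)·kBT/V by construction (exact
discretization, stationary start, dt < τmin/10 enforced). They share the
estimators' functional-form assumptions, so recovery tests certify the
estimators, not the model; they deliberately do not mimic real
FUS/hnRNPA1 binodal values. Conclusions about real proteins additionally
require the force field to be right — that part is validated separately by
the force/invariance suites and, at reduced scale, by the demixing test.

The demixing check evolves 40 chains of a 20-bead maximum-λ homopolymer
slab at 0.4 g/cm³, T = 150 K: with λ = 1 the slab persists
(condensed/dilute density ratio ≫ 5, condensed plateau ≈ 0.77 g/cm³); with
λ = 0 the same initial slab homogenizes (ratio < 1.5 after 1.5 ns). The
conformational comparison follows the two-bulk-runs protocol: P(Rg) of
chains in the slab interior versus isolated chains in a large box at the
same T = 250 K — condensed-phase chains are consistently more expanded
(Rg ≈ 1.1 nm vs ≈ 0.92 nm over 3 seeds), because an isolated sticky chain
collapses into a globule while melt chains swell to make intermolecular
contacts. Problem sizes (hundreds of beads, 10⁴–10⁵ steps) are chosen so
the whole suite runs on one CPU in minutes; cluster-scale runs of the full
150–530-residue proteins use the same code paths unchanged.

## Numerical choices and edge cases

* Combining rules applied once and cached (`InteractionTable`); unknown
  residue codes fail loudly with the offending code named.
* Nonbonded terms exclude directly bonded pairs only (1-2 exclusion).
* Contact boundary distances equal to the cutoff count as contacts.
* The tanh fit swaps branches if the optimizer converges mirrored.
* `stress_series` refuses dt ≥ τmin/10 (resolution guard);
  `relaxation_modulus` refuses series shorter than 10× the longest lag.
* Degenerate Rg histograms (all values identical) and wrapped chains (any
  bond longer than half the box) raise instead of returning silent numbers.
* Pipeline stages hash their (kind, params, seed) into a manifest and are
  skipped when outputs and hashes match, so reruns are byte-identical and
  deleting one stage's outputs retriggers only that stage.

## Known limitations

* The force at the cutoff retains the (tiny) tail value of the
  truncated-shifted potential; energy is continuous, the force is not.
* The circular-mean recentering assumes a single dominant slab; multi-slab
  configurations would need the cluster-based variant.
* Maxwell-mode covariance (and hence the viscosity error bar) assumes
  independent residuals; correlated G(t) noise makes it optimistic.
* The elastic-network helix template is a generic ideal helix, not a
  crystallographic structure.
* Reported absolute viscosities inherit the model's coarse-grained
  timescales and should be compared between conditions, not to experiment.
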