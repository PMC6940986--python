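# saxshybrid

Small-angle X-ray scattering (SAXS) analysis and C2-symmetric hybrid
modeling for two-domain homodimeric proteins, built around the workflow
used to determine the solution architecture of the intracellular region of
a CNNM-family magnesium transporter: a dimer of nucleotide-sensing
CBS-module domains stacked on a dimer of cyclic-nucleotide-binding-homology
domains, joined by disordered linkers.

The package is aimed at structural biologists who have a 1D solution
scattering curve `(q, I, σ)` and want, in one importable toolkit:

- **Primary analysis** — Guinier fit (Rg, I(0), automatic q·Rg ∈ [0.3, 1.3]
  window), indirect Fourier transform to the pair-distance distribution
  P(r) with automatic Dmax selection, Porod invariant/volume/exponent with
  the MW(kDa) = 0.58 × V(nm³) mass rule, the dimensionless Kratky
  representation, and oligomeric-state inference.
- **Forward scattering** — the Debye sum
  `I(q) = Σᵢⱼ fᵢfⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ)` for bead or atomic models
  (histogram-accelerated with an exact path for verification), the analytic
  sphere form factor, and the scale + reduced-χ² fit of model to data with
  `χ² = Σ((c·Iₘ − I_d)/σ)²/(N−1)`.
- **Ab initio shape reconstruction** — simulated-annealing dummy-residue
  (one bead per residue, 3.8 Å bonds) models against a curve, plus ensemble
  alignment, normalized spatial discrepancy (NSD) and occupancy-grid
  consensus averaging.
- **Symmetric rigid-body assembly** — detection of a dimer's two-fold axis,
  a grid search over the rotation φ and axial separation t of two dimers on
  a shared C2 axis under three scenarios, a χ² gate, reporting of
  χ²-degenerate rotamer pairs, and a morphological-complementarity
  tie-break (buried Shrake–Rupley interface area minus a near-clash
  penalty).
- **Linker completion** — missing disordered segments grown as steered
  self-avoiding bead chains, mirrored by the C2 operation, selected by
  full-model χ².
- **Synthetic data** — ground-truth toy structures (spheres, dumbbells,
  two-domain C2 dimers with flat/twisted conformations and optional
  linkers) and SEC-SAXS-like noisy curves, so the entire pipeline is
  testable end to end without any download.

## Worked example

`python examples/01_primary_analysis.py` builds a C2 dimer (Rg ≈ 36 Å),
simulates a noisy curve, and runs the full primary analysis:

```
truth:    Rg = 36.33 A   Dmax = 121.1 A
Guinier:  Rg = 36.06 +- 0.41 A   I0 = 2.657e+06   sRg window 0.32-1.29
P(r):     Dmax = 112.1 A   Rg = 36.44 A   I0 = 2.666e+06
Porod:    V = 105.8 nm^3   exponent = 1.16   MW = 61.4 kDa (x0.58)
Oligomer: ratio = 2.00 -> state 2
```

Guinier and real-space Rg agree with the truth to < 1%; Dmax from 2%-noise
data is recovered to ~10 Å (its statistical limit — see
`docs/methods.md`); the Porod mass over the per-protomer mass identifies a
dimer. The low Porod exponent reflects the rod-like intermediate regime of
this elongated particle within the fitted q·Rg window.

`python examples/03_symmetric_assembly.py` then recovers a known rigid-body
arrangement from its noisy curve:

```
rank  phi(deg)  t(A)    chi2   interface(A^2)
   1      40.0   36.3   0.851        0
   2     140.0   36.3   0.851        0
   ...
truth was (phi, t) = (40, 36)
```

The best candidate lands on the generating rotation and separation (φ and
180° − φ are congruent for the centrosymmetric toy blocks), with reduced
χ² ≈ 0.85 against the data.

## Layout

```
src/saxshybrid/
  curves.py        curve I/O, instrument geometry, sequence masses
  coordinates.py   bead/atomic coordinate models, PDB I/O (gemmi)
  scattering.py    Debye sums, sphere form factor, chi2 fitting
  analysis.py      Guinier, P(r)/Dmax, Porod, Kratky, oligomer state
  beads.py         annealing reconstruction, NSD, ensemble averaging
  assembly.py      C2 axis detection, rigid-body search, SASA/complementarity
  linkers.py       self-avoiding linker growth, hybrid completion
  simulate.py      toy structures, noise model, benchmark fixtures
  config.py        all tolerances/grids in one place (YAML-overridable)
  cli.py           thin command-line layer
docs/methods.md    models, numerical choices, limitations
examples/          one narrative script per capability
```
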