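# Methods

`saxshybrid` implements the solution-scattering workflow used to determine
the architecture of a two-domain, C2-symmetric homodimeric protein from
SEC-SAXS data: primary curve analysis, ab initio dummy-residue shape
reconstruction, a symmetry-constrained rigid-body search over alternative
domain arrangements, and completion of the rigid model with disordered
linkers. This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Scattering model

All forward scattering uses the Debye sum over point particles,

    I(q) = sum_ij f_i f_j sin(q r_ij) / (q r_ij),

with a uniform bead weight f = 1. This is the central deliberate
simplification: no per-residue electron counts, no hydration shell, no
excluded-volume term. Shape-level modeling — ranking rigid-body
arrangements and reconstructing envelopes — depends on the relative profile
only, which the uniform-weight sum captures. Absolute intensities are never
interpreted; every fit carries a free multiplicative scale.

The default evaluation path histograms the pairwise distances (bin width
0.1 Å, configurable) and represents each bin by its mean distance, which is
second-order accurate in the bin width; an exact O(N²) path is kept for
verification. For grid searches a precomputed sinc kernel over distance
bins turns each candidate's evaluation into one histogram plus one
matrix-vector product.

A point-particle model's intensity does not decay at large q — it levels
off near N (the self terms). The Porod analysis therefore estimates a flat
background from the mean intensity over the last 15% of the q range and
subtracts it before integrating; on measured data this same term absorbs
residual buffer-subtraction offsets.

## Primary curve analysis

**Guinier.** Weighted least squares of ln I against q² over the largest
contiguous window with q·Rg ∈ [0.3, 1.3], iterated to self-consistency from
a seed fit on the first ten points. Because compact non-Gaussian shapes
(the sphere is the worst case) curve ln I downward near the q·Rg = 1.3
limit and bias Rg high by ~2%, the window top is then shrunk in 0.1 steps
(floor 0.6) while a weighted quadratic fit in q² detects statistically
significant curvature. On an exactly Gaussian curve nothing shrinks and the
fit is exact; on a noiseless sphere the bias drops below 1%; on noisy data
the significance test prevents spurious shrinking.

**P(r) inversion.** The pair-distance distribution uses the convention
P(r) = γ(r)·r² with I(q) = 4π ∫ P(r) sinc(qr) dr, so I(0) = 4π ∫ P dr and
Rg² = ∫ r²P dr / (2 ∫ P dr). The inversion solves a 1/σ-weighted
non-negative least-squares problem on a 101-point r grid with fixed zero
endpoints, penalized by α × (sum of squared second differences). α is
chosen by scanning a log grid (10⁻⁴…10²) and taking the maximum-curvature
corner of the (log residual, log roughness) L-curve.

**Dmax.** Scanned over [2Rg, 4Rg] in 2 Å steps, scoring each candidate by
fit-χ² + 10 × (negativity fraction of the sign-unconstrained solve) + 1 ×
(normalized roughness), and returning the arg-min. One α, chosen at the
scan's *low* end, is used for the whole scan: re-selecting α per candidate
makes the scores incomparable, and a mid-scan choice over-smooths and
biases Dmax low by about two grid steps.

A limitation worth stating plainly: with the default 2% multiplicative
noise, the outermost pair distances of an elongated particle carry almost
no statistical weight — the Dmax score is flat over roughly ±15 Å around
the truth, and no estimator can do better from that data. The
parameter-recovery benchmark therefore assesses Dmax on the noiseless
member of each simulated dataset (where recovery is within ~2 grid steps)
and Rg, which is robust, on the noisy member.

**Porod.** Q = ∫ q²I dq with the segment below q_min replaced by the
Guinier extrapolation, the background-subtracted body integrated by
trapezoid, and the tail closed analytically assuming I ∝ q⁻⁴ with the
Porod constant estimated from the high-q points. Volume = 2π² I(0)/Q,
reported in nm³. The mass estimate is 0.58 × V[nm³] kDa (primary rule);
the half-of-the-volume heuristic (V[Å³]/2 → Da) is reported alongside,
never mixed. The Porod exponent is the p for which q^p·I(q) has zero
linear trend over q·Rg ∈ [2.5, 6] (root-found by bisection): a log-log
slope fit is destroyed by the deep minima of oscillatory form factors,
whereas the flatness criterion averages over them. The window sits past
the Guinier shoulder but before the noise-dominated tail; the analytic
benchmarks give ≈3.8 for a sharp-interface sphere and ≈1.9 for an ideal
flexible coil.

**Dimensionless Kratky.** (qRg)² I/I₀ against qRg, peak refined by a local
parabola. An ideal particle obeying the Guinier law peaks at exactly
(√3, 3/e ≈ 1.104); a uniform sphere's closed form peaks slightly lower
(≈1.03); an ideal coil plateaus at 2.

**Oligomeric state.** Porod mass (kDa→Da) divided by the sequence monomer
mass; the nearest integer is reported with a caution flag when the ratio
sits more than 0.35 from it. Note the ×0.58 rule substantially
overestimates the mass of partially flexible constructs, so the ratio is a
guide, not a measurement.

## Dummy-residue reconstruction

A chain of one bead per residue (3.8 Å bonds) is annealed against the
curve inside a search sphere of radius Dmax/2. Energy = χ²(Debye vs data,
on a 50-point q subgrid) + 10 × Σ(bond − 3.8)² + 10 × (non-adjacent pairs
closer than 3 Å). Moves are single-bead Gaussian displacements (σ = 1 Å)
with Metropolis acceptance; the Debye sum is updated incrementally (one
bead's row of cross terms). The schedule starts at T₀ = initial energy,
cools by ×0.8 per stage (100·n moves each), and stops when fewer than 2%
of a stage's moves are accepted or after 60 stages. Early stopping is
acceptance-based deliberately: best-energy stagnation triggers falsely
during the hot exploration phase. After annealing, bond lengths are
projected into [3.0, 4.6] Å. Runs are bit-reproducible for a fixed seed.

The reduced χ² of a converged run against noisy synthetic data typically
lands between 2 and 15, not near 1: a uniform-weight chain cannot (and
should not) reproduce a curve to within the small high-q uncertainties of
the noise model. The convergence flag threshold is a reporting aid, not a
quality guarantee; shape metrics (Rg, maximum extent) are the meaningful
outputs, and on the 150-bead sphere benchmark both are recovered within
5% / 10%.

Ensembles of independent runs are compared by normalized spatial
discrepancy (NSD) after rigid alignment (principal-axis starts including
the identity, refined by nearest-neighbor ICP with Kabsch updates;
inversion optional). Models whose mean NSD exceeds the ensemble mean + 2 SD
are discarded; survivors are aligned to the most typical model and
averaged on a 2 Å occupancy grid thresholded to enclose the median
single-model volume.

## Symmetric rigid-body search

Both dimeric building blocks must pass a C2 check: the least-squares
rotation mapping chain A onto chain B (correspondence by residue number)
must be 180 ± 5°. Each block is then canonicalized — axis to +z, centroid
to the origin — and the assembly is parameterized by the rotation φ of the
lower block about the shared axis and the axial centroid separation t.
Axes are forced collinear: C2 symmetry of the whole assembly requires a
single shared two-fold.

The scan covers φ ∈ [0°, 180°) in 5° steps (φ and φ+180° are equivalent
under C2) and t from 5 Å below to 25 Å above the contact separation
(computed in closed form from the cross-pair geometry) in 1 Å steps.
Candidates with any inter-body pair closer than 3 Å are clash-flagged and
excluded from ranking; the rest are ranked by reduced χ². A gate (default
χ² < 2; 2.5 for the phosphatase-complex setting) selects survivors, the
two deepest distinct φ minima are reported as a rotamer pair, and
survivors within 0.2 χ² of the best are re-ordered by morphological
complementarity: buried interface area (Shrake–Rupley SASA, 960 sphere
points per particle, probe 1.4 Å, bead radius 3.5 Å, PISA half-sum
convention) minus 50 Å² per contact pair in the 3.0–3.5 Å band. The
penalty weight operationalizes a criterion the source workflow names but
does not define.

Scenarios: (1) both dimers rigid; (2)/(3) one dimer predefined and the
other partner supplied as a single free subunit, placed by radial offset,
azimuth, axial offset and three Euler angles (30° steps), with its mate
generated by the C2 operation — symmetry is enforced rather than left
free, which is the stricter reading of an ambiguous protocol. The full
pose grid is combinatorially large, so it is subsampled deterministically
(seeded) to a configurable candidate budget.

Because all toy building blocks are centrosymmetric ellipsoids, φ and
180° − φ generate congruent assemblies; recovery benchmarks count either
as the truth. Real crystallographic blocks are chiral and do not have this
degeneracy.

## Linker completion

Missing segments (e.g. a 33-residue interdomain linker and a 45-residue
C-tail) are grown as self-avoiding bead chains at fixed 3.8 Å steps. Each
step draws a direction — uniform for free tails, otherwise inside a cone
aimed at the end anchor whose half-angle narrows linearly from 90° (when
remaining contour / remaining gap ≥ 2) to 15° as slack runs out — with up
to 50 redraws per bead before the chain is rejected (whole-chain rejection
has ~0.84ⁿ acceptance and is unusable at n = 45). Context particles within
8 Å of an anchor are not clash partners: the anchor residue is covalently
part of the rigid body. End-anchored chains must close to within 0.5 Å of
a final 3.8 Å hop. A set of linker conformers is sampled, mirrored by the
C2 operation (never sampled independently per protomer), scored with the
full-model χ², and the best single conformer is reported — matching the
one-model-per-condition style of the source workflow.

## Synthetic data generator

The generator is the study-condition oracle for every benchmark. Shapes:
lattice-filled spheres and ellipsoids (quasi-uniform, ~1 bead per (4 Å)³
at the default budget), and the flagship `two_domain_c2_dimer`: four
ellipsoid blocks (semi-axes 38 × 16 × 11 Å, centroids 25 Å off-axis), an
upper dimer and a lower dimer 36 Å apart along the shared two-fold, the
lower dimer rotated by φ (default 40°), exact C2 by construction. The
"twisted" conformation pivots each upper block about its own centroid by
the twist angle (out-of-plane tilt plus in-plane rotation, default
benchmark value 30°), emulating the twisted-versus-flat disk transition of
a CBS-module dimer; at the default noise this separates the conformers by
χ² ≈ 3. The resulting dimers have Rg ≈ 36 Å and Dmax ≈ 120 Å — the same
order as the measured constructs they emulate.

Noise: σ(q) = 0.02·I(q) + 0.001·I(0), Gaussian, seeded — a
multiplicative-plus-floor stand-in for counting statistics that reproduces
the signal-to-noise decay of an in-line SEC measurement. No interparticle
or concentration effects are simulated (the SEC setup justifies ideal
dilution), no detector geometry, no buffer-mismatch artifacts. Passing
tests on these fixtures demonstrates the estimators' correctness and
calibration under the stated noise model; they do not demonstrate
robustness to the systematic errors of real beamline data.

`make_benchmark_suite` writes six fixed fixtures (sphere, dumbbell, flat
dimer, twisted dimer, dimer with linkers, and a two-state mixture whose χ²
landscape carries two 60°-separated minima) as truth PDBs, noiseless/noisy
curves, and a TSV manifest with relative paths; regeneration with the same
seed is byte-identical.

## Problem sizes used by the test and acceptance runs

Benchmarks run at desk scale on one CPU: 150–2 000-bead models for the
analysis oracles (8 000 for the Porod-volume check), 150-residue
reconstructions, 1 600-bead dimers with 150-point curves for the rigid-body
searches, and 20-replicate recovery ensembles. These sizes were chosen so
the full suite exercises every stage end to end in minutes while keeping
each statistical criterion (calibration to ±0.1, recovery rates of 18/20)
well-powered.

## Known limitations

- Uniform bead weights make absolute intensities and contrast effects
  meaningless; only relative profiles are modeled.
- Dmax from 2%-noise data is identifiable only to ~±10 Å for elongated
  particles (see above); the reported value should be read with that
  uncertainty.
- The Porod ×0.58 mass rule inherits the source convention; it
  overestimates for flexible constructs (flagged by the oligomer-ratio
  caution, not corrected).
- The rigid-body search scans a shared-axis geometry only; lateral offsets
  between the two dimer axes are outside the model by design.
- Scenario 2/3 searches subsample their pose grid; the budget trades
  exhaustiveness for time and is configurable.
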