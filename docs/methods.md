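# Methods

`lipidfes` implements the analysis layer of a lipid-transfer free-energy
study: the order parameters that track extraction of a tagged lipid from
a bilayer into a transfer protein, the membrane- and protein-side
structural descriptors used to interpret that process, and the
free-energy estimators that turn biased sampling into ΔF profiles.  All
of it is validated end to end on synthetic configurations and toy
stochastic samplers whose ground truth is known exactly.

Internal units are nm, ps, kJ/mol and kelvin, with
kB = 0.0083144621 kJ/mol/K; free energies are additionally reported in
kcal/mol using 4.184 kJ/kcal exactly.

## Collective variables

**Transport coordinate r_LxS.**  For the tagged lipid and its closest
leaflet, all hydrophobic carbon–carbon (CC) distances d_CC(i) are formed
under the minimum-image convention, and

    r_LxS = α1·min(d_CC) + α2·n_CC + α0,

with α1 = −2.247 nm⁻¹, α2 = 0.004828 per contact, α0 = 0.6014, so r_LxS
is unitless: large and positive with the lipid inserted, negative once
it is free in solution.  The differentiable min is the soft-min
γ/log Σ exp(γ/d) with γ = 200 nm, evaluated with a max-shift so that
γ/d ≈ 400 (d = 0.5 nm) cannot overflow.  The contact count is either the
hard count of d ≤ 1 nm (inclusive; the convention used for analysis) or
the smooth rational switching sum with d0 = 1 nm, r0 = 0.025 nm.

The rational form (1−x⁶)/(1−x¹²), x = (d−d0)/r0, evaluates near zero for
d ≪ d0, which contradicts its role as a contact counter; we therefore
use the convention of the enhanced-sampling engines: s = 1 for d ≤ d0
and s = 1/(1+x⁶) beyond, with the removable singularity s(d0+r0) = 1/2
filled in.  The literal rational form remains available behind
`literal=True` for comparison.

**Native-contact fraction Q.**  Q = N⁻¹ Σ [1+exp(β(r_ij − λ r_ij⁰))]⁻¹
with β = 50 nm⁻¹ and λ = 1.8 over an enumerated pair list.  The pair
list is built once from a bound-form reference ensemble
(`build_q_reference`) and serialized as a TSV artifact: hydrophobic
pairs (lipid hydrophobic carbons × cavity-lining-residue carbons, mean
distance ≤ 0.78 nm) and polar pairs (lipid headgroup/backbone heavy
atoms × recognition-residue heavy atoms, ≤ 0.55 nm); r_ij⁰ is the
ensemble-mean distance.  The exact heavy-atom definition of the lipid
headgroup/backbone set is configurable through the role table; the
shipped default is the phosphate group plus the first three sphingoid
carbons and the amide N/O.

**Leaflets.**  Phosphates are split about their z midplane; ties go to
the upper leaflet.  The tagged lipid's closest leaflet is recomputed per
frame from its phosphorus z.

## Membrane descriptors

* insertion depth: residue COM z minus mean phosphate z of the bound
  leaflet (negative = buried), averaged over frames;
* tail orientation: cos θ_z of the terminal-carbon→anchor vector (C2 or
  C2S anchors in the CHARMM36 dialect) against +z;
* thickness: mean phosphate z difference between leaflets;
* area per lipid: 2D periodic Voronoi tessellation of phosphorus
  positions per leaflet (3×3 tiling, shoelace areas of the central
  image; the tessellation exactly partitions Lx·Ly).  Protein atoms are
  excluded entirely;
* acyl order S_CC: ⟨(3cos²θ−1)/2⟩ over consecutive CC bond vectors vs
  +z, averaged over bonds, tails, frames.  This is the carbon–carbon
  convention, not the C–H (S_CD) one;
* hydrophobic contact counts: per-lipid lipid–lipid and lipid–protein CC
  contacts at the inclusive 1 nm cutoff, intra-lipid pairs excluded,
  computed with periodic KD-trees and checked against a brute-force
  double loop;
* protein-centered maps and radial shells: per-lipid values binned by xy
  displacement from the protein COM (empty bins stay undefined, the
  color zero is the membrane-only mean) or pooled into annular shells
  (cumulative optional) and compared with a protein-free reference by
  Welch's t-test on decorrelated samples, with the p < 0.001 / p < 0.01
  annotation tiers.

## Protein descriptors

* gate angle θ_α2: angle between the helix axis (two Cα atoms) and the
  oriented normal of a three-Cα plane; the normal's sign is fixed once
  from a reference structure so ensembles share a convention;
* cross-ensemble per-residue RMSD: the t⁻² double sum over frame pairs,
  computed in O(t) via E‖a−b‖² = E‖a‖² + E‖b‖² − 2⟨a⟩·⟨b⟩.  For unequal
  ensemble lengths we normalize by t_A·t_B (an extension of the
  equal-length definition);
* RMSF: per-atom fluctuation about the time-mean position of aligned
  frames;
* cavity volume: frames are superposed on a fixed Cα reference, a cavity
  region is detected once as the voxels (0.08 nm spacing by default)
  inside the Cα convex hull shrunk by a 0.14 nm probe radius that are
  free of protein heavy atoms (per-element vdW radii: C 0.17, N 0.155,
  O 0.152, S 0.18 nm) in at least 20% of reference frames (inclusive),
  and each frame's unoccluded volume of that region is reported.  Lipid
  atoms never occlude, so the volume includes space occupied by a bound
  lipid.  The grid origin snaps to a spacing multiple so volumes are
  reproducible.  The envelope is hull-based rather than
  alpha-sphere-based, so volumes are comparable to, but not
  bit-identical with, pocket-tracking tools.

## Free-energy estimation

**Well-tempered metadynamics bookkeeping.**  Hills from all walkers form
one time-ordered ledger (ties broken by walker id) feeding one shared
bias; heights temper as h = h0·exp(−V(c)/((γb−1)kBT)) with h0 = 2.5
kJ/mol and bias factor γb = 30 by default.  Half-harmonic walls (spring
500 kJ/mol) bound the first CV and are part of the applied bias.
Steered (moving-restraint) segments deposit no hills and are excluded
from estimation through explicit per-frame masks carried on the CV
series — never inferred downstream.

**Time-independent reweighting.**  Frame weights are
w(t) ∝ exp([V(s_t,t) − c(t)]/kBT), where V is the accumulated bias
(tabulated on the output grid) plus walls, and the offset

    c(t) = (1/β)[ln ∫e^{βγV/(γ−1)} ds − ln ∫e^{βV/(γ−1)} ds]

is evaluated on the biased-CV grid at every deposition and linearly
interpolated between depositions.  The weighted 2D histogram gives
ΔF = −kBT ln p, normalized to min 0; undefined bins stay NaN.  Errors
come from two contiguous time blocks (block count configurable; two
matches the common two-independent-blocks error convention).

**Scaled-time diagnostic.**  The same c(t) defines a scaled time
exp(c(t)/kBT); at quasi-steady state the log–log slope against
simulation time approaches γb − 1.  The diagnostic fits the asymptotic
regime (second half of the history by default), requires at least two
decades of hills, and flags the fit unreliable when R² < 0.99 or the
slope drifts between fit-window halves.

**WHAM.**  Standard self-consistent iteration over binned window
histograms to |Δf| < 10⁻⁸ kJ/mol, with a connectivity check that names
the gap between non-overlapping windows.  Errors again from contiguous
sample blocks per window.

**Marginalization and barriers.**  ΔF(x) = −kBT ln Σ_y e^{−ΔF(x,y)/kBT}Δy
over defined bins (errors propagate as the Boltzmann-weighted mean —
an approximation adequate for block errors of this size).  The
desorption barrier is the maximum of the min-0 1D profile inside a CV
window (default −2 < r_LxS < 3 on the transport coordinate; the toy
validation uses the analogous window bracketing its single barrier).

**Statistics.**  Flyvbjerg–Petersen blocking (pairwise halving; plateau
= first level whose successor stops increasing within its own error;
n_eff = variance ratio), contiguous-block standard errors, and Welch's
unequal-variance t-test (scipy backend; Welch–Satterthwaite dof; the
doubly-degenerate zero-variance cases return p = 1 for equal and p = 0
for unequal means).

## Synthetic ground truth

**Toy samplers.**  Overdamped Langevin (Euler–Maruyama) dynamics act
directly on CV-space coordinates of analytic potentials — a harmonic
well, a quartic double well B((x/a)²−1)² with exact barrier B, and a 2D
variant adding ½k_y y² + c·x·y with weak coupling (k_y = 10, c = 0.5, so
the y-marginal shifts the x landscape by ≤ 0.013 kJ/mol).  Biasing the
sampler's own coordinates replaces biasing molecular coordinates; this
validates every estimator while keeping molecular dynamics out of scope.
Quadrature ground truth (`analytic_fes`) uses per-bin composite Simpson
Boltzmann averages, matching what histogram estimators converge to.

Numerical choices: timestep 0.005 ps, friction 1 kJ/mol·ps/nm²
(stability requires dt < 2ζ/k for the stiffest curvature encountered).
The *biased* samplers (umbrella windows, metadynamics walkers) apply a
Metropolis accept/reject step to each Euler–Maruyama proposal (MALA), so
their stationary law is exact at finite timestep; the unbiased sampler
defaults to plain Euler–Maruyama, whose O(dt) stationary bias is part of
what the Boltzmann-inversion sanity check quantifies.  Seeds: one master
seed; walker/window streams derive as seed + index.

**Toy protocols.**  The umbrella protocol uses 20 equally spaced windows
across the double well, 52 000 steps per window with the leading 20/52
discarded (matching the 20 ns / 52 ns discard convention of the
atomistic protocol it scales down), leaving 32 000
samples per window.  The window spring is 100 kJ/mol per unit²: umbrella
windows must be stiffer than the largest negative potential curvature
(|U″(0)| = 4B = 60 kJ/mol at B = 15) or barrier-top windows become
bimodal with divergent correlation times; the atomistic protocol's
40 kJ/mol corresponds to its own, much wider CV scale.  The metadynamics
protocol mirrors the source scaled down: 2 walkers, hills every 100
steps with σ = 0.1 per CV (sized to the toy CV scale), γb = 30, walls at
the toy axis ends, 4×10⁵ steps per walker with the first half discarded.
These lengths were chosen by doubling until the reweighted surface's
deviation from quadrature stopped improving; the convergence diagnostic
runs on a 1D toy, which reaches the well-tempered asymptotic regime
within that budget (the 2D system does not — its offset growth is still
near-linear, a known slow approach, and its diagnostic slope would
under-read).

**Membrane fixtures.**  A two-leaflet square-lattice bilayer of
multi-bead lipids: phosphate bead, anchor bead, two 14-bead hydrophobic
tails (lattice constant 0.8 nm ⇒ 0.64 nm² per lipid; phosphate planes
±1.9 nm ⇒ 3.8 nm thickness — realistic fluid-phase POPC values), with
optional headgroup z jitter and per-lipid tail tilt.  Solvent slabs are
auto-sized so an extracted lipid cannot contact the opposite leaflet
through the periodic boundary.  Optional extras: a rigid hydrophobic
"disruptor" pseudo-protein whose neighborhood lipids have k tail-end
beads displaced out of contact range (parked on a sparse grid, spacing
above the cutoff), and a tagged lipid posed inserted, partially
extracted, or desorbed at a chosen height.  Every planted quantity —
areas, thickness, per-tail cosines, per-residue depths, per-lipid
contact counts from an independent brute-force double loop — is recorded
in a machine-checkable ledger.

What the fixtures do **not** emulate: lipid chemistry and force-field
energetics, tail conformational disorder (tails are straight bead
chains), undulations, solvent, and any real protein structure.  Passing
descriptor tests therefore demonstrates the correctness of the
*computations* (geometry, periodicity, counting, averaging), not the
realism of values on experimental membranes.  Likewise the contact
density of the bead lipids differs from atomistic lipids, so the
absolute r_LxS scale of fixtures (inserted ≈ 8, desorbed < 0) brackets
but does not reproduce atomistic values.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* Cavity envelope is convex-hull-based; deeply non-convex surface
  pockets outside the hull are not considered interior.
* The marginalized profile's error propagation is a weighted mean, not a
  full covariance treatment.
* Multi-walker metadynamics assumes all walkers share one bias and one
  temperature; no replica exchange, no kinetics.
* The 2D toy's scaled-time diagnostic needs substantially longer runs
  than its free-energy estimates do; use the 1D toy for diagnostic
  validation.
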