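# lipidfes

Analysis toolkit for free-energy studies of protein-mediated lipid
transfer between membranes: the collective variables that track a lipid
leaving a bilayer for a transfer protein's hydrophobic cavity, the
membrane and protein descriptors used to interpret that process, and the
free-energy estimators that turn biased simulations into ΔF profiles —
all validated on synthetic systems with exact ground truth.

It is written for simulators analyzing enhanced-sampling trajectories of
lipid extraction (e.g. ceramide-1-phosphate hand-off to its transfer
protein CPTP) and for anyone who needs well-tested implementations of
these estimators.

## What it computes

**Collective variables** (`lipidfes.cv`)

* the passive-transport reaction coordinate

  r_LxS = α₁·min(d_CC) + α₂·n_CC + α₀,  α₁ = −2.247 nm⁻¹,
  α₂ = 0.004828, α₀ = 0.6014,

  over the hydrophobic carbon–carbon distances between a tagged lipid
  and its closest leaflet, with the differentiable soft-min (γ = 200 nm)
  and the rational switching contact count (d₀ = 1 nm, r₀ = 0.025 nm);
* the fraction of native lipid–protein contacts
  Q = N⁻¹ Σ [1+exp(β(r_ij − λ r_ij⁰))]⁻¹ (β = 50 nm⁻¹, λ = 1.8), with
  the reference-pair builder (7.8 Å hydrophobic / 5.5 Å polar cutoffs).

**Membrane descriptors** (`lipidfes.membrane`): insertion depth, tail
orientation cos θ_z, bilayer thickness, periodic-Voronoi area per lipid,
acyl order S_CC, hydrophobic contact counts n_CC and n_CC(lip–prot),
protein-centered spatial maps and radial-shell statistics with Welch
significance on decorrelated samples.

**Protein descriptors** (`lipidfes.protein`): gate-helix polar angle,
cross-ensemble per-residue Cα RMSD, RMSF, and grid-based hydrophobic
cavity volume (20%-unoccupancy region tracking).

**Free energies** (`lipidfes.fes`): multi-walker well-tempered
metadynamics bookkeeping (PLUMED-style HILLS/COLVAR I/O), the
time-independent reweighting estimator with its c(t) offset, 1D umbrella
WHAM, Boltzmann marginalization, desorption-barrier extraction
(ΔF_des = max over a CV window of the min-zeroed profile, in kJ/mol and
kcal/mol), Flyvbjerg–Petersen blocking, block standard errors and
Welch's t-test.

**Synthetic ground truth** (`lipidfes.synthetic`): bilayer/protein
fixtures with ledgered planted observables, and Langevin samplers on
analytic double-well potentials driven by the umbrella and metadynamics
protocols, with quadrature free energies as the oracle.

## Worked example: recover a planted barrier

```python
import numpy as np
from lipidfes import synthetic as syn, fes

pot = syn.ToyPotential(form="double_well_1d", barrier=10.0)   # planted 10 kJ/mol
lp = syn.LangevinParams(n_steps=52000, seed=1)
windows = syn.run_toy_umbrella(pot, np.linspace(-1.9, 1.9, 20),
                               spring=100.0, langevin=lp)
profile = fes.wham_1d(windows, temperature=310.0, edges=np.linspace(-2, 2, 101))
barrier = fes.barrier_height(profile, window=(-0.9, 0.9))
truth = syn.analytic_fes(pot, np.linspace(-2, 2, 101), 310.0)
print(f"recovered barrier: {barrier.value_kj:.2f} kJ/mol "
      f"({barrier.value_kcal:.2f} kcal/mol) at x = {barrier.location:.2f}")
print(f"block SE at the barrier: {profile.error[barrier.index]:.2f} kJ/mol")
print(f"quadrature truth:  {fes.barrier_height(truth, window=(-0.9, 0.9)).value_kj:.2f} kJ/mol")
```

prints

```
recovered barrier: 10.08 kJ/mol (2.41 kcal/mol) at x = 0.02
block SE at the barrier: 0.11 kJ/mol
quadrature truth:  9.97 kJ/mol
```

The 20 umbrella windows sample the double well, WHAM stitches them into
one ΔF(x) profile normalized to zero at its global minimum, and the
barrier is the profile maximum inside the window bracketing the single
barrier — recovered here within one block standard error of the planted
10 kJ/mol (the quadrature value 9.97 differs from 10 only through bin
averaging).

A command-line interface wraps the same workflow
(`lipidfes run --stages synth,cv,fes --outdir out` with an optional YAML
config; `lipidfes validate` prints a recovery pass/fail table).

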