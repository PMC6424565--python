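# Methods

## The model

`cdfit` implements correlation-driven flexible fitting: an atomic model is
refined into a cryo-EM density by adding a global biasing potential

    Vfit = k · (1 − c.c.),        c.c. = Σ_v ρexp(v)·ρsim(v) / √(Σ ρexp² · Σ ρsim²)

to the molecular force field, where ρsim is obtained by spreading every
fitted atom as an isotropic Gaussian of width σ onto the experimental map's
grid.  The correlation is a plain cosine similarity over *all* voxels — no
mean subtraction, no mask — so amplitudes, phases and negative densities
(which mark hydrophobic regions by convention) all inform the fit.  A
Pearson (mean-subtracted) variant exists behind a flag but is not the
default.  Forces are the exact analytic gradient of Vfit: differentiating
the Gaussian kernels through the correlation quotient yields a cross term
(pulling atoms toward experimental density) and a normalization term
(from Σρsim²), which is why an atom outside all experimental density still
feels a force.  Degenerate norms (below 1e-30) raise rather than silently
returning zero.

Two deliberate conventions:

* **Unnormalized kernel.**  The Gaussian carries no (2πσ²)^(−3/2)
  prefactor.  c.c. is scale-invariant, so the prefactor is unobservable;
  omitting it makes the semigroup identity (spreading at √(σ1²+σ2²) equals
  blurring the σ1 spread with a σ2 kernel, up to the analytic (σ1/σtot)³
  amplitude factor) cleanly testable.
* **Per-axis truncation.**  The kernel is cut at `cutoff_multiplier·σ`
  (default 4) independently on each axis — a box, not a sphere.  This makes
  spreading and its gradient exactly separable into three 1-D factors,
  giving linear-time evaluation in pure vectorized numpy; the largest
  neglected amplitude on an axis is e⁻⁸ ≈ 3.4·10⁻⁴, far below map noise.

## Units and grids

Maps live in Å (MRC/CCP4 file convention); models and dynamics in MD units
(nm, ps, amu, kJ/mol).  The conversion factor (10 Å/nm) is applied in
exactly one module (`units`).  The grid contract: `origin` is the physical
coordinate of the **center** of voxel (0,0,0) and position(i,j,k) =
origin + (i,j,k)·voxel_size, exactly.  Axis-permuted files are
canonicalized on read (x fastest in memory); anisotropic voxels are
supported, non-orthorhombic cells rejected.  Trimming uses half-open voxel
boxes and shifts the origin so physical coordinates never move; trimmed
maps are re-origined, not zero-padded.  Resampling is trilinear over the
same physical box.

## The refinement protocol

Refinement is controlled by three time courses (σ, k, T) and runs in two
stages, with time quoted in "toy picoseconds": the standard wall-clock
protocols quoted in ns map 1:1 onto ps (a single configurable factor), preserving
every internal ratio.

1. **Half-map training.**  σ starts at 0.6 nm (a deliberately blurred ρsim,
   so the model adapts globally before locally) and k starts low; after a
   hold of 3/50 of the stage both ramp linearly to (σstop, kstop).  σstop
   comes from scanning 0.6→0.1 nm in 0.01 nm steps against the target map
   and taking the correlation argmax (ties to the larger, smoother σ).
   Only ρsim is ever resampled; the experimental map is used at full
   resolution throughout.  Temperature variants: 100 K/50 units,
   150 K/30, 200 K/20 — warmer variants sample faster but tolerate noisy
   maps less well.  Every 5 units the current model is stripped (waters,
   ions, hydrogens; atoms outside the fit mask stay excluded), spread at
   σstop, and compared to the training and validation half-maps by FSC.
2. **Full-map annealing.**  σ and k are held at their stop values (k is
   never increased once the validation map is out of play), the
   temperature is spiked to 300 K within 1 unit (500 K/3 units variant
   available) and cooled back linearly over the rest of the 15-unit
   annealing phase — the cooling shape is our choice, as only its duration
   is prescribed — followed by 5 units at base temperature.  The final
   model is the unweighted coordinate average over those last 5 units
   (optionally after superposing snapshots, off by default because the map
   frame anchors the model).

**Overfitting detection.**  Overfitting inflates agreement with the
training half-map specifically, so the detector scores the one-sided mean
gap `mean(max(0, FSC_train − FSC_val))` over shells up to the half-map
nominal resolution, flagging above 0.05 (both configurable).  A flagged
final checkpoint makes the report recommend the latest unflagged snapshot,
and stage 2 proceeds from it; remediation is advisory-and-deterministic
rather than an automatic re-run, to keep runs auditable.  Without a
validation map the run downgrades to full-map-only mode with a warning,
and `select_k_sweep` provides the alternative: independent refinements
over a k range, tabulating final correlation, FSC_avg and bond/angle RMS
deviations, then selecting the smallest k within 1% of the best
correlation whose geometry stays within bounds.  An energy-ratio
diagnostic Vfit/(Vfit+|Vff|) is reported alongside; the selection rule
itself is the operational criterion because it is directly testable.

**FSC conventions.**  Shells are |q| in physical units (Å⁻¹), one
frequency voxel of the largest box extent wide; the DC term is excluded;
the value is the real part of the normalized cross-spectrum, and empty
shells are skipped with a warning.  Resolution is the first downward
crossing of 0.143, linearly interpolated between shells; a curve that
never crosses reports Nyquist with a flag.  FSC_avg integrates the curve
(trapezoid) over s ∈ [1/100 Å⁻¹, 1/r] and divides by the interval, so a
constant curve returns its constant.  No soft-edge masking is applied
before FSC (a hook exists, default off).

## The toy engine

The full MD force field is out of scope; the engine supplies the minimal
ingredients the protocol actually exercises: harmonic bonds, harmonic
angles, harmonic torsions, and a soft-core repulsion ε(1−r/r_min)² between
pairs that are not 1-2 or 1-3 neighbors.  Torsions matter more than their
size suggests: without them a locally mirrored chain is isoenergetic with
the true one and blurred densities barely distinguish the two, so
refinement happily converges to scrambled-handedness structures —
chirality is exactly what torsions encode in real force fields.
Integration is Langevin dynamics with BAOAB splitting (one force
evaluation per step), friction 10 ps⁻¹, velocities starting at rest: exact
at T = 0, ergodic for these system sizes, and bitwise reproducible per
seed.  The minimizer is steepest descent with an adaptive step (accepted
steps grow 1.2×, rejected halve).  There is no pressure coupling (no
solvent, so pressure is undefined) and no constraints or virtual sites;
the 2 fs-equivalent step is stable because the toy springs are soft.  The
only coupling surface between engine and potentials is the force-provider
contract (coords in → energy + forces out, `set_time` hook for
schedules); the density potential and the toy force field are
interchangeable plug-ins under it, and an external engine could implement
the same contract.

## Synthetic data and study conditions

The fixture generator stands in for EMDB depositions.  Standard
conditions, chosen once: a 20-bead Cα-like polymer (helix with exact
0.38 nm bonds, 0.15 nm rise and 100°/residue twist, or a self-avoiding
random walk), uniform 12 amu beads, uniform spreading weights; a 32³ map
at 2 Å voxels centered on the polymer; ground truth spread at
σ_true = 0.2 nm (the typical σstop scale); half-maps = truth plus
independent noise at 0.1·RMS(truth) by default; the full map is the
half-map average (a real full map is an independent reconstruction — a
known simplification).  Three noise models: voxelwise white Gaussian
(default), low-pass-filtered ("colored"), and "blob" — spurious Gaussian
features at σ_true scattered around the molecule.  Real half-map noise is
colored and frequency-dependent; white noise suffices to exercise FSC
decay.  For overfitting *positive controls* the blob mode is the
informative one: a 20-bead model has no side-chain-like soft degrees of
freedom and simply cannot chase voxel-level noise, but it readily abandons
true density for artifact blobs at feature scale — which is also what
reconstruction artifacts look like to a refinement.  The overfitting
demonstration therefore uses blob noise at 0.4·RMS, where a moderate force
constant stays clean and an oversized one (30×) gets flagged.

**Force-constant scale.**  The standard k values (0.5–5×10⁵ kJ/mol) drive
systems of ~10⁴–10⁵ atoms; what transfers across system sizes is the
balance between Vfit and the force field, not the absolute number.  On the
20-bead fixture that balance lands at k_stop = 1×10⁴ kJ/mol
(`TOY_K_STOP`): the k sweep shows 10³ too weak to hold the structure
through annealing and 10⁵ distorting geometry, with the sweep's own
selection rule picking the optimum.  `default_protocol` keeps the
standard ramp shape and starts k at k_stop/10, the standard starting
ratio.

**Perturbations.**  "thermal-like" displaces beads by a chain-correlated
random field rescaled to the requested RMSD exactly; "domain-hinge"
rigidly rotates the second half of the chain about the midpoint, solving
the rotation angle by bisection to match the RMSD (bond lengths inside
each block preserved exactly).

## What the tests do and do not show

Recovery of the generating structure from 0.6 nm RMSD (3·σstop) with
final RMSD < 0.05 nm and c.c. > 0.99, the flagged/unflagged overfitting
contrast, and σstop recovery on the standard scan grid are all
demonstrated on this fixture.  They validate the machinery — gradients,
schedules, cross-validation, bookkeeping — under controlled conditions.
They do not demonstrate refinement quality on real maps: the toy has no
side chains, no solvent, no B-factor heterogeneity, its noise is
synthetic, and its energy landscape is far smoother than a real
force field's.  Stereochemical outlier *detection* is likewise out of
scope: `analysis_stats` consumes externally produced outlier flags and
computes the per-type propensity P(out|aa) = n_aa/N_aa (with its Bayes
factorization reported for completeness); merged pre/post statistics
concatenate counts.

## Numerical choices

* Spreading warns when σ falls below one voxel (undersampled ρsim) — the
  σ scan's lower end routinely triggers this on coarse toy grids.
* Correlation denominators < 1e-30 raise; FSC clips per-shell values into
  [−1, 1] against rounding.
* The σ-scan argmax breaks ties toward larger σ; the k sweep breaks ties
  toward smaller k (smallest adequate bias).
* Dihedral forces skip collinear quadruples (torsion undefined, no
  restoring force at measure-zero configurations).
* Problem sizes: 32³ maps, 20 beads, 70 time units (35,000 steps) for the
  variant-(i) protocol — a refinement takes ~2 minutes on one core, which
  is the design point for the whole test pyramid.
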