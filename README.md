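# cdfit

Correlation-driven flexible fitting of atomic models into cryo-EM density
maps, with half-map FSC cross-validation — as a desk-scale Python library
and CLI.

## The problem

Cryo-EM delivers density maps from near-atomic to subnanometer resolution;
turning a distant starting model into an accurate atomic interpretation of
such a map is the refinement problem.  Non-MD refiners need restraint
stacks and manual intervention to stay stereochemically sane; naive
MD-based fitting gets trapped in rugged high-resolution densities or
overfits noise.  The approach implemented here drives molecular dynamics
with a *global, soft* map term: a biasing potential

    Vfit = k · (1 − c.c.),
    c.c. = Σ_v ρexp(v) ρsim(v) / √(Σ_v ρexp(v)² · Σ_v ρsim(v)²),

where ρsim is the model spread onto the map grid as Gaussians of width σ.
Three parameters vary over the run: σ (effective resolution of ρsim,
ramped from blurred to sharp so the model adapts globally before locally),
k (the weight of the map term, ramped up), and the temperature (simulated
annealing to settle local detail).  Refinement first trains against one
half-map while cross-validating against the other via Fourier shell
correlation — a diverging FSC_train/FSC_val pair flags overfitting — then
finishes on the full map with annealing, and reports the coordinate
average of the final window as the refined model.

The library contains every ingredient as an importable, tested unit: map
I/O on the MRC/CCP4 grid contract, Gaussian density simulation with exact
analytic correlation forces, FSC/resolution/FSC_avg, a minimal bonded
force field + Langevin (BAOAB) engine behind a force-provider contract, the
staged protocol with k-sweep selection, a synthetic fixture generator
(polymers, ground-truth maps, half-map pairs, perturbations), and
validation statistics (Kabsch RMSD, per-residue outlier propensity
P(out|aa) = n_aa/N_aa).  See `docs/methods.md` for the science and the
design choices.

## A worked example

```bash
python examples/04_full_refinement.py
```

builds the standard synthetic system — a 20-bead polymer, a ground-truth
map at σ = 0.2 nm, half-maps — displaces the model 0.6 nm RMSD from the
truth and runs the variant-(iii) protocol.  It prints:

```
starting RMSD from truth: 0.600 nm
sigma_stop from scan: 0.20 nm
final RMSD to truth:  0.0129 nm
final correlation:    0.9973
verdict:              no overfitting
Vfit/(Vfit+|Vff|):    0.61
cross-validation divergence per checkpoint: ['0.000', '0.000', '0.000', '0.000']
```

The σ scan recovers the generating width (0.20 nm) from the map alone; the
staged refinement pulls the model from 0.6 nm error back to ~0.01 nm with
map-model correlation > 0.99; the train/validation FSC gap stays far below
the 0.05 flagging threshold, so the fit is not an artifact of chasing the
training half-map.  `examples/05_overfitting_detection.py` shows the
converse: against artifact-dominated half-maps, a 30× oversized force
constant trips the detector and the report recommends rolling back to the
latest clean snapshot.

The same operations are exposed as a CLI:

```bash
cdfit fixture -o fix/ --seed 1
cdfit scan-sigma fix/model.pdb fix/full.mrc --lo 0.1 --hi 0.6 --step 0.01
cdfit refine fix/model.pdb --train fix/half1.mrc --val fix/half2.mrc \
      --full fix/full.mrc --topology fix/topology.json \
      --sigma-stop 0.2 --k-stop 1e4 --weight-mode uniform -o out/
cdfit simulate-map out/final.pdb --like fix/full.mrc --sigma 0.2 \
      --weight-mode uniform -o out/final_sim.mrc
cdfit fsc out/final_sim.mrc fix/full.mrc -o fsc.csv
```

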