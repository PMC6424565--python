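"""End-to-end refinement of a perturbed polymer into its half-maps.

Generates the standard fixture (polymer, half-maps, full map), displaces the
model 0.6 nm from the truth, and runs the staged protocol: σ/k ramps against
the training half-map with FSC cross-validation, then full-map annealing and
final-model averaging.  Takes a couple of minutes.
"""

import warnings

import numpy as np

from cdfit import default_protocol, run_refinement, scan_sigma, superpose_rmsd
from cdfit.fixtures import (
    TOY_K_STOP,
    FixtureSpec,
    make_ground_truth_maps,
    make_toy_polymer,
    perturb_model,
)

spec = FixtureSpec(noise_sd=0.0)
model, topo = make_toy_polymer(spec)
full, half1, half2, truth = make_ground_truth_maps(model, spec)
start = perturb_model(model, 0.6, seed=11)
print(f"starting RMSD from truth: "
      f"{superpose_rmsd(start, model, align=False).rmsd:.3f} nm")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sigma_stop = scan_sigma(model, full, 0.10, 0.60, 0.01,
                            weight_mode="uniform").sigma_stop
print(f"sigma_stop from scan: {sigma_stop:.2f} nm")

config = default_protocol(sigma_stop, TOY_K_STOP, variant="200K/20", seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_refinement(start, topo, half1, half2, full, config)

final_rmsd = superpose_rmsd(report.final_model, model, align=False).rmsd
print(f"final RMSD to truth:  {final_rmsd:.4f} nm")
print(f"final correlation:    {report.trajectory.cc[-1]:.4f}")
print(f"verdict:              {report.verdict}")
print(f"Vfit/(Vfit+|Vff|):    {report.energy_ratio:.2f}")
print("cross-validation divergence per checkpoint:",
      [f"{r.divergence:.3f}" for r in report.crossval_records])
# A successful run ends within ~0.05 nm of the generating structure with
# cc > 0.99 and no train/val divergence — the refinement recovered the truth
# without overfitting the training half-map.
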