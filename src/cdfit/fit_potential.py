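"""The correlation-driven biasing potential.

The agreement between the experimental map ρexp and the simulated map ρsim
is measured by the real-space correlation coefficient

    c.c. = Σ_v ρexp(v)·ρsim(v) / sqrt(Σ_v ρexp(v)² · Σ_v ρsim(v)²)

taken over *all* voxels with no mean subtraction and no mask, so negative
densities contribute with their sign and the full map information is used.
The biasing potential is

    Vfit = k · (1 − c.c.)

with k in kJ/mol setting the weight of the density term relative to the
molecular force field.  Forces are the exact analytic negative gradient of
Vfit with respect to the fitted atoms' coordinates, obtained by
differentiating the Gaussian kernels through the correlation quotient: both
the ρexp·ρsim cross term and the Σρsim² normalization term contribute, so an
atom can feel a force even where the experimental density vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_model import AtomicModel, SpreadParams, spread_atoms, spread_inner_gradients
from .map_io import DensityMap, require_same_grid
from .units import ANGSTROM_PER_NM

__all__ = ["FitState", "correlation", "fit_energy_forces", "DensityFitPotential"]

#: Denominators below this are treated as degenerate rather than rounded to 0.
_NORM_EPS = 1e-30


@dataclass
class FitState:
    """Snapshot of the biasing potential at one protocol instant."""

    k: float
    sigma: float
    cc: float
    energy: float
    forces: np.ndarray

    def __post_init__(self):
        if abs(self.cc) > 1 + 1e-9:
            raise ValueError(f"|cc| = {abs(self.cc)} exceeds 1")
        expected = self.k * (1.0 - self.cc)
        if abs(self.energy - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("energy inconsistent with k·(1 − cc)")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite forces")


def correlation(a: DensityMap, b: DensityMap, mean_subtract: bool = False) -> float:
    """Real-space correlation coefficient between two maps on the same grid.

    By default this is the plain cosine similarity over all voxels (no mean
    subtraction); ``mean_subtract=True`` gives the Pearson variant.
    """
    require_same_grid(a, b)
    av = a.values.ravel()
    bv = b.values.ravel()
    if mean_subtract:
        av = av - av.mean()
        bv = bv - bv.mean()
    denom2 = float(av @ av) * float(bv @ bv)
    if denom2 < _NORM_EPS:
        raise ValueError("correlation undefined: a map has (near-)zero norm")
    return float(av @ bv) / np.sqrt(denom2)


def fit_energy_forces(
    model: AtomicModel, exp_map: DensityMap, k: float, params: SpreadParams
) -> FitState:
    """Evaluate Vfit = k(1 − c.c.) and its exact per-atom forces.

    Forces (kJ mol⁻¹ nm⁻¹) act only on fit-masked atoms and push the model
    toward higher correlation with ``exp_map``; ``k = 0`` gives zero energy
    and zero forces while still reporting the current c.c.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    a = exp_map.values
    Saa = float(np.vdot(a, a))
    if Saa < _NORM_EPS:
        raise ValueError("experimental map has (near-)zero norm")

    if k == 0.0:
        sim = spread_atoms(model, exp_map, params)
        cc = correlation(exp_map, sim)
        return FitState(
            k=0.0, sigma=params.sigma, cc=cc, energy=0.0,
            forces=np.zeros_like(model.coords),
        )

    sim, dSab, dSbb = spread_inner_gradients(model, exp_map, params, a)
    b = sim.values
    Sbb = float(np.vdot(b, b))
    Sab = float(np.vdot(a, b))
    if Saa * Sbb < _NORM_EPS:
        raise ValueError("simulated map has (near-)zero norm")
    norm = np.sqrt(Saa * Sbb)
    cc = Sab / norm
    # chain rule through the quotient; gradients arrive per Å, convert to per nm
    dcc = dSab / norm - (cc / (2.0 * Sbb)) * dSbb
    forces = k * dcc * ANGSTROM_PER_NM
    forces[~model.fit_mask] = 0.0
    return FitState(
        k=k, sigma=params.sigma, cc=cc, energy=k * (1.0 - cc), forces=forces
    )


class DensityFitPotential:
    """Force provider wrapping ``fit_energy_forces`` for the toy engine.

    ``k`` and ``sigma`` may be retargeted between evaluations (the protocol
    drives them along their schedules via :meth:`set_time`).  The last
    evaluated correlation coefficient is kept for bookkeeping.
    """

    def __init__(
        self,
        exp_map: DensityMap,
        sigma: float,
        k: float,
        cutoff_multiplier: float = 4.0,
        weight_mode: str = "atomic_number",
        k_schedule=None,
        sigma_schedule=None,
    ):
        self.exp_map = exp_map
        self.sigma = float(sigma)
        self.k = float(k)
        self.cutoff_multiplier = cutoff_multiplier
        self.weight_mode = weight_mode
        self.k_schedule = k_schedule
        self.sigma_schedule = sigma_schedule
        self.last_cc = np.nan

    def set_time(self, t: float) -> None:
        if self.k_schedule is not None:
            self.k = float(self.k_schedule.value(t))
        if self.sigma_schedule is not None:
            self.sigma = float(self.sigma_schedule.value(t))

    def params(self) -> SpreadParams:
        return SpreadParams(
            sigma=self.sigma,
            cutoff_multiplier=self.cutoff_multiplier,
            weight_mode=self.weight_mode,
        )

    def energy_forces(self, model: AtomicModel, coords: np.ndarray):
        state = fit_energy_forces(
            model.with_coords(coords), self.exp_map, self.k, self.params()
        )
        self.last_cc = state.cc
        return state.energy, state.forces
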