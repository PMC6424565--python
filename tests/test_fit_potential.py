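"""Correlation coefficient, Vfit energy and analytic biasing forces."""

import numpy as np
import pytest

from cdfit.density_model import AtomicModel, SpreadParams, spread_atoms
from cdfit.fit_potential import FitState, correlation, fit_energy_forces
from cdfit.fixtures import perturb_model
from cdfit.map_io import DensityMap
from cdfit.units import ANGSTROM_PER_NM


def cube_map(n=32, voxel=2.0):
    dims = np.array([n, n, n])
    return DensityMap(np.zeros(tuple(dims)), voxel, -(dims - 1) / 2 * voxel)


@pytest.fixture
def displaced(polymer, maps):
    model, _ = polymer
    return perturb_model(model, 0.3, seed=1)


class TestCorrelation:
    def test_self_correlation(self, random_map):
        assert correlation(random_map, random_map) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self, random_map):
        neg = DensityMap(-random_map.values, random_map.voxel_size, random_map.origin)
        assert correlation(random_map, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_cosine(self):
        # a = [1, 0], b = [1, 1] on a 2×1×1-like grid → 1/√2
        a = DensityMap(np.array([1.0, 0.0]).reshape(2, 1, 1).repeat(2, 1).repeat(2, 2),
                       1.0, 0.0)
        b = DensityMap(np.ones((2, 2, 2)), 1.0, 0.0)
        assert correlation(a, b) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_scale_invariance(self, random_map):
        scaled = DensityMap(
            7.3 * random_map.values, random_map.voxel_size, random_map.origin
        )
        other = DensityMap(
            np.roll(random_map.values, 3, axis=0),
            random_map.voxel_size,
            random_map.origin,
        )
        assert correlation(scaled, other) == pytest.approx(
            correlation(random_map, other), abs=1e-12
        )

    def test_grid_mismatch_rejected(self, random_map):
        other = DensityMap(
            random_map.values, random_map.voxel_size * 2, random_map.origin
        )
        with pytest.raises(ValueError, match="grid mismatch"):
            correlation(random_map, other)

    def test_zero_norm_rejected(self, random_map):
        zero = random_map.empty_like()
        with pytest.raises(ValueError, match="zero norm"):
            correlation(random_map, zero)

    def test_pearson_variant_removes_offset(self, random_map):
        offset = DensityMap(
            random_map.values + 100.0, random_map.voxel_size, random_map.origin
        )
        assert correlation(offset, random_map, mean_subtract=True) == pytest.approx(
            correlation(random_map, random_map, mean_subtract=True), abs=1e-9
        )


class TestFitEnergyForces:
    def test_noiseless_self_map_is_stationary(self, polymer, maps, uniform_params):
        model, _ = polymer
        k = 1e5
        state = fit_energy_forces(model, maps["truth"], k, uniform_params)
        assert state.cc == pytest.approx(1.0, abs=1e-9)
        assert state.energy == pytest.approx(0.0, abs=1e-6)
        assert np.abs(state.forces).max() < 1e-6 * k  # per nm

    def test_zero_k(self, displaced, maps, uniform_params):
        state = fit_energy_forces(displaced, maps["truth"], 0.0, uniform_params)
        assert state.energy == 0.0
        assert not state.forces.any()
        assert state.cc < 1.0

    def test_forces_scale_linearly_with_k(self, displaced, maps, uniform_params):
        s1 = fit_energy_forces(displaced, maps["truth"], 1e4, uniform_params)
        s2 = fit_energy_forces(displaced, maps["truth"], 3e4, uniform_params)
        np.testing.assert_allclose(s2.forces, 3.0 * s1.forces, rtol=1e-12)
        assert s2.energy == pytest.approx(3.0 * s1.energy, rel=1e-12)

    def test_masked_atoms_feel_no_force(self, displaced, maps, uniform_params):
        m = displaced.copy()
        m.fit_mask = m.fit_mask.copy()
        m.fit_mask[::3] = False
        state = fit_energy_forces(m, maps["truth"], 1e5, uniform_params)
        assert not state.forces[::3].any()
        assert state.forces[1::3].any()

    def test_finite_difference_oracle(self, displaced, maps, uniform_params):
        """Analytic forces vs central differences of the energy, 20 atoms."""
        k = 1e5
        state = fit_energy_forces(displaced, maps["truth"], k, uniform_params)
        h = 1e-5  # nm
        fmax = np.abs(state.forces).max()
        worst = 0.0
        for i in range(displaced.n_atoms):
            for ax in range(3):
                cp = displaced.coords.copy()
                cp[i, ax] += h
                ep = fit_energy_forces(
                    displaced.with_coords(cp), maps["truth"], k, uniform_params
                ).energy
                cm = displaced.coords.copy()
                cm[i, ax] -= h
                em = fit_energy_forces(
                    displaced.with_coords(cm), maps["truth"], k, uniform_params
                ).energy
                fd = -(ep - em) / (2 * h)
                worst = max(worst, abs(fd - state.forces[i, ax]) / fmax)
        assert worst < 1e-4

    def test_brute_force_untruncated_oracle(self, uniform_params):
        """Truncated separable kernel vs a plain double loop over atoms×voxels."""
        rng = np.random.default_rng(3)
        model = AtomicModel(coords=rng.uniform(-0.4, 0.4, (5, 3)))
        template = cube_map(12, 2.0)
        exp_vals = rng.standard_normal(template.dims)
        exp_map = DensityMap(exp_vals, template.voxel_size, template.origin)
        k, sigma = 1e4, 0.25
        params = SpreadParams(sigma, weight_mode="uniform", cutoff_multiplier=8.0)
        state = fit_energy_forces(model, exp_map, k, params)

        # oracle: untruncated sums, gradients by explicit kernel derivative
        axes = template.axes()
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pos = np.stack([X, Y, Z], axis=-1) / ANGSTROM_PER_NM  # nm
        sim = np.zeros(template.dims)
        for c in model.coords:
            d2 = ((pos - c) ** 2).sum(-1)
            sim += np.exp(-d2 / (2 * sigma**2))
        Saa = (exp_vals**2).sum()
        Sbb = (sim**2).sum()
        Sab = (exp_vals * sim).sum()
        cc = Sab / np.sqrt(Saa * Sbb)
        forces = np.zeros((5, 3))
        for idx, c in enumerate(model.coords):
            d2 = ((pos - c) ** 2).sum(-1)
            kern = np.exp(-d2 / (2 * sigma**2))
            grad = kern[..., None] * (pos - c) / sigma**2  # d kern / d atom pos
            dSab = (exp_vals[..., None] * grad).sum((0, 1, 2))
            dSbb = 2 * (sim[..., None] * grad).sum((0, 1, 2))
            forces[idx] = k * (dSab / np.sqrt(Saa * Sbb) - cc / (2 * Sbb) * dSbb)
        assert state.cc == pytest.approx(cc, rel=1e-6)
        np.testing.assert_allclose(state.forces, forces, rtol=1e-3, atol=1e-3 * np.abs(forces).max())

    def test_descent_direction(self, displaced, maps, uniform_params):
        """A small step along the force lowers Vfit (conservative field)."""
        k = 1e5
        state = fit_energy_forces(displaced, maps["truth"], k, uniform_params)
        step = 1e-6 * state.forces / np.abs(state.forces).max()
        moved = fit_energy_forces(
            displaced.with_coords(displaced.coords + step),
            maps["truth"], k, uniform_params,
        )
        assert moved.energy < state.energy

    def test_normalization_term_forces_outside_density(self, uniform_params):
        """An atom far from all experimental density still feels the
        sim-map normalization force in general."""
        template = cube_map(24, 2.0)
        exp_vals = np.zeros(template.dims)
        exp_vals[4:8, 4:8, 4:8] = 1.0
        exp_map = DensityMap(exp_vals, template.voxel_size, template.origin)
        # two atoms: one inside the density, one in an empty corner
        model = AtomicModel(coords=[[-1.5, -1.5, -1.5], [1.8, 1.8, 1.8]])
        state = fit_energy_forces(model, exp_map, 1e5, uniform_params)
        assert np.abs(state.forces[1]).max() > 0.0

    def test_state_invariants_enforced(self):
        with pytest.raises(ValueError, match="cc"):
            FitState(k=1.0, sigma=0.2, cc=1.5, energy=-0.5, forces=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="energy"):
            FitState(k=2.0, sigma=0.2, cc=0.5, energy=0.0, forces=np.zeros((1, 3)))
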