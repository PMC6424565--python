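"""Synthetic test systems: toy polymers, ground-truth maps and half-map pairs.

Real refinements start from EMDB reconstructions and deposited models; the
desk-scale analogue generated here is a Cα-like polymer (helix or
self-avoiding random walk, one bead per residue at 0.38 nm spacing), a
ground-truth map produced by Gaussian spreading at a known σ, and two
half-maps made by adding independent noise realizations to the truth.  The
"full" map is the half-map average.  Noise is voxelwise i.i.d. Gaussian by
default; a low-pass (colored) mode and a feature-scale "blob" artifact mode
(used for overfitting positive controls) are also available.  Everything is
deterministic per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .density_model import AtomicModel, SpreadParams, spread_atoms
from .map_io import DensityMap
from .toy_engine import ToyTopology

__all__ = [
    "FixtureSpec",
    "TOY_K_STOP",
    "make_toy_polymer",
    "make_ground_truth_maps",
    "perturb_model",
]


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic system.

    Defaults describe the standard desk-scale fixture: a 20-bead helical
    polymer (b0 = 0.38 nm, the Cα–Cα spacing), a 32³ map at 2 Å voxels,
    ground-truth width σ = 0.2 nm (the typical σstop scale), and half-map
    noise at 10% of the truth RMS.
    """

    n_atoms: int = 20
    b0: float = 0.38                 # nm
    geometry: str = "helix"          # "helix" | "random-walk"
    map_dims: tuple = (32, 32, 32)
    voxel_size: float = 2.0          # Å
    sigma_true: float = 0.2          # nm
    noise_sd: float = 0.1            # fraction of RMS(truth)
    noise_mode: str = "white"        # "white" | "lowpass" | "blob"
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 3:
            raise ValueError("n_atoms must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.geometry not in ("helix", "random-walk"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.noise_mode not in ("white", "lowpass", "blob"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    def template_map(self) -> DensityMap:
        """Zero map centered on the origin (where polymers are centered)."""
        dims = np.asarray(self.map_dims)
        voxel = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,))
        origin = -(dims - 1) / 2.0 * voxel
        return DensityMap(np.zeros(tuple(dims)), voxel, origin)


# Toy bonded parameters: soft enough for a 2 fs-equivalent step, stiff
# enough that geometry is meaningful. Uniform 12 amu beads. Torsions keep
# the chain's handedness — without them a mirrored helix is isoenergetic.
_KB_BOND = 1000.0   # kJ/mol/nm²
_K_THETA = 100.0    # kJ/mol/rad²
_K_PHI = 50.0       # kJ/mol/rad²
_REPULSION = (0.7, 10.0, 0.35)

#: Standard biasing force constant for the toy system (kJ/mol).  The large-
#: system protocols quote k ≈ 0.5–5×10⁵ kJ/mol for ~10⁵-atom complexes; what
#: transfers across system sizes is the balance between Vfit and the force
#: field, not the absolute number.  1×10⁴ sits at the optimum of the k sweep
#: on the standard 20-bead fixture: strong enough to hold the fit through
#: annealing, weak enough not to crush the toy geometry.
TOY_K_STOP = 1.0e4


def _helix_coords(n: int, b0: float) -> np.ndarray:
    """Helical Cα trace with exact bond length b0 (rise 0.15 nm, 100°/res)."""
    rise = 0.15
    twist = np.deg2rad(100.0)
    radius = np.sqrt(b0 * b0 - rise * rise) / (2.0 * np.sin(twist / 2.0))
    i = np.arange(n)
    coords = np.stack(
        [radius * np.cos(i * twist), radius * np.sin(i * twist), i * rise], axis=1
    )
    return coords - coords.mean(axis=0)


def _random_walk_coords(n: int, b0: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding chain with fixed bond length and gentle bending."""
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    min_sep = 1.2 * _REPULSION[2]
    for _ in range(1, n):
        for _attempt in range(200):
            # bend by a limited random angle so the chain stays polymer-like
            kick = rng.normal(scale=0.5, size=3)
            new_dir = direction + kick
            new_dir /= np.linalg.norm(new_dir)
            candidate = coords[-1] + b0 * new_dir
            prior = np.array(coords[:-1]) if len(coords) > 1 else np.empty((0, 3))
            if prior.size == 0 or np.min(
                np.linalg.norm(prior - candidate, axis=1)
            ) > min_sep:
                break
        else:
            raise RuntimeError("self-avoiding walk failed to place an atom")
        coords.append(candidate)
        direction = new_dir
    coords = np.array(coords)
    return coords - coords.mean(axis=0)


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cos_t = np.clip(
        (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
    )
    return float(np.arccos(cos_t))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return float(
        np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2)
    )


def make_toy_polymer(spec: FixtureSpec):
    """Build a connected polymer at bonded equilibrium plus its topology.

    Bond b0 and the per-angle θ0 are set to the constructed geometry, so the
    fresh polymer has (near-)zero toy energy and forces.  Deterministic per
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "helix":
        coords = _helix_coords(spec.n_atoms, spec.b0)
    else:
        coords = _random_walk_coords(spec.n_atoms, spec.b0, rng)
    model = AtomicModel(coords=coords, masses=np.full(spec.n_atoms, 12.0))
    bonds = [(i, i + 1, spec.b0, _KB_BOND) for i in range(spec.n_atoms - 1)]
    angles = [
        (i, i + 1, i + 2, _angle(coords[i], coords[i + 1], coords[i + 2]), _K_THETA)
        for i in range(spec.n_atoms - 2)
    ]
    dihedrals = [
        (
            i, i + 1, i + 2, i + 3,
            _dihedral(coords[i], coords[i + 1], coords[i + 2], coords[i + 3]),
            _K_PHI,
        )
        for i in range(spec.n_atoms - 3)
    ]
    topo = ToyTopology(
        bonds=bonds, angles=angles, dihedrals=dihedrals, repulsion=_REPULSION
    )
    return model, topo


def toy_spread_params(spec: FixtureSpec, sigma: float | None = None) -> SpreadParams:
    """Uniform-weight spreading parameters for toy (chemistry-free) systems."""
    return SpreadParams(
        sigma=spec.sigma_true if sigma is None else sigma, weight_mode="uniform"
    )


def _noise_field(truth: DensityMap, model: AtomicModel, spec, sd, rng):
    """One noise realization, scaled to standard deviation ``sd``.

    "white": voxelwise i.i.d. Gaussian.  "lowpass": the same smoothed to
    ~1.5 voxels (colored).  "blob": spurious Gaussian features at the same
    width as real ones, scattered around the molecule — the feature-scale
    artifacts that reconstruction noise presents to a refinement, and the
    kind of noise a small model can actually overfit.
    """
    if spec.noise_mode == "blob":
        lo = model.coords.min(axis=0) - 0.5
        hi = model.coords.max(axis=0) + 0.5
        n_blobs = max(10, 2 * model.n_atoms)
        decoys = AtomicModel(
            coords=rng.uniform(lo, hi, size=(n_blobs, 3)),
            weights=rng.uniform(0.5, 1.5, size=n_blobs),
        )
        field = spread_atoms(
            decoys, truth, SpreadParams(spec.sigma_true, weight_mode="uniform")
        ).values
        field = field - field.mean()
        return sd * field / field.std()
    noise = rng.standard_normal(truth.dims)
    if spec.noise_mode == "lowpass":
        noise = gaussian_filter(noise, sigma=1.5, mode="wrap")
        noise /= noise.std()
    return sd * noise


def make_ground_truth_maps(model: AtomicModel, spec: FixtureSpec):
    """(full, half1, half2, truth) maps for a model under the fixture spec.

    truth = ρsim(model, σ_true); half_i = truth + independent noise with
    sd = noise_sd · RMS(truth); full = (half1 + half2)/2 (noise averaged
    down by √2).  Noise seeds derive from ``spec.seed``.
    """
    template = spec.template_map()
    truth = spread_atoms(model, template, toy_spread_params(spec))
    truth.label = "truth"
    rms = np.sqrt(np.mean(truth.values**2))
    sd = spec.noise_sd * rms
    child_seeds = np.random.SeedSequence(spec.seed).spawn(2)
    halves = []
    for tag, ss in zip(("half1", "half2"), child_seeds):
        rng = np.random.default_rng(ss)
        values = truth.values + _noise_field(truth, model, spec, sd, rng)
        halves.append(
            DensityMap(values, truth.voxel_size.copy(), truth.origin.copy(), label=tag)
        )
    half1, half2 = halves
    full = DensityMap(
        (half1.values + half2.values) / 2.0,
        truth.voxel_size.copy(),
        truth.origin.copy(),
        label="full",
    )
    return full, half1, half2, truth


def perturb_model(
    model: AtomicModel, magnitude: float, mode: str = "thermal-like", seed: int = 0
) -> AtomicModel:
    """Displace a model so its RMSD from the input equals ``magnitude`` (nm).

    "thermal-like" applies a chain-correlated random displacement rescaled
    to the exact RMSD; "domain-hinge" rigidly rotates the second half of the
    chain about a random axis through the chain midpoint (bond lengths
    inside each block are preserved exactly), solving for the rotation angle
    that reproduces the requested RMSD.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return model.copy()
    rng = np.random.default_rng(seed)
    coords = model.coords.copy()
    n = len(coords)

    if mode == "thermal-like":
        disp = rng.standard_normal((n, 3))
        disp = gaussian_filter1d(disp, sigma=2.0, axis=0, mode="nearest")
        rmsd = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        disp *= magnitude / rmsd
        return model.with_coords(coords + disp)

    if mode == "domain-hinge":
        mid = n // 2
        pivot = coords[mid]
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)

        def rmsd_at(angle):
            rotated = _rotate_block(coords, mid, pivot, axis, angle)
            return np.sqrt(np.mean(np.sum((rotated - coords) ** 2, axis=1)))

        hi = np.pi
        if rmsd_at(hi) < magnitude:
            warnings.warn(
                f"domain-hinge saturates at RMSD {rmsd_at(hi):.3f} nm "
                f"< requested {magnitude} nm; using 180° rotation",
                stacklevel=2,
            )
            return model.with_coords(_rotate_block(coords, mid, pivot, axis, hi))
        lo = 0.0
        for _ in range(60):
            midangle = 0.5 * (lo + hi)
            if rmsd_at(midangle) < magnitude:
                lo = midangle
            else:
                hi = midangle
        return model.with_coords(_rotate_block(coords, mid, pivot, axis, hi))

    raise ValueError(f"unknown perturbation mode {mode!r}")


def _rotate_block(coords, start, pivot, axis, angle):
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(angle * axis)
    out = coords.copy()
    out[start:] = rot.apply(coords[start:] - pivot) + pivot
    return out
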