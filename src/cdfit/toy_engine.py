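"""A minimal bonded force field and integrator standing in for the MD engine.

The refinement machinery only needs something that (a) produces forces from
a model geometry and (b) integrates them at a target temperature.  This
module provides a deliberately small version of both: harmonic bonds and
angles plus a soft-core repulsion between non-bonded pairs, a steepest
descent minimizer, and Langevin (BAOAB) dynamics with a piecewise-linear
temperature schedule.  It is exact at T = 0 and ergodic for the small
polymers the fixtures generate.

The coupling surface between the engine and any potential is the force
provider contract: an object with

    energy_forces(model, coords) -> (energy kJ/mol, forces (N,3) kJ/mol/nm)

and an optional ``set_time(t)`` hook for time-dependent parameters.  The
density fitting potential and the toy force field are interchangeable
plug-ins under this contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density_model import AtomicModel
from .units import KB

__all__ = [
    "ToyTopology",
    "ThermostatSchedule",
    "Trajectory",
    "ToyForceField",
    "toy_energy_forces",
    "minimize",
    "integrate_langevin",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when dynamics or minimization blows up (NaN energy/forces)."""

    def __init__(self, message, step=None, max_force=None):
        super().__init__(message)
        self.step = step
        self.max_force = max_force


@dataclass
class ToyTopology:
    """Bonded terms of the toy force field.

    bonds : list of (i, j, b0 nm, kb kJ/mol/nm²) harmonic bonds.
    angles : list of (i, j, k, θ0 rad, kθ kJ/mol/rad²); j is the apex.
    dihedrals : list of (i, j, k, l, φ0 rad, kφ kJ/mol/rad²), harmonic in the
        wrapped torsion deviation.  Torsions are what give a chain geometry
        its handedness; without them a mirrored conformation is isoenergetic.
    repulsion : (cutoff nm, ε kJ/mol, r_min nm) soft-core term
        ε·(1 − r/r_min)² for r < r_min between pairs that are neither bonded
        nor 1–3 neighbors.
    """

    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    repulsion: tuple = (0.7, 10.0, 0.35)

    def __post_init__(self):
        for i, j, b0, kb in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if b0 <= 0:
                raise ValueError(f"bond ({i},{j}) has b0 = {b0} <= 0")
        cutoff, eps, rmin = self.repulsion
        if cutoff <= 0 or rmin <= 0:
            raise ValueError("repulsion cutoff and r_min must be > 0")

    def validate_indices(self, n_atoms: int) -> None:
        for i, j, *_ in self.bonds:
            if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                raise ValueError(f"bond index ({i},{j}) out of range for {n_atoms} atoms")
        for i, j, k, *_ in self.angles:
            if not all(0 <= a < n_atoms for a in (i, j, k)):
                raise ValueError(
                    f"angle index ({i},{j},{k}) out of range for {n_atoms} atoms"
                )
        for i, j, k, l, *_ in self.dihedrals:
            if not all(0 <= a < n_atoms for a in (i, j, k, l)):
                raise ValueError(
                    f"dihedral index ({i},{j},{k},{l}) out of range for {n_atoms} atoms"
                )

    def excluded_pairs(self) -> set:
        """1–2 and 1–3 pairs excluded from the repulsion term."""
        excl = set()
        for i, j, *_ in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for i, _, k, *_ in self.angles:
            excl.add((min(i, k), max(i, k)))
        return excl


@dataclass
class ThermostatSchedule:
    """Piecewise-linear target temperature vs time, plus Langevin parameters."""

    times: np.ndarray
    temps: np.ndarray
    friction: float = 10.0     # ps⁻¹
    seed: int = 0

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=np.float64))
        self.temps = np.atleast_1d(np.asarray(self.temps, dtype=np.float64))
        if len(self.times) != len(self.temps):
            raise ValueError("times and temps length mismatch")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if np.any(self.temps < 0):
            raise ValueError("temperatures must be >= 0")

    def temperature(self, t: float) -> float:
        return float(np.interp(t, self.times, self.temps))

    @classmethod
    def constant(cls, temp: float, friction: float = 10.0, seed: int = 0):
        return cls(times=[0.0], temps=[temp], friction=friction, seed=seed)


@dataclass
class Trajectory:
    """Per-snapshot record of a dynamics run."""

    times: list = field(default_factory=list)
    coords: list = field(default_factory=list)
    cc: list = field(default_factory=list)
    vfit: list = field(default_factory=list)
    vff: list = field(default_factory=list)
    temps: list = field(default_factory=list)
    stride: int = 1

    def append(self, time, coords, cc, vfit, vff, temp):
        self.times.append(float(time))
        self.coords.append(np.array(coords, copy=True))
        self.cc.append(float(cc))
        self.vfit.append(float(vfit))
        self.vff.append(float(vff))
        self.temps.append(float(temp))

    def extend(self, other: "Trajectory"):
        self.times += other.times
        self.coords += other.coords
        self.cc += other.cc
        self.vfit += other.vfit
        self.vff += other.vff
        self.temps += other.temps

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def last_coords(self) -> np.ndarray:
        return self.coords[-1]

    def window(self, duration: float) -> list:
        """Indices of snapshots within ``duration`` of the final time."""
        t_end = self.times[-1]
        return [i for i, t in enumerate(self.times) if t >= t_end - duration - 1e-9]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "cc": self.cc,
                "vfit": self.vfit,
                "vff": self.vff,
                "T_target": self.temps,
            }
        )


def toy_energy_forces(model: AtomicModel, topo: ToyTopology):
    """Energy and exact analytic forces of the toy bonded force field."""
    coords = model.coords
    topo.validate_indices(model.n_atoms)
    energy = 0.0
    forces = np.zeros_like(coords)

    for i, j, b0, kb in topo.bonds:
        d = coords[i] - coords[j]
        r = np.linalg.norm(d)
        delta = r - b0
        energy += 0.5 * kb * delta * delta
        if r > 1e-12:
            f = -kb * delta * d / r
            forces[i] += f
            forces[j] -= f

    for i, j, k, th0, kth in topo.angles:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.linalg.norm(u)
        nv = np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            continue
        uh, vh = u / nu, v / nv
        cos_t = np.clip(uh @ vh, -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        dE = kth * (theta - th0)
        energy += 0.5 * kth * (theta - th0) ** 2
        dth_di = (cos_t * uh - vh) / (nu * sin_t)
        dth_dk = (cos_t * vh - uh) / (nv * sin_t)
        forces[i] -= dE * dth_di
        forces[k] -= dE * dth_dk
        forces[j] += dE * (dth_di + dth_dk)

    for i, j, k, l, phi0, kphi in topo.dihedrals:
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        sq1, sq2 = n1 @ n1, n2 @ n2
        nb2 = np.linalg.norm(b2)
        if sq1 < 1e-18 or sq2 < 1e-18 or nb2 < 1e-12:
            continue  # collinear: torsion undefined, no restoring force
        phi = np.arctan2(np.cross(n1, n2) @ (b2 / nb2), n1 @ n2)
        dphi = (phi - phi0 + np.pi) % (2.0 * np.pi) - np.pi
        energy += 0.5 * kphi * dphi * dphi
        dE = kphi * dphi
        # standard analytic torsion gradient
        dphi_di = -(nb2 / sq1) * n1
        dphi_dl = (nb2 / sq2) * n2
        c12 = (b1 @ b2) / (nb2 * nb2)
        c32 = (b3 @ b2) / (nb2 * nb2)
        dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
        dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
        forces[i] -= dE * dphi_di
        forces[j] -= dE * dphi_dj
        forces[k] -= dE * dphi_dk
        forces[l] -= dE * dphi_dl

    cutoff, eps, rmin = topo.repulsion
    if eps > 0:
        excl = topo.excluded_pairs()
        n = model.n_atoms
        for i in range(n):
            d = coords[i + 1 :] - coords[i]
            r = np.linalg.norm(d, axis=1)
            for jj in np.flatnonzero(r < rmin):
                j = i + 1 + jj
                if (i, j) in excl:
                    continue
                rij = r[jj]
                if rij < 1e-12:
                    continue
                x = 1.0 - rij / rmin
                energy += eps * x * x
                f = (2.0 * eps / rmin) * x * d[jj] / rij
                forces[i] -= f
                forces[j] += f

    return energy, forces


class ToyForceField:
    """Force provider wrapping :func:`toy_energy_forces`."""

    def __init__(self, topology: ToyTopology):
        self.topology = topology

    def set_time(self, t: float) -> None:
        pass

    def energy_forces(self, model: AtomicModel, coords: np.ndarray):
        return toy_energy_forces(model.with_coords(coords), self.topology)


def _total(potentials, model, coords):
    e_tot = 0.0
    f_tot = np.zeros_like(coords)
    for p in potentials:
        e, f = p.energy_forces(model, coords)
        e_tot += e
        f_tot += f
    return e_tot, f_tot


def minimize(
    model: AtomicModel,
    potentials,
    max_steps: int = 2000,
    tol: float = 1.0,
    step0: float = 0.01,
) -> AtomicModel:
    """Steepest descent with adaptive step; stops at max|force| < tol.

    The trial displacement is ``h · F / max|F|`` (largest component moves by
    ``h`` nm); accepted steps (energy decreased) grow h by 1.2, rejected ones
    shrink it by half.  Total energy is non-increasing across accepted steps.
    """
    if not potentials:
        raise ValueError("need at least one force provider")
    coords = model.coords.copy()
    energy, forces = _total(potentials, model, coords)
    if not np.isfinite(energy):
        raise IntegrationError("NaN energy at minimization start", step=0)
    h = step0
    for step in range(max_steps):
        fmax = np.max(np.abs(forces))
        if fmax < tol:
            break
        trial = coords + h * forces / fmax
        e_trial, f_trial = _total(potentials, model, trial)
        if not np.isfinite(e_trial):
            raise IntegrationError(
                f"NaN energy at minimization step {step}", step=step, max_force=fmax
            )
        if e_trial < energy:
            coords, energy, forces = trial, e_trial, f_trial
            h *= 1.2
        else:
            h *= 0.5
            if h < 1e-10:
                break
    return model.with_coords(coords)


def _bookkeep(potentials, model, coords):
    """(cc, vfit, vff, total forces) with energies split by provider kind."""
    vfit = vff = 0.0
    cc = np.nan
    f_tot = np.zeros_like(coords)
    for p in potentials:
        e, f = p.energy_forces(model, coords)
        f_tot += f
        if hasattr(p, "last_cc"):
            vfit += e
            cc = p.last_cc
        else:
            vff += e
    return cc, vfit, vff, f_tot


def integrate_langevin(
    model: AtomicModel,
    potentials,
    thermostat: ThermostatSchedule,
    dt: float,
    n_steps: int,
    t0: float = 0.0,
    snapshot_stride: int = 10,
    rng: np.random.Generator | None = None,
    velocities: np.ndarray | None = None,
    record_initial: bool = True,
    trajectory: Trajectory | None = None,
):
    """Langevin (BAOAB) dynamics at the schedule's target temperature.

    Returns ``(trajectory, final_coords, final_velocities)``.  Identical
    seeds give bitwise-identical trajectories; at T = 0 with zero forces the
    coordinates never move (velocities start at rest).  Time-dependent
    providers receive ``set_time`` with the absolute time ``t0 + step·dt``
    before each force evaluation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # conservative stability estimate from the stiffest bond
    stiffest = 0.0
    for p in potentials:
        topo = getattr(p, "topology", None)
        if topo is not None:
            for _, _, _, kb in topo.bonds:
                stiffest = max(stiffest, kb)
    if stiffest > 0:
        omega = np.sqrt(2.0 * stiffest / np.min(model.masses))
        if dt > 0.1 * 2.0 * np.pi / omega:
            warnings.warn(
                f"dt = {dt} ps is large for the stiffest bond "
                f"(suggest < {0.1 * 2 * np.pi / omega:.4f} ps)",
                stacklevel=2,
            )
    if rng is None:
        rng = np.random.default_rng(thermostat.seed)
    gamma = thermostat.friction
    m = model.masses[:, None]
    coords = model.coords.copy()
    vel = np.zeros_like(coords) if velocities is None else velocities.copy()
    traj = trajectory if trajectory is not None else Trajectory(stride=snapshot_stride)

    t = t0
    for p in potentials:
        if hasattr(p, "set_time"):
            p.set_time(t)
    cc, vfit, vff, forces = _bookkeep(potentials, model, coords)
    if record_initial:
        traj.append(t, coords, cc, vfit, vff, thermostat.temperature(t))

    c1 = np.exp(-gamma * dt)
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * forces / m
        coords += 0.5 * dt * vel
        temp = thermostat.temperature(t + 0.5 * dt)
        c2 = np.sqrt(KB * temp * (1.0 - c1 * c1) / model.masses)[:, None]
        vel = c1 * vel + c2 * rng.standard_normal(coords.shape)
        coords += 0.5 * dt * vel
        t = t0 + step * dt
        for p in potentials:
            if hasattr(p, "set_time"):
                p.set_time(t)
        cc, vfit, vff, forces = _bookkeep(potentials, model, coords)
        vel += 0.5 * dt * forces / m
        if not (np.all(np.isfinite(coords)) and np.all(np.isfinite(forces))):
            raise IntegrationError(
                f"dynamics unstable at step {step} (t = {t:.4f} ps): "
                "non-finite coordinates or forces — reduce k or dt",
                step=step,
                max_force=float(np.nanmax(np.abs(forces))),
            )
        if step % snapshot_stride == 0 or step == n_steps:
            traj.append(t, coords, cc, vfit, vff, thermostat.temperature(t))
    return traj, coords, vel
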