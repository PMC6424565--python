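"""The staged refinement protocol: ramps, annealing, cross-validation.

A refinement runs in two stages:

1. **Half-map training** at a low constant temperature.  σ starts high
   (0.6 nm — a deliberately blurred ρsim so the model first adapts globally)
   and k starts low (a tenth of its target by default).  After a short hold
   both are ramped
   linearly to their targets (σstop from the correlation scan, kstop chosen
   by cross-validation), so resolution and map weight only ever tighten.
   Model-vs-train and model-vs-validation FSC curves are recorded at a fixed
   stride; a flagged train/val divergence at the end of the stage marks
   overfitting, in which case the report recommends (and stage 2 proceeds
   from) the latest unflagged snapshot.

2. **Full-map refinement with simulated annealing**: σ and k are held at
   their stop values, the temperature is spiked (300 K default, 500 K
   variant) and cooled back down; k is never increased further because there
   is no longer a validation map.  The final model is the unweighted
   coordinate average over the trailing window (5 time units).

Times are quoted in toy picoseconds; the standard wall-clock protocols in
ns map onto them 1:1 (1 ns → 1 ps), preserving every ratio (3:47
hold:ramp, 5-unit crossval stride, 15+5 annealing stage).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .density_model import AtomicModel, SpreadParams, spread_atoms
from .fit_potential import DensityFitPotential, correlation
from .fsc_validation import (
    CrossValidationRecord,
    compute_fsc,
    divergence,
    fsc_avg,
    model_to_map_for_fsc,
    resolution_at,
)
from .map_io import DensityMap, require_same_grid
from .toy_engine import (
    ThermostatSchedule,
    ToyForceField,
    ToyTopology,
    Trajectory,
    integrate_langevin,
)

__all__ = [
    "ParameterSchedule",
    "StageSpec",
    "ProtocolConfig",
    "RefinementReport",
    "default_protocol",
    "run_refinement",
    "select_k_sweep",
    "final_model",
]

SIGMA_START = 0.6      # nm
K_START = 0.5e5        # kJ/mol


@dataclass
class ParameterSchedule:
    """Piecewise-linear time course; evaluation clamps outside the nodes."""

    nodes: list                # [(time, value), ...] with ascending times
    units: str = ""            # "nm" | "kJ/mol" | "K"

    def __post_init__(self):
        times = [t for t, _ in self.nodes]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("schedule node times must be ascending")
        if not self.nodes:
            raise ValueError("schedule needs at least one node")

    def value(self, t: float) -> float:
        times = np.array([n[0] for n in self.nodes])
        vals = np.array([n[1] for n in self.nodes])
        return float(np.interp(t, times, vals))

    @property
    def final(self) -> float:
        return float(self.nodes[-1][1])


@dataclass
class StageSpec:
    name: str
    map_role: str              # "half1" | "full"
    duration: float            # time units (toy ps)
    crossval_stride: float | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"stage {self.name}: duration must be > 0")
        if self.map_role not in ("half1", "full"):
            raise ValueError(f"stage {self.name}: unknown map role {self.map_role!r}")


@dataclass
class ProtocolConfig:
    sigma_schedule: ParameterSchedule
    k_schedule: ParameterSchedule
    thermostat: ThermostatSchedule
    stages: list
    anneal: dict = field(default_factory=lambda: {"peak_K": 300.0, "heat": 1.0})
    final_window: float = 5.0
    seed: int = 0
    dt: float = 0.002                  # ps
    snapshot_interval: float = 0.5     # time units between stored snapshots
    weight_mode: str = "uniform"
    cutoff_multiplier: float = 4.0
    divergence_threshold: float = 0.05
    divergence_s_max: float | None = None   # Å⁻¹; None → half-map nominal resolution
    geometry_bond_rms_max: float = 0.02     # nm, k-sweep selection bound
    geometry_angle_rms_max: float = 0.2     # rad

    def __post_init__(self):
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        if self.sigma_schedule.nodes[0][1] < self.sigma_schedule.final:
            raise ValueError("sigma schedule must not increase (resolution only tightens)")

    @property
    def sigma_stop(self) -> float:
        return self.sigma_schedule.final

    @property
    def k_stop(self) -> float:
        return self.k_schedule.final

    def spread_params(self, sigma: float) -> SpreadParams:
        return SpreadParams(
            sigma=sigma,
            cutoff_multiplier=self.cutoff_multiplier,
            weight_mode=self.weight_mode,
        )

    def to_dict(self) -> dict:
        return {
            "sigma_schedule": self.sigma_schedule.nodes,
            "k_schedule": self.k_schedule.nodes,
            "thermostat": {
                "times": self.thermostat.times.tolist(),
                "temps": self.thermostat.temps.tolist(),
                "friction": self.thermostat.friction,
                "seed": self.thermostat.seed,
            },
            "stages": [
                [s.name, s.map_role, s.duration, s.crossval_stride]
                for s in self.stages
            ],
            "anneal": self.anneal,
            "final_window": self.final_window,
            "seed": self.seed,
            "dt": self.dt,
            "snapshot_interval": self.snapshot_interval,
            "weight_mode": self.weight_mode,
            "cutoff_multiplier": self.cutoff_multiplier,
            "divergence_threshold": self.divergence_threshold,
            "divergence_s_max": self.divergence_s_max,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RefinementReport:
    trajectory: Trajectory
    crossval_records: list
    final_model: AtomicModel
    sigma_stop: float
    k_stop: float
    overfitting_flagged: bool
    verdict: str
    recommended_time: float | None
    energy_ratio: float
    provenance: dict


_VARIANTS = {"100K/50": (100.0, 50.0), "150K/30": (150.0, 30.0), "200K/20": (200.0, 20.0)}


def default_protocol(
    sigma_stop: float,
    k_stop: float,
    variant: str = "100K/50",
    anneal_peak: float = 300.0,
    k_start: float | None = None,
    seed: int = 0,
    **overrides,
) -> ProtocolConfig:
    """The standard two-stage protocol for a chosen temperature incarnation.

    Variants: (i) 100 K for 50 units, (ii) 150 K for 30, (iii) 200 K for 20
    (higher temperatures sample faster but tolerate less noise).  σ holds at
    0.6 nm and k at ``k_start`` for the first 3/50 of the stage, then both
    ramp linearly to (σstop, kstop).  ``k_start`` defaults to k_stop/10,
    preserving the standard 0.5→5×10⁵ kJ/mol starting ratio across system
    sizes.  Stage 2 is 15 units of annealing (heat to ``anneal_peak`` within
    1 unit for the 300 K scheme, 3 units for 500 K, then a linear cool-down)
    plus 5 units at base temperature; σ and k stay constant there and the
    final model is averaged over the last 5.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}")
    if not (0 < sigma_stop <= SIGMA_START):
        raise ValueError(
            f"sigma_stop must be in (0, {SIGMA_START}] nm (resolution only increases), "
            f"got {sigma_stop}"
        )
    if k_stop <= 0:
        raise ValueError(f"k_stop must be > 0, got {k_stop}")
    if k_start is None:
        k_start = k_stop / 10.0
    if not (0 < k_start <= k_stop):
        raise ValueError(f"k_start must be in (0, k_stop], got {k_start}")
    base_T, stage1 = _VARIANTS[variant]
    hold = 3.0 * stage1 / 50.0
    heat = 3.0 if anneal_peak >= 500.0 else 1.0
    anneal, settle = 15.0, 5.0
    t1 = stage1
    t2 = stage1 + anneal + settle

    sigma_schedule = ParameterSchedule(
        [(0.0, SIGMA_START), (hold, SIGMA_START), (t1, sigma_stop)], units="nm"
    )
    k_schedule = ParameterSchedule(
        [(0.0, k_start), (hold, k_start), (t1, k_stop)], units="kJ/mol"
    )
    thermostat = ThermostatSchedule(
        times=[0.0, t1, t1 + heat, t1 + anneal, t2],
        temps=[base_T, base_T, anneal_peak, base_T, base_T],
        seed=seed,
    )
    stages = [
        StageSpec("half-map training", "half1", stage1, crossval_stride=5.0),
        StageSpec("full-map annealing", "full", anneal + settle, crossval_stride=None),
    ]
    return ProtocolConfig(
        sigma_schedule=sigma_schedule,
        k_schedule=k_schedule,
        thermostat=thermostat,
        stages=stages,
        anneal={"peak_K": anneal_peak, "heat": heat},
        final_window=settle,
        seed=seed,
        **overrides,
    )


def final_model(
    traj: Trajectory, window: float, base: AtomicModel | None = None,
    superpose: bool = False,
) -> AtomicModel | np.ndarray:
    """Unweighted coordinate average over the trailing ``window`` of a run.

    ``superpose=True`` aligns every snapshot to the last frame before
    averaging; off by default since the map frame anchors the model.
    Returns an :class:`AtomicModel` when ``base`` carries the metadata,
    otherwise the averaged coordinate array.
    """
    span = traj.times[-1] - traj.times[0]
    if window > span + 1e-9:
        raise ValueError(f"window {window} exceeds trajectory span {span}")
    idx = traj.window(window)
    frames = [traj.coords[i] for i in idx]
    if superpose:
        from .analysis_stats import superpose_rmsd

        ref = frames[-1]
        aligned = []
        for f in frames:
            res = superpose_rmsd(f, ref, align=True)
            aligned.append(f @ res.rotation.T + res.translation)
        frames = aligned
    mean = np.mean(frames, axis=0)
    return base.with_coords(mean) if base is not None else mean


def _crossval_record(
    model, coords, t, sigma_stop, train_map, val_map, config, s_max
) -> CrossValidationRecord:
    sim = model_to_map_for_fsc(
        model.with_coords(coords), train_map, sigma_stop,
        weight_mode=config.weight_mode,
    )
    train_curve = compute_fsc(sim, train_map)
    val_curve = compute_fsc(sim, val_map)
    score, flagged = divergence(
        train_curve, val_curve, s_max=s_max, threshold=config.divergence_threshold
    )
    return CrossValidationRecord(
        time=t, train=train_curve, val=val_curve, divergence=score, flagged=flagged
    )


def run_refinement(
    model: AtomicModel,
    topo: ToyTopology,
    train_map: DensityMap,
    val_map: DensityMap | None,
    full_map: DensityMap,
    config: ProtocolConfig,
) -> RefinementReport:
    """Execute the staged protocol and return the full refinement record.

    The caller is responsible for rigid pre-placement of the model in the
    map frame.  Without a validation map the half-map stage runs without
    cross-validation (full-map-only mode) and a warning is emitted.
    """
    require_same_grid(train_map, full_map)
    if val_map is not None:
        require_same_grid(train_map, val_map)
    else:
        warnings.warn(
            "no validation map: running without cross-validation "
            "(overfitting cannot be detected)",
            stacklevel=2,
        )
    sigma_stop, k_stop = config.sigma_stop, config.k_stop
    rng = np.random.default_rng(config.seed)
    snap_stride = max(1, int(round(config.snapshot_interval / config.dt)))
    traj = Trajectory(stride=snap_stride)

    s_max = config.divergence_s_max
    if s_max is None and val_map is not None:
        half_fsc = compute_fsc(train_map, val_map)
        s_max = resolution_at(half_fsc).crossing_freq

    ff = ToyForceField(topo)
    records: list[CrossValidationRecord] = []
    coords = model.coords.copy()
    vel = None
    t = 0.0

    stage1, stage2 = config.stages[0], config.stages[1] if len(config.stages) > 1 else None

    fit1 = DensityFitPotential(
        train_map,
        sigma=config.sigma_schedule.value(0.0),
        k=config.k_schedule.value(0.0),
        cutoff_multiplier=config.cutoff_multiplier,
        weight_mode=config.weight_mode,
        k_schedule=config.k_schedule,
        sigma_schedule=config.sigma_schedule,
    )
    stride_t = stage1.crossval_stride or stage1.duration
    n_segments = max(1, int(round(stage1.duration / stride_t)))
    seg_steps = int(round(stride_t / config.dt))
    for seg in range(n_segments):
        traj, coords, vel = integrate_langevin(
            model.with_coords(coords),
            [ff, fit1],
            config.thermostat,
            dt=config.dt,
            n_steps=seg_steps,
            t0=t,
            snapshot_stride=snap_stride,
            rng=rng,
            velocities=vel,
            record_initial=(seg == 0),
            trajectory=traj,
        )
        t += stride_t
        if val_map is not None:
            records.append(
                _crossval_record(
                    model, coords, t, sigma_stop, train_map, val_map, config, s_max
                )
            )

    flagged = bool(records) and records[-1].flagged
    recommended_time = None
    if flagged:
        clean = [r for r in records if not r.flagged]
        recommended_time = clean[-1].time if clean else traj.times[0]
        # roll back to the latest snapshot at/before the recommended time
        idx = max(i for i, tt in enumerate(traj.times) if tt <= recommended_time + 1e-9)
        coords = traj.coords[idx].copy()
        vel = None

    if stage2 is not None:
        fit2 = DensityFitPotential(
            full_map,
            sigma=sigma_stop,
            k=config.k_schedule.value(t),   # clamped: kstop, never increased further
            cutoff_multiplier=config.cutoff_multiplier,
            weight_mode=config.weight_mode,
        )
        n_steps = int(round(stage2.duration / config.dt))
        traj, coords, vel = integrate_langevin(
            model.with_coords(coords),
            [ff, fit2],
            config.thermostat,
            dt=config.dt,
            n_steps=n_steps,
            t0=t,
            snapshot_stride=snap_stride,
            rng=rng,
            velocities=vel,
            record_initial=False,
            trajectory=traj,
        )
        t += stage2.duration

    final = final_model(traj, config.final_window, base=model)
    idx = traj.window(config.final_window)
    vfit = np.array([traj.vfit[i] for i in idx])
    vff = np.array([traj.vff[i] for i in idx])
    denom = vfit + np.abs(vff)
    energy_ratio = float(np.mean(vfit / np.where(denom > 0, denom, np.inf)))
    verdict = (
        "no overfitting"
        if not flagged
        else "overfitting detected; earlier snapshot recommended"
    )
    if val_map is None:
        verdict = "not cross-validated (no validation map)"
    return RefinementReport(
        trajectory=traj,
        crossval_records=records,
        final_model=final,
        sigma_stop=sigma_stop,
        k_stop=k_stop,
        overfitting_flagged=flagged,
        verdict=verdict,
        recommended_time=recommended_time,
        energy_ratio=energy_ratio,
        provenance={"seed": config.seed, "config_hash": config.config_hash()},
    )


def _geometry_rms(coords: np.ndarray, topo: ToyTopology):
    """(bond RMS deviation nm, angle RMS deviation rad) from equilibrium."""
    bond_dev = []
    for i, j, b0, _ in topo.bonds:
        bond_dev.append(np.linalg.norm(coords[i] - coords[j]) - b0)
    ang_dev = []
    for i, j, k, th0, _ in topo.angles:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cos_t = np.clip(
            (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
        )
        ang_dev.append(np.arccos(cos_t) - th0)
    return (
        float(np.sqrt(np.mean(np.square(bond_dev)))) if bond_dev else 0.0,
        float(np.sqrt(np.mean(np.square(ang_dev)))) if ang_dev else 0.0,
    )


def select_k_sweep(
    model: AtomicModel,
    topo: ToyTopology,
    full_map: DensityMap,
    k_values,
    config: ProtocolConfig,
):
    """Full-map-only refinements over a range of force constants.

    The no-half-map path: one independent refinement per k, a per-k table of
    map-model agreement and toy-geometry diagnostics, and a selection rule —
    the smallest k whose final correlation is within 1% of the best while
    bond/angle RMS deviations stay below the configured bounds.

    Returns ``(best_report, table)`` where ``table`` is a pandas DataFrame.
    """
    import pandas as pd

    k_list = list(k_values)
    if not k_list:
        raise ValueError("empty k list")
    deduped = list(dict.fromkeys(k_list))
    if len(deduped) != len(k_list):
        warnings.warn("duplicate k values removed from sweep", stacklevel=2)
    k_list = deduped

    rows, reports = [], {}
    failures = []
    for k in k_list:
        cfg = _with_k_stop(config, k)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = run_refinement(model, topo, full_map, None, full_map, cfg)
        except Exception as exc:  # instability at extreme k is an expected outcome
            failures.append((k, exc))
            continue
        params = cfg.spread_params(cfg.sigma_stop)
        sim = spread_atoms(rep.final_model, full_map, params)
        cc = correlation(full_map, sim)
        curve = compute_fsc(sim, full_map)
        res = resolution_at(curve)
        try:
            favg = fsc_avg(curve, max(res.resolution, 1.0 / curve.freqs[-1] + 1e-9))
        except ValueError:
            favg = np.nan
        bond_rms, ang_rms = _geometry_rms(rep.final_model.coords, topo)
        rows.append(
            {"k": k, "cc": cc, "fsc_avg": favg,
             "bond_rms_nm": bond_rms, "angle_rms_rad": ang_rms}
        )
        reports[k] = rep
    if not rows:
        raise RuntimeError(
            f"all {len(k_list)} sweep refinements failed; last error: {failures[-1][1]}"
        )
    table = pd.DataFrame(rows)
    best_cc = table["cc"].max()
    ok = (
        (table["cc"] >= best_cc * 0.99)
        & (table["bond_rms_nm"] <= config.geometry_bond_rms_max)
        & (table["angle_rms_rad"] <= config.geometry_angle_rms_max)
    )
    candidates = table[ok] if ok.any() else table[table["cc"] >= best_cc * 0.99]
    selected_k = float(candidates["k"].min())
    table.attrs["selected_k"] = selected_k
    return reports[selected_k], table


def _with_k_stop(config: ProtocolConfig, k_stop: float) -> ProtocolConfig:
    nodes = list(config.k_schedule.nodes)
    new_nodes = nodes[:-1] + [(nodes[-1][0], k_stop)]
    return ProtocolConfig(
        sigma_schedule=config.sigma_schedule,
        k_schedule=ParameterSchedule(new_nodes, units="kJ/mol"),
        thermostat=config.thermostat,
        stages=config.stages,
        anneal=config.anneal,
        final_window=config.final_window,
        seed=config.seed,
        dt=config.dt,
        snapshot_interval=config.snapshot_interval,
        weight_mode=config.weight_mode,
        cutoff_multiplier=config.cutoff_multiplier,
        divergence_threshold=config.divergence_threshold,
        divergence_s_max=config.divergence_s_max,
        geometry_bond_rms_max=config.geometry_bond_rms_max,
        geometry_angle_rms_max=config.geometry_angle_rms_max,
    )
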