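"""Fourier shell correlation, resolution estimation and overfitting detection.

FSC between two maps a, b on the same grid:

    FSC(s) = Re Σ_{q ∈ shell s} F_a(q)·conj(F_b(q))
             / sqrt(Σ_{shell} |F_a(q)|² · Σ_{shell} |F_b(q)|²)

with shells of spatial frequency |q| (physical units, Å⁻¹, so anisotropic
voxels are handled correctly) of width 1/(N·Δ) where N·Δ is the largest box
extent.  The nominal resolution is the first downward crossing of the 0.143
threshold (linearly interpolated); FSC_avg is the mean of the curve over
s ∈ [1/100 Å⁻¹, 1/r].

Overfitting is detected by comparing the model-vs-training-map curve
(FSC_train) with the model-vs-validation-map curve (FSC_val): refinement
into noise inflates FSC_train specifically, so the detector scores the
one-sided mean gap mean(max(0, FSC_train − FSC_val)) over shells up to the
map's nominal resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density_model import AtomicModel, SpreadParams, spread_atoms
from .map_io import DensityMap, require_same_grid

__all__ = [
    "FSCCurve",
    "ResolutionEstimate",
    "CrossValidationRecord",
    "compute_fsc",
    "resolution_at",
    "fsc_avg",
    "divergence",
    "model_to_map_for_fsc",
]


@dataclass
class FSCCurve:
    """Shell-resolved correlation between two maps (DC term excluded)."""

    freqs: np.ndarray      # shell-center spatial frequencies, Å⁻¹, ascending
    values: np.ndarray     # FSC per shell, in [−1, 1]
    shell_width: float     # frequency bin width, Å⁻¹

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.freqs) != len(self.values):
            raise ValueError("freqs and values length mismatch")
        if len(self.freqs) and (np.any(np.diff(self.freqs) <= 0) or self.freqs[0] <= 0):
            raise ValueError("freqs must be positive and strictly ascending")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("|FSC| exceeds 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"freq_inv_angstrom": self.freqs, "fsc": self.values})


@dataclass
class ResolutionEstimate:
    """Resolution from a threshold crossing of an FSC curve."""

    resolution: float        # Å
    crossing_freq: float     # Å⁻¹
    crossed: bool            # False => curve never dropped below the threshold
    at_boundary: bool        # True => already below threshold in the first shell


@dataclass
class CrossValidationRecord:
    """Paired train/val FSC curves at one refinement checkpoint."""

    time: float
    train: FSCCurve
    val: FSCCurve
    divergence: float
    flagged: bool

    def __post_init__(self):
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if len(self.train.freqs) != len(self.val.freqs) or not np.allclose(
            self.train.freqs, self.val.freqs
        ):
            raise ValueError("train and val curves must share shells")


def compute_fsc(a: DensityMap, b: DensityMap) -> FSCCurve:
    """FSC between two maps on the same grid, shells by |q| in Å⁻¹."""
    require_same_grid(a, b)
    Fa = np.fft.fftn(a.values)
    Fb = np.fft.fftn(b.values)
    freqs_axes = [
        np.fft.fftfreq(a.dims[ax], d=a.voxel_size[ax]) for ax in range(3)
    ]
    qx, qy, qz = np.meshgrid(*freqs_axes, indexing="ij", sparse=True)
    q = np.sqrt(qx * qx + qy * qy + qz * qz)

    extent = np.array(a.dims) * a.voxel_size
    width = 1.0 / np.max(extent)            # one frequency voxel of the largest axis
    nyquist = 1.0 / (2.0 * np.max(a.voxel_size))
    n_shells = int(np.floor(nyquist / width + 0.5))

    shell = np.rint(q / width).astype(np.intp)
    cross = np.real(Fa * np.conj(Fb)).ravel()
    pa = (np.abs(Fa) ** 2).ravel()
    pb = (np.abs(Fb) ** 2).ravel()
    sh = shell.ravel()
    keep = sh <= n_shells
    num = np.bincount(sh[keep], weights=cross[keep], minlength=n_shells + 1)
    da = np.bincount(sh[keep], weights=pa[keep], minlength=n_shells + 1)
    db = np.bincount(sh[keep], weights=pb[keep], minlength=n_shells + 1)
    counts = np.bincount(sh[keep], minlength=n_shells + 1)

    freqs, values = [], []
    for s in range(1, n_shells + 1):        # shell 0 is the DC term — excluded
        if counts[s] == 0:
            warnings.warn(f"empty FSC shell at {s * width:.4f} Å⁻¹ skipped",
                          stacklevel=2)
            continue
        denom = np.sqrt(da[s] * db[s])
        if denom == 0:
            warnings.warn(
                f"zero-power FSC shell at {s * width:.4f} Å⁻¹ skipped", stacklevel=2
            )
            continue
        freqs.append(s * width)
        values.append(np.clip(num[s] / denom, -1.0, 1.0))
    return FSCCurve(np.array(freqs), np.array(values), shell_width=width)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> ResolutionEstimate:
    """Resolution r = 1/s* at the first downward crossing of ``threshold``.

    The crossing frequency is linearly interpolated between adjacent shells.
    A curve already below the threshold in its first shell reports that
    shell's frequency (boundary case); a curve that never drops below
    reports the last shell (Nyquist) with ``crossed=False``.
    """
    if not (-1 < threshold < 1):
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    if len(curve.freqs) == 0:
        raise ValueError("empty FSC curve")
    v, f = curve.values, curve.freqs
    if v[0] < threshold:
        return ResolutionEstimate(1.0 / f[0], f[0], crossed=True, at_boundary=True)
    for i in range(len(v) - 1):
        if v[i] >= threshold > v[i + 1]:
            s = f[i] + (f[i + 1] - f[i]) * (v[i] - threshold) / (v[i] - v[i + 1])
            return ResolutionEstimate(1.0 / s, s, crossed=True, at_boundary=False)
    return ResolutionEstimate(1.0 / f[-1], f[-1], crossed=False, at_boundary=False)


def fsc_avg(curve: FSCCurve, r: float, s_min: float = 0.01) -> float:
    """Mean FSC over s ∈ [1/100 Å⁻¹, 1/r] (trapezoidal, normalized).

    Dividing the integral by the interval length makes a constant curve
    return its constant, so FSC_avg is directly comparable across boxes.
    """
    s_max = 1.0 / r
    if s_max <= s_min:
        raise ValueError(
            f"resolution {r} Å gives 1/r = {s_max:.4f} <= {s_min} Å⁻¹: empty range"
        )
    if s_max > curve.freqs[-1] + curve.shell_width:
        raise ValueError(
            f"1/r = {s_max:.4f} Å⁻¹ beyond curve support ({curve.freqs[-1]:.4f})"
        )
    grid = np.unique(
        np.concatenate(
            [[s_min], curve.freqs[(curve.freqs > s_min) & (curve.freqs < s_max)],
             [s_max]]
        )
    )
    vals = np.interp(grid, curve.freqs, curve.values)
    return float(np.trapezoid(vals, grid) / (s_max - s_min))


def divergence(
    train: FSCCurve, val: FSCCurve, s_max: float, threshold: float = 0.05
) -> tuple[float, bool]:
    """One-sided train/val gap: mean over shells ≤ s_max of max(0, train − val).

    Returns ``(score, flagged)`` with ``flagged = score > threshold``.  The
    gap is one-sided because overfitting inflates FSC_train specifically.
    """
    if len(train.freqs) != len(val.freqs) or not np.allclose(train.freqs, val.freqs):
        raise ValueError("train and val curves must share shells")
    sel = train.freqs <= s_max
    if not np.any(sel):
        raise ValueError(f"no FSC shells at or below s_max = {s_max} Å⁻¹")
    gap = np.maximum(0.0, train.values[sel] - val.values[sel])
    score = float(gap.mean())
    return score, score > threshold


def strip_for_fsc(model: AtomicModel) -> AtomicModel:
    """Drop waters, ions and hydrogens before map comparison."""
    keep = ~model.is_water_or_ion() & ~model.is_hydrogen()
    if not np.any(keep):
        raise ValueError("model empty after stripping waters/ions/hydrogens")
    return model.select(keep)


def model_to_map_for_fsc(
    model: AtomicModel,
    template: DensityMap,
    sigma_stop: float,
    weight_mode: str = "atomic_number",
) -> DensityMap:
    """Simulated density of the stripped model at σstop on the template grid.

    Waters, ions and hydrogens are dropped first; atoms outside the fit mask
    (regions without experimental density) stay excluded from the comparison
    just as they were excluded from the fitting potential.
    """
    stripped = strip_for_fsc(model)
    params = SpreadParams(sigma=sigma_stop, weight_mode=weight_mode)
    return spread_atoms(stripped, template, params)
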