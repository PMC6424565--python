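"""Model validation statistics: superposition RMSD and outlier propensities.

The per-residue outlier propensity asks how likely a residue of a given
amino-acid type is to be a stereochemical (rotamer/Ramachandran) outlier.
Writing N_aa and n_aa for the counts of residues and outliers of one type,
and N_tot = ΣN_aa, n_tot = Σn_aa for the grand totals, Bayes' theorem gives

    P(out | aa) = P(aa | out) · P(out) / P(aa)
                = (n_aa/n_tot) · (n_tot/N_tot) / (N_aa/N_tot)
                = n_aa / N_aa

so the propensity is simply the outlier count scaled by the type's
occurrence in the sequence.  Outlier *detection* is upstream (MolProbity or
similar); this module consumes the flags and computes the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OutlierCounts",
    "SuperpositionResult",
    "outlier_propensity",
    "superpose_rmsd",
]


@dataclass
class OutlierCounts:
    """Residue and outlier counts per amino-acid type."""

    n_residues: dict     # type -> N_aa
    n_outliers: dict     # type -> n_aa

    def __post_init__(self):
        for aa, n_out in self.n_outliers.items():
            n_res = self.n_residues.get(aa, 0)
            if n_out < 0 or n_res < 0:
                raise ValueError(f"negative count for {aa}")
            if n_out > n_res:
                raise ValueError(
                    f"{aa}: {n_out} outliers exceed {n_res} residues"
                )

    @property
    def total_residues(self) -> int:
        return sum(self.n_residues.values())

    @property
    def total_outliers(self) -> int:
        return sum(self.n_outliers.values())

    @classmethod
    def from_flags(cls, residue_types, outlier_flags) -> "OutlierCounts":
        """Build counts from per-residue (type, is_outlier) records."""
        n_res: dict = {}
        n_out: dict = {}
        for aa, flag in zip(residue_types, outlier_flags):
            n_res[aa] = n_res.get(aa, 0) + 1
            n_out[aa] = n_out.get(aa, 0) + int(bool(flag))
        return cls(n_res, n_out)

    def merged(self, other: "OutlierCounts") -> "OutlierCounts":
        """Concatenate counts (e.g. pre-equilibration + post-refinement)."""
        n_res = dict(self.n_residues)
        n_out = dict(self.n_outliers)
        for aa, n in other.n_residues.items():
            n_res[aa] = n_res.get(aa, 0) + n
        for aa, n in other.n_outliers.items():
            n_out[aa] = n_out.get(aa, 0) + n
        return OutlierCounts(n_res, n_out)


def outlier_propensity(counts: OutlierCounts) -> pd.DataFrame:
    """Per-type P(out|aa) = n_aa/N_aa plus its Bayes factorization terms.

    Types with N_aa = 0 are undefined and omitted with a warning.  Columns:
    residue_type, N_aa, n_aa, propensity, p_aa_given_out, p_out, p_aa.
    """
    N_tot = counts.total_residues
    n_tot = counts.total_outliers
    rows = []
    for aa in sorted(counts.n_residues):
        N_aa = counts.n_residues[aa]
        n_aa = counts.n_outliers.get(aa, 0)
        if N_aa == 0:
            warnings.warn(f"residue type {aa} absent from sequence: "
                          "propensity undefined, omitted", stacklevel=2)
            continue
        rows.append(
            {
                "residue_type": aa,
                "N_aa": N_aa,
                "n_aa": n_aa,
                "propensity": n_aa / N_aa,
                "p_aa_given_out": n_aa / n_tot if n_tot else np.nan,
                "p_out": n_tot / N_tot if N_tot else np.nan,
                "p_aa": N_aa / N_tot if N_tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # proper rotation, det = +1
    translation: np.ndarray    # applied after rotation, same units as input
    rmsd: float
    units: str = "nm"
    selection: str = "all"

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _coords_of(x) -> np.ndarray:
    return np.asarray(x.coords if hasattr(x, "coords") else x, dtype=np.float64)


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation + translation mapping mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def superpose_rmsd(
    mobile,
    reference,
    align_sel=None,
    score_sel=None,
    align: bool = True,
    units: str = "nm",
) -> SuperpositionResult:
    """RMSD between two structures, with optional Kabsch superposition.

    ``align_sel`` selects the atoms used to fit the rigid transform (e.g. a
    single subunit); ``score_sel`` the atoms the RMSD is reported on (e.g.
    the whole complex) — they are independent.  ``align=False`` reports the
    raw coordinate RMSD with an identity transform.  Accepts
    :class:`AtomicModel` instances or plain (N, 3) arrays.
    """
    mob = _coords_of(mobile)
    ref = _coords_of(reference)
    if mob.shape != ref.shape:
        raise ValueError(f"selection mismatch: {mob.shape} vs {ref.shape}")
    align_sel = slice(None) if align_sel is None else np.asarray(align_sel)
    score_sel = slice(None) if score_sel is None else np.asarray(score_sel)

    if align:
        ma, ra = mob[align_sel], ref[align_sel]
        if len(ma) < 3:
            raise ValueError(f"need >= 3 atoms for alignment, got {len(ma)}")
        R, t = _kabsch(ma, ra)
    else:
        R, t = np.eye(3), np.zeros(3)
    moved = mob @ R.T + t
    diff = moved[score_sel] - ref[score_sel]
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, units=units,
        selection="custom" if score_sel is not None else "all",
    )
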