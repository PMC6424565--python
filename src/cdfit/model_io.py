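"""PDB input/output for atomic models (gemmi-backed).

PDB coordinates are in Å; :class:`~cdfit.density_model.AtomicModel` stores
nm, so conversion happens here at the boundary.  Trajectories are written as
multi-model PDB files.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .density_model import AtomicModel
from .units import ANGSTROM_PER_NM

__all__ = ["read_pdb", "write_pdb", "write_trajectory_pdb"]


def read_pdb(path) -> AtomicModel:
    """Read the first model of a PDB/mmCIF file into an AtomicModel."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    st.setup_entities()
    coords, elements, res_names, res_ids, chain_ids, masses = [], [], [], [], [], []
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                el = atom.element.name if atom.element else "C"
                elements.append(el)
                res_names.append(residue.name)
                res_ids.append(residue.seqid.num)
                chain_ids.append(chain.name)
                masses.append(atom.element.weight if atom.element else 12.0)
    if not coords:
        raise ValueError(f"{path}: structure contains no atoms")
    return AtomicModel(
        coords=np.array(coords) / ANGSTROM_PER_NM,
        elements=elements,
        res_names=res_names,
        res_ids=np.array(res_ids),
        chain_ids=chain_ids,
        masses=np.array(masses),
    )


def _to_structure(model: AtomicModel, coords_list) -> gemmi.Structure:
    st = gemmi.Structure()
    for frame_idx, coords in enumerate(coords_list, start=1):
        gmodel = gemmi.Model(frame_idx)
        coords_A = np.asarray(coords) * ANGSTROM_PER_NM
        chain = None
        last_chain_id = None
        last_res_key = None
        residue = None
        for i in range(model.n_atoms):
            cid = model.chain_ids[i]
            if cid != last_chain_id:
                chain = gemmi.Chain(str(cid))
                gmodel.add_chain(chain)
                chain = gmodel[-1]
                last_chain_id = cid
                last_res_key = None
            rkey = (cid, int(model.res_ids[i]), model.res_names[i])
            if rkey != last_res_key:
                residue = gemmi.Residue()
                residue.name = model.res_names[i]
                residue.seqid = gemmi.SeqId(int(model.res_ids[i]), " ")
                chain.add_residue(residue)
                residue = chain[-1]
                last_res_key = rkey
            atom = gemmi.Atom()
            el = model.elements[i] or "C"
            atom.name = f"{el}{i % 1000}" if len(el) < 3 else el
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*coords_A[i])
            residue.add_atom(atom)
        st.add_model(gmodel)
    st.setup_entities()
    return st


def write_pdb(model: AtomicModel, path) -> None:
    """Write a single-model PDB file (coordinates converted nm → Å)."""
    _to_structure(model, [model.coords]).write_pdb(str(path))


def write_trajectory_pdb(model: AtomicModel, coords_list, path) -> None:
    """Write a list of coordinate frames as a multi-model PDB file."""
    _to_structure(model, coords_list).write_pdb(str(path))
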