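"""Unit conventions shared by the whole package.

Density maps live in Å (the MRC/CCP4 file convention); atomic models and
everything dynamical (bonds, σ, forces, integration) live in standard MD
units: nm, ps, amu, kJ/mol.  The nm↔Å conversion happens in exactly one
place — these constants — and only at the map/model boundary.
"""

#: Å per nm. The single length-conversion factor of the package.
ANGSTROM_PER_NM = 10.0

#: Boltzmann constant in kJ mol⁻¹ K⁻¹.
KB = 0.008314462618


def nm_to_angstrom(x):
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x):
    return x / ANGSTROM_PER_NM
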