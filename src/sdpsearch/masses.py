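"""Monoisotopic mass constants for peptide chemistry.

Residue masses, the water added on peptide-bond hydrolysis and the proton
mass all come from :mod:`pyteomics.mass` so that every mass in the package
is consistent with the standard tables used across the field.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Mass of one water molecule (Da), added once per peptide.
WATER: float = _pmass.calculate_mass(formula="H2O")

#: Mass of a proton (Da); converts between neutral mass and m/z.
PROTON: float = _pmass.nist_mass["H+"][0][0]

#: Carbamidomethylation of cysteine, the common fixed alkylation (Da).
CARBAMIDOMETHYL: float = 57.021464

#: Residue letters outside the standard 20 occasionally seen in databases.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")
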