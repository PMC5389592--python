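"""Peptide mass arithmetic.

Masses are monoisotopic throughout: CE-TOF peak lists are deconvoluted and
deisotoped upstream, so the neutral monoisotopic mass is the quantity the
pipeline matches on.  Residue masses come from the pyteomics ``std_aa_mass``
table (Unimod/IUPAC values); a neutral peptide mass is the sum of its residue
masses plus one water (18.0105646863 Da).  No post-translational modifications
are modelled.
"""

from __future__ import annotations

from pyteomics import mass as _pt_mass

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER_MONO = _pt_mass.calculate_mass(formula="H2O")


def compute_peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass (Da) of an unmodified peptide.

    Parameters
    ----------
    sequence:
        Peptide sequence over the 20 standard one-letter residue codes.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-standard character.
    """
    if not sequence:
        raise ValueError("empty peptide sequence has no mass")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"unknown residue(s) {sorted(bad)} in sequence {sequence!r}; "
            "only the 20 standard amino acids are supported"
        )
    return float(_pt_mass.fast_mass(sequence))


def ppm_deviation(observed: float, reference: float) -> float:
    """Signed mass deviation of *observed* from *reference* in ppm."""
    if reference <= 0:
        raise ValueError("reference mass must be positive")
    return (observed - reference) / reference * 1e6
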