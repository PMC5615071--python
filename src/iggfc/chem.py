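"""Elemental composition, monoisotopic mass and isotope envelopes for glycopeptides.

Glycopeptide chemistry is handled at the level of element-count maps
(``{"C": 50, "H": 72, ...}``).  Peptide backbones are converted to element
counts with :mod:`pyteomics.mass`; glycan monosaccharides are added as residue
(anhydro) formulas.  Isotope envelopes are computed by convolving per-element
isotopologue distributions, which is exact for the small molecules handled
here (a few hundred atoms).
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as _pmass

#: Mass added per charge in m/z conversion (proton mass, Da).
PROTON_MASS = 1.007276

#: Spacing between consecutive isotopologue peaks (Da). The 13C-12C mass
#: difference is used because the A+1 peak of a glycopeptide is carbon
#: dominated; divide by charge for m/z spacing.
ISOTOPE_SPACING = 1.003355

# residue (anhydro) formulas of the monosaccharides found on IgG Fc N-glycans
GLYCAN_RESIDUES = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}


def peptide_formula(peptide: str) -> dict[str, int]:
    """Element counts of an intact (water-terminated) peptide.

    Raises
    ------
    ValueError
        If ``peptide`` contains a non-standard residue letter.
    """
    try:
        comp = _pmass.Composition(sequence=peptide)
    except Exception as exc:  # pyteomics raises its own error type
        raise ValueError(f"unknown residue in peptide {peptide!r}: {exc}") from exc
    return {el: int(n) for el, n in comp.items()}


def elemental_formula(peptide: str, glycan=None) -> dict[str, int]:
    """Element counts of a glycopeptide: peptide + glycan residue formulas.

    Parameters
    ----------
    peptide : str
        Amino-acid sequence (standard one-letter codes).
    glycan : GlycanComposition or None
        Monosaccharide counts to add; ``None`` gives the bare peptide.
    """
    formula = peptide_formula(peptide)
    if glycan is not None:
        for unit, counts in GLYCAN_RESIDUES.items():
            n = getattr(glycan, unit)
            for el, c in counts.items():
                formula[el] = formula.get(el, 0) + n * c
    return formula


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map: sum of lightest-isotope masses."""
    if not formula:
        raise ValueError("empty elemental formula")
    total = 0.0
    for el, n in formula.items():
        if el not in _pmass.nist_mass:
            raise ValueError(f"unknown element {el!r}")
        total += n * _pmass.nist_mass[el][0][0]
    return total


def _element_distribution(element: str) -> np.ndarray:
    """Isotopologue probability vector for one atom, indexed by neutron excess."""
    iso = _pmass.nist_mass[element]
    masses = sorted(k for k in iso if k != 0 and iso[k][1] > 0)
    base = masses[0]
    dist = np.zeros(masses[-1] - base + 1)
    for k in masses:
        dist[k - base] = iso[k][1]
    return dist


def isotope_envelope(formula: dict[str, int], k: int = 3) -> np.ndarray:
    """First ``k`` isotopologue probabilities of a molecule.

    The per-element single-atom distributions are raised to the atom count by
    repeated squaring and convolved across elements; probabilities are
    normalized over *all* isotopologues, so the returned ``k`` values sum to
    at most 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not formula:
        raise ValueError("empty elemental formula")
    result = np.ones(1)
    for el, n in formula.items():
        if n == 0:
            continue
        single = _element_distribution(el)
        # power by repeated squaring, truncating to the first k terms as we go
        power = np.ones(1)
        base = single
        m = n
        while m:
            if m & 1:
                power = np.convolve(power, base)[: k + 8]
            m >>= 1
            if m:
                base = np.convolve(base, base)[: k + 8]
        result = np.convolve(result, power)[: k + 8]
    out = np.zeros(k)
    take = min(k, result.size)
    out[:take] = result[:take]
    return out


def target_mz(monoisotopic: float, charge: int, n_isotopes: int = 3) -> list[float]:
    """m/z values of the first isotopologues of a protonated ion at ``charge``."""
    return [
        (monoisotopic + i * ISOTOPE_SPACING + charge * PROTON_MASS) / charge
        for i in range(n_isotopes)
    ]
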