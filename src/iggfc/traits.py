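"""Derived glycosylation features from normalized glycoform profiles.

Five features summarize a subclass glycoform profile (percentages per
glycoform summing to 100):

* **fucosylation** — % of glycopeptides carrying a core fucose;
* **bisection** — % carrying a bisecting GlcNAc;
* **galactosylation** — % of galactoses per antenna (2 antennae per
  biantennary glycan): 100 * sum(g_i * a_i) / (2 * sum(a_i));
* **sialylation** — % of sialic acids per antenna, analogous;
* **SA per gal** — % of galactoses that carry a sialic acid:
  100 * sum(s_i * a_i) / sum(g_i * a_i).

Per-glycan variants report the % of glycans carrying at least one galactose
(resp. sialic acid).  Fucosylation is undefined for IgG4 because the panel
quantifies no afucosylated IgG4 species; it is reported as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .panel import parse_shorthand

TRAIT_NAMES = ["fucosylation", "bisection", "galactosylation", "sialylation",
               "sa_per_gal"]
PER_GLYCAN_NAMES = ["gal_per_glycan", "sial_per_glycan"]


@dataclass
class TraitVector:
    subclass: str
    fucosylation: float  # NaN when undefined (IgG4)
    bisection: float
    galactosylation: float
    sialylation: float
    sa_per_gal: float  # NaN when no galactose present
    gal_per_glycan: float
    sial_per_glycan: float
    fucosylation_defined: bool = True

    def as_dict(self) -> dict:
        return {name: getattr(self, name)
                for name in TRAIT_NAMES + PER_GLYCAN_NAMES}


def compute_traits(profile: dict, subclass: str) -> TraitVector:
    """Derive the five glycosylation features from one subclass profile.

    Parameters
    ----------
    profile : dict
        Glycoform shorthand -> relative abundance (percent; any positive
        total is accepted, traits are scale invariant).
    subclass : str
        "IgG1", "IgG2" or "IgG4".
    """
    total = float(sum(profile.values()))
    if total <= 0:
        raise ValueError("profile has no positive abundance")
    fuc = bis = gal_units = sia_units = gal_any = sia_any = 0.0
    for code, a in profile.items():
        g = parse_shorthand(code)
        if g.fucosylated:
            fuc += a
        if g.bisecting:
            bis += a
        gal_units += g.galactoses * a
        sia_units += g.sialic * a
        if g.galactoses >= 1:
            gal_any += a
        if g.sialic >= 1:
            sia_any += a
    if gal_units == 0 and sia_units > 0:
        raise ValueError("sialylation without galactosylation is infeasible")
    fuc_defined = subclass != "IgG4"
    return TraitVector(
        subclass=subclass,
        fucosylation=100.0 * fuc / total if fuc_defined else math.nan,
        bisection=100.0 * bis / total,
        galactosylation=100.0 * gal_units / (2.0 * total),
        sialylation=100.0 * sia_units / (2.0 * total),
        sa_per_gal=(100.0 * sia_units / gal_units) if gal_units > 0 else math.nan,
        gal_per_glycan=100.0 * gal_any / total,
        sial_per_glycan=100.0 * sia_any / total,
        fucosylation_defined=fuc_defined,
    )


def compute_per_glycan_variants(profile: dict) -> tuple[float, float]:
    """(% glycans with >= 1 galactose, % with >= 1 sialic acid)."""
    tv = compute_traits(profile, "IgG1")
    return tv.gal_per_glycan, tv.sial_per_glycan
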