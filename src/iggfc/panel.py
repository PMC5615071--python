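"""The glycopeptide analyte panel for subclass-specific IgG Fc glycoprofiling.

Tryptic Fc glycopeptides of IgG1 (EEQYNSTYR), IgG2 (EEQFNSTFR) and IgG4
(EEQFNSTYR) carry a biantennary complex-type N-glycan varying in galactose
(G0/G1/G2), core fucose (F), bisecting GlcNAc (N) and sialic acid (S1/S2).
A shorthand such as ``G1FNS1`` names one glycoform.  The panel enumerates the
quantified glycoforms per subclass, their masses, isotope envelopes and
target m/z values at 2+ and 3+.

Afucosylated IgG4 glycopeptides are excluded from quantification: their
masses overlap with the far more abundant fucosylated IgG1 glycopeptides and
cannot be distinguished from tailing of the latter.  Two low-abundance IgG2
glycoforms (G1FNS1, G2FNS1) are carried but flagged for exclusion from
statistics downstream because of a severe batch effect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import chem

SUBCLASS_PEPTIDES = {
    "IgG1": "EEQYNSTYR",
    "IgG2": "EEQFNSTFR",
    "IgG4": "EEQFNSTYR",
}

#: default glycoform grid: {G0,G1,G2} x {+/-N} x {+/-F} plus the singly
#: sialylated {G1S1,G2S1,G1NS1,G2NS1} x {+/-F} = 20 compositions
DEFAULT_GLYCOFORMS = [
    "G0", "G0F", "G0N", "G0FN",
    "G1", "G1F", "G1N", "G1FN",
    "G2", "G2F", "G2N", "G2FN",
    "G1S1", "G1FS1", "G1NS1", "G1FNS1",
    "G2S1", "G2FS1", "G2NS1", "G2FNS1",
]

#: IgG2 glycoforms excluded from statistics (severe batch effect, <0.4% abundance)
IGG2_STATISTICS_EXCLUSIONS = ["G1FNS1", "G2FNS1"]

#: default retention-time apex per subclass (s); glycoforms of one subclass
#: co-elute closely, so a single apex per subclass is used
DEFAULT_SUBCLASS_RT = {"IgG2": 290.0, "IgG4": 330.0, "IgG1": 370.0}

_SHORTHAND_RE = re.compile(r"^G(?P<gal>[0-2])(?P<fuc>F?)(?P<bis>N?)(?:S(?P<sia>[1-2]))?$")


class ShorthandError(ValueError):
    """Malformed or chemically infeasible glycoform shorthand."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide composition of a biantennary IgG Fc N-glycan."""

    galactoses: int
    bisecting: bool
    fucosylated: bool
    sialic: int

    def __post_init__(self):
        if not 0 <= self.galactoses <= 2:
            raise ShorthandError(f"galactoses out of range: {self.galactoses}")
        if not 0 <= self.sialic <= 2:
            raise ShorthandError(f"sialic acids out of range: {self.sialic}")
        if self.sialic > self.galactoses:
            raise ShorthandError(
                f"{self.sialic} sialic acid(s) but only {self.galactoses} "
                "galactose(s); a sialic acid requires a galactose"
            )

    @property
    def hex(self) -> int:
        return 3 + self.galactoses

    @property
    def hexnac(self) -> int:
        return 4 + (1 if self.bisecting else 0)

    @property
    def dhex(self) -> int:
        return 1 if self.fucosylated else 0

    @property
    def neuac(self) -> int:
        return self.sialic

    @property
    def shorthand(self) -> str:
        code = f"G{self.galactoses}"
        if self.fucosylated:
            code += "F"
        if self.bisecting:
            code += "N"
        if self.sialic:
            code += f"S{self.sialic}"
        return code


def parse_shorthand(code: str) -> GlycanComposition:
    """Parse a glycoform shorthand like ``G1FNS1`` into a composition.

    Raises :class:`ShorthandError` for malformed codes and for infeasible
    compositions (sialic acid without galactose).
    """
    m = _SHORTHAND_RE.match(code)
    if m is None:
        raise ShorthandError(f"malformed glycoform shorthand: {code!r}")
    return GlycanComposition(
        galactoses=int(m.group("gal")),
        bisecting=bool(m.group("bis")),
        fucosylated=bool(m.group("fuc")),
        sialic=int(m.group("sia") or 0),
    )


@dataclass(frozen=True)
class Analyte:
    """One subclass-specific glycopeptide with mass, envelope and m/z targets."""

    subclass: str
    shorthand: str
    glycan: GlycanComposition
    peptide: str
    monoisotopic_mass: float
    envelope: tuple  # first-k isotopologue probabilities, sum <= 1
    expected_rt: float  # seconds

    def target_mz(self, charge: int, n_isotopes: int = 3) -> list[float]:
        return chem.target_mz(self.monoisotopic_mass, charge, n_isotopes)


def make_analyte(subclass: str, shorthand: str, expected_rt: float,
                 n_isotopes: int = 3) -> Analyte:
    glycan = parse_shorthand(shorthand)
    peptide = SUBCLASS_PEPTIDES[subclass]
    formula = chem.elemental_formula(peptide, glycan)
    return Analyte(
        subclass=subclass,
        shorthand=shorthand,
        glycan=glycan,
        peptide=peptide,
        monoisotopic_mass=chem.monoisotopic_mass(formula),
        envelope=tuple(chem.isotope_envelope(formula, n_isotopes)),
        expected_rt=expected_rt,
    )


@dataclass
class Panel:
    """Quantified analytes plus the list of excluded (subclass, glycoform, reason)."""

    analytes: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    def subclass_analytes(self, subclass: str) -> list:
        return [a for a in self.analytes if a.subclass == subclass]

    def get(self, subclass: str, shorthand: str) -> Analyte:
        for a in self.analytes:
            if a.subclass == subclass and a.shorthand == shorthand:
                return a
        raise KeyError((subclass, shorthand))

    @property
    def subclasses(self) -> list:
        seen = []
        for a in self.analytes:
            if a.subclass not in seen:
                seen.append(a.subclass)
        return seen

    def statistics_exclusions(self) -> list:
        """(subclass, shorthand) pairs flagged excluded-from-statistics."""
        return [(s, g) for s, g, reason in self.excluded
                if reason == "severe batch effect"]


def build_panel(glycoforms=None, subclass_rt=None) -> Panel:
    """Build the default quantification panel.

    IgG1 and IgG2 quantify the full glycoform grid; IgG4 keeps only the
    fucosylated compositions (afucosylated IgG4 overlaps in mass with
    fucosylated IgG1).  IgG2 G1FNS1/G2FNS1 are quantified but flagged for
    downstream exclusion from statistics.
    """
    glycoforms = list(DEFAULT_GLYCOFORMS if glycoforms is None else glycoforms)
    if len(set(glycoforms)) != len(glycoforms):
        raise ValueError("duplicate glycoform shorthand in panel config")
    subclass_rt = dict(DEFAULT_SUBCLASS_RT if subclass_rt is None else subclass_rt)

    panel = Panel()
    for subclass in ("IgG1", "IgG2", "IgG4"):
        rt = subclass_rt[subclass]
        for code in glycoforms:
            glycan = parse_shorthand(code)
            if subclass == "IgG4" and not glycan.fucosylated:
                panel.excluded.append(
                    (subclass, code, "afucosylated IgG4 overlaps fucosylated IgG1"))
                continue
            panel.analytes.append(make_analyte(subclass, code, rt))
    for code in IGG2_STATISTICS_EXCLUSIONS:
        if code in glycoforms:
            panel.excluded.append(("IgG2", code, "severe batch effect"))
    return panel


# ---------------------------------------------------------------------------
# TSV serialization

PANEL_COLUMNS = ["subclass", "shorthand", "peptide", "hex", "hexnac", "dhex",
                 "neuac", "expected_rt_s"]


def write_panel_tsv(panel: Panel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for a in panel.analytes:
            g = a.glycan
            fh.write("\t".join(map(str, [a.subclass, a.shorthand, a.peptide,
                                         g.hex, g.hexnac, g.dhex, g.neuac,
                                         repr(a.expected_rt)])) + "\n")


def read_panel_tsv(path) -> Panel:
    panel = Panel()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PANEL_COLUMNS:
            raise ValueError(f"unexpected panel TSV header: {header}")
        for line in fh:
            sub, code, peptide, *_, rt = line.rstrip("\n").split("\t")
            a = make_analyte(sub, code, float(rt))
            if a.peptide != peptide:
                raise ValueError(f"peptide mismatch for {sub} in panel TSV")
            panel.analytes.append(a)
    return panel
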