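"""In silico proteolysis and epitope-preserving peptide selection.

A protease is a deterministic cut-site rule (cleavage residues, side,
Keil-style proline suppression).  ``digest`` enumerates products with up
to ``max_missed`` internal cut sites; ``peptides_covering_epitope``
filters and ranks the products that keep an antibody's linear epitope on
a single peptide, which is the design constraint for immuno-affinity
MALDI assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import RESIDUE_MASSES, ModifiedPeptide, mono_mass

__all__ = [
    "ProteaseRule",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "ARGC",
    "LYSC",
    "ASPN",
    "GLUC",
    "PROTEASES",
    "DigestPeptide",
    "EpitopeSpec",
    "EpitopeDestroyedError",
    "cut_sites",
    "digest",
    "peptides_covering_epitope",
    "compare_proteases",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: residues, side ('C' or 'N'), suppression rules.

    ``suppress_before_proline`` implements the Keil rule (no cleavage when
    the next residue is proline).  ``suppress_near_mods`` optionally skips
    cut sites within one residue of a modified position, emulating the
    reduced cleavage efficiency observed next to phosphorylated residues;
    it is off by default and only consulted when modified positions are
    passed to :func:`cut_sites`.
    """

    name: str
    residues: frozenset[str]
    side: str = "C"
    suppress_before_proline: bool = True
    suppress_near_mods: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError("side must be 'C' or 'N'")


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"))
CHYMOTRYPSIN = ProteaseRule("chymotrypsin", frozenset("FYWL"))
CHYMOTRYPSIN_M = ProteaseRule("chymotrypsin+M", frozenset("FYWLM"))
ARGC = ProteaseRule("argc", frozenset("R"))
LYSC = ProteaseRule("lysc", frozenset("K"), suppress_before_proline=False)
ASPN = ProteaseRule("aspn", frozenset("D"), side="N", suppress_before_proline=False)
GLUC = ProteaseRule("gluc", frozenset("E"))

PROTEASES = {
    r.name: r
    for r in (TRYPSIN, CHYMOTRYPSIN, CHYMOTRYPSIN_M, ARGC, LYSC, ASPN, GLUC)
}


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic product with protein coordinates and P1/P1' flanks.

    ``start``/``end`` are 1-based inclusive protein coordinates;
    ``missed`` counts internal cut sites; ``before``/``after`` are the
    flanking residues ('-' at protein termini), supporting the
    ``R.PEPTIDE.K`` notation.
    """

    sequence: str
    start: int
    end: int
    missed: int
    before: str = "-"
    after: str = "-"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")

    @property
    def flanked(self) -> str:
        return f"{self.before}.{self.sequence}.{self.after}"

    def to_peptide(self, protein: str | None = None) -> ModifiedPeptide:
        return ModifiedPeptide(self.sequence, protein=protein, start=self.start)

    def peptide_position(self, protein_position: int) -> int:
        """Convert a 1-based protein coordinate to a 1-based peptide position."""
        if not self.start <= protein_position <= self.end:
            raise ValueError(
                f"protein position {protein_position} outside peptide {self.start}-{self.end}"
            )
        return protein_position - self.start + 1


@dataclass(frozen=True)
class EpitopeSpec:
    """The linear epitope an antibody requires intact on one peptide.

    ``required_sites`` are protein positions whose modification state the
    antibody reads (e.g. pS235 & pS236); ``any_of`` switches the semantics
    from all-of to at-least-one-of (cross-reactive antibodies).
    """

    protein: str
    start: int
    end: int
    required_sites: tuple[int, ...] = ()
    any_of: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid epitope range")
        for pos in self.required_sites:
            if not self.start <= pos <= self.end:
                raise ValueError(f"required site {pos} outside epitope range")


class EpitopeDestroyedError(ValueError):
    """The protease cuts inside the epitope, so no covering peptide exists."""


def cut_sites(
    sequence: str,
    rule: ProteaseRule,
    modified_positions: Iterable[int] = (),
) -> list[int]:
    """0-based cut positions (a cut at i separates sequence[:i] and sequence[i:]).

    Deterministic: identical inputs always yield the identical site list.
    """
    modset = set(modified_positions) if rule.suppress_near_mods else set()
    sites: list[int] = []
    n = len(sequence)
    for i, res in enumerate(sequence):
        if res not in rule.residues:
            continue
        cut = i + 1 if rule.side == "C" else i
        if cut <= 0 or cut >= n:
            continue
        if rule.side == "C" and rule.suppress_before_proline and sequence[cut] == "P":
            continue
        if modset:
            # positions here are 1-based; suppress cuts within +/-1 of a mod
            pos = i + 1
            if any(abs(pos - m) <= 1 for m in modset):
                continue
        sites.append(cut)
    return sites


def digest(
    protein_sequence: str,
    rule: ProteaseRule,
    max_missed: int = 0,
    offset: int = 1,
    modified_positions: Iterable[int] = (),
) -> list[DigestPeptide]:
    """All proteolytic products with 0..max_missed internal cut sites.

    ``offset`` is the protein coordinate of the first residue of
    ``protein_sequence`` (1-based), so partial protein regions keep their
    native numbering.  Zero-missed products tile the input exactly.
    """
    if not protein_sequence:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    for i, res in enumerate(protein_sequence, start=1):
        RESIDUE_MASSES.residue_mono(res, i)  # validates residues
    sites = cut_sites(protein_sequence, rule, modified_positions)
    bounds = [0, *sites, len(protein_sequence)]
    peptides: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            lo, hi = bounds[i], bounds[j]
            peptides.append(
                DigestPeptide(
                    sequence=protein_sequence[lo:hi],
                    start=offset + lo,
                    end=offset + hi - 1,
                    missed=j - i - 1,
                    before=protein_sequence[lo - 1] if lo > 0 else "-",
                    after=protein_sequence[hi] if hi < len(protein_sequence) else "-",
                )
            )
    return peptides


def peptides_covering_epitope(
    protein_sequence: str,
    epitope: EpitopeSpec,
    rule: ProteaseRule,
    max_missed: int = 2,
    offset: int = 1,
) -> list[DigestPeptide]:
    """Digest products fully containing the epitope, best candidates first.

    Ranking: fewest missed cleavages, then shortest, then lowest start.
    An empty list means the protease destroys the epitope at this
    missed-cleavage ceiling.
    """
    end_coord = offset + len(protein_sequence) - 1
    if epitope.start < offset or epitope.end > end_coord:
        raise ValueError(
            f"epitope {epitope.start}-{epitope.end} outside sequence {offset}-{end_coord}"
        )
    covering = [
        p
        for p in digest(protein_sequence, rule, max_missed, offset)
        if p.start <= epitope.start and p.end >= epitope.end
    ]
    return sorted(covering, key=lambda p: (p.missed, len(p.sequence), p.start))


def compare_proteases(
    protein_sequence: str,
    epitope: EpitopeSpec,
    rules: Sequence[ProteaseRule],
    max_missed: int = 2,
    offset: int = 1,
) -> list[dict]:
    """Best covering peptide per protease, with the residues it adds.

    ``extra_positions`` are the protein coordinates inside the best
    peptide but outside the epitope — the adjacent region each protease
    exposes (e.g. an upstream phosphosite the tryptic peptide misses).
    """
    rows: list[dict] = []
    for rule in rules:
        candidates = peptides_covering_epitope(
            protein_sequence, epitope, rule, max_missed, offset
        )
        if not candidates:
            rows.append(
                {
                    "protease": rule.name,
                    "peptide": None,
                    "mono_mass": None,
                    "extra_positions": (),
                }
            )
            continue
        best = candidates[0]
        extra = tuple(
            pos
            for pos in range(best.start, best.end + 1)
            if pos < epitope.start or pos > epitope.end
        )
        rows.append(
            {
                "protease": rule.name,
                "peptide": best,
                "mono_mass": mono_mass(best.sequence),
                "extra_positions": extra,
            }
        )
    return rows
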