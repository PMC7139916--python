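"""Peptide mass engine.

Computes singly protonated (MH+) monoisotopic and average masses of
peptides carrying positioned modifications, stable-isotope labels and
point substitutions, plus singly charged b/y fragment ions.  MALDI-TOF
produces predominantly z = 1 ions, so every mass here is an MH+ value;
higher charge states are deliberately out of scope.

The residue mass constants are shipped as a versioned plain-text table
(``data/residue_masses.tsv``) so they can be diffed and audited; they are
loaded once at import time and are immutable afterwards.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

__all__ = [
    "WATER_MONO",
    "WATER_AVG",
    "PROTON",
    "ResidueMassTable",
    "RESIDUE_MASSES",
    "Modification",
    "MODIFICATIONS",
    "LabelScheme",
    "SILAC_K8_R10",
    "SIS_K8_V6",
    "ModSite",
    "ModifiedPeptide",
    "mono_mass",
    "avg_mass",
    "label_delta",
    "fragment_ions",
    "apply_substitution",
]

WATER_MONO = 18.010565
WATER_AVG = 18.0153
PROTON = 1.007276


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""


def _load_table() -> tuple[Mapping[str, float], Mapping[str, float]]:
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    text = (
        importlib.resources.files("maldiplex")
        .joinpath("data/residue_masses.tsv")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, m, a = line.split("\t")
        mono[res] = float(m)
        avg[res] = float(a)
    return MappingProxyType(mono), MappingProxyType(avg)


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue monoisotopic and average masses (Da) for the 20 standard amino acids."""

    mono: Mapping[str, float]
    avg: Mapping[str, float]
    version: str = "1"

    def residue_mono(self, res: str, position: int | None = None) -> float:
        try:
            return self.mono[res]
        except KeyError:
            where = f" at position {position}" if position is not None else ""
            raise UnknownResidueError(f"unknown residue {res!r}{where}") from None

    def residue_avg(self, res: str, position: int | None = None) -> float:
        try:
            return self.avg[res]
        except KeyError:
            where = f" at position {position}" if position is not None else ""
            raise UnknownResidueError(f"unknown residue {res!r}{where}") from None


RESIDUE_MASSES = ResidueMassTable(*_load_table())


@dataclass(frozen=True)
class Modification:
    """A covalent modification with monoisotopic/average mass deltas (Da).

    ``targets`` restricts which residues may carry the modification;
    ``terminus`` optionally restricts it to the N or C terminal residue.
    """

    name: str
    delta_mono: float
    delta_avg: float
    targets: frozenset[str]
    terminus: str | None = None

    def allows(self, residue: str) -> bool:
        return residue in self.targets


PHOSPHO = Modification("phospho", 79.96633, 79.9799, frozenset("STY"))
ACETYL = Modification("acetyl", 42.01057, 42.0367, frozenset("K"))
METHYL = Modification("methyl", 14.01565, 14.0266, frozenset("KR"))
DIMETHYL = Modification("dimethyl", 28.03130, 28.0532, frozenset("KR"))
TRIMETHYL = Modification("trimethyl", 42.04695, 42.0797, frozenset("K"))
CARBAMIDOMETHYL = Modification("carbamidomethyl", 57.02146, 57.0513, frozenset("C"))

MODIFICATIONS: Mapping[str, Modification] = MappingProxyType(
    {
        m.name: m
        for m in (PHOSPHO, ACETYL, METHYL, DIMETHYL, TRIMETHYL, CARBAMIDOMETHYL)
    }
)


@dataclass(frozen=True)
class LabelScheme:
    """Per-residue stable-isotope label deltas.

    ``mode`` selects ``nominal`` integer shifts (the convention used when
    reporting calculated SILAC/SIS masses: K+8, R+10, V+6) or ``exact``
    isotopologue deltas for real-data work.  The per-peptide delta is the
    sum over labelled residues.
    """

    name: str
    nominal: Mapping[str, float]
    exact: Mapping[str, float]
    mode: str = "nominal"

    def __post_init__(self) -> None:
        if self.mode not in ("nominal", "exact"):
            raise ValueError(f"label mode must be nominal or exact, got {self.mode!r}")
        for res in self.nominal:
            if abs(self.nominal[res] - self.exact[res]) >= 0.05:
                raise ValueError(
                    f"nominal and exact deltas for {res} differ by >= 0.05 Da"
                )

    @property
    def deltas(self) -> Mapping[str, float]:
        return self.nominal if self.mode == "nominal" else self.exact

    def delta_for(self, residue: str) -> float:
        try:
            return self.deltas[residue]
        except KeyError:
            raise ValueError(f"label scheme {self.name!r} has no delta for residue {residue!r}") from None

    def with_mode(self, mode: str) -> "LabelScheme":
        return LabelScheme(self.name, self.nominal, self.exact, mode)


# 13C/15N isotopologue deltas: K+8 = 6x(13C-12C) + 2x(15N-14N), R+10, V+6.
SILAC_K8_R10 = LabelScheme(
    "SILAC K+8/R+10",
    nominal=MappingProxyType({"K": 8.0, "R": 10.0}),
    exact=MappingProxyType({"K": 8.014199, "R": 10.008269}),
)

# Synthetic SIS standards may label non-terminal residues too (heavy valine).
SIS_K8_V6 = LabelScheme(
    "SIS K+8/V+6",
    nominal=MappingProxyType({"K": 8.0, "V": 6.0}),
    exact=MappingProxyType({"K": 8.014199, "V": 6.013809}),
)


@dataclass(frozen=True)
class ModSite:
    """A modification placed at a 1-based position within a peptide."""

    position: int
    mod: Modification

    def label(self, sequence: str) -> str:
        return f"{self.mod.name}@{sequence[self.position - 1]}{self.position}"


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications and labelled residues.

    Positions are 1-based within the peptide.  ``protein`` / ``start``
    optionally anchor the peptide in protein coordinates (1-based,
    inclusive), and ``mutation`` records an applied point substitution.
    """

    sequence: str
    mods: tuple[ModSite, ...] = ()
    labeled_positions: tuple[int, ...] = ()
    protein: str | None = None
    start: int | None = None
    mutation: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, res in enumerate(self.sequence, start=1):
            if res not in RESIDUE_MASSES.mono:
                raise UnknownResidueError(f"unknown residue {res!r} at position {i}")
        seen: dict[int, str] = {}
        for site in self.mods:
            if not 1 <= site.position <= len(self.sequence):
                raise ValueError(
                    f"modification position {site.position} outside peptide of length {len(self.sequence)}"
                )
            res = self.sequence[site.position - 1]
            if not site.mod.allows(res):
                raise ValueError(
                    f"{site.mod.name} not allowed on residue {res}{site.position}"
                )
            if site.position in seen:
                raise ValueError(
                    f"position {site.position} already carries {seen[site.position]}"
                )
            seen[site.position] = site.mod.name
        for pos in self.labeled_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"labeled position {pos} outside peptide")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int | None:
        return None if self.start is None else self.start + len(self.sequence) - 1

    def mod_delta_mono(self) -> float:
        return sum(site.mod.delta_mono for site in self.mods)

    def mod_delta_avg(self) -> float:
        return sum(site.mod.delta_avg for site in self.mods)

    def describe_mods(self) -> str:
        if not self.mods:
            return "-"
        return ",".join(s.label(self.sequence) for s in sorted(self.mods, key=lambda s: s.position))


def _as_peptide(peptide: ModifiedPeptide | str) -> ModifiedPeptide:
    return peptide if isinstance(peptide, ModifiedPeptide) else ModifiedPeptide(peptide)


def label_delta(peptide: ModifiedPeptide | str, scheme: LabelScheme) -> float:
    """Summed label mass delta (Da) over the peptide's labelled positions.

    In ``nominal`` mode this is an exact integer (e.g. two labelled
    lysines at K+8 give 16.0); ``exact`` mode sums isotopologue deltas.
    """
    peptide = _as_peptide(peptide)
    return sum(
        scheme.delta_for(peptide.sequence[pos - 1]) for pos in peptide.labeled_positions
    )


def mono_mass(peptide: ModifiedPeptide | str, scheme: LabelScheme | None = None) -> float:
    """Monoisotopic MH+ mass (Da): residues + water + proton + mods + labels."""
    peptide = _as_peptide(peptide)
    m = sum(
        RESIDUE_MASSES.residue_mono(res, i)
        for i, res in enumerate(peptide.sequence, start=1)
    )
    m += WATER_MONO + PROTON + peptide.mod_delta_mono()
    if peptide.labeled_positions:
        if scheme is None:
            raise ValueError("peptide has labeled positions but no label scheme given")
        m += label_delta(peptide, scheme)
    return m


def avg_mass(peptide: ModifiedPeptide | str, scheme: LabelScheme | None = None) -> float:
    """Average MH+ mass (Da) using the average residue table."""
    peptide = _as_peptide(peptide)
    m = sum(
        RESIDUE_MASSES.residue_avg(res, i)
        for i, res in enumerate(peptide.sequence, start=1)
    )
    m += WATER_AVG + PROTON + peptide.mod_delta_avg()
    if peptide.labeled_positions:
        if scheme is None:
            raise ValueError("peptide has labeled positions but no label scheme given")
        m += label_delta(peptide, scheme)
    return m


def fragment_ions(
    peptide: ModifiedPeptide | str,
    series: str,
    charge: int = 1,
) -> list[tuple[str, float]]:
    """Singly charged b- or y-ion m/z values.

    b_i = sum of the first i residue masses (+ their modifications) + proton;
    y_i = sum of the last i residue masses (+ their modifications) + water
    + proton.  Each series has n-1 members.
    """
    if charge != 1:
        raise ValueError("only singly charged fragments are supported")
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    peptide = _as_peptide(peptide)
    seq = peptide.sequence
    mod_at = {s.position: s.mod.delta_mono for s in peptide.mods}
    n = len(seq)
    ions: list[tuple[str, float]] = []
    if series == "b":
        running = PROTON
        for i in range(1, n):
            running += RESIDUE_MASSES.residue_mono(seq[i - 1], i) + mod_at.get(i, 0.0)
            ions.append((f"b{i}", running))
    else:
        running = WATER_MONO + PROTON
        for i in range(1, n):
            pos = n - i + 1
            running += RESIDUE_MASSES.residue_mono(seq[pos - 1], pos) + mod_at.get(pos, 0.0)
            ions.append((f"y{i}", running))
    return ions


def apply_substitution(
    peptide: ModifiedPeptide | str, position: int, new_residue: str
) -> ModifiedPeptide:
    """Return the point-mutant peptide with ``position`` (1-based) replaced.

    The mass difference from the wild type equals the residue-mass
    difference of the substitution (e.g. A -> V is +28.0313 Da mono).
    """
    peptide = _as_peptide(peptide)
    if not 1 <= position <= len(peptide.sequence):
        raise ValueError(f"position {position} outside peptide")
    if new_residue not in RESIDUE_MASSES.mono:
        raise UnknownResidueError(f"unknown residue {new_residue!r}")
    old = peptide.sequence[position - 1]
    seq = peptide.sequence[: position - 1] + new_residue + peptide.sequence[position:]
    return ModifiedPeptide(
        sequence=seq,
        mods=peptide.mods,
        labeled_positions=peptide.labeled_positions,
        protein=peptide.protein,
        start=peptide.start,
        mutation=f"{old}{position if peptide.start is None else peptide.start + position - 1}{new_residue}",
    )
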