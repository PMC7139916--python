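"""Assay definitions and multiplexed panel compilation.

An assay is one antibody's validated target peptides together with the
full variant space the bead can capture: required modifications (the
sites the antibody reads), optional extra variable modifications
(phospho/acetyl/methyl ladders), point-mutation alleles and heavy-label
channels, each with its reference MH+ mass.  A panel compiles several
assays into a sorted mass index used to decode randomly arrayed spots,
reporting any cross-assay mass collisions within the linear-mode
tolerance as a designability check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    LabelScheme,
    Modification,
    ModifiedPeptide,
    ModSite,
    apply_substitution,
    avg_mass,
    mono_mass,
)
from .digest import (
    DigestPeptide,
    EpitopeDestroyedError,
    EpitopeSpec,
    ProteaseRule,
    cut_sites,
    peptides_covering_epitope,
)

__all__ = [
    "VariableModRule",
    "Variant",
    "AssayDefinition",
    "AssayPanel",
    "VariantOverflowError",
    "enumerate_variants",
    "build_assay",
    "compile_panel",
]

MAX_VARIANTS_PER_ASSAY = 10_000


class VariantOverflowError(ValueError):
    """The variant space exceeds the per-assay cap."""


@dataclass(frozen=True)
class VariableModRule:
    """One variable-modification class and the residues eligible to carry it."""

    mod: Modification
    residues: frozenset[str]


@dataclass(frozen=True)
class Variant:
    """One reference entry: a concrete modified/labelled peptide and its masses.

    ``pair_id`` is shared by the light and heavy channel of the same
    peptide form, which is how SILAC pairs are located.  When several
    enumerated forms share a mass (within 1e-6 Da) they are collapsed to
    one record; ``multiplicity`` counts them and ``compositions`` keeps
    the distinct modification compositions for ambiguity reporting.
    """

    variant_id: str
    pair_id: str
    peptide: ModifiedPeptide
    mono: float
    avg: float
    missed: int
    mod_counts: Mapping[str, int]
    n_extra: int
    label_state: str  # 'L', 'H', or '-' when the assay is unlabelled
    mutation: str | None = None
    multiplicity: int = 1
    compositions: tuple[str, ...] = ()


def _mod_counts(mods: Sequence[ModSite]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for site in mods:
        counts[site.mod.name] = counts.get(site.mod.name, 0) + 1
    return counts


def _composition_label(counts: Mapping[str, int], missed: int) -> str:
    short = {"phospho": "p", "acetyl": "ac", "methyl": "me", "dimethyl": "me2",
             "trimethyl": "me3", "carbamidomethyl": "cam"}
    parts = [f"{n}{short.get(name, name)}" for name, n in sorted(counts.items())] or ["unmod"]
    return "+".join(parts) + f"/{missed}XC"


def enumerate_variants(
    base: DigestPeptide,
    required_mods: Sequence[tuple[int, Modification]] = (),
    variable_rules: Sequence[VariableModRule] = (),
    max_extra: int = 0,
    any_of: bool = False,
    mutations: Sequence[tuple[int, str]] = (),
    labels: LabelScheme | None = None,
    protein: str | None = None,
) -> list[Variant]:
    """Enumerate the reference variant space of one base peptide.

    ``required_mods`` are (protein position, modification) pairs the
    antibody reads; with ``any_of`` every non-empty subset is generated
    (cross-reactive capture), otherwise all are mandatory.  Variable
    modifications add 0..``max_extra`` placements on eligible residues
    not already modified.  ``mutations`` are (protein position, residue)
    alternative alleles kept alongside the wild type; ``labels`` doubles
    the space into light/heavy channels.  Duplicate-mass variants are
    collapsed with multiplicity recorded.
    """
    if max_extra < 0:
        raise ValueError("max_extra must be >= 0")

    if any_of and required_mods:
        required_sets = [
            combo
            for k in range(1, len(required_mods) + 1)
            for combo in itertools.combinations(required_mods, k)
        ]
    else:
        required_sets = [tuple(required_mods)]

    alleles: list[tuple[int, str] | None] = [None, *mutations]
    label_states = ["-"] if labels is None else ["L", "H"]

    raw: list[Variant] = []
    for allele in alleles:
        if allele is None:
            pep_seq = base.sequence
            mutation = None
        else:
            pos, new_res = allele
            ppos = base.peptide_position(pos)
            old = base.sequence[ppos - 1]
            pep_seq = base.sequence[: ppos - 1] + new_res + base.sequence[ppos:]
            mutation = f"{old}{pos}{new_res}"

        for req in required_sets:
            req_sites = []
            ok = True
            for pos, mod in req:
                ppos = base.peptide_position(pos)
                if not mod.allows(pep_seq[ppos - 1]):
                    if allele is not None:
                        ok = False  # mutation removed the modifiable residue
                        break
                    raise ValueError(
                        f"required {mod.name} incompatible with residue "
                        f"{pep_seq[ppos - 1]} at protein position {pos}"
                    )
                req_sites.append(ModSite(ppos, mod))
            if not ok:
                continue
            taken = {s.position for s in req_sites}

            # eligible (position, mod) assignments for variable mods
            eligible: dict[int, list[Modification]] = {}
            for rule in variable_rules:
                for i, res in enumerate(pep_seq, start=1):
                    if i in taken or res not in rule.residues or not rule.mod.allows(res):
                        continue
                    eligible.setdefault(i, []).append(rule.mod)

            positions = sorted(eligible)
            for k in range(0, max_extra + 1):
                for pos_combo in itertools.combinations(positions, k):
                    for mod_choice in itertools.product(
                        *(eligible[p] for p in pos_combo)
                    ):
                        extra_sites = [
                            ModSite(p, m) for p, m in zip(pos_combo, mod_choice)
                        ]
                        all_sites = tuple(
                            sorted(req_sites + extra_sites, key=lambda s: s.position)
                        )
                        for state in label_states:
                            labeled: tuple[int, ...] = ()
                            if state == "H":
                                labeled = tuple(
                                    i
                                    for i, res in enumerate(pep_seq, start=1)
                                    if res in labels.deltas
                                )
                                if not labeled:
                                    # no labelable residue: the heavy channel
                                    # is indistinguishable from light
                                    continue
                            pep = ModifiedPeptide(
                                pep_seq,
                                mods=all_sites,
                                labeled_positions=labeled,
                                protein=protein,
                                start=base.start,
                                mutation=mutation,
                            )
                            counts = _mod_counts(all_sites)
                            comp = _composition_label(counts, base.missed)
                            mod_str = pep.describe_mods()
                            pair = f"{pep_seq}|{base.missed}XC|{mod_str}" + (
                                f"|{mutation}" if mutation else ""
                            )
                            vid = pair + (f"|{state}" if state != "-" else "")
                            raw.append(
                                Variant(
                                    variant_id=vid,
                                    pair_id=pair,
                                    peptide=pep,
                                    mono=mono_mass(pep, labels),
                                    avg=avg_mass(pep, labels),
                                    missed=base.missed,
                                    mod_counts=counts,
                                    n_extra=k,
                                    label_state=state,
                                    mutation=mutation,
                                    compositions=(comp,),
                                )
                            )
                            if len(raw) > MAX_VARIANTS_PER_ASSAY:
                                raise VariantOverflowError(
                                    f"variant space of {base.sequence} exceeds "
                                    f"{MAX_VARIANTS_PER_ASSAY}"
                                )

    # collapse duplicate masses (same label state)
    collapsed: dict[tuple[str, float], Variant] = {}
    for v in raw:
        key = (v.label_state, round(v.mono, 6))
        if key not in collapsed:
            collapsed[key] = v
        else:
            kept = collapsed[key]
            comps = tuple(dict.fromkeys(kept.compositions + v.compositions))
            collapsed[key] = Variant(
                **{
                    **kept.__dict__,
                    "multiplicity": kept.multiplicity + 1,
                    "compositions": comps,
                }
            )
    return sorted(collapsed.values(), key=lambda v: (v.mono, v.label_state))


@dataclass(frozen=True)
class AssayDefinition:
    """One antibody's validated peptide variants with reference masses."""

    assay_id: str
    accession: str
    protein_name: str
    designation: str  # e.g. "p(S235 & S236)" or "Total, C-terminal"
    epitope: EpitopeSpec
    protease: ProteaseRule
    max_missed: int
    variants: tuple[Variant, ...]
    labels: LabelScheme | None = None

    def variant(self, variant_id: str) -> Variant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    @property
    def reference_masses(self) -> list[float]:
        return [v.mono for v in self.variants]


def build_assay(
    assay_id: str,
    region_sequence: str,
    epitope: EpitopeSpec,
    protease: ProteaseRule,
    *,
    offset: int = 1,
    max_missed: int = 2,
    required_mods: Sequence[tuple[int, Modification]] = (),
    any_of: bool = False,
    variable_rules: Sequence[VariableModRule] = (),
    max_extra: int = 0,
    mutations: Sequence[tuple[int, str]] = (),
    labels: LabelScheme | None = None,
    protein_name: str = "",
    designation: str = "",
) -> AssayDefinition:
    """Digest the region, keep epitope-covering peptides, enumerate variants.

    Raises :class:`EpitopeDestroyedError` (naming the offending cut site)
    when the protease cuts inside the epitope so that no covering peptide
    exists at the missed-cleavage ceiling.
    """
    covering = peptides_covering_epitope(
        region_sequence, epitope, protease, max_missed, offset
    )
    if not covering:
        sites = [
            offset + c
            for c in cut_sites(region_sequence, protease)
            if epitope.start <= offset + c - 1 < epitope.end
        ]
        detail = (
            f" ({protease.name} cuts after position {sites[0] - 1})" if sites else ""
        )
        raise EpitopeDestroyedError(
            f"no peptide covers epitope {epitope.start}-{epitope.end} "
            f"with {protease.name} at <= {max_missed} missed cleavages{detail}"
        )
    variants: list[Variant] = []
    for pep in covering:
        variants.extend(
            enumerate_variants(
                pep,
                required_mods=required_mods,
                variable_rules=variable_rules,
                max_extra=max_extra,
                any_of=any_of,
                mutations=mutations,
                labels=labels,
                protein=epitope.protein,
            )
        )
        if len(variants) > MAX_VARIANTS_PER_ASSAY:
            raise VariantOverflowError(
                f"assay {assay_id} exceeds {MAX_VARIANTS_PER_ASSAY} variants"
            )
    return AssayDefinition(
        assay_id=assay_id,
        accession=epitope.protein,
        protein_name=protein_name,
        designation=designation,
        epitope=epitope,
        protease=protease,
        max_missed=max_missed,
        variants=tuple(variants),
        labels=labels,
    )


@dataclass(frozen=True)
class MassCollision:
    assay_a: str
    variant_a: str
    assay_b: str
    variant_b: str
    delta: float


@dataclass
class AssayPanel:
    """Compiled, searchable reference database for a multiplexed experiment."""

    assays: tuple[AssayDefinition, ...]
    linear_tol: float = 0.25
    reflector_ppm: float = 25.0
    collisions: tuple[MassCollision, ...] = ()
    _masses: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _records: tuple[tuple[str, Variant], ...] = field(default=(), repr=False)

    def assay(self, assay_id: str) -> AssayDefinition:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)

    @property
    def index_size(self) -> int:
        return len(self._records)

    def candidates(self, mz: float, tol: float) -> list[tuple[str, Variant, float]]:
        """(assay_id, variant, error) for every reference mass within tol of mz."""
        lo = np.searchsorted(self._masses, mz - tol)
        hi = np.searchsorted(self._masses, mz + tol)
        out = []
        for i in range(lo, hi):
            aid, var = self._records[i]
            out.append((aid, var, mz - var.mono))
        return out


def compile_panel(
    assays: Sequence[AssayDefinition],
    linear_tol: float = 0.25,
    reflector_ppm: float = 25.0,
) -> AssayPanel:
    """Sort every reference mass into one index; record cross-assay collisions.

    Collisions (two assays' reference masses within the linear tolerance)
    are warnings, not errors: compilation succeeds and the report lets the
    panel designer decide.
    """
    if not assays:
        raise ValueError("panel needs at least one assay")
    ids = [a.assay_id for a in assays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate assay ids")
    records = sorted(
        ((a.assay_id, v) for a in assays for v in a.variants),
        key=lambda t: t[1].mono,
    )
    masses = np.array([v.mono for _, v in records])
    collisions: list[MassCollision] = []
    for i in range(len(records)):
        j = i + 1
        while j < len(records) and masses[j] - masses[i] <= linear_tol:
            if records[i][0] != records[j][0]:
                collisions.append(
                    MassCollision(
                        records[i][0],
                        records[i][1].variant_id,
                        records[j][0],
                        records[j][1].variant_id,
                        float(masses[j] - masses[i]),
                    )
                )
            j += 1
    return AssayPanel(
        assays=tuple(assays),
        linear_tol=linear_tol,
        reflector_ppm=reflector_ppm,
        collisions=tuple(collisions),
        _masses=masses,
        _records=tuple(records),
    )
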