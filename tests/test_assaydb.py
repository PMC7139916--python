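"""Assay building and panel compilation: variant spaces, masses, collisions."""

import itertools
import math

import numpy as np
import pytest

from maldiplex.assaydb import (
    VariableModRule,
    VariantOverflowError,
    build_assay,
    compile_panel,
    enumerate_variants,
)
from maldiplex.chem import (
    MODIFICATIONS,
    SILAC_K8_R10,
    avg_mass,
    mono_mass,
)
from maldiplex.digest import (
    CHYMOTRYPSIN,
    TRYPSIN,
    DigestPeptide,
    EpitopeDestroyedError,
    EpitopeSpec,
)

PHOS = MODIFICATIONS["phospho"]
ACETYL = MODIFICATIONS["acetyl"]


def dp(seq, start=1, missed=0, before="-", after="-"):
    return DigestPeptide(seq, start, start + len(seq) - 1, missed, before, after)


def test_no_variables_yields_single_required_variant():
    base = dp("RLSVELTSSLFR", start=673, missed=1)
    variants = enumerate_variants(base, required_mods=[(675, PHOS)])
    assert len(variants) == 1
    v = variants[0]
    assert v.mono == pytest.approx(1487.762, abs=1e-3)
    assert v.mod_counts == {"phospho": 1}


def test_variant_count_is_binomial_sum():
    """m eligible residues with <= e extras gives sum C(m, k) variants."""
    base = dp("RLSSLRASTSKSESSQK", start=233, missed=3)
    for e in range(0, 4):
        variants = enumerate_variants(
            base,
            required_mods=[(235, PHOS), (236, PHOS)],
            variable_rules=[VariableModRule(PHOS, frozenset("ST"))],
            max_extra=e,
        )
        m = 6  # S/T positions outside the two required serines
        expected_forms = sum(math.comb(m, k) for k in range(e + 1))
        assert sum(v.multiplicity for v in variants) == expected_forms
        # masses collapse to one entry per extra-phospho count
        assert len(variants) == e + 1


def test_ladder_masses_are_arithmetic_in_phospho():
    base = dp("RLSSLRASTSKSESSQK", start=233, missed=3)
    variants = enumerate_variants(
        base,
        required_mods=[(235, PHOS), (236, PHOS)],
        variable_rules=[VariableModRule(PHOS, frozenset("ST"))],
        max_extra=3,
    )
    masses = sorted(v.mono for v in variants)
    assert masses[0] == pytest.approx(2011.921, abs=1e-3)
    assert np.allclose(np.diff(masses), 79.96633, atol=1e-9)


def test_any_of_semantics_gives_cross_reactive_singles_and_double():
    base = dp("RVVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", start=20, missed=1)
    variants = enumerate_variants(
        base, required_mods=[(37, PHOS), (46, PHOS)], any_of=True
    )
    masses = sorted(round(v.mono, 3) for v in variants)
    assert masses == [3283.599, 3363.566]
    single = variants[0] if variants[0].mono < variants[1].mono else variants[1]
    assert single.multiplicity == 2  # pT37 and pT46 collapse to one mass


def test_mutation_alleles_kept_alongside_wild_type():
    base = dp("RAGGEESQFEMDI", start=106, missed=1)
    variants = enumerate_variants(base, mutations=[(107, "V")])
    masses = sorted(round(v.mono, 3) for v in variants)
    assert masses == [1468.637, 1496.669]
    mutant = next(v for v in variants if v.mutation)
    assert mutant.mutation == "A107V"
    assert mutant.peptide.sequence == "RVGGEESQFEMDI"


def test_labels_double_the_space_with_correct_shifts():
    base = dp("DMYDKEYYSVHNK", start=1228, missed=1)
    variants = enumerate_variants(
        base, required_mods=[(1234, PHOS), (1235, PHOS)], labels=SILAC_K8_R10
    )
    by_state = {v.label_state: v for v in variants}
    assert by_state["L"].mono == pytest.approx(1851.670, abs=1e-3)
    assert by_state["H"].mono == pytest.approx(1867.670, abs=1e-3)
    assert by_state["L"].pair_id == by_state["H"].pair_id


def test_required_mod_on_incompatible_residue_is_rejected():
    base = dp("RAGGEESQFEMDI", start=106, missed=1)
    with pytest.raises(ValueError, match="incompatible"):
        enumerate_variants(base, required_mods=[(107, PHOS)])  # A107


def test_variant_overflow_is_an_explicit_error():
    base = dp("SSSSSSSSSSSSSSSSSSSS")
    with pytest.raises(VariantOverflowError):
        enumerate_variants(
            base,
            variable_rules=[VariableModRule(PHOS, frozenset("S"))],
            max_extra=20,
            labels=SILAC_K8_R10,
        )


def test_build_assay_4ebp1_total_reference_masses(regions):
    region = regions["4EBP1_CT"]
    assay = build_assay(
        "ebp1_total",
        region.sequence,
        EpitopeSpec("4EBP1_CT", 109, 118),
        TRYPSIN,
        offset=region.start,
        max_missed=2,
    )
    masses = sorted(round(v.mono, 3) for v in assay.variants)
    assert masses == [1312.536, 1468.637, 2138.929]


def test_build_assay_pt37_46_reference_masses(regions):
    region = regions["4EBP1_NT"]
    assay = build_assay(
        "ebp1_pt37_46",
        region.sequence,
        EpitopeSpec("4EBP1_NT", 37, 46, required_sites=(37, 46), any_of=True),
        TRYPSIN,
        offset=region.start,
        max_missed=1,
        required_mods=[(37, PHOS), (46, PHOS)],
        any_of=True,
    )
    masses = sorted(round(v.mono, 3) for v in assay.variants)
    assert masses == [3127.498, 3207.465, 3283.599, 3363.566]


def test_build_assay_cmet_average_mass_for_two_missed(regions):
    region = regions["CMET"]
    assay = build_assay(
        "cmet",
        region.sequence,
        EpitopeSpec("CMET", 1234, 1235),
        TRYPSIN,
        offset=region.start,
        max_missed=1,
        required_mods=[(1234, PHOS), (1235, PHOS)],
    )
    by_seq = {v.peptide.sequence: v for v in assay.variants}
    assert set(by_seq) == {"EYYSVHNK", "EYYSVHNKTGAK", "DMYDKEYYSVHNK"}
    # independent average-table computation (printed value differs by ~0.01
    # from any standard average table; the computed value is authoritative)
    v = by_seq["DMYDKEYYSVHNK"]
    assert v.avg == pytest.approx(avg_mass(v.peptide), abs=1e-9)
    assert v.avg == pytest.approx(1852.815, abs=0.05)


def test_build_assay_epitope_destroyed_names_cut_site():
    with pytest.raises(EpitopeDestroyedError, match="trypsin"):
        build_assay(
            "bad",
            "AAKRAA",
            EpitopeSpec("X", 3, 5),
            TRYPSIN,
            max_missed=0,
        )


def test_every_stored_mass_recomputes_from_its_peptide(panel):
    for assay in panel.assays:
        for v in assay.variants:
            assert v.mono == pytest.approx(
                mono_mass(v.peptide, assay.labels), abs=1e-9
            )
            assert v.avg == pytest.approx(avg_mass(v.peptide, assay.labels), abs=1e-9)


def test_panel_compilation_is_deterministic(panel):
    from maldiplex.demo import demo_panel

    again = demo_panel()
    assert [a.assay_id for a in again.assays] == [a.assay_id for a in panel.assays]
    assert [
        (aid, v.variant_id, v.mono)
        for a, b in zip(panel.assays, again.assays)
        for aid, v in ((a.assay_id, w) for w in b.variants)
    ] == [
        (a.assay_id, v.variant_id, v.mono) for a in panel.assays for v in a.variants
    ]


def test_demo_panel_has_no_cross_assay_collisions(panel):
    """Pairwise distance check: all 8 assays separable at +/- 0.25 Da."""
    assert panel.collisions == ()
    records = [
        (a.assay_id, v.mono) for a in panel.assays for v in a.variants
    ]
    for (ida, ma), (idb, mb) in itertools.combinations(records, 2):
        if ida != idb:
            assert abs(ma - mb) > 0.25


def test_single_assay_panel_index_length(panel):
    single = compile_panel([panel.assays[0]])
    assert single.index_size == len(panel.assays[0].variants)


def test_colliding_assays_compile_with_warning(regions):
    region = regions["4EBP1_CT"]
    kwargs = dict(offset=region.start, max_missed=2)
    a = build_assay(
        "a", region.sequence, EpitopeSpec("4EBP1_CT", 109, 118), TRYPSIN, **kwargs
    )
    b = build_assay(
        "b", region.sequence, EpitopeSpec("4EBP1_CT", 109, 118), TRYPSIN, **kwargs
    )
    compiled = compile_panel([a, b])
    assert len(compiled.collisions) > 0
    with pytest.raises(ValueError, match="duplicate"):
        compile_panel([a, a])
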