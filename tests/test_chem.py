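"""Mass engine: published masses, independent elemental oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as ptmass

from maldiplex.chem import (
    MODIFICATIONS,
    PROTON,
    RESIDUE_MASSES,
    SILAC_K8_R10,
    SIS_K8_V6,
    WATER_AVG,
    WATER_MONO,
    ModifiedPeptide,
    ModSite,
    UnknownResidueError,
    apply_substitution,
    avg_mass,
    fragment_ions,
    label_delta,
    mono_mass,
)

PHOS = MODIFICATIONS["phospho"]
CAM = MODIFICATIONS["carbamidomethyl"]

RESIDUES = sorted(RESIDUE_MASSES.mono)
seqs = st.text(alphabet=RESIDUES, min_size=1, max_size=30)


def pep(seq, phospho=(), cam=(), labeled=()):
    mods = tuple(ModSite(p, PHOS) for p in phospho) + tuple(ModSite(p, CAM) for p in cam)
    return ModifiedPeptide(seq, mods=mods, labeled_positions=tuple(labeled))


# Theoretical MH+ values as printed for the validated assays (3 decimals).
PUBLISHED_MONO = [
    (pep("AGGEESQFEMDI"), None, 1312.536),
    (pep("RAGGEESQFEMDI"), None, 1468.637),
    (pep("NSPEDKRAGGEESQFEMDI"), None, 2138.929),
    (pep("RNSPEDKRAGGEESQFEMDI"), None, 2295.030),
    (pep("RNSPEDKRAGGEESQFEMDI", phospho=(3,)), None, 2374.997),
    (pep("RVGGEESQFEMDI"), None, 1496.669),
    (pep("VVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", phospho=(17,)), None, 3127.498),
    (pep("VVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", phospho=(17, 26)), None, 3207.465),
    (pep("RVVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", phospho=(18,)), None, 3283.599),
    (pep("RVVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", phospho=(18, 27)), None, 3363.566),
    (pep("VADPDHDHTGFLTEYVATR", phospho=(13, 15)), None, 2303.937),
    (pep("IADPEHDHTGFLTEYVATR", phospho=(13, 15)), None, 2331.968),
    (pep("RLSSLRASTSKSESSQK", phospho=(3, 4)), None, 2011.921),
    (pep("RRLSSLRASTSKSESSQK", phospho=(4, 5)), None, 2168.022),
    (pep("TRTDSYSAGQSVEILDGVELGEPAHK", phospho=(5,)), None, 2839.315),
    (pep("YCRPESQEHPEADPGSAAPYLK", phospho=(20,), cam=(2,)), None, 2582.102),
    (pep("DMYDKEYYSVHNK", phospho=(7, 8)), None, 1851.670),
    (pep("DMYDKEYYSVHNK", phospho=(7, 8), labeled=(5, 13)), SILAC_K8_R10, 1867.670),
    (pep("DMYDKEYYSVHNK", phospho=(7, 8), labeled=(10, 13)), SIS_K8_V6, 1865.670),
    (pep("HSSYPAGTEDDEGMGEEPSPFR", phospho=(3,)), None, 2474.944),
    (pep("RLSVELTSSLFR", phospho=(3,)), None, 1487.762),
    (pep("RPHFPQFSYSASGTA"), None, 1652.782),
]


@pytest.mark.parametrize("peptide,scheme,expected", PUBLISHED_MONO)
def test_mono_mass_reproduces_published_values(peptide, scheme, expected):
    assert mono_mass(peptide, scheme) == pytest.approx(expected, abs=1.5e-3)


def test_single_glycine_masses_follow_constant_table():
    assert mono_mass("G") == pytest.approx(57.02146 + WATER_MONO + PROTON, abs=1e-9)
    assert round(mono_mass("G"), 3) == 76.039
    assert round(avg_mass("G"), 3) == 76.074


@settings(max_examples=40, deadline=None)
@given(seqs)
def test_mono_mass_matches_elemental_composition_oracle(seq):
    """Independent oracle: summed atomic composition via pyteomics."""
    expected = ptmass.calculate_mass(sequence=seq) + PROTON
    assert mono_mass(seq) == pytest.approx(expected, abs=1e-4)


@settings(max_examples=25, deadline=None)
@given(seqs)
def test_avg_mass_exceeds_mono_and_tracks_elemental_oracle(seq):
    assert avg_mass(seq) > mono_mass(seq)
    # independent isotope-abundance tables differ by a few mDa per residue
    oracle = ptmass.calculate_mass(sequence=seq, average=True) + PROTON
    assert avg_mass(seq) == pytest.approx(oracle, abs=0.01 + 0.005 * len(seq))


@settings(max_examples=25, deadline=None)
@given(seqs, seqs)
def test_concatenation_identity(a, b):
    lhs = mono_mass(a + b)
    rhs = mono_mass(a) + mono_mass(b) - WATER_MONO - PROTON
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_phospho_ladder_spacing_is_constant():
    seq = "RLSSLRASTSKSESSQK"
    ladder = [
        mono_mass(pep(seq)),
        mono_mass(pep(seq, phospho=(3,))),
        mono_mass(pep(seq, phospho=(3, 4))),
        mono_mass(pep(seq, phospho=(3, 4, 9))),
    ]
    diffs = np.diff(ladder)
    assert np.allclose(diffs, 79.96633, atol=1e-9)


def test_mutation_delta_equals_residue_difference():
    wt = pep("RAGGEESQFEMDI")
    mut = apply_substitution(wt, 2, "V")
    assert mut.sequence == "RVGGEESQFEMDI"
    delta = mono_mass(mut) - mono_mass(wt)
    assert delta == pytest.approx(99.06841 - 71.03711, abs=1e-9)
    assert delta == pytest.approx(28.0313, abs=1e-4)


def test_label_deltas_nominal_and_exact():
    both_k = pep("DMYDKEYYSVHNK", labeled=(5, 13))
    assert label_delta(both_k, SILAC_K8_R10) == 16.0
    two_r = pep("RVVLGDGVQLPPGDYSTTPGGTLFSTTPGGTR", labeled=(1, 32))
    assert label_delta(two_r, SILAC_K8_R10) == 20.0
    one_k = pep("DMYDKEYYSVHNK", labeled=(13,))
    assert label_delta(one_k, SILAC_K8_R10.with_mode("exact")) == pytest.approx(
        8.0142, abs=1e-4
    )
    # nominal and exact stay within 0.05 Da per labelled residue
    assert abs(
        label_delta(both_k, SILAC_K8_R10)
        - label_delta(both_k, SILAC_K8_R10.with_mode("exact"))
    ) < 0.05 * 2


def test_fragment_ions_b_and_y_series():
    ions = dict(fragment_ions("RAGGEESQFEMDI", "b"))
    assert len(ions) == 12
    assert ions["b2"] == pytest.approx(156.10111 + 71.03711 + PROTON, abs=1e-6)
    assert round(ions["b2"], 3) == pytest.approx(228.146, abs=1.5e-3)
    gg = fragment_ions("GG", "b")
    assert len(gg) == 1
    assert gg[0][1] == pytest.approx(58.029, abs=1e-3)


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet=RESIDUES, min_size=2, max_size=20))
def test_fragment_complementarity(seq):
    """y_(n-1) + b_1 = MH+ + proton, and each b_i/y_(n-i) pair likewise."""
    b = dict(fragment_ions(seq, "b"))
    y = dict(fragment_ions(seq, "y"))
    total = mono_mass(seq) + PROTON
    n = len(seq)
    for i in range(1, n):
        assert b[f"b{i}"] + y[f"y{n - i}"] == pytest.approx(total, abs=1e-9)


def test_modified_fragments_shift_only_past_the_site():
    plain = dict(fragment_ions("VADPDHDHTGFLTEYVATR", "b"))
    phos = dict(fragment_ions(pep("VADPDHDHTGFLTEYVATR", phospho=(13,)), "b"))
    assert phos["b12"] == pytest.approx(plain["b12"], abs=1e-9)
    assert phos["b13"] - plain["b13"] == pytest.approx(79.96633, abs=1e-9)


def test_unknown_residue_is_rejected_with_position():
    with pytest.raises(UnknownResidueError, match="position 3"):
        ModifiedPeptide("AGXDE")
    with pytest.raises(ValueError):
        ModifiedPeptide("")


def test_modification_must_sit_on_allowed_residue():
    with pytest.raises(ValueError, match="not allowed"):
        pep("AGGEE", phospho=(1,))  # A cannot carry phospho
    with pytest.raises(ValueError, match="already carries"):
        ModifiedPeptide("AS", mods=(ModSite(2, PHOS), ModSite(2, PHOS)))


def test_residue_table_is_immutable_and_complete():
    assert len(RESIDUE_MASSES.mono) == 20
    assert all(RESIDUE_MASSES.mono[r] < RESIDUE_MASSES.avg[r] for r in RESIDUE_MASSES.mono)
    with pytest.raises(TypeError):
        RESIDUE_MASSES.mono["G"] = 0.0
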