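"""Decode randomly arrayed spots against a compiled assay panel.

Because beads settle into microwells at random, the analyte identity of
a spot is unknown until its spectrum is matched against the panel's
reference masses.  Matching is tolerance-based: an absolute window in
linear mode (0.25 Da strict, with a documented 0.5 Da fallback tier for
the mass accuracy actually seen in linear acquisitions) and a relative
ppm window in reflector mode.  The spot is assigned to the assay with
the highest summed matched intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .assaydb import AssayDefinition, AssayPanel, Variant
from .chem import LabelScheme, label_delta
from .spectra import Peak

__all__ = [
    "ToleranceSettings",
    "PeakMatch",
    "Annotation",
    "match_spot",
    "annotate_ladder",
    "find_silac_pairs",
    "SilacPair",
]


@dataclass(frozen=True)
class ToleranceSettings:
    """Matching windows per acquisition mode.

    ``linear_tol``: strict absolute window (Da).  ``linear_fallback``:
    wider second-tier window, reflecting that observed linear-mode masses
    can deviate by ~0.3 Da from calculation; fallback matches are tagged.
    ``reflector_ppm``: relative window for reflector mode.
    """

    linear_tol: float = 0.25
    linear_fallback: float = 0.5
    reflector_ppm: float = 25.0

    def __post_init__(self) -> None:
        if self.linear_tol <= 0 or self.reflector_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.linear_fallback < self.linear_tol:
            raise ValueError("fallback tolerance cannot be tighter than strict")

    def window(self, mz: float, mode: str, fallback: bool = False) -> float:
        if mode == "reflector":
            return mz * self.reflector_ppm * 1e-6
        return self.linear_fallback if fallback else self.linear_tol


@dataclass(frozen=True)
class PeakMatch:
    """One peak assigned to one reference variant; error = observed - expected."""

    assay_id: str
    variant: Variant
    observed_mz: float
    expected_mz: float
    error: float
    intensity: float
    tier: str  # 'strict' or 'fallback'


@dataclass(frozen=True)
class Annotation:
    """The decoded identity of one spot."""

    spot: str | None
    assay_id: str | None
    matches: tuple[PeakMatch, ...]
    unmatched: tuple[Peak, ...]
    explained_fraction: float


def match_spot(
    peaks: Sequence[Peak],
    panel: AssayPanel,
    mode: str = "linear",
    tol: ToleranceSettings | None = None,
    spot: str | None = None,
    allow_fallback: bool = True,
) -> Annotation:
    """Assign each peak to its nearest reference mass and decode the spot.

    Ties between equally plausible references go to the smaller absolute
    error, then the lower assay id.  The spot's assay is the one with the
    highest summed matched intensity; peaks matching no reference within
    the active tolerance are reported unmatched.
    """
    if panel.index_size == 0:
        raise ValueError("empty panel")
    tol = tol or ToleranceSettings(panel.linear_tol, max(panel.linear_tol, 0.5), panel.reflector_ppm)
    matches: list[PeakMatch] = []
    unmatched: list[Peak] = []
    for peak in peaks:
        strict_win = tol.window(peak.mz, mode, fallback=False)
        search_win = (
            tol.window(peak.mz, mode, fallback=True)
            if (mode == "linear" and allow_fallback)
            else strict_win
        )
        cands = panel.candidates(peak.mz, search_win)
        if not cands:
            unmatched.append(peak)
            continue
        aid, var, err = min(cands, key=lambda c: (abs(c[2]), c[0]))
        tier = "strict" if abs(err) <= strict_win else "fallback"
        matches.append(
            PeakMatch(
                assay_id=aid,
                variant=var,
                observed_mz=peak.mz,
                expected_mz=var.mono,
                error=err,
                intensity=peak.intensity,
                tier=tier,
            )
        )
    total = sum(p.intensity for p in peaks)
    if matches:
        by_assay: dict[str, float] = {}
        for m in matches:
            by_assay[m.assay_id] = by_assay.get(m.assay_id, 0.0) + m.intensity
        assay_id = max(sorted(by_assay), key=lambda a: by_assay[a])
        explained = by_assay[assay_id] / total if total > 0 else 0.0
    else:
        assay_id = None
        explained = 0.0
    return Annotation(
        spot=spot,
        assay_id=assay_id,
        matches=tuple(matches),
        unmatched=tuple(unmatched),
        explained_fraction=explained,
    )


def annotate_ladder(annotation: Annotation, assay: AssayDefinition) -> list[dict]:
    """Label each matched mass with its modification composition and XC level.

    For combinatorially modified targets (multiply phosphorylated tails,
    histone acetyl/methyl ladders) each matched reference corresponds to
    a composition such as '3p/3XC'.  When distinct compositions collapse
    onto one mass, all are reported and the row is flagged ambiguous.
    """
    rows: list[dict] = []
    for m in annotation.matches:
        if m.assay_id != assay.assay_id:
            continue
        v = m.variant
        rows.append(
            {
                "observed_mz": m.observed_mz,
                "expected_mz": m.expected_mz,
                "missed": v.missed,
                "label_state": v.label_state,
                "phospho": v.mod_counts.get("phospho", 0),
                "acetyl": v.mod_counts.get("acetyl", 0),
                "methyl": v.mod_counts.get("methyl", 0),
                "compositions": v.compositions,
                "ambiguous": len(v.compositions) > 1,
                "intensity": m.intensity,
            }
        )
    rows.sort(key=lambda r: r["expected_mz"])
    return rows


@dataclass(frozen=True)
class SilacPair:
    """A light/heavy peak pair for one peptide form (singletons allowed)."""

    pair_id: str
    light: Peak | None
    heavy: Peak | None
    delta: float  # expected heavy - light mass difference

    @property
    def status(self) -> str:
        if self.light and self.heavy:
            return "pair"
        return "light-only" if self.light else "heavy-only"


def find_silac_pairs(
    peaks: Sequence[Peak],
    assay: AssayDefinition,
    tol: ToleranceSettings | None = None,
    mode: str = "linear",
) -> list[SilacPair]:
    """Locate light/heavy peak pairs for every labelled variant of an assay.

    For each light/heavy reference pair, the nearest peak within
    tolerance of each channel is taken; if only one channel has a peak a
    singleton is reported so missing-channel ratios stay flagged rather
    than silently zero.
    """
    if assay.labels is None:
        raise ValueError(f"assay {assay.assay_id} declares no label scheme")
    tol = tol or ToleranceSettings()

    def nearest(mz: float) -> Peak | None:
        window = tol.window(mz, mode, fallback=(mode == "linear"))
        best = None
        for p in peaks:
            err = abs(p.mz - mz)
            if err <= window and (best is None or err < abs(best.mz - mz)):
                best = p
        return best

    by_pair: dict[str, dict[str, Variant]] = {}
    for v in assay.variants:
        if v.label_state in ("L", "H"):
            by_pair.setdefault(v.pair_id, {})[v.label_state] = v

    pairs: list[SilacPair] = []
    for pair_id in sorted(by_pair):
        channels = by_pair[pair_id]
        if "L" not in channels or "H" not in channels:
            continue
        light_ref, heavy_ref = channels["L"], channels["H"]
        lp = nearest(light_ref.mono)
        hp = nearest(heavy_ref.mono)
        if lp is None and hp is None:
            continue
        pairs.append(
            SilacPair(
                pair_id=pair_id,
                light=lp,
                heavy=hp,
                delta=heavy_ref.mono - light_ref.mono,
            )
        )
    return pairs
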