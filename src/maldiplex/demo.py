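"""Packaged demonstration panel and end-to-end simulation experiments.

The demo FASTA carries the protein regions behind a published
eight-assay multiplexed panel (4EBP1 x3, mTOR, CTNNB1, AKT1, BAD, RPS6),
with region offsets preserving native protein numbering.  The helpers
here run complete in silico experiments against that panel: random-array
spot decoding and SILAC ratio recovery, both fully seeded.
"""

from __future__ import annotations

import importlib.resources
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import ToleranceSettings, find_silac_pairs, match_spot
from .assaydb import AssayPanel, Variant
from .io import ProteinRegion, load_panel_config, read_fasta
from .quant import ReplicateSummary, ratio_from_pair, replicate_stats
from .spectra import SimulationParams, Spectrum, pick_peaks, simulate_spectrum, subtract_baseline

__all__ = [
    "demo_regions",
    "demo_panel",
    "TABLE1_RATIOS_HL",
    "TABLE1_LIGHT_MASSES",
    "representative_pair",
    "simulate_assay_spot",
    "decoding_experiment",
    "silac_experiment",
]

# Published average H:L ratios for the demo panel's representative peptides.
TABLE1_RATIOS_HL: Mapping[str, float] = {
    "ebp1_total": 1.22,
    "mtor_ps2448": 0.15,
    "ctnnb1_ps675": 1.73,
    "akt1_total": 2.89,
    "ebp1_pt37_46": 0.25,
    "ebp1_ps65_t70": 0.01,
    "bad_ps75": 0.33,
    "rps6_ps235_236": 0.04,
}

# Calculated light-channel MH+ of each assay's representative reference peptide.
TABLE1_LIGHT_MASSES: Mapping[str, float] = {
    "ebp1_total": 1468.637,
    "mtor_ps2448": 2839.315,
    "ctnnb1_ps675": 1487.762,
    "akt1_total": 1652.782,
    "ebp1_pt37_46": 3363.566,
    "ebp1_ps65_t70": 3985.840,
    "bad_ps75": 2474.944,
    "rps6_ps235_236": 2011.921,
}


def demo_regions() -> list[ProteinRegion]:
    ref = importlib.resources.files("maldiplex").joinpath("data/demo_proteins.fasta")
    with importlib.resources.as_file(ref) as path:
        return read_fasta(path)


def demo_panel() -> AssayPanel:
    ref = importlib.resources.files("maldiplex").joinpath("data/demo_panel.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_panel_config(path, demo_regions())


def representative_pair(panel: AssayPanel, assay_id: str) -> tuple[Variant, Variant]:
    """The (light, heavy) reference variants at the assay's published mass."""
    assay = panel.assay(assay_id)
    target = TABLE1_LIGHT_MASSES[assay_id]
    light = min(
        (v for v in assay.variants if v.label_state == "L"),
        key=lambda v: abs(v.mono - target),
    )
    if abs(light.mono - target) > 0.01:
        raise ValueError(f"no reference variant near {target} in {assay_id}")
    heavy = next(
        v
        for v in assay.variants
        if v.pair_id == light.pair_id and v.label_state == "H"
    )
    return light, heavy


def simulate_assay_spot(
    panel: AssayPanel,
    assay_id: str,
    seed: int,
    ratio_hl: float | None = None,
    min_snr: float = 50.0,
    noise_sd: float = 1.0,
    baseline: float = 5.0,
    spot: str | None = None,
) -> Spectrum:
    """Simulate one micro-spot spectrum for a single assay's bead.

    Without a ratio the spot contains the assay's light-channel variants;
    with one it contains the representative SILAC pair, scaled so the
    weaker channel still reaches ``min_snr`` times the noise floor.
    """
    if ratio_hl is None:
        variants = [v for v in panel.assay(assay_id).variants if v.label_state in ("L", "-")]
        rng = np.random.default_rng(seed + 1)
        peaks = [
            (v.mono, min_snr * noise_sd * float(rng.uniform(1.0, 3.0)))
            for v in variants
        ]
    else:
        light, heavy = representative_pair(panel, assay_id)
        light_h = min_snr * noise_sd * max(1.0, 1.0 / ratio_hl)
        peaks = [(light.mono, light_h), (heavy.mono, light_h * ratio_hl)]
    params = SimulationParams(
        peaks=tuple(peaks),
        seed=seed,
        noise_sd=noise_sd,
        baseline_amplitude=baseline,
    )
    return simulate_spectrum(params, spot=spot)


def decoding_experiment(
    panel: AssayPanel,
    n_spots: int = 100,
    seed: int = 0,
    min_snr: float = 20.0,
    tol: ToleranceSettings | None = None,
) -> tuple[int, int]:
    """Random-array decoding: simulate spots, re-identify them, count hits.

    Spots are drawn uniformly from the panel's assays; each is simulated,
    baseline-subtracted, peak-picked and matched back against the panel.
    Returns (correct, total).
    """
    rng = np.random.default_rng(seed)
    ids = [a.assay_id for a in panel.assays]
    correct = 0
    for i in range(n_spots):
        truth = ids[int(rng.integers(len(ids)))]
        spot_seed = int(rng.integers(2**31 - 1))
        spec = simulate_assay_spot(
            panel, truth, seed=spot_seed, min_snr=min_snr, spot=f"S{i:03d}"
        )
        peaks = pick_peaks(subtract_baseline(spec))
        ann = match_spot(peaks, panel, mode=spec.mode, tol=tol, spot=spec.spot)
        if ann.assay_id == truth:
            correct += 1
    return correct, n_spots


def silac_experiment(
    panel: AssayPanel,
    ratios_hl: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    min_snr: float = 20.0,
) -> dict[str, ReplicateSummary]:
    """Inject known H:L ratios, run annotate -> quantify, summarize recovery."""
    ratios_hl = dict(ratios_hl if ratios_hl is not None else TABLE1_RATIOS_HL)
    rng = np.random.default_rng(seed)
    out: dict[str, ReplicateSummary] = {}
    for assay_id, true_ratio in ratios_hl.items():
        assay = panel.assay(assay_id)
        light_ref, _ = representative_pair(panel, assay_id)
        observed: list[float] = []
        for rep in range(n_replicates):
            spec = simulate_assay_spot(
                panel,
                assay_id,
                seed=int(rng.integers(2**31 - 1)),
                ratio_hl=true_ratio,
                min_snr=min_snr,
            )
            peaks = pick_peaks(subtract_baseline(spec))
            pairs = find_silac_pairs(peaks, assay)
            for pair in pairs:
                if pair.pair_id != light_ref.pair_id:
                    continue
                rec = ratio_from_pair(pair, assay_id, "H:L", replicate=f"r{rep + 1}")
                if rec.defined:
                    observed.append(rec.ratio)
        if not observed:
            raise RuntimeError(f"no ratio recovered for {assay_id}")
        out[assay_id] = replicate_stats(observed)
    return out
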