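"""File formats, array geometry and run configuration.

Native interchange formats are plain text: FASTA for proteins (regions
may carry a ``region_start=N`` key in the header to keep native protein
numbering), two-column peak/profile files for spectra, tab-separated
tables for compiled panels, annotations and quantification, and
YAML/JSON for panel and run configuration.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from . import chem
from .assaydb import AssayDefinition, AssayPanel, VariableModRule, build_assay, compile_panel
from .calibrate import CalMeasurement
from .chem import MODIFICATIONS, SILAC_K8_R10, LabelScheme
from .digest import PROTEASES, EpitopeSpec
from .spectra import Peak, Spectrum

__all__ = [
    "ProteinRegion",
    "read_fasta",
    "read_peaklist",
    "write_peaklist",
    "read_spectrum",
    "write_spectrum",
    "panel_table",
    "write_panel_table",
    "annotation_table",
    "quant_table",
    "read_calibration_table",
    "write_calibration_table",
    "load_panel_config",
    "ArrayLayout",
    "layout_coordinates",
    "RunConfig",
]


@dataclass(frozen=True)
class ProteinRegion:
    """A protein (or region of one) with its native start coordinate."""

    accession: str
    sequence: str
    start: int = 1
    description: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def read_fasta(path: str | Path) -> list[ProteinRegion]:
    """Read protein records; a ``region_start=N`` header token sets numbering."""
    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        start = 1
        for token in rec.description.split():
            if token.startswith("region_start="):
                start = int(token.split("=", 1)[1])
        regions.append(
            ProteinRegion(
                accession=rec.id.split("|")[0],
                sequence=str(rec.seq).upper(),
                start=start,
                description=rec.description,
            )
        )
    return regions


def read_peaklist(path: str | Path) -> list[Peak]:
    """Two/three-column text: m/z, intensity[, snr]; malformed lines are named."""
    peaks: list[Peak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            mz = float(fields[0])
            intensity = float(fields[1])
            snr = float(fields[2]) if len(fields) > 2 else float("inf")
        except (ValueError, IndexError):
            raise ValueError(f"{path}: malformed peak list line {lineno}: {line!r}") from None
        peaks.append(Peak(mz=mz, intensity=intensity, snr=snr))
    return peaks


def write_peaklist(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# m/z\tintensity\tsnr\n")
        for p in peaks:
            fh.write(f"{p.mz:.4f}\t{p.intensity:.6g}\t{p.snr:.4g}\n")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Profile spectrum text: '#mode=', '#seed=' headers then m/z<TAB>intensity."""
    with open(path, "w") as fh:
        fh.write(f"#mode={spectrum.mode}\n")
        if spectrum.seed is not None:
            fh.write(f"#seed={spectrum.seed}\n")
        if spectrum.spot:
            fh.write(f"#spot={spectrum.spot}\n")
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.4f}\t{inten:.6g}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    mode, seed, spot = "linear", None, None
    mzs: list[float] = []
    intens: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "mode":
                mode = value
            elif key == "seed":
                seed = int(value)
            elif key == "spot":
                spot = value
            continue
        try:
            mz, inten = line.split("\t") if "\t" in line else line.split()
            mzs.append(float(mz))
            intens.append(float(inten))
        except ValueError:
            raise ValueError(f"{path}: malformed spectrum line {lineno}: {line!r}") from None
    import numpy as np

    mz_arr = np.array(mzs)
    return Spectrum(
        mz=mz_arr,
        intensity=np.array(intens),
        mode=mode,
        mass_range=(float(mz_arr.min()), float(mz_arr.max())) if mzs else (750.0, 7000.0),
        spot=spot,
        seed=seed,
    )


def panel_table(panel: AssayPanel) -> pd.DataFrame:
    """Compiled reference table: one row per (assay, variant)."""
    rows = []
    for assay in panel.assays:
        for v in assay.variants:
            rows.append(
                {
                    "assay_id": assay.assay_id,
                    "accession": assay.accession,
                    "protein": assay.protein_name,
                    "designation": assay.designation,
                    "variant_id": v.variant_id,
                    "sequence": v.peptide.sequence,
                    "mods": v.peptide.describe_mods(),
                    "missed": v.missed,
                    "label_state": v.label_state,
                    "mutation": v.mutation or "-",
                    "mono_mass": round(v.mono, 4),
                    "avg_mass": round(v.avg, 4),
                    "multiplicity": v.multiplicity,
                }
            )
    return pd.DataFrame(rows)


def write_panel_table(panel: AssayPanel, path: str | Path) -> None:
    panel_table(panel).to_csv(path, sep="\t", index=False)


def annotation_table(annotations: Iterable) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        for m in ann.matches:
            rows.append(
                {
                    "spot": ann.spot,
                    "assay": ann.assay_id,
                    "variant": m.variant.variant_id,
                    "expected_mz": round(m.expected_mz, 4),
                    "observed_mz": round(m.observed_mz, 4),
                    "error_da": round(m.error, 4),
                    "error_ppm": round(1e6 * m.error / m.expected_mz, 2),
                    "intensity": m.intensity,
                    "tier": m.tier,
                }
            )
    return pd.DataFrame(rows)


def quant_table(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "assay_id": r.assay_id,
                "variant_id": r.variant_id,
                "replicate": r.replicate,
                "light": r.light,
                "heavy": r.heavy,
                "orientation": r.orientation,
                "ratio": r.ratio if r.ratio is not None else "undefined",
            }
        )
    return pd.DataFrame(rows)


def write_calibration_table(measurements: Sequence[CalMeasurement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("level_fmol\treplicate\tratio\tdetected\n")
        for m in measurements:
            fh.write(f"{m.level_fmol:.6g}\t{m.replicate}\t{m.ratio:.6g}\t{int(m.detected)}\n")


def read_calibration_table(path: str | Path) -> list[CalMeasurement]:
    out: list[CalMeasurement] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            level, rep, ratio, detected = line.split("\t")
            out.append(
                CalMeasurement(
                    level_fmol=float(level),
                    replicate=int(rep),
                    ratio=float(ratio),
                    detected=bool(int(detected)),
                )
            )
        except ValueError:
            raise ValueError(f"{path}: malformed calibration line {lineno}: {line!r}") from None
    return out


def load_panel_config(
    path: str | Path, regions: Sequence[ProteinRegion]
) -> AssayPanel:
    """Build and compile a panel from a YAML/JSON config plus protein regions.

    Per-assay keys: id, accession, epitope_start, epitope_end,
    required_mods (list of 'phospho@S235'), any_of, variable_mods
    (list of 'phospho:ST'), max_extra, protease, max_missed,
    labels ('silac' or none), mutations (list of 'A107V'), protein, designation.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    by_acc = {r.accession: r for r in regions}
    assays: list[AssayDefinition] = []
    for entry in cfg["assays"]:
        region = by_acc[entry["accession"]]
        required = []
        for spec_str in entry.get("required_mods", []):
            mod_name, _, site = spec_str.partition("@")
            required.append((int(site[1:]), MODIFICATIONS[mod_name]))
        variable = []
        for spec_str in entry.get("variable_mods", []):
            mod_name, _, residues = spec_str.partition(":")
            variable.append(
                VariableModRule(MODIFICATIONS[mod_name], frozenset(residues))
            )
        mutations = []
        for mut in entry.get("mutations", []):
            mutations.append((int(mut[1:-1]), mut[-1]))
        labels = SILAC_K8_R10 if entry.get("labels") == "silac" else None
        epitope = EpitopeSpec(
            protein=entry["accession"],
            start=entry["epitope_start"],
            end=entry["epitope_end"],
            required_sites=tuple(pos for pos, _ in required),
            any_of=bool(entry.get("any_of", False)),
        )
        assays.append(
            build_assay(
                entry["id"],
                region.sequence,
                epitope,
                PROTEASES[entry.get("protease", "trypsin")],
                offset=region.start,
                max_missed=entry.get("max_missed", 2),
                required_mods=required,
                any_of=bool(entry.get("any_of", False)),
                variable_rules=variable,
                max_extra=entry.get("max_extra", 0),
                mutations=mutations,
                labels=labels,
                protein_name=entry.get("protein", region.accession),
                designation=entry.get("designation", ""),
            )
        )
    tol = cfg.get("tolerances", {})
    return compile_panel(
        assays,
        linear_tol=tol.get("linear_da", 0.25),
        reflector_ppm=tol.get("reflector_ppm", 25.0),
    )


@dataclass(frozen=True)
class ArrayLayout:
    """Micro-spot array geometry on a standard 25 x 75 mm slide.

    ``pitch_mm`` is centre-to-centre spot spacing; ``spot_um`` the spot
    diameter.  The default 26 x 88 grid at 0.8 mm pitch gives the
    2288-spot array of the 500 um gasket format.
    """

    rows: int = 26
    columns: int = 88
    pitch_mm: float = 0.8
    spot_um: float = 500.0
    slide_mm: tuple[float, float] = (25.0, 75.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.columns < 1 or self.pitch_mm <= 0:
            raise ValueError("invalid layout")
        height, width = self.slide_mm
        spot_mm = self.spot_um / 1000.0
        if (self.rows - 1) * self.pitch_mm + spot_mm > height:
            raise ValueError("rows do not fit the slide height")
        if (self.columns - 1) * self.pitch_mm + spot_mm > width:
            raise ValueError("columns do not fit the slide width")

    @property
    def n_spots(self) -> int:
        return self.rows * self.columns


def layout_coordinates(layout: ArrayLayout) -> list[tuple[str, float, float]]:
    """Row-major (spot id, x mm, y mm); origin at the top-left spot centre.

    x runs along the 75 mm slide axis (columns), y along the 25 mm axis.
    """
    margin = layout.spot_um / 2000.0
    coords = []
    for r in range(layout.rows):
        for c in range(layout.columns):
            coords.append(
                (
                    f"R{r + 1:02d}C{c + 1:02d}",
                    margin + c * layout.pitch_mm,
                    margin + r * layout.pitch_mm,
                )
            )
    return coords


@dataclass(frozen=True)
class RunConfig:
    """A fully serializable description of one pipeline run."""

    panel_path: str
    fasta_path: str
    mode: str = "linear"
    linear_tol: float = 0.25
    reflector_ppm: float = 25.0
    orientation: str = "H:L"
    seed: int = 0
    out_dir: str = "results"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def digest_hash(self) -> str:
        """Stable hash of the canonical config, for run provenance logging."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
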