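"""Relative quantification from paired peak intensities.

Ratios use peak height as the primary measure (peak area is available at
the spectrum level but height is the convention adopted here).  Ratio
orientation (H:L vs L:H) is explicit metadata everywhere — published
tables mix both conventions, so a silent default would corrupt results.
Undefined ratios (a missing channel) propagate as flagged records, never
as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .annotate import SilacPair
from .spectra import Spectrum

__all__ = [
    "QuantRecord",
    "ReplicateSummary",
    "pair_ratio",
    "ratio_from_pair",
    "replicate_stats",
    "fold_change",
    "normalize_to_reference",
]


@dataclass(frozen=True)
class QuantRecord:
    """One ratio observation for an assay variant in one replicate."""

    assay_id: str
    variant_id: str
    light: float
    heavy: float
    ratio: float | None
    orientation: str  # 'H:L' or 'L:H'
    replicate: str | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ratio and coefficient of variation over analytical replicates."""

    mean: float
    cv_percent: float | None  # None when n < 2
    n: int


def pair_ratio(light: float, heavy: float, orientation: str = "H:L") -> float | None:
    """Simple intensity quotient in the declared orientation.

    Returns None (an undefined, flagged ratio) when the denominator is
    zero; raises if both intensities are zero.
    """
    if orientation not in ("H:L", "L:H"):
        raise ValueError(f"orientation must be 'H:L' or 'L:H', got {orientation!r}")
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be non-negative")
    if light == 0 and heavy == 0:
        raise ValueError("both intensities are zero")
    num, den = (heavy, light) if orientation == "H:L" else (light, heavy)
    return None if den == 0 else num / den


def ratio_from_pair(
    pair: SilacPair,
    assay_id: str,
    orientation: str = "H:L",
    replicate: str | None = None,
) -> QuantRecord:
    """Build a QuantRecord from a located SILAC pair.

    A singleton (missing channel) always yields an undefined, flagged
    ratio — never a zero — regardless of orientation.
    """
    light = pair.light.intensity if pair.light else 0.0
    heavy = pair.heavy.intensity if pair.heavy else 0.0
    if pair.light is None or pair.heavy is None:
        ratio = None
    else:
        ratio = pair_ratio(light, heavy, orientation)
    return QuantRecord(
        assay_id=assay_id,
        variant_id=pair.pair_id,
        light=light,
        heavy=heavy,
        ratio=ratio,
        orientation=orientation,
        replicate=replicate,
    )


def replicate_stats(ratios: Sequence[float]) -> ReplicateSummary:
    """Mean and CV% (sample sd, n-1 denominator) of replicate ratios."""
    if len(ratios) == 0:
        raise ValueError("no ratios")
    arr = np.asarray(ratios, dtype=float)
    mean = float(arr.mean())
    if arr.size < 2:
        return ReplicateSummary(mean=mean, cv_percent=None, n=1)
    sd = float(arr.std(ddof=1))
    return ReplicateSummary(mean=mean, cv_percent=100.0 * sd / mean, n=arr.size)


def fold_change(a: ReplicateSummary, b: ReplicateSummary) -> float:
    """Quotient of mean ratios (a over b); scale-invariant in both channels."""
    if b.mean == 0:
        raise ZeroDivisionError("denominator summary has zero mean")
    return a.mean / b.mean


def normalize_to_reference(
    spectra: Iterable[Spectrum], reference_mz: float, tol: float = 0.5
) -> list[Spectrum]:
    """Scale each spectrum so the reference peak's height equals 1.

    The reference is the highest intensity within ``tol`` of
    ``reference_mz``; a spectrum lacking signal there is a named failure
    rather than a silently unscaled output.  Intra-spectrum intensity
    ratios are preserved exactly.
    """
    out: list[Spectrum] = []
    for i, spec in enumerate(spectra):
        window = (spec.mz >= reference_mz - tol) & (spec.mz <= reference_mz + tol)
        if not window.any():
            raise ValueError(
                f"reference m/z {reference_mz} outside spectrum {spec.spot or i}"
            )
        ref = float(spec.intensity[window].max())
        if ref <= 0:
            raise ValueError(
                f"no reference peak at {reference_mz} +/- {tol} in spectrum {spec.spot or i}"
            )
        out.append(replace(spec, intensity=spec.intensity / ref))
    return out
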