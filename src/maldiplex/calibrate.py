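"""Spike calibration curves and replicate-rule LOD/LOQ.

A forward curve spikes a constant heavy standard and a serial dilution
of light synthetic peptide into background; its low-spike plateau
reports the endogenous analyte level.  A reverse curve varies the heavy
standard against constant light and yields the assay's detection limits.
"Identifiable" is operationalized as a matched peak within the active
mass tolerance at S/N >= 3.  The LOD is the lowest spike level detected
in more than half of its replicates (>= 2 of 3); the LOQ additionally
requires the replicate ratio CV to stay below 30%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quant import replicate_stats

__all__ = [
    "SpikeDesign",
    "CalMeasurement",
    "CurveFit",
    "CalibrationResult",
    "build_design",
    "simulate_calibration",
    "fit_curve",
    "lod",
    "loq",
    "endogenous_estimate",
    "median_replicate_cv",
    "calibrate",
]


@dataclass(frozen=True)
class SpikeDesign:
    """Spike-in layout: orientation, constant channel, level series, replicates."""

    orientation: str  # 'forward' (constant heavy, varied light) or 'reverse'
    constant_fmol: float
    levels: tuple[float, ...]  # strictly decreasing; may end with a 0.0 blank
    replicates: int = 3
    background: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(b >= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly decreasing")

    @property
    def spiked_levels(self) -> tuple[float, ...]:
        return tuple(l for l in self.levels if l > 0)


@dataclass(frozen=True)
class CalMeasurement:
    """One replicate observation at one spike level."""

    level_fmol: float
    replicate: int
    ratio: float  # varied channel over constant channel
    detected: bool


@dataclass(frozen=True)
class CurveFit:
    """Log-log least squares of ratio vs spike on the retained linear levels."""

    slope: float
    intercept: float
    r_squared: float
    retained_levels: tuple[float, ...]
    excluded_levels: tuple[float, ...]
    dynamic_range: float  # log10 span of retained levels
    is_linear: bool


@dataclass(frozen=True)
class CalibrationResult:
    design: SpikeDesign
    measurements: tuple[CalMeasurement, ...]
    fit: CurveFit
    lod_fmol: float | None
    loq_fmol: float | None
    endogenous_fmol: float | None = None


def build_design(
    orientation: str,
    constant_fmol: float,
    top_fmol: float,
    dilution_factor: float,
    n_levels: int,
    include_blank: bool = False,
    replicates: int = 3,
    background: str = "",
) -> SpikeDesign:
    """Geometric dilution series from ``top_fmol`` (e.g. 10,000 / 3^k)."""
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    if top_fmol <= 0 or constant_fmol <= 0 or n_levels < 1:
        raise ValueError("amounts and level count must be positive")
    levels = [top_fmol / dilution_factor**k for k in range(n_levels)]
    if include_blank:
        levels.append(0.0)
    return SpikeDesign(
        orientation=orientation,
        constant_fmol=constant_fmol,
        levels=tuple(levels),
        replicates=replicates,
        background=background,
    )


def simulate_calibration(
    design: SpikeDesign,
    seed: int,
    endogenous_fmol: float = 0.0,
    cv: float = 0.2,
    noise_floor_fmol: float = 1.0,
    snr_threshold: float = 3.0,
) -> list[CalMeasurement]:
    """Seeded synthetic responses with multiplicative (lognormal) noise.

    The varied channel responds proportionally to spiked amount (plus the
    endogenous contribution on forward curves).  ``cv`` is the total
    assay-level coefficient of variation of the measured ratio, applied
    to the varied channel; a replicate is detected when its
    varied-channel signal reaches ``snr_threshold`` times the noise
    floor, mirroring the S/N >= 3 peak-detection rule.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))

    def jitter() -> float:
        return float(rng.lognormal(-(sigma**2) / 2.0, sigma))

    out: list[CalMeasurement] = []
    for level in design.levels:
        varied_true = level + (endogenous_fmol if design.orientation == "forward" else 0.0)
        for rep in range(1, design.replicates + 1):
            varied = varied_true * jitter()
            out.append(
                CalMeasurement(
                    level_fmol=level,
                    replicate=rep,
                    ratio=varied / design.constant_fmol,
                    detected=varied >= snr_threshold * noise_floor_fmol,
                )
            )
    return out


def _by_level(measurements: Sequence[CalMeasurement]) -> dict[float, list[CalMeasurement]]:
    grouped: dict[float, list[CalMeasurement]] = {}
    for m in measurements:
        grouped.setdefault(m.level_fmol, []).append(m)
    return grouped


def fit_curve(
    design: SpikeDesign,
    measurements: Sequence[CalMeasurement],
    residual_cutoff: float = 0.1,
    slope_tol: float = 0.2,
) -> CurveFit:
    """Least squares on log10(mean ratio) vs log10(spike), trimming nonlinearity.

    When the design includes a blank, its mean ratio (the endogenous
    response on a forward curve) is subtracted from every level first —
    the standard-addition correction — so the spike response itself is
    what gets fitted.  Levels whose residual exceeds ``residual_cutoff``
    (log10 units) are then excluded one at a time, worst first, dropping
    noise-dominated low levels and saturated ones.  The dynamic range is
    the log10 span of the retained levels.  At least 3 detected levels
    are required.
    """
    grouped = _by_level(measurements)
    blank = 0.0
    if 0.0 in design.levels and grouped.get(0.0):
        blank = float(np.mean([m.ratio for m in grouped[0.0]]))
    pts: list[tuple[float, float]] = []
    for level in design.spiked_levels:
        reps = [m for m in grouped.get(level, []) if m.detected]
        if len(reps) >= 1:
            mean_ratio = float(np.mean([m.ratio for m in reps])) - blank
            if mean_ratio > 0:
                pts.append((level, mean_ratio))
    if len(pts) < 3:
        raise ValueError(f"need >= 3 detected levels to fit, have {len(pts)}")

    retained = sorted(pts)
    excluded: list[float] = []
    while True:
        x = np.log10([p[0] for p in retained])
        y = np.log10([p[1] for p in retained])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        worst = int(np.argmax(np.abs(resid)))
        if abs(resid[worst]) <= residual_cutoff or len(retained) <= 3:
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            levels = tuple(p[0] for p in retained)
            return CurveFit(
                slope=float(slope),
                intercept=float(intercept),
                r_squared=r2,
                retained_levels=levels,
                excluded_levels=tuple(sorted(excluded)),
                dynamic_range=float(np.log10(max(levels) / min(levels))),
                is_linear=abs(slope - 1.0) <= slope_tol,
            )
        excluded.append(retained[worst][0])
        del retained[worst]


def lod(design: SpikeDesign, measurements: Sequence[CalMeasurement]) -> float | None:
    """Lowest spiked level detected in more than half of its replicates.

    With the canonical 3 replicates this is the at-least-2-of-3 rule;
    None means no level qualifies.
    """
    grouped = _by_level(measurements)
    qualifying = [
        level
        for level in design.spiked_levels
        if sum(m.detected for m in grouped.get(level, ()))
        > len(grouped.get(level, ())) / 2.0
        and grouped.get(level)
    ]
    return min(qualifying) if qualifying else None


def loq(
    design: SpikeDesign,
    measurements: Sequence[CalMeasurement],
    cv_limit: float = 30.0,
) -> float | None:
    """Lowest level passing the LOD rule with replicate ratio CV below the limit.

    Because the LOQ rule strictly contains the LOD rule, LOQ >= LOD on
    every input.
    """
    grouped = _by_level(measurements)
    qualifying = []
    for level in design.spiked_levels:
        reps = grouped.get(level, [])
        detected = [m for m in reps if m.detected]
        if not reps or len(detected) <= len(reps) / 2.0:
            continue
        if len(detected) < 2:
            continue
        stats = replicate_stats([m.ratio for m in detected])
        if stats.cv_percent is not None and stats.cv_percent < cv_limit:
            qualifying.append(level)
    return min(qualifying) if qualifying else None


def endogenous_estimate(
    design: SpikeDesign,
    measurements: Sequence[CalMeasurement],
    plateau_fraction: float = 1.0,
) -> float:
    """Endogenous amount from the low-spike plateau of a forward curve.

    At spike levels well below the endogenous amount the measured ratio
    plateaus at endogenous/constant.  The blank (or lowest level) seeds a
    first estimate; levels with spike <= ``plateau_fraction`` x that
    estimate form the plateau, and each plateau replicate contributes
    ratio x constant - spike.  The top of the curve never enters.
    """
    if design.orientation != "forward":
        raise ValueError("endogenous estimation requires a forward curve")
    grouped = _by_level(measurements)
    seed_level = min(design.levels)
    seed_ratios = [m.ratio for m in grouped.get(seed_level, [])]
    if not seed_ratios:
        raise ValueError("no measurements at the lowest level")
    first_guess = float(np.mean(seed_ratios)) * design.constant_fmol
    plateau_levels = [
        l for l in design.levels if l <= max(plateau_fraction * first_guess, seed_level)
    ]
    contributions = [
        m.ratio * design.constant_fmol - m.level_fmol
        for l in plateau_levels
        for m in grouped.get(l, [])
    ]
    if not contributions:
        raise ValueError("no plateau detected")
    return max(0.0, float(np.mean(contributions)))


def median_replicate_cv(measurements: Sequence[CalMeasurement]) -> float:
    """Median CV% across levels with >= 2 detected replicates."""
    cvs = []
    for level, reps in _by_level(measurements).items():
        detected = [m.ratio for m in reps if m.detected]
        if len(detected) >= 2:
            stats = replicate_stats(detected)
            if stats.cv_percent is not None:
                cvs.append(stats.cv_percent)
    if not cvs:
        raise ValueError("no level has >= 2 detected replicates")
    return float(np.median(cvs))


def calibrate(
    design: SpikeDesign,
    measurements: Sequence[CalMeasurement],
    residual_cutoff: float = 0.1,
    cv_limit: float = 30.0,
) -> CalibrationResult:
    """Fit the curve and apply the LOD/LOQ (and, forward, endogenous) rules."""
    fit = fit_curve(design, measurements, residual_cutoff=residual_cutoff)
    endo = None
    if design.orientation == "forward":
        try:
            endo = endogenous_estimate(design, measurements)
        except ValueError:
            endo = None
    return CalibrationResult(
        design=design,
        measurements=tuple(measurements),
        fit=fit,
        lod_fmol=lod(design, measurements),
        loq_fmol=loq(design, measurements, cv_limit=cv_limit),
        endogenous_fmol=endo,
    )
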