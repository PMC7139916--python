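"""Spike designs, curve fits and the replicate-based LOD/LOQ rules."""

import numpy as np
import pytest

from maldiplex.calibrate import (
    CalMeasurement,
    SpikeDesign,
    build_design,
    calibrate,
    endogenous_estimate,
    fit_curve,
    lod,
    loq,
    median_replicate_cv,
    simulate_calibration,
)


def meas(level, rep, ratio, detected=True):
    return CalMeasurement(level, rep, ratio, detected)


def brute_force_lod_loq(design, measurements, cv_limit=30.0):
    """Independent rule evaluation straight from the definitions."""
    best_lod, best_loq = None, None
    for level in sorted(design.spiked_levels):
        reps = [m for m in measurements if m.level_fmol == level]
        det = [m for m in reps if m.detected]
        if not reps or len(det) <= len(reps) / 2:
            continue
        if best_lod is None or level < best_lod:
            best_lod = level if best_lod is None else min(best_lod, level)
        if len(det) >= 2:
            vals = np.array([m.ratio for m in det])
            cv = 100 * vals.std(ddof=1) / vals.mean()
            if cv < cv_limit and (best_loq is None or level < best_loq):
                best_loq = level
    return best_lod, best_loq


def test_forward_design_reaches_printed_bottom_level():
    d = build_design("forward", 1000.0, 10000.0, 3.0, 11, include_blank=True)
    assert len(d.levels) == 12
    assert d.levels[0] == 10000.0
    assert d.levels[10] == pytest.approx(0.169, abs=0.01)  # ~0.17 fmol
    assert d.levels[11] == 0.0


def test_reverse_design_depth_alternatives():
    # a 12-point series bottoms out near 0.06 fmol, an 11-point one near 0.17
    eleven = build_design("reverse", 1000.0, 10000.0, 3.0, 11)
    twelve = build_design("reverse", 1000.0, 10000.0, 3.0, 12)
    assert eleven.levels[-1] == pytest.approx(0.169, abs=0.01)
    assert twelve.levels[-1] == pytest.approx(0.056, abs=0.005)


def test_design_validation():
    with pytest.raises(ValueError):
        build_design("forward", 1000.0, 10000.0, 1.0, 5)
    with pytest.raises(ValueError):
        build_design("sideways", 1000.0, 10000.0, 3.0, 5)
    single = build_design("forward", 1000.0, 500.0, 3.0, 1)
    assert single.levels == (500.0,)


def test_lod_rule_application():
    d = SpikeDesign("reverse", 1000.0, (10.0, 3.0, 1.0))
    ms = (
        [meas(10.0, r, 0.01, True) for r in (1, 2, 3)]
        + [meas(3.0, 1, 0.003, True), meas(3.0, 2, 0.003, True), meas(3.0, 3, 0.003, False)]
        + [meas(1.0, 1, 0.001, True), meas(1.0, 2, 0.001, False), meas(1.0, 3, 0.001, False)]
    )
    assert lod(d, ms) == 3.0
    all_in = [meas(l, r, 0.01, True) for l in d.levels for r in (1, 2, 3)]
    assert lod(d, all_in) == 1.0
    none_in = [meas(l, r, 0.01, False) for l in d.levels for r in (1, 2, 3)]
    assert lod(d, none_in) is None


def test_loq_requires_cv_below_limit():
    d = SpikeDesign("reverse", 1000.0, (10.0, 3.0))
    noisy_low = (
        [meas(10.0, 1, 0.010), meas(10.0, 2, 0.011), meas(10.0, 3, 0.009)]  # CV ~10%
        + [meas(3.0, 1, 0.001), meas(3.0, 2, 0.004), meas(3.0, 3, 0.0002)]  # CV ~115%
    )
    assert lod(d, noisy_low) == 3.0
    assert loq(d, noisy_low) == 10.0


def test_noiseless_data_gives_loq_equal_lod():
    d = build_design("reverse", 1000.0, 1000.0, 3.0, 5)
    ms = simulate_calibration(d, seed=0, cv=0.0, noise_floor_fmol=1.0)
    assert lod(d, ms) == loq(d, ms)


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
def test_lod_loq_match_brute_force_and_order(seed):
    d = build_design("reverse", 1000.0, 10000.0, 3.0, 12)
    ms = simulate_calibration(d, seed=seed, cv=0.35, noise_floor_fmol=2.0)
    got_lod, got_loq = lod(d, ms), loq(d, ms)
    exp_lod, exp_loq = brute_force_lod_loq(d, ms)
    assert got_lod == exp_lod
    assert got_loq == exp_loq
    if got_lod is not None and got_loq is not None:
        assert got_loq >= got_lod


def test_reducing_noise_never_raises_expected_lod_or_loq():
    """Detection near the threshold is stochastic replicate by replicate, so
    the monotonicity of the limits with shrinking noise holds in expectation."""
    d = build_design("reverse", 1000.0, 10000.0, 3.0, 12)
    top = max(d.levels)

    def mean_limits(cv):
        lods, loqs = [], []
        for seed in range(30):
            ms = simulate_calibration(d, seed=seed, cv=cv, noise_floor_fmol=2.0)
            l, q = lod(d, ms), loq(d, ms)
            lods.append(l if l is not None else 3 * top)
            loqs.append(q if q is not None else 3 * top)
        return np.mean(lods), np.mean(loqs)

    results = [mean_limits(cv) for cv in (0.6, 0.3, 0.1, 0.0)]
    for (lod_hi, loq_hi), (lod_lo, loq_lo) in zip(results, results[1:]):
        assert lod_lo <= lod_hi * 1.05 + 1e-9
        assert loq_lo <= loq_hi * 1.05 + 1e-9


def test_noiseless_proportional_fit_is_exact():
    d = build_design("reverse", 1000.0, 10000.0, 3.0, 8)
    ms = simulate_calibration(d, seed=0, cv=0.0)
    fit = fit_curve(d, ms)
    assert fit.slope == pytest.approx(1.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.is_linear
    assert fit.dynamic_range == pytest.approx(np.log10(3.0**7), abs=1e-9)


def test_noisy_fit_slope_near_unity():
    d = build_design("reverse", 1000.0, 10000.0, 3.0, 8)
    ms = simulate_calibration(d, seed=3, cv=0.10)
    fit = fit_curve(d, ms)
    assert abs(fit.slope - 1.0) < 0.1


def test_saturated_response_is_flagged_nonlinear():
    d = SpikeDesign("reverse", 1000.0, (1000.0, 100.0, 10.0))
    ms = [meas(l, r, 0.5) for l in d.levels for r in (1, 2, 3)]
    fit = fit_curve(d, ms)
    assert not fit.is_linear
    assert abs(fit.slope) < 0.05


def test_too_few_detected_levels_is_an_error():
    d = SpikeDesign("reverse", 1000.0, (100.0, 10.0))
    ms = [meas(l, r, 0.01) for l in d.levels for r in (1, 2, 3)]
    with pytest.raises(ValueError, match="3 detected levels"):
        fit_curve(d, ms)


def test_endogenous_recovery_and_plateau_windowing():
    d = build_design("forward", 1000.0, 10000.0, 3.0, 11, include_blank=True)
    ms = simulate_calibration(d, seed=5, endogenous_fmol=15.0, cv=0.2)
    est = endogenous_estimate(d, ms)
    assert est == pytest.approx(15.0, rel=0.2)
    # invariant to the top three spike levels
    top3 = set(sorted(d.levels, reverse=True)[:3])
    trimmed = [m for m in ms if m.level_fmol not in top3]
    d_trim = SpikeDesign("forward", 1000.0, tuple(l for l in d.levels if l not in top3))
    assert endogenous_estimate(d_trim, trimmed) == pytest.approx(est, rel=1e-9)


def test_zero_endogenous_estimates_near_zero():
    d = build_design("forward", 1000.0, 10000.0, 3.0, 11, include_blank=True)
    ms = simulate_calibration(d, seed=6, endogenous_fmol=0.0, cv=0.2)
    assert endogenous_estimate(d, ms) < 1.0


def test_reverse_curve_rejected_for_endogenous():
    d = build_design("reverse", 1000.0, 100.0, 3.0, 4)
    ms = simulate_calibration(d, seed=1)
    with pytest.raises(ValueError, match="forward"):
        endogenous_estimate(d, ms)


def test_median_cv_recovers_injected_noise_level():
    d = build_design("forward", 1000.0, 10000.0, 3.0, 11, include_blank=True)
    ms = simulate_calibration(d, seed=17, endogenous_fmol=15.0, cv=0.2)
    assert 15.0 <= median_replicate_cv(ms) <= 25.0


def test_full_calibration_result_contract():
    d = build_design("forward", 1000.0, 10000.0, 3.0, 11, include_blank=True)
    ms = simulate_calibration(d, seed=2, endogenous_fmol=15.0, cv=0.2)
    result = calibrate(d, ms)
    assert result.loq_fmol >= result.lod_fmol
    assert result.endogenous_fmol == pytest.approx(15.0, rel=0.25)
    assert abs(result.fit.slope - 1.0) < 0.1
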