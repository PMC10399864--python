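"""ddPCR Poisson correction, ratio CIs, copy-number series, kinetics fits."""

import math

import numpy as np
import pytest

from birkit.amber import (
    DropletChannel,
    call_synthesis,
    channel_from_counts,
    copy_number_series,
    fit_boltzmann,
    lambda_from_droplets,
    max_copy_number,
    quantify_table,
    quantify_timepoint,
    ratio_with_ci,
)
from birkit.errors import InputError, SaturatedChannelError
from birkit.synth import generate_droplet_counts, generate_droplet_timecourse


def test_lambda_closed_forms():
    lam, lo, hi = lambda_from_droplets(0, 20_000)
    assert lam == 0.0 and lo == 0.0
    lam, lo, hi = lambda_from_droplets(10_000, 20_000)
    assert lam == pytest.approx(math.log(2), abs=1e-12)
    assert lo < lam < hi


def test_lambda_saturation_is_an_explicit_error():
    with pytest.raises(SaturatedChannelError):
        lambda_from_droplets(20_000, 20_000)
    with pytest.raises(InputError):
        lambda_from_droplets(5, 0)


def test_lambda_strictly_increasing_in_positive_count():
    lams = [lambda_from_droplets(k, 1000)[0] for k in range(0, 1000, 37)]
    assert all(b > a for a, b in zip(lams, lams[1:]))


def test_ratio_of_identical_channels_is_one_with_ci_containing_one():
    ch = channel_from_counts("P2", 9000, 20_000)
    r = ratio_with_ci(ch, ch)
    assert r.ratio == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high


def test_ratio_doubles_when_lambda_doubles():
    ref = DropletChannel("ACT1", 20_000, 0, lam=0.4, ci_low=0.38, ci_high=0.42)
    tgt = DropletChannel("P2", 20_000, 0, lam=0.8, ci_low=0.76, ci_high=0.84)
    assert ratio_with_ci(tgt, ref).ratio == pytest.approx(2.0)


def test_ratio_requires_nonzero_reference():
    zero = channel_from_counts("ACT1", 0, 20_000)
    tgt = channel_from_counts("P2", 9000, 20_000)
    with pytest.raises(InputError):
        ratio_with_ci(tgt, zero)


def test_delta_method_ci_is_narrower_but_ordered():
    tgt = channel_from_counts("P2", 12_000, 20_000)
    ref = channel_from_counts("ACT1", 9000, 20_000)
    cons = ratio_with_ci(tgt, ref, "conservative")
    delta = ratio_with_ci(tgt, ref, "delta")
    assert cons.ci_low < delta.ci_low < delta.ratio < delta.ci_high < cons.ci_high


def test_ratio_ci_width_shrinks_like_root_n():
    # same positive fractions at n = 5000 vs 20000 -> widths in ratio ~ 2
    small = ratio_with_ci(channel_from_counts("P2", 3000, 5000),
                          channel_from_counts("ACT1", 2000, 5000), "delta")
    large = ratio_with_ci(channel_from_counts("P2", 12_000, 20_000),
                          channel_from_counts("ACT1", 8000, 20_000), "delta")
    shrink = (small.ci_high - small.ci_low) / (large.ci_high - large.ci_low)
    assert shrink == pytest.approx(2.0, rel=0.05)


def _series_from_ratios(ratios_by_time, locus="P2"):
    tps = []
    for t, lam_t in ratios_by_time.items():
        tgt = DropletChannel(locus, 20_000, 0, lam=lam_t, ci_low=lam_t * 0.95,
                             ci_high=lam_t * 1.05)
        ref = DropletChannel("ACT1", 20_000, 0, lam=1.0, ci_low=0.95, ci_high=1.05)
        tps.append(quantify_timepoint(t, tgt, ref))
    return tps


def test_copy_number_normalizes_to_the_zero_hour_ratio():
    tps = copy_number_series(_series_from_ratios({0: 0.8, 5: 0.8, 10: 0.8}))
    assert all(tp.copy_number == pytest.approx(1.0) for tp in tps)
    tps = copy_number_series(_series_from_ratios({0: 0.8, 10: 0.8 * 1.7}))
    by_time = {tp.time_hr: tp for tp in tps}
    assert by_time[0].copy_number == pytest.approx(1.0)
    assert by_time[10].copy_number == pytest.approx(1.7)


def test_missing_zero_hour_is_an_error():
    with pytest.raises(InputError):
        copy_number_series(_series_from_ratios({5: 0.8, 10: 0.9}))


@pytest.mark.parametrize(
    ("cn", "called"), [(1.09, False), (1.10, True), (1.7, True), (0.0, False)]
)
def test_synthesis_call_threshold_is_inclusive(cn, called):
    assert call_synthesis(cn) is called


def test_synthesis_call_with_ci_requirement():
    assert call_synthesis(1.3, ci_low=1.15, require_ci=True)
    assert not call_synthesis(1.3, ci_low=1.05, require_ci=True)
    with pytest.raises(InputError):
        call_synthesis(1.3, require_ci=True)


def boltzmann(t, base, top, t_half, tau):
    return base + (top - base) / (1 + np.exp((t_half - t) / tau))


def test_boltzmann_fit_recovers_noiseless_parameters():
    t = np.arange(0, 11, dtype=float)
    y = boltzmann(t, 1.0, 1.7, 5.0, 1.0)
    fit = fit_boltzmann(t, y)
    assert fit.converged
    assert fit.rss < 1e-10
    assert fit.base == pytest.approx(1.0, abs=1e-5)
    assert fit.top == pytest.approx(1.7, abs=1e-5)
    assert fit.t_half == pytest.approx(5.0, abs=1e-4)
    assert fit.tau == pytest.approx(1.0, abs=1e-4)


def test_boltzmann_fit_flags_constant_series():
    t = np.arange(0, 11, dtype=float)
    fit = fit_boltzmann(t, np.ones_like(t))
    assert abs(fit.top - fit.base) < 1e-6 or not fit.converged


def test_boltzmann_fit_is_monotone_when_top_above_base():
    t = np.arange(0, 11, dtype=float)
    y = boltzmann(t, 1.0, 1.6, 4.0, 1.5) + 0.01 * np.sin(t)
    fit = fit_boltzmann(t, y)
    if fit.top >= fit.base:
        grid = fit.predict(np.linspace(0, 10, 201))
        assert (np.diff(grid) >= -1e-12).all()


def test_boltzmann_fit_input_requirements():
    with pytest.raises(InputError):
        fit_boltzmann([0, 1, 2, 3], [1, 1, 1, 1])
    with pytest.raises(InputError):
        fit_boltzmann([0, 1, 2, 3, 3.5], [1, 1, 1, 1, 1])


def test_max_copy_number_reports_peak_and_time():
    tps = copy_number_series(
        _series_from_ratios({0: 1.0, 2: 1.2, 5: 1.3, 10: 1.15})
    )
    assert max_copy_number(tps)["P2"] == (pytest.approx(1.3), 5)
    # monotone series: the maximum is the last value
    mono = copy_number_series(_series_from_ratios({0: 1.0, 5: 1.3, 10: 1.6}))
    assert max_copy_number(mono)["P2"] == (pytest.approx(1.6), 10)


def test_max_copy_number_at_least_final_value():
    rng = np.random.default_rng(3)
    for _ in range(20):
        ratios = {float(t): 1.0 if t == 0 else float(rng.uniform(0.9, 2.0))
                  for t in range(0, 11, 2)}
        tps = copy_number_series(_series_from_ratios(ratios))
        mx, _t = max_copy_number(tps)["P2"]
        final = max(tps, key=lambda tp: tp.time_hr).copy_number
        assert mx >= final - 1e-12


def test_simulated_copy_number_round_trip():
    """Median estimate across 50 seeds within 0.05 of the generating ratio,
    for ratios spanning the no-synthesis to full-duplication range."""
    for true_ratio in (1.0, 1.1, 1.7, 2.0):
        estimates = []
        for seed in range(50):
            df = generate_droplet_counts(true_ratio, ref_lambda=1.0,
                                         n_droplets=20_000, seed=seed)
            series = quantify_table(df)
            (cn,) = [tp.copy_number for tp in series if tp.time_hr > 0]
            estimates.append(cn)
        assert abs(np.median(estimates) - true_ratio) < 0.05


def test_no_synthesis_false_positive_rate():
    calls = 0
    for seed in range(200):
        df = generate_droplet_counts(1.0, ref_lambda=1.0, n_droplets=20_000, seed=seed)
        series = quantify_table(df)
        (cn,) = [tp.copy_number for tp in series if tp.time_hr > 0]
        calls += call_synthesis(cn)
    assert calls / 200 <= 0.05


def test_quantify_table_full_timecourse():
    course = {0.0: 1.0, 2.0: 1.05, 4.0: 1.3, 6.0: 1.55, 8.0: 1.65, 10.0: 1.7}
    df = generate_droplet_timecourse(course, seed=5)
    series = quantify_table(df)
    assert len(series) == len(course)
    fit = fit_boltzmann([tp.time_hr for tp in series],
                        [tp.copy_number for tp in series])
    assert fit.top == pytest.approx(1.7, abs=0.1)
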