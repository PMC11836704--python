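import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as t_dist

from seedsmr.respirometry import (
    PO2Trace,
    TraceError,
    filter_outlier_replicates,
    fit_slope,
    process_species,
    q10_correct,
    saturation_vapour_pressure,
    slope_to_vo2,
    smooth_trace,
    truncate_hypoxia,
)
from seedsmr.simulate import SimulationConfig, simulate_traces


def make_trace(po2, times=None, **kwargs):
    po2 = np.asarray(po2, dtype=float)
    if times is None:
        times = np.arange(len(po2), dtype=float) * 0.5
    defaults = dict(
        chamber_id="ch1", species="sp", volume_ul=1500.0, n_seeds=5, t_measure=20.0
    )
    defaults.update(kwargs)
    return PO2Trace(times=np.asarray(times, float), po2=po2, **defaults)


class TestSmoothing:
    def test_constant_signal(self):
        out = smooth_trace(make_trace([5, 5, 5, 5]), window=3)
        assert np.allclose(out.po2, [5, 5])

    def test_linear_ramp(self):
        out = smooth_trace(make_trace([1, 2, 3, 4, 5]), window=3)
        assert np.allclose(out.po2, [2, 3, 4])

    def test_linear_signal_stays_linear(self):
        tr = make_trace(21 - 0.4 * np.arange(20) * 0.5, times=np.arange(20) * 0.5)
        out = smooth_trace(tr, window=3)
        slope, se = fit_slope(out)
        assert slope == pytest.approx(-0.4, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_variance_reduced_to_third(self, rng):
        # Monte-Carlo oracle: a 3-point mean of iid noise has variance 1/3
        noise = rng.normal(0, 1.0, 1000) + 20.0
        out = smooth_trace(make_trace(noise), window=3)
        detrended = out.po2 - out.po2.mean()
        assert np.var(detrended) == pytest.approx(1 / 3, rel=0.15)

    def test_too_short_trace_rejected(self):
        with pytest.raises(TraceError):
            smooth_trace(make_trace([20, 19]), window=3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(make_trace([20, 19, 18, 17]), window=4)


class TestHypoxiaTruncation:
    def test_never_below_threshold_unchanged(self):
        tr = make_trace([20, 19.5, 19, 18.5, 18])
        out = truncate_hypoxia(tr, 0.8)
        assert len(out) == len(tr)

    def test_threshold_scan(self):
        # threshold 0.8 * 20 = 16; 15.9 is the first reading below it
        tr = make_trace([20, 18, 16, 15.9, 15])
        out = truncate_hypoxia(tr, 0.8, strict=False)
        assert np.allclose(out.po2, [20, 18, 16])

    def test_short_prefix_flagged_unusable(self):
        tr = make_trace([20, 18, 16, 15.9, 15])
        with pytest.raises(TraceError, match="unusable"):
            truncate_hypoxia(tr, 0.8, strict=True)

    def test_recovery_not_readmitted(self):
        tr = make_trace([20, 15, 17, 18, 19])
        out = truncate_hypoxia(tr, 0.8, strict=False)
        assert len(out) == 1  # only the pre-hypoxic prefix survives

    @given(
        st.lists(st.floats(min_value=1.0, max_value=25.0), min_size=4, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_output_is_prefix_of_input(self, po2):
        tr = make_trace(po2)
        out = truncate_hypoxia(tr, 0.8, strict=False)
        assert len(out) <= len(tr)
        assert np.array_equal(out.po2, tr.po2[: len(out)])


class TestSlope:
    def test_exact_line(self):
        times = np.arange(10) * 0.5
        tr = make_trace(21 - 0.5 * times, times=times)
        slope, se = fit_slope(tr)
        assert slope == pytest.approx(-0.5, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_constant_trace_zero_slope(self):
        slope, _ = fit_slope(make_trace([7, 7, 7, 7, 7]))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_three_se(self, rng):
        times = np.arange(30) * 0.5
        hits = 0
        for _ in range(500):
            po2 = 21 - 0.3 * times + rng.normal(0, 0.05, len(times))
            slope, se = fit_slope(make_trace(po2, times=times))
            if abs(slope - (-0.3)) <= 3 * se:
                hits += 1
        assert hits >= 0.95 * 500


class TestVO2Conversion:
    def test_zero_slope_zero_rate(self):
        assert slope_to_vo2(0.0, 1000, 1, 20.0) == 0.0

    def test_unit_ratios_cancel(self):
        # at 0 deg C with a dry-pressure slope equal to 1/1000 of pressure
        v = slope_to_vo2(
            -0.101325, 1000.0, 1, 0.0, pressure_kpa=101.325, correct_vapour=False
        )
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_field_case(self):
        # independent arithmetic: 20 deg C, 98 kPa ambient, 5 seeds
        slope, volume, n, t, p = -0.2, 1500.0, 5, 20.0, 98.0
        svp = 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
        expected = (-slope / (p - svp)) * volume * (273.15 / (273.15 + t)) / n
        got = slope_to_vo2(slope, volume, n, t, pressure_kpa=p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.5844, abs=2e-4)  # frozen value

    def test_positive_slope_warns(self):
        with pytest.warns(UserWarning, match="positive"):
            slope_to_vo2(0.1, 1000, 1, 20.0)

    def test_custom_stp_hook(self):
        v_id = slope_to_vo2(-0.1, 1000, 1, 20.0, stp_correction=lambda vol, t: vol)
        v_std = slope_to_vo2(-0.1, 1000, 1, 20.0)
        assert v_id > v_std  # identity hook skips the shrink to STP volume

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            slope_to_vo2(-0.1, 0, 1, 20.0)
        with pytest.raises(ValueError):
            slope_to_vo2(-0.1, 1000, 1, 20.0, pressure_kpa=0.0)


class TestOutlierFilter:
    def test_identical_slopes_all_kept(self):
        assert filter_outlier_replicates([-1.0] * 5).all()

    def test_gross_outlier_excluded(self):
        kept = filter_outlier_replicates([-1, -1, -1, -1, -10])
        assert list(kept) == [True, True, True, True, False]

    def test_permutation_invariance(self, rng):
        slopes = np.array([-1.0, -1.1, -0.9, -1.05, -5.0, -0.95])
        base = filter_outlier_replicates(slopes)
        for _ in range(10):
            perm = rng.permutation(len(slopes))
            assert np.array_equal(filter_outlier_replicates(slopes[perm]), base[perm])

    def test_null_exclusion_rate_matches_t_oracle(self, rng):
        # leave-one-out statistic: (x - mean of 9 others)/sd(others) is
        # sqrt(10/9) * t_8 under iid normality, so the per-replicate
        # exclusion probability at k = 2 is 2 * sf_t8(2 * sqrt(9/10))
        n = 10
        p_excl = 2 * t_dist.sf(2.0 * np.sqrt((n - 1) / n), df=n - 2)
        expected = n * p_excl
        excluded = 0
        n_sim = 2000
        for _ in range(n_sim):
            slopes = rng.normal(-1.0, 0.1, n)
            excluded += (~filter_outlier_replicates(slopes)).sum()
        assert excluded / n_sim == pytest.approx(expected, abs=0.1)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            filter_outlier_replicates([-1.0, -2.0])


class TestQ10:
    def test_same_temperature_identity(self):
        assert q10_correct(1.7, 20.0) == pytest.approx(1.7)

    def test_down_correction_from_30(self):
        assert q10_correct(1.0, 30.0) == pytest.approx(0.4)

    def test_up_correction_from_18(self):
        assert q10_correct(1.0, 18.0) == pytest.approx(2.5**0.2)

    def test_bad_q10_rejected(self):
        with pytest.raises(ValueError):
            q10_correct(1.0, 20.0, q10=0.0)

    @given(
        st.floats(min_value=0.001, max_value=100.0),
        st.floats(min_value=10.0, max_value=35.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_invertibility(self, smr, temp):
        back = q10_correct(q10_correct(smr, temp, 20.0), 20.0, temp)
        assert back == pytest.approx(smr, rel=1e-12)

    def test_monotone_in_temperature_gap(self):
        vals = [q10_correct(1.0, t) for t in (30, 25, 20, 15, 10)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSpeciesPipeline:
    def test_noiseless_traces_recover_rate_exactly(self):
        cfg = SimulationConfig(trace_noise_sd=0.0, p_contaminated=0.0)
        row = pd.Series({"species": "sp1", "t_measure_c": 24.0, "smr_t": 0.8})
        res = process_species(simulate_traces(row, cfg, 11))
        assert res.smr_t == pytest.approx(0.8, rel=1e-12)
        assert res.smr20 == pytest.approx(q10_correct(0.8, 24.0), rel=1e-12)

    def test_noisy_recovery_small_bias(self, rng):
        cfg = SimulationConfig(trace_noise_sd=0.05, p_contaminated=0.0)
        rel_errors = []
        for i in range(10):
            vo2 = 10 ** rng.uniform(-2, 1)
            row = pd.Series(
                {"species": f"s{i}", "t_measure_c": 22.0, "smr_t": vo2}
            )
            res = process_species(simulate_traces(row, cfg, 500 + i))
            rel_errors.append(res.smr_t / vo2 - 1)
        assert abs(np.mean(rel_errors)) < 0.02

    def test_no_usable_replicates_raises(self):
        # all traces crash through the hypoxia threshold immediately
        tr = make_trace([20, 10, 5, 2.5, 1.2])
        with pytest.raises(TraceError, match="no usable"):
            process_species([tr])


def test_saturation_vapour_pressure_reference_points():
    # Buck-equation checkpoints: ~0.611 kPa at 0 C, ~2.34 kPa at 20 C
    assert saturation_vapour_pressure(0.0) == pytest.approx(0.611, abs=0.002)
    assert saturation_vapour_pressure(20.0) == pytest.approx(2.34, abs=0.01)
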