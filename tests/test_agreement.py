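"""Agreement statistics: closed-form cases, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import biaffm
from biaffm import InputValidationError, StatisticalError

# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation
# ---------------------------------------------------------------------------


def oracle_ccc(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x) / (n - 1)
    syy = sum((v - my) ** 2 for v in y) / (n - 1)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    ccc = 2 * sxy / (sxx + syy + (mx - my) ** 2)
    rho = sxy / (sxx * syy) ** 0.5
    return ccc, rho, ccc / rho


def oracle_pure_error(pred, ref):
    return (sum((p - r) ** 2 for p, r in zip(pred, ref)) / len(pred)) ** 0.5


def oracle_calibration(pred, ref):
    # normal equations for ref = a + b*pred, solved explicitly
    n = len(pred)
    sx = sum(pred)
    sy = sum(ref)
    sxx = sum(p * p for p in pred)
    sxy = sum(p * r for p, r in zip(pred, ref))
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    resid = [r - a - b * p for p, r in zip(pred, ref)]
    ssr = sum(e * e for e in resid)
    sst = sum((r - sy / n) ** 2 for r in ref)
    r2 = 1 - ssr / sst
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    see = (ssr / (n - 2)) ** 0.5
    return r2_adj, see


def oracle_bland_altman(pred, ref):
    n = len(pred)
    d = [p - r for p, r in zip(pred, ref)]
    bias = sum(d) / n
    sd = (sum((v - bias) ** 2 for v in d) / (n - 1)) ** 0.5
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


class TestOracleEquivalence:
    def test_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 20))
            ref = rng.normal(58.0, 6.0, n)
            pred = ref + rng.normal(1.0, 2.0, n)
            ccc, rho, cb = biaffm.lin_ccc(pred, ref)
            o_ccc, o_rho, o_cb = oracle_ccc(list(pred), list(ref))
            assert ccc == pytest.approx(o_ccc, abs=1e-10)
            assert rho == pytest.approx(o_rho, abs=1e-10)
            assert cb == pytest.approx(o_cb, abs=1e-10)
            assert biaffm.pure_error(pred, ref) == pytest.approx(
                oracle_pure_error(list(pred), list(ref)), abs=1e-10
            )
            r2_adj, see = biaffm.calibration_fit(pred, ref)
            o_r2, o_see = oracle_calibration(list(pred), list(ref))
            assert r2_adj == pytest.approx(o_r2, abs=1e-9)
            assert see == pytest.approx(o_see, abs=1e-9)
            bias, lo, hi, _, _ = biaffm.bland_altman(pred, ref)
            o_bias, o_lo, o_hi = oracle_bland_altman(list(pred), list(ref))
            assert (bias, lo, hi) == pytest.approx((o_bias, o_lo, o_hi), abs=1e-10)


class TestDifferenceSummary:
    def test_constant_offsets_match_printed_percentages(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0.0, 2.5, 100)
        ref = 58.2 + ref - ref.mean()  # force reference mean exactly 58.2
        mean_diff, _, pct = biaffm.difference_summary(ref + 2.4, ref)
        assert mean_diff == pytest.approx(2.4, abs=1e-12)
        assert pct == pytest.approx(4.1237, abs=1e-3)
        _, _, pct = biaffm.difference_summary(ref + 1.3, ref)
        assert pct == pytest.approx(2.2337, abs=1e-3)
        _, _, pct = biaffm.difference_summary(ref - 3.0, ref)
        assert pct == pytest.approx(5.1546, abs=1e-3)  # absolute value

    def test_identical_series(self):
        x = np.array([58.0, 60.0, 55.0])
        assert biaffm.difference_summary(x, x) == (0.0, 0.0, 0.0)

    def test_rejects_mismatch(self):
        with pytest.raises(InputValidationError):
            biaffm.difference_summary([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(StatisticalError):
            biaffm.difference_summary([1.0], [1.0])


class TestPairedComparison:
    def test_identical_series_is_null(self):
        x = np.array([55.0, 58.0, 61.0, 57.0, 59.0])
        t, p, _ = biaffm.paired_comparison(x, x)
        assert t == 0.0
        assert p == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(58.2, 6.5, 50)
        pred = ref + 5.0 + rng.normal(0.0, 1.0, 50)
        t, p, _ = biaffm.paired_comparison(pred, ref)
        assert p < 1e-3
        assert t > 20  # shift 5, noise SD 1, n=50 -> t around 35

    def test_non_normal_series_triggers_log_transform(self):
        rng = np.random.default_rng(2)
        ref = np.exp(rng.normal(4.0, 0.8, 80))  # heavily skewed, positive
        pred = ref * 1.01
        _, _, flagged = biaffm.paired_comparison(pred, ref)
        assert flagged

    def test_transform_with_nonpositive_values_rejected(self):
        ref = np.array([1.0, 1.0, 1.0, 1.0, 50.0, -2.0, 3.0, 1.0])
        with pytest.raises(InputValidationError, match="non-positive"):
            biaffm.paired_comparison(ref, np.abs(ref) + 1)


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([50.0, 55.0, 60.0, 65.0])
        assert biaffm.lin_ccc(x, x) == pytest.approx((1.0, 1.0, 1.0))

    def test_location_shift_hits_only_accuracy(self):
        x = np.array([50.0, 55.0, 60.0, 65.0, 58.0])
        ccc, rho, cb = biaffm.lin_ccc(x + 3.0, x)
        assert rho == pytest.approx(1.0)
        assert cb < 1.0
        assert ccc == pytest.approx(cb)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(58.0, 6.0, 40)
        b = a + rng.normal(1.0, 3.0, 40)
        assert biaffm.lin_ccc(a, b) == pytest.approx(biaffm.lin_ccc(b, a))

    def test_decomposition_identity_and_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(58.0, 6.0, 30)
            b = a + rng.normal(rng.normal(), 2.0, 30)
            ccc, rho, cb = biaffm.lin_ccc(a, b)
            assert ccc == pytest.approx(rho * cb, abs=1e-12)
            assert 0 < cb <= 1.0 + 1e-12
            assert abs(ccc) <= abs(rho) + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticalError):
            biaffm.lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPureError:
    @pytest.mark.parametrize(
        "pred, ref, expected",
        [
            ([58.0, 60.0], [58.0, 60.0], 0.0),
            ([60.0, 62.0, 59.0], [58.0, 60.0, 57.0], 2.0),
            ([59.0, 57.0, 60.0], [58.0, 58.0, 58.0], np.sqrt(2.0)),
        ],
    )
    def test_closed_forms(self, pred, ref, expected):
        assert biaffm.pure_error(pred, ref) == pytest.approx(expected, abs=1e-12)

    def test_decomposes_into_bias_and_spread(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(60.0, 5.0, 37)
        ref = rng.normal(58.0, 5.0, 37)
        pe = biaffm.pure_error(pred, ref)
        mean_diff, sd_diff, _ = biaffm.difference_summary(pred, ref)
        n = 37
        assert pe**2 == pytest.approx(
            mean_diff**2 + sd_diff**2 * (n - 1) / n, rel=1e-12
        )
        assert pe >= abs(mean_diff)


class TestCalibrationFit:
    def test_exact_line(self):
        pred = np.linspace(50.0, 70.0, 10)
        r2_adj, see = biaffm.calibration_fit(pred, 2.0 * pred + 1.0)
        assert r2_adj == pytest.approx(1.0)
        assert see == pytest.approx(0.0, abs=1e-10)

    def test_residual_sd_recovered(self):
        rng = np.random.default_rng(6)
        pred = rng.normal(58.0, 6.0, 264)
        ref = pred + rng.normal(0.0, 2.2, 264)
        _, see = biaffm.calibration_fit(pred, ref)
        assert 1.9 < see < 2.5

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticalError):
            biaffm.calibration_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_limits_from_constructed_differences(self):
        # differences with mean 0.6 and sample SD exactly 3.2
        ref = np.array([58.0, 58.0, 58.0])
        pred = ref + 0.6 + 3.2 * np.array([-1.0, 0.0, 1.0])
        bias, lo, hi, _, _ = biaffm.bland_altman(pred, ref)
        assert bias == pytest.approx(0.6)
        assert lo == pytest.approx(-5.672)
        assert hi == pytest.approx(6.872)

    def test_identical_series(self):
        x = np.array([55.0, 58.0, 61.0])
        bias, lo, hi, trend_r, _ = biaffm.bland_altman(x, x)
        assert (bias, lo, hi, trend_r) == (0.0, 0.0, 0.0, 0.0)

    def test_limit_width_is_392_sd(self):
        rng = np.random.default_rng(7)
        pred = rng.normal(60.0, 6.0, 50)
        ref = rng.normal(58.0, 6.0, 50)
        _, lo, hi, _, _ = biaffm.bland_altman(pred, ref)
        _, sd_diff, _ = biaffm.difference_summary(pred, ref)
        assert hi - lo == pytest.approx(2 * 1.96 * sd_diff, rel=1e-12)


class TestTechnicalError:
    def test_identical_replicates(self):
        x = np.array([480.0, 470.0, 500.0])
        report = biaffm.technical_error(x, x)
        assert report.tem == 0.0
        assert report.cv_pct == 0.0
        assert report.n_pairs == 3

    def test_single_pair_closed_form(self):
        report = biaffm.technical_error([10.0], [11.0])
        assert report.tem == pytest.approx(np.sqrt(0.5))

    @given(c=st.floats(0.1, 10.0))
    def test_scales_linearly(self, c):
        test = np.array([480.0, 470.0, 500.0, 455.0])
        retest = test + np.array([3.0, -4.0, 1.0, -2.0])
        base = biaffm.technical_error(test, retest)
        scaled = biaffm.technical_error(c * test, c * retest)
        assert scaled.tem == pytest.approx(c * base.tem, rel=1e-9)
        # CV% is scale-free
        assert scaled.cv_pct == pytest.approx(base.cv_pct, rel=1e-9)


class TestBuildReport:
    def test_identical_series(self):
        x = np.array([55.0, 58.0, 61.0, 57.0, 59.0])
        report = biaffm.build_report("self", x, x)
        assert report.mean_diff == 0.0
        assert report.ccc == pytest.approx(1.0)
        assert report.pure_error == 0.0
        assert report.paired_p == 1.0

    def test_full_catalogue_pipeline(self, cohort, reference_ffm):
        reports = [
            biaffm.build_report(ps.equation_id, ps.values, reference_ffm)
            for ps in biaffm.predict_all(cohort)
        ]
        assert len(reports) == 9
        for report in reports:
            assert report.ccc == pytest.approx(
                report.precision_rho * report.accuracy_cb, abs=1e-12
            )
            assert report.pure_error >= abs(report.mean_diff)
            assert report.loa_upper - report.loa_lower == pytest.approx(
                2 * 1.96 * report.sd_diff, rel=1e-9
            )
            assert report.n == len(cohort)

    def test_rounded_table_layout(self, cohort, reference_ffm):
        reports = [
            biaffm.build_report(ps.equation_id, ps.values, reference_ffm)
            for ps in biaffm.predict_all(cohort, ["eq3", "specific"])
        ]
        table = biaffm.reports_to_frame(reports, rounded=True)
        assert list(table["equation_id"]) == ["eq3", "specific"]
        assert "significant_vs_reference" in table.columns
        # rounding conventions: 1 dp kg, 4 dp rho, 2 dp ccc
        assert (table["mean_diff"] == table["mean_diff"].round(1)).all()
        assert (table["precision_rho"] == table["precision_rho"].round(4)).all()
        assert (table["ccc"] == table["ccc"].round(2)).all()
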