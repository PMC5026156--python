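"""Reliability metrics: agreement scores, ICCs, block averaging, paired
tests, and qualitative classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirsrel.errors import InputError
from nirsrel.reliability import (block_average, classify_effect_size,
                                 classify_reliability, cluster_amplitude,
                                 icc_average_from_single, icc_oneway,
                                 overlap_counts, paired_test,
                                 pattern_correlation, r_overlap, r_quantity,
                                 timecourse_correlation)


class TestAgreementScores:
    @pytest.mark.parametrize("a1,a2,expected", [
        (9, 7, 0.88), (6, 6, 1.00), (1, 7, 0.25), (6, 11, 0.71), (6, 0, 0.00),
    ])
    def test_r_quantity_worked_examples(self, a1, a2, expected):
        assert round(r_quantity(a1, a2), 2) == expected

    def test_r_quantity_undefined_without_significant_channels(self):
        assert np.isnan(r_quantity(0, 0))

    @pytest.mark.parametrize("a1,a2,ov,expected", [
        (6, 6, 6, 1.0), (9, 7, 0, 0.0), (6, 6, 5, 0.8333),
    ])
    def test_r_overlap_examples(self, a1, a2, ov, expected):
        assert r_overlap(a1, a2, ov) == pytest.approx(expected, abs=1e-4)

    def test_r_overlap_invalid_overlap_rejected(self):
        with pytest.raises(InputError):
            r_overlap(3, 2, 3)
        with pytest.raises(InputError):
            r_quantity(-1, 2)

    @given(a1=st.integers(0, 30), a2=st.integers(0, 30), data=st.data())
    def test_symmetry_and_bounds(self, a1, a2, data):
        ov = data.draw(st.integers(0, min(a1, a2)))
        rq, ro = r_quantity(a1, a2), r_overlap(a1, a2, ov)
        if a1 + a2 == 0:
            assert np.isnan(rq) and np.isnan(ro)
            return
        assert 0.0 <= rq <= 1.0 and 0.0 <= ro <= 1.0
        assert rq == pytest.approx(r_quantity(a2, a1))
        assert ro == pytest.approx(r_overlap(a2, a1, ov))
        # location agreement is capped by the smaller activation set
        assert ro <= 2.0 * min(a1, a2) / (a1 + a2) + 1e-12

    def test_overlap_counts(self):
        assert overlap_counts({1, 2, 3}, {2, 3, 9}) == (3, 3, 2)


class TestPatternCorrelation:
    def test_identity_and_negation(self, rng):
        x = rng.normal(size=24)
        assert pattern_correlation(x, x) == pytest.approx(1.0)
        assert pattern_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=24), rng.normal(size=24)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pattern_correlation(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_degenerate_inputs(self, rng):
        assert np.isnan(pattern_correlation(np.ones(24), rng.normal(size=24)))
        with pytest.raises(InputError):
            pattern_correlation([1.0, 2.0], [2.0, 1.0])

    def test_timecourse_correlation_detects_shape_reversal(self):
        t = np.linspace(0, 1, 100)
        asymmetric = t * np.exp(-5 * t)
        assert timecourse_correlation(asymmetric, asymmetric) == pytest.approx(1.0)
        assert timecourse_correlation(asymmetric, asymmetric[::-1]) < 1.0


class TestICC:
    def test_zero_within_subject_variance(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0]])
        res = icc_oneway(X)
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_pure_noise_clamps_near_zero(self, rng):
        X = rng.normal(size=(300, 2))
        res = icc_oneway(X)
        assert 0.0 <= res.icc_single < 0.1
        assert 0.0 <= res.icc_average < 0.2

    def test_matches_hand_computed_anova(self):
        X = np.array([[1.0, 2.0], [4.0, 6.0], [7.0, 9.0], [10.0, 13.0]])
        n, k = 4, 2
        row_means = X.mean(axis=1)
        grand = X.mean()
        bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
        wms = np.sum((X - row_means[:, None]) ** 2) / (n * (k - 1))
        res = icc_oneway(X)
        assert res.bms == pytest.approx(bms)
        assert res.wms == pytest.approx(wms)
        assert res.icc_single == pytest.approx((bms - wms) / (bms + wms), rel=1e-12)
        assert res.icc_average == pytest.approx((bms - wms) / bms, rel=1e-12)

    def test_matches_pingouin(self, rng):
        """Dual route: agree with pingouin's one-way ICC1 / ICC1k."""
        import pandas as pd
        import pingouin as pg

        X = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        frame = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "session": np.tile([1, 2], 12),
            "score": X.reshape(-1),
        })
        table = pg.intraclass_corr(frame, targets="subject", raters="session",
                                   ratings="score").set_index("Type")
        res = icc_oneway(X)
        assert res.icc_single_raw == pytest.approx(table.loc["ICC(1,1)", "ICC"], abs=1e-6)
        assert res.icc_average_raw == pytest.approx(table.loc["ICC(1,k)", "ICC"], abs=1e-6)

    def test_spearman_brown_identity_preclamp(self, rng):
        for _ in range(25):
            X = rng.normal(size=(10, 2)) + 0.5 * rng.normal(size=(10, 1))
            res = icc_oneway(X)
            implied = icc_average_from_single(res.icc_single_raw, k=2)
            assert abs(res.icc_average_raw - implied) < 1e-10

    def test_average_at_least_single_when_nonnegative(self, rng):
        for _ in range(25):
            X = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
            res = icc_oneway(X)
            if res.icc_single_raw >= 0:
                assert res.icc_average >= res.icc_single

    def test_reference_cluster_pairs(self):
        """Single-session cluster ICCs of 0.74 and 0.58 imply two-session
        averages of 0.85 and 0.73 under the k=2 mean-squares relationship."""
        assert round(icc_average_from_single(0.74, k=2), 2) == 0.85
        assert round(icc_average_from_single(0.58, k=2), 2) == 0.73

    def test_input_validation(self):
        with pytest.raises(InputError):
            icc_oneway(np.ones((1, 2)))
        with pytest.raises(InputError):
            icc_oneway(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestClusterAmplitude:
    def test_mean_of_equal_betas(self):
        betas = np.full((1, 6), 0.42)
        assert cluster_amplitude(betas, (1, 2, 3))[0] == pytest.approx(0.42)

    def test_arithmetic_mean(self):
        betas = np.array([[0.1, 0.2, 0.3, 9.9]])
        assert cluster_amplitude(betas, (1, 2, 3))[0] == pytest.approx(0.2)

    def test_missing_channel_rejected(self):
        with pytest.raises(InputError):
            cluster_amplitude(np.ones((2, 4)), (3, 4, 5))

    def test_cluster_icc_beats_mean_single_channel_icc(self, rng):
        """Averaging channels with independent measurement noise raises the
        ICC relative to the mean of the member-channel ICCs."""
        wins, n_rep = 0, 200
        for _ in range(n_rep):
            subj = rng.normal(0, 1.0, size=(17, 1, 1))
            sess = subj + rng.normal(0, 0.6, size=(17, 2, 1))
            betas = sess + rng.normal(0, 0.8, size=(17, 2, 3))  # channel noise
            singles = [icc_oneway(betas[:, :, c]).icc_single for c in range(3)]
            cluster = icc_oneway(betas.mean(axis=2)).icc_single
            wins += cluster > np.mean(singles)
        assert wins / n_rep > 0.9


class TestBlockAverage:
    fs = 10.0
    onsets = [20.0, 80.0, 140.0, 200.0, 260.0]

    def test_constant_series_averages_to_zero(self):
        series = np.full(3200, 7.0)
        _, avg = block_average(series, self.fs, self.onsets)
        assert np.allclose(avg, 0.0)

    def test_noiseless_response_equals_single_trial(self):
        t = np.arange(3200) / self.fs
        epoch_shape = lambda tt: np.exp(-0.5 * ((tt - 10) / 4) ** 2)
        series = np.zeros_like(t)
        for onset in self.onsets:
            mask = (t >= onset - 5) & (t < onset + 40)
            series[mask] += epoch_shape(t[mask] - onset)
        epoch_time, avg = block_average(series, self.fs, self.onsets)
        single = epoch_shape(epoch_time)
        single -= single[(epoch_time >= -5) & (epoch_time < 0)].mean()
        assert np.allclose(avg, single, atol=1e-10)

    def test_noise_reduction_scales_with_sqrt_of_blocks(self, rng):
        sds = []
        for _ in range(300):
            noise = rng.normal(size=3200)
            _, avg = block_average(noise, self.fs, self.onsets, baseline_s=(0.0, 0.0))
            sds.append(avg.std())
        assert np.mean(sds) == pytest.approx(1.0 / np.sqrt(5), rel=0.05)

    def test_out_of_bounds_epoch_excluded_with_warning(self):
        series = np.zeros(700)  # 70 s: fits the epoch at 20 s, not at 48 s
        with pytest.warns(UserWarning, match="excluded"):
            _, avg = block_average(series, self.fs, [20.0, 48.0])
        assert avg.shape[0] == 450
        with pytest.raises(InputError):
            block_average(series, self.fs, [1000.0])


class TestPairedTest:
    def test_identical_sessions(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.d == 0.0 and res.p == 1.0

    def test_constant_shift_with_jitter(self, rng):
        x = rng.normal(size=400)
        shift, jitter_sd = 0.8, 0.2
        y = x + shift + rng.normal(0, jitter_sd, size=400)
        res = paired_test(x, y)
        assert res.d == pytest.approx(shift / jitter_sd, rel=0.15)
        assert res.direction == "+ve"

    def test_textbook_five_pair_oracle(self):
        """Differences (2,4,4,4,6): mean 4, SD sqrt(2), t = 4/(sqrt(2)/sqrt(5))."""
        s1 = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
        s2 = s1 + np.array([2.0, 4.0, 4.0, 4.0, 6.0])
        res = paired_test(s1, s2)
        # differences are taken session2 - session1
        assert res.t == pytest.approx(4.0 / (np.sqrt(2.0) / np.sqrt(5.0)), rel=1e-12)
        assert res.d == pytest.approx(4.0 / np.sqrt(2.0), rel=1e-12)
        assert res.direction == "+ve"
        assert res.p == pytest.approx(0.00323, abs=2e-4)

    def test_zero_variance_differences(self):
        res = paired_test([1.0, 2.0], [2.0, 3.0])
        assert np.isinf(res.d) and res.p == 0.0


class TestClassification:
    @pytest.mark.parametrize("value,label", [
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
        (0.74, "good"), (0.75, "excellent"), (1.0, "excellent"), (-0.2, "poor"),
    ])
    def test_reliability_bands(self, value, label):
        assert classify_reliability(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            classify_reliability(1.2)
        assert classify_reliability(float("nan")) == "n/a"

    @pytest.mark.parametrize("d,label", [
        (0.1, "negligible"), (0.2, "small"), (0.5, "medium"),
        (-0.9, "large"), (0.8, "large"),
    ])
    def test_effect_size_bands(self, d, label):
        assert classify_effect_size(d) == label
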