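"""GLM estimation: HRF shape, design-matrix construction, Cochrane-Orcutt
correction, one-sided tests, and Benjamini-Yekutieli FDR."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from nirsrel.config import AmplitudeModel, SimulationConfig, SystemicModel
from nirsrel.design import DesignSpec, generate_design
from nirsrel.errors import EstimationError, InputError
from nirsrel.glm import (build_design_matrix, fdr_correct,
                         fit_glm_cochrane_orcutt, group_level_map,
                         lag1_autocorrelation, one_sided_p)
from nirsrel.hrf import canonical_hrf
from nirsrel.simulate import channel_amplitudes, simulate_haemo

SILENT = SystemicModel(cardiac_amplitude=0, mayer_amplitude=0, drift_amplitude=0,
                       stim_locked_amplitude=0, noise_sd=0)


class TestCanonicalHRF:
    def test_shape_properties(self):
        h = canonical_hrf(10.0)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        assert 4.0 <= np.argmax(h) / 10.0 <= 6.0
        # exactly one sign change: positive lobe then undershoot
        signs = np.sign(h[np.abs(h) > 1e-12])
        changes = np.sum(signs[1:] != signs[:-1])
        assert changes == 1

    def test_peak_location_matches_dense_double_gamma(self):
        t = np.arange(0.0, 32.0, 1e-3)
        dense = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
        dense_peak = t[np.argmax(dense)]
        h = canonical_hrf(10.0)
        assert np.argmax(h) / 10.0 == pytest.approx(dense_peak, abs=0.1)


class TestDesignMatrix:
    def _design(self, onsets, total, controls=()):
        return DesignSpec(onsets={"A-ONLY": tuple(onsets)}, block_duration_s=24.0,
                          control_onsets=tuple(controls), total_duration_s=total)

    def test_single_block_matches_direct_convolution(self):
        fs = 10.0
        design = self._design([20.0], 100.0)
        dm = build_design_matrix(design, fs)
        kernel = canonical_hrf(fs)
        kernel = kernel / kernel.sum()
        box = np.zeros(1000)
        box[200:440] = 1.0
        oracle = np.convolve(box, kernel)[:1000]
        col = dm.matrix[:, dm.labels.index("A-ONLY")]
        assert np.allclose(col, oracle, atol=1e-12)
        assert np.all(dm.matrix[:, dm.labels.index("intercept")] == 1.0)
        assert np.all(dm.matrix[:, dm.labels.index("control")] == 0.0)

    def test_two_blocks_are_sum_of_singles(self):
        fs = 10.0
        both = build_design_matrix(self._design([20.0, 120.0], 250.0), fs)
        one = build_design_matrix(self._design([20.0], 250.0), fs)
        two = build_design_matrix(self._design([120.0], 250.0), fs)
        i = both.labels.index("A-ONLY")
        assert np.allclose(both.matrix[:, i], one.matrix[:, i] + two.matrix[:, i])

    def test_onset_beyond_recording_rejected(self):
        with pytest.raises(InputError):
            build_design_matrix(self._design([200.0], 100.0), 10.0)


class TestCochraneOrcutt:
    @pytest.fixture
    def design_matrix(self):
        config = SimulationConfig(seed=0)
        design = generate_design(config, rng_seed=3)
        return build_design_matrix(design, config.fs)

    def test_noiseless_recovery_is_exact(self, design_matrix, quiet):
        beta_true = np.array([0.07, 0.03, 0.05, 0.0, 0.2])
        y = design_matrix.matrix @ beta_true
        fit = fit_glm_cochrane_orcutt(y, design_matrix)
        for label, b in zip(design_matrix.labels, beta_true):
            assert fit.coef(label)[0] == pytest.approx(b, abs=1e-8)
        assert abs(fit.rho) < 1e-6

    def test_simulated_amplitudes_recovered_without_noise(self, quiet):
        """Simulator and GLM share the HRF, so noise-free condition betas
        equal the simulated amplitudes exactly."""
        config = SimulationConfig(n_channels=1, responsive_channels=(1,),
                                  systemic=SILENT, seed=0)
        design = generate_design(config, rng_seed=5)
        amps = channel_amplitudes(config, np.array([0.07, 0.035, 0.075]))
        hbo, _, _ = simulate_haemo(design, config, amps, rng_seed=0)
        dm = build_design_matrix(design, config.fs)
        fit = fit_glm_cochrane_orcutt(hbo[0], dm)
        for ci, c in enumerate(config.conditions):
            assert fit.coef(c)[0] == pytest.approx(amps[0, ci], abs=1e-9)

    def test_rho_matches_autocorrelation_oracle(self, design_matrix, rng, quiet):
        X = design_matrix.matrix
        keep = ~np.all(X == 0.0, axis=0)
        Xk = X[:, keep]
        y = Xk @ rng.normal(size=Xk.shape[1]) + rng.normal(size=X.shape[0])
        fit = fit_glm_cochrane_orcutt(y, design_matrix)
        beta1, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        e = y - Xk @ beta1
        assert fit.rho == pytest.approx(np.sum(e[1:] * e[:-1]) / np.sum(e ** 2), rel=1e-10)

    def test_stage2_matches_statsmodels_on_transformed_model(self, design_matrix, rng, quiet):
        """Dual route: our stage-2 estimates equal an independent OLS fit of
        the quasi-differenced data."""
        import statsmodels.api as sm

        X = design_matrix.matrix
        keep = ~np.all(X == 0.0, axis=0)
        Xk = X[:, keep]
        y = Xk @ rng.normal(size=Xk.shape[1]) + np.cumsum(rng.normal(size=X.shape[0])) * 0.01
        fit = fit_glm_cochrane_orcutt(y, design_matrix)
        ys = y[1:] - fit.rho * y[:-1]
        Xs = Xk[1:] - fit.rho * Xk[:-1]
        ref = sm.OLS(ys, Xs).fit()
        kept_labels = [l for l, k in zip(design_matrix.labels, keep) if k]
        for i, label in enumerate(kept_labels):
            beta, se, t = fit.coef(label)
            assert beta == pytest.approx(ref.params[i], rel=1e-8)
            assert se == pytest.approx(ref.bse[i], rel=1e-6)
            assert t == pytest.approx(ref.tvalues[i], rel=1e-6)
        assert fit.dof == int(ref.df_resid)

    def test_t_invariant_to_rescaling(self, design_matrix, rng, quiet):
        X = design_matrix.matrix
        y = X[:, 0] * 0.05 + rng.normal(size=X.shape[0]) * 0.02
        f1 = fit_glm_cochrane_orcutt(y, design_matrix)
        f2 = fit_glm_cochrane_orcutt(1000.0 * y, design_matrix)
        b1, _, t1 = f1.coef("A-ONLY")
        b2, _, t2 = f2.coef("A-ONLY")
        assert b2 == pytest.approx(1000.0 * b1, rel=1e-9)
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_rank_deficiency_rejected(self, quiet):
        from nirsrel.glm import DesignMatrix
        X = np.column_stack([np.ones(50), np.ones(50)])
        dm = DesignMatrix(matrix=X, labels=("a", "intercept"), fs=10.0)
        with pytest.raises(EstimationError):
            fit_glm_cochrane_orcutt(np.random.default_rng(0).normal(size=50), dm)


class TestOneSidedP:
    def test_zero_t_gives_half(self):
        assert one_sided_p(0.0, 30, "functional") == pytest.approx(0.5)
        assert one_sided_p(0.0, 30, "hbr") == pytest.approx(0.5)

    def test_tail_convention(self):
        assert one_sided_p(-4.0, 30, "hbr") < 0.01
        assert one_sided_p(-4.0, 30, "hbo") > 0.99

    def test_matches_numeric_cdf_oracle(self):
        dof, t_val = 25, 1.7
        upper, _ = integrate.quad(lambda u: stats.t.pdf(u, dof), t_val, np.inf)
        assert one_sided_p(t_val, dof, "functional") == pytest.approx(upper, rel=1e-6)

    def test_unknown_measure_rejected(self):
        with pytest.raises(InputError):
            one_sided_p(1.0, 10, "total-haemoglobin")


def _by_oracle(p, q=0.05):
    """Exhaustive step-up search over all rejection counts."""
    m = len(p)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    best = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / (m * c_m):
            best = i
    return frozenset(int(j) for j in order[:best])


class TestFDR:
    def test_all_ones_rejects_nothing(self):
        assert fdr_correct(np.ones(24)) == frozenset()

    def test_uniform_strong_signal_rejects_all(self):
        assert fdr_correct(np.full(24, 1e-6)) == frozenset(range(24))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            p = rng.uniform(size=24) ** rng.uniform(1, 4)
            assert fdr_correct(p) == _by_oracle(p)

    def test_matches_statsmodels_by(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(30):
            p = rng.uniform(size=24) ** 3
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_by")
            assert fdr_correct(p) == frozenset(np.nonzero(reject)[0])

    def test_by_subset_of_bh(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(30):
            p = rng.uniform(size=24) ** 2
            bh, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert fdr_correct(p) <= frozenset(np.nonzero(bh)[0])

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            fdr_correct([0.5, 1.2])


class TestGroupLevel:
    def test_saturated_signal_flags_all_channels(self, rng):
        betas = 1.0 + 0.001 * rng.normal(size=(10, 24))
        amap = group_level_map(betas, "functional")
        assert amap.significant == tuple(range(1, 25))

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(InputError):
            group_level_map(np.ones((1, 24)), "hbo")

    def test_null_betas_control_false_discoveries(self, rng):
        """Under a zero-mean null the false-discovery proportion stays at
        or below q on average."""
        fdps = []
        for _ in range(300):
            betas = rng.normal(size=(17, 24))
            amap = group_level_map(betas, "functional", q=0.05)
            fdps.append(len(amap.significant) > 0)
        assert np.mean(fdps) <= 0.05 + 0.03
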