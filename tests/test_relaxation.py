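"""NH correlation functions, multi-exponential fitting, and observables."""

import numpy as np
import pandas as pd
import pytest

import idrdyn.relaxation as rx
import idrdyn.synthetic as syn
from idrdyn.ensemble import VectorSeries


class TestNHCorrelation:
    def test_constant_vector_gives_unit_correlation(self):
        v = np.tile(np.array([0.0, 0.0, 1.0]), (50, 1, 1))
        vs = VectorSeries(residue_ids=[1], vectors=v, frame_interval=20.0)
        corr = rx.nh_correlation(vs, max_lag=0.5)[0]
        assert np.allclose(corr.values, 1.0, atol=1e-12)

    def test_alternating_orthogonal_vectors(self):
        # z, x, z, x ...: P2(0) = -1/2 at odd lags, P2(1) = 1 at even lags
        v = np.zeros((40, 1, 3))
        v[0::2, 0, 2] = 1.0
        v[1::2, 0, 0] = 1.0
        vs = VectorSeries(residue_ids=[1], vectors=v, frame_interval=20.0)
        corr = rx.nh_correlation(vs, max_lag=0.2)[0]
        assert np.allclose(corr.values[0::2], -0.5, atol=1e-12)  # odd lags
        assert np.allclose(corr.values[1::2], 1.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        vs, _ = syn.rotdiff_vector_series(D=0.3, n_frames=400, seed=5, n_vectors=2)
        corrs = rx.nh_correlation(vs, max_lag=2.0)
        for j, corr in enumerate(corrs):
            bf = rx.brute_force_p2_correlation(vs.vectors[:, j, :], corr.lags_ns.size)
            assert np.allclose(corr.values, bf, atol=1e-12)

    def test_max_lag_truncated_with_warning(self):
        vs, _ = syn.rotdiff_vector_series(D=0.3, n_frames=50, seed=0)
        with pytest.warns(UserWarning):
            corr = rx.nh_correlation(vs, max_lag=25.0)[0]
        assert corr.lags_ns.size == 49


class TestLadder:
    def test_thresholds_match_model_selection_rule(self):
        assert rx.ladder_threshold(1) == 0.25
        assert rx.ladder_threshold(2) == pytest.approx(1.0 / 6.0)

    def test_noiseless_single_exponential_selects_order_one(self):
        corr, _ = syn.multiexp_corr_samples([0.8], [5.0])
        fit = rx.multiexp_fit_ladder(corr)
        assert fit.order == 1
        assert fit.amplitudes[0] == pytest.approx(0.8, abs=1e-3)
        assert fit.taus_ns[0] == pytest.approx(5.0, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_three_exponential_recovery_with_noise(self, seed):
        truth_a = np.array([0.22, 0.36, 0.23])
        truth_t = np.array([11.5, 2.4, 0.34])
        corr, _ = syn.multiexp_corr_samples(truth_a, truth_t, noise_sd=5e-4, seed=seed)
        fit = rx.multiexp_fit_ladder(corr)
        assert fit.order == 3
        assert np.all(np.abs(fit.taus_ns - truth_t) / truth_t < 0.10)
        assert np.all(np.diff(fit.taus_ns) < 0)  # tau_1 > tau_2 > tau_3
        assert fit.a_sum == pytest.approx(truth_a.sum(), abs=0.05)

    def test_fit_failure_raises_with_diagnostics(self):
        corr = rx.CorrelationFunction(1, np.linspace(0.02, 1, 60), np.full(60, np.nan))
        with pytest.raises(RuntimeError, match="residue 1"):
            rx.multiexp_fit_ladder(corr)


def _fit(amps, taus, residue=1):
    amps = np.asarray(amps, dtype=float)
    taus = np.asarray(taus, dtype=float)
    return rx.MultiExpFit(
        residue_id=residue, order=len(amps), amplitudes=amps,
        amplitude_errors=np.zeros_like(amps), taus_ns=taus,
        tau_errors_ns=np.zeros_like(taus), chi2=0.0,
    )


class TestSpectralDensity:
    def test_j0_equals_amplitude_weighted_tau(self):
        assert rx.spectral_density(_fit([1.0], [1.0])) == pytest.approx(1e-9)

    def test_omega_tau_one_halves_the_term(self):
        tau_s = 1e-9
        j = rx.spectral_density(_fit([0.6], [1.0]), omega=1.0 / tau_s)
        assert j == pytest.approx(0.6 * tau_s / 2.0)

    def test_timescale_rescaling_value(self):
        corr = rx.Corrections(tau_s_ns=16.75)
        eff = corr.effective_taus_ns(np.array([11.5]))
        assert eff[0] == pytest.approx(11.5 / (1.0 + 11.5 / 16.75))
        assert eff[0] == pytest.approx(6.82, abs=0.01)

    def test_ultrafast_component_restores_unit_amplitude(self):
        fit = _fit([0.5, 0.3], [10.0, 1.0])
        corr = rx.Corrections(tau_f_ps=10.0)
        # total amplitude of the corrected model: A_sum + (1 - A_sum) = 1
        assert fit.a_sum + (1.0 - fit.a_sum) == 1.0
        j0 = rx.spectral_density(fit, corr, 0.0)
        assert j0 == pytest.approx((0.5 * 10 + 0.3 * 1) * 1e-9 + 0.2 * 10e-12)

    def test_j_monotonically_decreasing_in_frequency(self):
        fit = _fit([0.4, 0.4], [8.0, 0.5])
        omegas = np.linspace(0, 5e9, 50)
        j = rx.spectral_density(fit, omega=omegas)
        assert np.all(np.diff(j) < 0)


class TestObservables:
    def test_null_spectral_density_gives_zero_rates(self):
        rec = rx.relaxation_observables(_fit([0.0], [1.0]))
        assert rec.r1 == 0.0 and rec.r2 == 0.0
        assert np.isnan(rec.noe)

    def test_dipolar_constant_magnitude(self):
        # f_DD = (1/10) (mu0 hbar gammaN gammaH / 4 pi r^3)^2 ~ 5.2e8 s^-2
        assert rx.FieldParams().f_dd == pytest.approx(5.2e8, rel=0.01)

    def test_extreme_narrowing_noe_limit(self):
        fp = rx.FieldParams(delta_csa_ppm=0.0)
        rec = rx.relaxation_observables(_fit([1.0], [1e-6]), fieldp=fp)
        assert rec.noe == pytest.approx(1.0 + fp.gamma_h / (2.0 * fp.gamma_n), rel=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_r2_at_least_half_r1(self, seed):
        rng = np.random.default_rng(seed)
        fit = _fit(rng.uniform(0.05, 0.4, 3), np.sort(rng.uniform(0.1, 15.0, 3))[::-1])
        rec = rx.relaxation_observables(fit)
        assert rec.r2 >= rec.r1 / 2.0


class TestAUC:
    def test_arithmetic_decomposition(self):
        table = rx.auc_profile([_fit([0.5, 0.3], [10.0, 1.0])])
        assert table.loc[1, "auc_ns"] == pytest.approx(5.3)
        assert table.loc[1, "term1_ns"] == pytest.approx(5.0)

    def test_equals_spectral_density_at_zero(self):
        fit = _fit([0.22, 0.36, 0.23], [11.5, 2.4, 0.34])
        corr = rx.Corrections(tau_f_ps=10.0)
        table = rx.auc_profile([fit], corr)
        assert table.loc[1, "auc_ns"] == pytest.approx(
            rx.spectral_density(fit, corr, 0.0) * 1e9, abs=1e-12
        )

    def test_rescaling_strictly_decreases_auc(self):
        fit = _fit([0.4, 0.3], [12.0, 2.0])
        plain = rx.auc_profile([fit]).loc[1, "auc_ns"]
        scaled = rx.auc_profile([fit], rx.Corrections(tau_s_ns=16.75)).loc[1, "auc_ns"]
        assert scaled < plain


class TestCompareProfiles:
    def _tables(self, offset=0.0, sd=0.0, n_rep=3, seed=0):
        rng = np.random.default_rng(seed)
        residues = np.arange(1, 31)
        truth = 4.0 + 0.5 * np.sin(residues / 4.0)
        exp = pd.Series(truth, index=residues)
        pred = pd.DataFrame(
            {r: truth + offset + rng.normal(scale=sd, size=truth.size) for r in range(n_rep)},
            index=residues,
        )
        return pred, exp

    def test_perfect_prediction_zero_rmse(self):
        pred, exp = self._tables()
        assert rx.compare_profiles(pred, exp).rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_rmse_delta(self):
        pred, exp = self._tables(offset=0.7)
        assert rx.compare_profiles(pred, exp).rmse == pytest.approx(0.7)

    def test_terminal_residues_excluded(self):
        pred, exp = self._tables()
        exp.iloc[0] += 100.0  # corrupt the first residue only
        assert rx.compare_profiles(pred, exp, exclude_terminal=1).rmse == pytest.approx(
            0.0, abs=1e-12
        )

    def test_bootstrap_ci_width_scales_with_replicate_noise(self):
        sd = 0.3
        pred, exp = self._tables(sd=sd, n_rep=12, seed=42)
        comp = rx.compare_profiles(pred, exp, n_boot=2000, seed=1)
        width = (comp.table["ci_high"] - comp.table["ci_low"]).mean()
        analytic = 2.0 * 1.96 * sd / np.sqrt(12)
        assert width == pytest.approx(analytic, rel=0.20)

    def test_single_replicate_warns(self):
        pred, exp = self._tables(n_rep=1)
        with pytest.warns(UserWarning):
            rx.compare_profiles(pred, exp)
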