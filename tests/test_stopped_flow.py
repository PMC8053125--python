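"""Trace preprocessing, k_obs/k_on analysis and AIC/BIC comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aptakinetics as ak
from aptakinetics.errors import InputError
from aptakinetics.stopped_flow import (
    GlobalFitResult,
    normalize_contract,
)


def _mono_trace(k=20.0, amp=0.8, offset=0.2, n=200, t_end=1.0):
    t = np.linspace(0.0, t_end, n)
    return t, offset + amp * np.exp(-k * t)


class TestPreprocess:
    def test_identical_noiseless_shots_reduce_to_normalized_input(self):
        t, s = _mono_trace()
        trace = ak.preprocess([s.copy() for _ in range(25)], t, 8.0, 2.0)
        np.testing.assert_allclose(trace.signal, normalize_contract(s), atol=1e-12)
        assert trace.n_averaged == 25

    def test_affine_offset_and_scale_removed_exactly(self):
        t = np.linspace(0.0, 1.0, 300)
        pure = np.exp(-12.0 * t)
        trace = ak.preprocess([0.8 * pure + 0.2], t, 8.0, 2.0)
        np.testing.assert_allclose(trace.signal, normalize_contract(pure), atol=1e-12)

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        k=st.floats(5.0, 50.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_property(self, a, b, k):
        t = np.linspace(0.0, 1.0, 120)
        x = np.exp(-k * t)
        np.testing.assert_allclose(
            normalize_contract(a * x + b), normalize_contract(x), atol=1e-9
        )

    def test_shot_averaging_reduces_noise_as_sqrt_n(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 1.0, 400)
        clean = np.exp(-10.0 * t)
        n_shots, sigma = 20, 0.01
        shots = [clean + rng.normal(0, sigma, t.size) for _ in range(n_shots)]
        trace = ak.preprocess(shots, t, 8.0, 2.0)
        resid = trace.signal - normalize_contract(clean)
        # exclude the anchored first point; expect ~ sigma/sqrt(20)
        assert np.std(resid[1:]) == pytest.approx(sigma / np.sqrt(n_shots), rel=0.4)

    def test_unreached_plateau_flagged(self):
        t = np.linspace(0.0, 1.0, 200)
        slow = np.exp(-1.5 * t)  # still decaying at the end of the window
        trace = ak.preprocess([slow], t, 8.0, 2.0)
        assert trace.plateau_warning

    def test_requires_at_least_one_trace(self):
        with pytest.raises(InputError):
            ak.preprocess([], np.linspace(0, 1, 10), 8.0, 2.0)


class TestMonoExponential:
    def test_exact_rate_recovered_from_pure_exponential(self):
        t, s = _mono_trace(k=20.0, amp=1.0, offset=0.0)
        trace = ak.StoppedFlowTrace(t, s, 8.0, 2.0)
        fit = ak.fit_monoexponential(trace)
        assert fit.success
        assert fit.k_obs == pytest.approx(20.0, rel=1e-6)

    def test_model1_trace_kobs_near_pseudo_first_order_value(self):
        # mild deviation from a single exponential due to ligand depletion
        series = ak.gen_stopped_flow(
            "model1", {"k1": 7.78, "km1": 0.33},
            design=ak.StoppedFlowDesign(ligand_concs_uM=(4.0,), duration_s=0.5),
            noise=ak.NoiseSpec(sigma=0.0, seed=0),
        )
        fit = ak.fit_monoexponential(series.traces[0])
        assert fit.k_obs == pytest.approx(ak.pfo_kobs(7.78, 0.33, 4.0), rel=0.3)

    def test_model4_kobs_between_linearized_eigenvalues(self, a_model4):
        scheme, rates = a_model4
        L0 = 20.0  # 10 eq: ligand effectively constant
        series = ak.gen_stopped_flow(
            scheme, rates,
            design=ak.StoppedFlowDesign(ligand_concs_uM=(L0,), duration_s=1.0),
            noise=ak.NoiseSpec(sigma=0.0, seed=0),
        )
        fit = ak.fit_monoexponential(series.traces[0])
        # eigenvalues of the pseudo-first-order two-step rate matrix
        k1, km1, k2, km2 = (rates[s] for s in ("k1", "km1", "k2", "km2"))
        m = np.array([[-(k1 * L0 + 0), km1, 0],
                      [k1 * L0, -(km1 + k2), km2],
                      [0, k2, -km2]])
        eig = np.sort(np.abs(np.linalg.eigvals(m)))
        slow, fast = eig[1], eig[2]
        assert slow < fit.k_obs < fast

    def test_non_decaying_trace_reports_failure(self):
        t = np.linspace(0.0, 1.0, 100)
        trace = ak.StoppedFlowTrace(t, 1.0 - np.exp(-5 * t), 8.0, 2.0)
        fit = ak.fit_monoexponential(trace)
        assert not fit.success
        assert "decay" in fit.message


class TestKonRegression:
    @staticmethod
    def _series_from_kobs(concs, kobs):
        traces = []
        for c, k in zip(concs, kobs):
            t = np.linspace(0.0, max(8.0 / k, 0.2), 300)
            traces.append(ak.StoppedFlowTrace(t, np.exp(-k * t), c, 2.0))
        return ak.TraceSeries(traces=traces, label="synthetic")

    def test_exact_line_recovered(self):
        concs = np.array([4.0, 8.0, 12.0, 16.0, 20.0])
        series = self._series_from_kobs(concs, 5.0 * concs + 0.2)
        res = ak.kon_regression(series)
        assert res.k_on == pytest.approx(5.0, rel=1e-4)
        assert res.intercept == pytest.approx(0.2, rel=1e-2)
        assert not res.excluded

    def test_model1_series_slope_matches_association_rate(self):
        series = ak.gen_stopped_flow_preset(
            "A-model1", noise=ak.NoiseSpec(sigma=0.0, seed=0)
        )
        res = ak.kon_regression(series)
        assert res.k_on == pytest.approx(7.78, rel=0.05)

    def test_saturating_point_flagged_and_excluded(self):
        concs = np.array([4.0, 8.0, 12.0, 16.0, 20.0, 40.0])
        kobs = 5.0 * concs + 0.2
        kobs[-1] = 5.0 * 22.0  # k_obs plateaus at high ligand excess
        series = self._series_from_kobs(concs, kobs)
        res = ak.kon_regression(series)
        assert res.excluded == [5]
        assert res.k_on == pytest.approx(5.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        concs = np.array([4.0, 8.0])
        series = self._series_from_kobs(concs, 5.0 * concs)
        with pytest.raises(InputError, match=">= 3"):
            ak.kon_regression(series)


class TestPredictSignal:
    def test_fully_responding_complexes_give_constant_signal(self, time_grid):
        obs = ak.ObservableMap(responses={"B": 1.0})
        signal = ak.predict_signal(
            "model1", {"k1": 5.0, "km1": 0.1}, obs, 8.0, 2.0, time_grid
        )
        np.testing.assert_allclose(signal, signal[0], atol=1e-8)

    def test_complete_quench_when_receptor_in_excess(self, time_grid):
        grid = np.linspace(0.0, 5.0, 100)
        signal = ak.predict_signal(
            "model5", {"k1": 5.0, "km1": 0.0, "k2": 10.0},
            ak.ObservableMap(), 2.0, 4.0, grid,
        )
        assert abs(signal[-1]) < 1e-3

    def test_long_time_signal_matches_equilibrium_algebra(self, a_model4):
        scheme, rates = a_model4
        L0, R0 = 4.0, 2.0
        kd = ak.apparent_kd(scheme, rates)
        # exact 1:1 equilibrium with depletion: (R0-C)(L0-C) = kd*C
        s = R0 + L0 + kd
        bound_eq = 0.5 * (s - np.sqrt(s**2 - 4 * R0 * L0))
        grid = np.linspace(0.0, 60.0, 400)
        raw_end_expected = (L0 - bound_eq) / L0
        traj = ak.simulate(scheme, rates, ak.initial_state(scheme, R0, L0, rates), grid)
        raw_end = traj["L"][-1] / L0
        assert raw_end == pytest.approx(raw_end_expected, rel=1e-4)


class TestModelComparison:
    @staticmethod
    def _fit(scheme_id, rss, n, p):
        return GlobalFitResult(
            scheme_id=scheme_id, rates={}, rate_se={}, responses={},
            response_se={}, rss=rss, rmsd=np.sqrt(rss / n), n_points=n,
            n_parameters=p, n_starts=1, seed=0, success=True,
        )

    def test_equal_rss_penalty_identities(self):
        n = 1000
        table = ak.compare_models(
            [self._fit("model1", 1.0, n, 2), self._fit("model4", 1.0, n, 3)]
        )
        by_id = {r.scheme_id: r for r in table.rows}
        assert by_id["model4"].delta_aic == pytest.approx(2.0)
        assert by_id["model4"].delta_bic == pytest.approx(np.log(n))
        assert by_id["model1"].delta_aic == 0.0

    def test_single_fit_has_zero_deltas(self):
        table = ak.compare_models([self._fit("model1", 1.0, 100, 2)])
        assert table.rows[0].delta_aic == 0.0
        assert table.rows[0].delta_bic == 0.0

    def test_deltas_nonnegative_with_zero_minimum(self):
        rng = np.random.default_rng(7)
        fits = [
            self._fit(f"m{i}", float(rng.uniform(0.5, 5.0)), 500, int(rng.integers(2, 6)))
            for i in range(5)
        ]
        table = ak.compare_models(fits)
        assert min(r.delta_aic for r in table.rows) == 0.0
        assert min(r.delta_bic for r in table.rows) == 0.0
        assert all(r.delta_aic >= 0 and r.delta_bic >= 0 for r in table.rows)

    def test_bic_penalty_stronger_per_parameter_above_e_squared(self):
        for n in (8, 100, 1000):
            aic_a, bic_a = ak.information_criteria(1.0, n, 2)
            aic_b, bic_b = ak.information_criteria(1.0, n, 3)
            assert (bic_b - bic_a) > (aic_b - aic_a)

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(InputError, match="n_points"):
            ak.compare_models(
                [self._fit("model1", 1.0, 100, 2), self._fit("model4", 1.0, 200, 4)]
            )
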