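import warnings

import numpy as np
import pytest

from mitopet.errors import FitError
from mitopet.kinetics import (
    FramePredictor,
    OneTissueParams,
    TwoTissueParams,
    fit_1tc,
    fit_2tc,
    fit_ma1,
    parameter_precision,
    predict_1tc,
    predict_2tc,
    select_model,
    time_stability,
)
from mitopet.synthetic_data import simulate_tac
from mitopet.tac_io import FrameSchedule, TimeActivityCurve

from conftest import ode_frame_oracle


class TestPredict1TC:
    def test_zero_influx_gives_zero(self, input_model, brain_sched):
        pred = predict_1tc(OneTissueParams(0.0, 0.1, 0.0), input_model, brain_sched)
        np.testing.assert_allclose(pred, 0.0, atol=1e-14)

    def test_pure_vascular_signal(self, input_model, brain_sched, brain_predictor):
        pred = predict_1tc(OneTissueParams(0.0, 0.1, 0.05), input_model, brain_sched)
        np.testing.assert_allclose(pred, 0.05 * brain_predictor.vb_frames, rtol=1e-12)

    def test_matches_independent_ode_solution(self, input_model, brain_sched):
        params = OneTissueParams(0.5, 0.05, 0.05)
        oracle = ode_frame_oracle(params, input_model, brain_sched)
        pred = predict_1tc(params, input_model, brain_sched)
        np.testing.assert_allclose(pred, oracle, rtol=1e-3)

    def test_schedule_beyond_input_support_rejected(self, brain_sched):
        class ShortInput:
            t_max = 30.0

            def parent_plasma(self, t):
                return np.ones(np.shape(t))

            def whole_blood(self, t):
                return np.ones(np.shape(t))

            def total_plasma(self, t):
                return np.ones(np.shape(t))

            def parent_fraction(self, t):
                return np.ones(np.shape(t))

        with pytest.raises(FitError, match="support"):
            predict_1tc(OneTissueParams(0.5, 0.05), ShortInput(), brain_sched)

    def test_time_unit_invariance(self, input_model, brain_sched):
        """Consistently converting minutes to seconds leaves the frame-level
        prediction unchanged."""

        class SecondsInput:
            t_max = np.inf

            def __init__(self, inner):
                self.inner = inner

            def parent_plasma(self, t):
                return self.inner.parent_plasma(np.asarray(t) / 60.0)

            def whole_blood(self, t):
                return self.inner.whole_blood(np.asarray(t) / 60.0)

            def total_plasma(self, t):
                return self.inner.total_plasma(np.asarray(t) / 60.0)

            def parent_fraction(self, t):
                return self.inner.parent_fraction(np.asarray(t) / 60.0)

        params_min = OneTissueParams(0.5, 0.05, 0.05)
        params_sec = OneTissueParams(0.5 / 60.0, 0.05 / 60.0, 0.05)
        sched_sec = FrameSchedule(
            brain_sched.start * 60.0, brain_sched.end * 60.0
        )
        a = predict_1tc(params_min, input_model, brain_sched, dt=0.05)
        b = predict_1tc(params_sec, SecondsInput(input_model), sched_sec, dt=3.0)
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestFit1TC:
    def test_noiseless_recovery(self, input_model, brain_sched, brain_params):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        fit = fit_1tc(tac, input_model)
        assert fit.converged
        assert fit.params.K1 == pytest.approx(brain_params.K1, rel=1e-3)
        assert fit.params.k2 == pytest.approx(brain_params.k2, rel=1e-3)
        assert fit.params.vB == pytest.approx(brain_params.vB, abs=1e-4)
        assert fit.vt == pytest.approx(10.0, rel=1e-3)

    def test_noisy_fit_truth_within_confidence(
        self, input_model, cardiac_sched, cardiac_params, cardiac_predictor
    ):
        tac, _ = simulate_tac(
            cardiac_params, input_model, cardiac_sched, noise_level=0.3,
            seed=42, predictor=cardiac_predictor,
        )
        fit = fit_1tc(tac, input_model, predictor=cardiac_predictor)
        assert abs(fit.vt - cardiac_params.VT) < 4 * fit.vt_se

    def test_scale_equivariance(self, input_model, brain_sched, brain_params):
        """Multiplying TAC and input by a constant leaves the kinetic
        parameters unchanged."""

        class ScaledInput:
            t_max = np.inf

            def __init__(self, inner, c):
                self.inner, self.c = inner, c

            def parent_plasma(self, t):
                return self.c * self.inner.parent_plasma(t)

            def whole_blood(self, t):
                return self.c * self.inner.whole_blood(t)

            def total_plasma(self, t):
                return self.c * self.inner.total_plasma(t)

            def parent_fraction(self, t):
                return self.inner.parent_fraction(t)

        tac, _ = simulate_tac(
            brain_params, input_model, brain_sched, noise_level=0.2, seed=5
        )
        fit = fit_1tc(tac, input_model)
        c = 37.5
        scaled_tac = TimeActivityCurve(
            tac.schedule, c * tac.concentration, tac.region, tac.subject_id,
            has_noise_model=True,
        )
        fit_scaled = fit_1tc(scaled_tac, ScaledInput(input_model, c))
        for nm in fit.param_names:
            assert getattr(fit_scaled.params, nm) == pytest.approx(
                getattr(fit.params, nm), rel=1e-6, abs=1e-12
            )

    def test_too_few_frames_rejected(self, input_model):
        sched = FrameSchedule(np.arange(5.0), np.arange(5.0) + 1.0)
        tac = TimeActivityCurve(sched, np.ones(5), "r", "s")
        with pytest.raises(FitError, match="6 frames"):
            fit_1tc(tac, input_model)


class TestFit2TC:
    def test_nested_model_agrees_on_1tc_data(
        self, input_model, brain_sched, brain_params
    ):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        vt_1tc = fit_1tc(tac, input_model).vt
        vt_2tc = fit_2tc(tac, input_model).vt
        assert vt_2tc == pytest.approx(vt_1tc, rel=0.02)

    def test_noiseless_2tc_recovery(self, input_model, brain_sched):
        truth = TwoTissueParams(0.3, 0.2, 0.05, 0.05, 0.0)
        assert truth.VT == pytest.approx(3.0)
        tac, _ = simulate_tac(truth, input_model, brain_sched)
        fit = fit_2tc(tac, input_model)
        assert fit.vt == pytest.approx(3.0, rel=0.01)

    def test_k3_zero_reduces_to_1tc(self, input_model, brain_sched):
        truth = TwoTissueParams(0.5, 0.05, 1e-9, 0.05, 0.0)
        tac, _ = simulate_tac(truth, input_model, brain_sched)
        fit = fit_2tc(tac, input_model)
        assert fit.params.k3 <= 1e-3


class TestSelectModel:
    def test_parsimony_on_1tc_data(self, input_model, brain_sched, brain_params):
        tac, _ = simulate_tac(
            brain_params, input_model, brain_sched, noise_level=0.1, seed=11
        )
        f1 = fit_1tc(tac, input_model)
        f2 = fit_2tc(tac, input_model)
        assert select_model([f1, f2]).model == "1tc"

    def test_tie_goes_to_fewer_parameters(self, input_model, brain_sched, brain_params):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        f1 = fit_1tc(tac, input_model)
        f2 = fit_2tc(tac, input_model)
        f2.aic = f1.aic  # constructed tie
        assert select_model([f2, f1]).model == "1tc"

    def test_single_converged_candidate_warns(
        self, input_model, brain_sched, brain_params
    ):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        f1 = fit_1tc(tac, input_model)
        f2 = fit_2tc(tac, input_model)
        f2.converged = False
        with pytest.warns(UserWarning, match="only one converged"):
            assert select_model([f1, f2]) is f1

    def test_no_converged_fit_raises(self, input_model, brain_sched, brain_params):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        f1 = fit_1tc(tac, input_model)
        f1.converged = False
        with pytest.raises(FitError):
            select_model([f1])


class _ConstantInfusionInput:
    """Constant plasma concentration from injection onward."""

    t_max = np.inf

    def __init__(self, level=5.0):
        self.level = level

    def _const(self, t):
        return np.full(np.shape(np.atleast_1d(t)), self.level)

    parent_plasma = _const
    total_plasma = _const
    whole_blood = _const

    def parent_fraction(self, t):
        return np.ones(np.shape(np.atleast_1d(t)))


class TestMA1:
    def test_cross_estimator_agreement_noiseless(
        self, input_model, brain_sched, brain_params
    ):
        tac, _ = simulate_tac(
            OneTissueParams(brain_params.K1, brain_params.k2, 0.0),
            input_model, brain_sched,
        )
        fit = fit_ma1(tac, input_model, t_star=30.0)
        assert fit.converged
        assert fit.vt == pytest.approx(10.0, rel=0.01)
        assert fit.b < 0

    def test_equilibrium_recovery_constant_infusion(self):
        """Under constant infusion the tissue approaches V_T·Cp and MA1
        recovers V_T from the approach to equilibrium."""
        infusion = _ConstantInfusionInput()
        sched = FrameSchedule(np.arange(0, 120, 5.0), np.arange(0, 120, 5.0) + 5.0)
        truth = OneTissueParams(0.5, 0.05, 0.0)
        tac, clean = simulate_tac(truth, infusion, sched)
        assert clean[-1] == pytest.approx(truth.VT * infusion.level, rel=0.01)
        fit = fit_ma1(tac, infusion, t_star=20.0)
        assert fit.vt == pytest.approx(truth.VT, rel=1e-3)

    def test_t_star_beyond_last_frame_rejected(self, input_model, brain_sched):
        tac = TimeActivityCurve(
            brain_sched, np.ones(brain_sched.n_frames), "r", "s"
        )
        with pytest.raises(FitError):
            fit_ma1(tac, input_model, t_star=80.0)

    def test_irreversible_uptake_flagged(self, input_model, brain_sched):
        """Accumulating (non-reversible-appearing) tissue kinetics produce a
        non-negative second MA1 coefficient and a flagged result."""
        from scipy.integrate import solve_ivp

        def rhs(t, y):  # dC/dt = K1*Cp + 0.01*C: supralinear accumulation
            cp = float(np.atleast_1d(input_model.parent_plasma(t))[0])
            return [0.3 * cp + 0.01 * y[0]]

        sol = solve_ivp(rhs, (0.0, brain_sched.total_end), [0.0],
                        method="LSODA", rtol=1e-9, dense_output=True)
        conc = np.array([float(sol.sol(t)[0]) for t in brain_sched.mid])
        tac = TimeActivityCurve(brain_sched, conc, "r", "s")
        fit = fit_ma1(tac, input_model, t_star=30.0)
        assert not fit.converged
        assert "non_reversible_appearance" in fit.flags
        assert np.isnan(fit.vt)


class TestTimeStability:
    def test_full_duration_is_identity(
        self, input_model, cardiac_sched, cardiac_params, cardiac_predictor
    ):
        tac, _ = simulate_tac(
            cardiac_params, input_model, cardiac_sched,
            predictor=cardiac_predictor,
        )
        df = time_stability(tac, input_model, [cardiac_sched.total_end])
        assert df.percent_difference.iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_slow_kinetics_error_shrinks_with_duration(
        self, input_model, cardiac_sched, cardiac_params, cardiac_predictor
    ):
        tac, _ = simulate_tac(
            cardiac_params, input_model, cardiac_sched,
            predictor=cardiac_predictor,
        )
        df = time_stability(tac, input_model, [60.0, 120.0, 285.0, 435.0])
        diffs = df.percent_difference.abs().to_numpy()
        assert np.all(np.diff(diffs) <= 1e-6)

    def test_truncation_leaving_too_few_frames_flagged(
        self, input_model, cardiac_params
    ):
        # 15-min frames: only 4 end by 60 min, below the 6-frame minimum
        sched = FrameSchedule(np.arange(0, 120, 15.0), np.arange(0, 120, 15.0) + 15.0)
        tac, _ = simulate_tac(cardiac_params, input_model, sched)
        df = time_stability(tac, input_model, [60.0, 120.0])
        assert df.flagged.iloc[0]
        assert np.isnan(df.percent_difference.iloc[0])
        assert not df.flagged.iloc[1]

    def test_truncation_below_60_rejected(
        self, input_model, cardiac_sched, cardiac_params
    ):
        tac, _ = simulate_tac(cardiac_params, input_model, cardiac_sched)
        with pytest.raises(ValueError):
            time_stability(tac, input_model, [30.0])


class TestParameterPrecision:
    def test_noiseless_cov_is_negligible(
        self, input_model, brain_sched, brain_params
    ):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        cov = parameter_precision(fit_1tc(tac, input_model))
        assert cov["VT"] < 1e-3

    def test_doubling_noise_doubles_vt_cov(
        self, input_model, brain_sched, brain_params, brain_predictor
    ):
        ratios = []
        for rep in range(40):
            covs = []
            for level in (0.1, 0.2):
                tac, _ = simulate_tac(
                    brain_params, input_model, brain_sched, noise_level=level,
                    seed=900 + rep, predictor=brain_predictor,
                )
                covs.append(
                    parameter_precision(
                        fit_1tc(tac, input_model, predictor=brain_predictor)
                    )["VT"]
                )
            ratios.append(covs[1] / covs[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_delta_method_matches_bootstrap(
        self, input_model, brain_sched, brain_params, brain_predictor
    ):
        """K1 %COV from the fit covariance vs a 500-replicate parametric
        bootstrap, within 30% relative.  Weights match the generating noise
        variance (duration/concentration) so the delta-method covariance is
        computed under a correctly specified model."""
        level = 0.2
        tac, clean = simulate_tac(
            brain_params, input_model, brain_sched, noise_level=level,
            seed=77, predictor=brain_predictor,
        )
        weights = brain_sched.duration / np.maximum(clean, 1e-3)
        fit = fit_1tc(tac, input_model, weights=weights,
                      predictor=brain_predictor)
        analytic = parameter_precision(fit)["K1"]
        k1s = np.empty(500)
        for i in range(500):
            rep, _ = simulate_tac(
                brain_params, input_model, brain_sched, noise_level=level,
                seed=10_000 + i, predictor=brain_predictor,
            )
            k1s[i] = fit_1tc(
                rep, input_model, weights=weights, n_starts=2,
                predictor=brain_predictor,
            ).params.K1
        bootstrap = 100.0 * k1s.std(ddof=1) / k1s.mean()
        assert analytic == pytest.approx(bootstrap, rel=0.30)

    def test_non_converged_fit_rejected(
        self, input_model, brain_sched, brain_params
    ):
        tac, _ = simulate_tac(brain_params, input_model, brain_sched)
        fit = fit_1tc(tac, input_model)
        fit.converged = False
        with pytest.raises(FitError):
            parameter_precision(fit)
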