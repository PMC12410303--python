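import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, database=None)
settings.load_profile("derandomized")

from mitopet.kinetics import FramePredictor, OneTissueParams
from mitopet.synthetic_data import (
    InputFunctionModel,
    brain_schedule,
    cardiac_multisession_schedule,
    cardiac_static_schedule,
)


@pytest.fixture(scope="session")
def input_model():
    return InputFunctionModel()


@pytest.fixture(scope="session")
def brain_sched():
    return brain_schedule()


@pytest.fixture(scope="session")
def cardiac_sched():
    return cardiac_multisession_schedule()


@pytest.fixture(scope="session")
def static_sched():
    return cardiac_static_schedule()


@pytest.fixture(scope="session")
def brain_predictor(input_model, brain_sched):
    return FramePredictor(input_model, brain_sched)


@pytest.fixture(scope="session")
def cardiac_predictor(input_model, cardiac_sched):
    return FramePredictor(input_model, cardiac_sched)


@pytest.fixture(scope="session")
def cardiac_params():
    """Heart-like kinetics: influx ~100x efflux, V_T = 100."""
    return OneTissueParams(K1=0.5, k2=0.005, vB=0.1)


@pytest.fixture(scope="session")
def brain_params():
    """Brain-like kinetics: V_T = 10."""
    return OneTissueParams(K1=0.5, k2=0.05, vB=0.05)


def ode_frame_oracle(params, input_model, schedule, rtol=1e-10):
    """Independent stiff-ODE frame-averaged 1TC prediction.

    Integrates dC/dt = K1·Cp − k2·C (augmented with its running integral for
    exact frame averages) with LSODA, and adds the vascular term from direct
    quadrature of the whole-blood curve.  Shares no code with the package's
    recurrence-based predictor.
    """
    from scipy.integrate import quad, solve_ivp

    K1, k2, vB = params.K1, params.k2, params.vB

    def rhs(t, y):
        cp = float(np.atleast_1d(input_model.parent_plasma(t))[0])
        return [K1 * cp - k2 * y[0], y[0]]

    sol = solve_ivp(
        rhs,
        (0.0, schedule.total_end),
        [0.0, 0.0],
        method="LSODA",
        rtol=rtol,
        atol=1e-13,
        dense_output=True,
        max_step=0.5,
    )
    tissue = np.array(
        [
            (sol.sol(e)[1] - sol.sol(s)[1]) / (e - s)
            for s, e in zip(schedule.start, schedule.end)
        ]
    )
    wb = np.array(
        [
            quad(
                lambda t: float(np.atleast_1d(input_model.whole_blood(t))[0]),
                s,
                e,
                limit=200,
            )[0]
            / (e - s)
            for s, e in zip(schedule.start, schedule.end)
        ]
    )
    return (1.0 - vB) * tissue + vB * wb
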