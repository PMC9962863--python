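import numpy as np
import pytest

import hemoscale as hs
from hemoscale.pk import EPO, ROMI, SC, DoseEvent
from hemoscale.synthetic import StudyDesign


@pytest.fixture(scope="session")
def human_pk():
    return hs.default_human_pk()


@pytest.fixture(scope="session")
def human_pd():
    return hs.default_human_pd()


@pytest.fixture(scope="session")
def human_baselines(human_pd):
    return hs.derive_baselines(human_pd)


@pytest.fixture(scope="session")
def rat_pk():
    return hs.default_rat_pk()


@pytest.fixture(scope="session")
def rat_pd():
    return hs.default_rat_pd()


@pytest.fixture(scope="session")
def recovery_design():
    """Two-dose-level romiplostim study used by the estimation tests.

    A high (10 ug/kg) and a low (1 ug/kg) weekly SC arm with platelet
    sampling every two days over three weeks: concentrations straddle
    SC50_RM, which keeps the Emax/EC50 pair identifiable.  The coarse
    grid keeps each likelihood evaluation cheap.
    """
    def weekly(dose):
        return [DoseEvent(7 * w * 24.0, ROMI, SC, dose, 0.3)
                for w in range(2)]

    times = list(np.arange(0.0, 504.1, 48.0))
    return StudyDesign(
        arms={"romi_high": weekly(10.0), "romi_low": weekly(1.0)},
        sampling_times={"PLT": times},
        residual_cv={"PLT": 0.07},
        horizon_h=504.0,
        seed=0,
        grid_step_h=4.0,
    )


@pytest.fixture(scope="session")
def epo_only_design():
    """EPO-monotherapy-arm design: romiplostim parameters carry no
    information here (used for the non-identifiability check)."""
    epo_events = [
        DoseEvent((7 * w + off) * 24.0, EPO, SC, 450.0, 0.3)
        for w in range(2) for off in (0, 2, 4)
    ]
    times = list(np.arange(0.0, 504.1, 48.0))
    return StudyDesign(
        arms={"epo": epo_events},
        sampling_times={"PLT": times, "RBC": times},
        residual_cv={"PLT": 0.07, "RBC": 0.07},
        horizon_h=504.0,
        seed=1,
        grid_step_h=4.0,
    )
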