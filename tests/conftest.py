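import numpy as np
import pytest

from fpetki.frames import FrameSchedule
from fpetki.kinetics import internal_grid
from fpetki.synthetic import BloodModelParams, make_input_functions
from fpetki.types import AdministrationSchedule, InputFunctionSet, TaskSchedule


@pytest.fixture(scope="session")
def frames() -> FrameSchedule:
    return FrameSchedule.uniform(50.0, 1.0)


@pytest.fixture(scope="session")
def task() -> TaskSchedule:
    return TaskSchedule()


@pytest.fixture(scope="session")
def default_inputs() -> InputFunctionSet:
    """Bolus+infusion input functions from the default blood model."""
    return make_input_functions(AdministrationSchedule(), BloodModelParams())


@pytest.fixture(scope="session")
def constant_plasma_inputs() -> InputFunctionSet:
    """Idealized constant parent plasma with no metabolite and no blood
    signal difference (whole blood equal to plasma)."""
    t = internal_grid(50.0)
    cp = np.full_like(t, 10.0)
    return InputFunctionSet(t=t, whole_blood=cp, parent=cp, metabolite=np.zeros_like(t))
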