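import numpy as np
import pytest

from isletpk import (
    BiexpDisposition,
    InfusionProtocol,
    TwoCompParams,
    default_mouse_model,
    micro_from_macro,
)


@pytest.fixture
def mouse_disposition() -> BiexpDisposition:
    """Mouse blood clearance: 80% at 1.9 min, 20% at 26.8 min."""
    return BiexpDisposition(
        scale_c0=1.0,
        frac_fast=0.80,
        t_half_fast_min=1.9,
        frac_slow=0.20,
        t_half_slow_min=26.8,
    )


@pytest.fixture
def human_disposition() -> BiexpDisposition:
    """Human bolus disposition: 73% at 1 min, 27% at 63 min."""
    return BiexpDisposition(
        scale_c0=1.0,
        frac_fast=0.73,
        t_half_fast_min=1.0,
        frac_slow=0.27,
        t_half_slow_min=63.0,
    )


@pytest.fixture
def human_micro(human_disposition) -> TwoCompParams:
    return micro_from_macro(human_disposition)


@pytest.fixture
def infusion_60min() -> InfusionProtocol:
    return InfusionProtocol(rate=1.0, t_start=0.0, t_end=60.0)


@pytest.fixture
def infusion_schedule() -> list:
    """Rising phase, plateau approach, and post-infusion samples."""
    return [1, 2, 4, 8, 15, 30, 45, 60, 62, 65, 70, 80, 100, 130, 180]


@pytest.fixture
def mouse_model():
    return default_mouse_model()


def random_two_comp(rng: np.random.Generator) -> TwoCompParams:
    """A random identifiable two-compartment parameter set."""
    return TwoCompParams(
        k10=float(rng.uniform(0.01, 0.5)),
        k12=float(rng.uniform(0.01, 1.0)),
        k21=float(rng.uniform(0.01, 1.0)),
        v_central=float(rng.uniform(0.5, 5.0)),
    )
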