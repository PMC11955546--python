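import numpy as np
import pytest

import htrpet as hp


@pytest.fixture(scope="session")
def schedule():
    return hp.FrameSchedule.default_htr()


@pytest.fixture(scope="session")
def aif(schedule):
    return hp.generate_aif(hp.AIFConfig(), schedule)


@pytest.fixture(scope="session")
def small_spec():
    """Compact grid for fast fitting tests; the true parameters used in the
    recovery tests lie exactly on its nodes."""
    return hp.GridSpec(
        td_range=(1.0, 3.0), td_step=0.5, tc_range=(5.0, 9.0), tc_step=0.5, k2_range=(0.05, 1.0), n_k2=8
    )


@pytest.fixture(scope="session")
def fdg_like(small_spec):
    """Moderate-extraction parameter set on the small grid's nodes."""
    k2 = float(small_spec.k2_values()[4])
    return hp.AATHParams(cbf=0.5, k1=0.165, k2=k2, tc=7.0, td=2.0)


@pytest.fixture(scope="session")
def small_basis(small_spec, aif, schedule):
    return hp.precompute_bases(small_spec, aif, schedule, "aath")
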