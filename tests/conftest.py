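import pytest
from hypothesis import settings

import cleftflow as cf
from cleftflow.params import MM_TO_CGS, NM_TO_CM, UM_TO_CM

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Baseline constants: wide cleft, long cleft, hypertonic lumen."""
    return cf.Parameters()


@pytest.fixture(scope="session")
def fig3_params():
    """The canonical length-sweep conditions: c3=290, c4=300, c1=600 mM, b=400 nm."""
    return cf.Parameters(
        c3=290 * MM_TO_CGS, c4=300 * MM_TO_CGS, c1=600 * MM_TO_CGS,
        b=400 * NM_TO_CM, L=100 * UM_TO_CM,
    )


@pytest.fixture(scope="session")
def homogeneous_params(fig3_params):
    """Outlet and lumen pinned at c_hom: the homogeneous state is exact."""
    s = cf.derived_scales(fig3_params)
    return fig3_params.replace(c1=s.c_hom, c4=s.c_hom)
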