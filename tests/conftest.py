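import numpy as np
import pytest

from crcsim import (
    MutationProfile,
    ParameterSet,
    SigmoidParams,
    SimulationSettings,
    load_reference,
)


@pytest.fixture(scope="session")
def reference():
    """Shipped calibrated parameter set and its reference PHYL delay."""
    return load_reference()


@pytest.fixture(scope="session")
def ref_params(reference):
    return reference[0]


@pytest.fixture(scope="session")
def ref_tau(reference):
    return reference[1]


@pytest.fixture(scope="session")
def ref_settings(ref_tau):
    return SimulationSettings(t_end=28.0, tau=ref_tau)


@pytest.fixture(scope="session")
def wt_run(ref_params, ref_settings):
    from crcsim import normal_run

    return normal_run(ref_params, ref_settings)


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """A random, structurally valid parameter set (not biologically tuned)."""

    def sig():
        return SigmoidParams(
            a=float(rng.uniform(0.1, 5.0)),
            b=float(rng.uniform(0.2, 3.0)),
            n=float(rng.uniform(1.0, 4.0)),
        )

    return ParameterSet(
        sigmoid_asc_auto=sig(), sigmoid_asc_sens=sig(), sigmoid_asc_chn=sig(),
        sigmoid_sens=sig(), sigmoid_scrt=sig(), sigmoid_chn=sig(),
        sigmoid_phyl=sig(),
        m_x=float(rng.uniform(0.05, 2.0)), m_y=float(rng.uniform(0.05, 2.0)),
        m_e=float(rng.uniform(0.05, 2.0)), m_z=float(rng.uniform(0.05, 2.0)),
        m_u=float(rng.uniform(0.05, 2.0)), m_w=float(rng.uniform(0.05, 2.0)),
        m_p=float(rng.uniform(0.05, 2.0)),
        D=float(rng.uniform(0.0, 2.0)), G=float(rng.uniform(0.0, 2.0)),
        S=float(rng.uniform(0.0, 2.0)), U=float(rng.uniform(0.0, 2.0)),
        Cy=float(rng.uniform(0.0, 1.0)), Ce=float(rng.uniform(0.0, 1.0)),
        d1=float(rng.uniform(0.0, 2.0)), d2=float(rng.uniform(0.0, 2.0)),
        d3=float(rng.uniform(0.0, 2.0)), q=float(rng.uniform(0.0, 10.0)),
        x0=float(rng.uniform(0.0, 2.0)), y0=float(rng.uniform(0.0, 2.0)),
        z0=float(rng.uniform(0.0, 2.0)), u0=float(rng.uniform(0.0, 2.0)),
        w0=float(rng.uniform(0.0, 2.0)), p0=float(rng.uniform(0.0, 2.0)),
        E0=float(rng.uniform(0.0, 2.0)),
    )


def random_mutation(rng: np.random.Generator) -> MutationProfile:
    k = rng.uniform(0.0, 1.0, size=7)
    return MutationProfile(*map(float, k))
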