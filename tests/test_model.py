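"""Unit and property tests for the regulatory terms and the system RHS."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings as hsettings, strategies as st

from crcsim import (
    MutationProfile,
    ParameterSet,
    ProteinState,
    SigmoidParams,
    evaluate_rhs,
    hill_activation,
    repression_factor,
)
from crcsim.model import DomainError, NumericError

from conftest import random_mutation, random_parameter_set


# -- hill_activation ----------------------------------------------------------


@pytest.mark.parametrize(
    "v, params, expected",
    [
        (0.0, SigmoidParams(a=1.7, b=0.4, n=3.0), 0.0),
        (2.0, SigmoidParams(a=2.0, b=2.0, n=3.0), 1.0),  # half saturation
        (10.0, SigmoidParams(a=1.0, b=1.0, n=2.0), 100.0 / 101.0),
    ],
)
def test_hill_activation_values(v, params, expected):
    assert hill_activation(v, params) == pytest.approx(expected, rel=1e-12)


def test_hill_activation_rejects_negative_input():
    with pytest.raises(DomainError):
        hill_activation(-0.1, SigmoidParams(a=1, b=1, n=2))


@given(
    v1=st.floats(0, 50), v2=st.floats(0, 50),
    a=st.floats(0.01, 10), b=st.floats(0.01, 10), n=st.floats(0.5, 6),
)
@hsettings(max_examples=200, derandomize=True)
def test_hill_activation_bounded_and_monotone(v1, v2, a, b, n):
    p = SigmoidParams(a=a, b=b, n=n)
    lo, hi = sorted((v1, v2))
    r_lo, r_hi = hill_activation(lo, p), hill_activation(hi, p)
    # mathematically r < a strictly; to double precision r may round to a
    assert 0.0 <= r_lo <= r_hi <= a


def test_sigmoid_params_validation():
    with pytest.raises(DomainError):
        SigmoidParams(a=0.0, b=1.0, n=2.0)
    with pytest.raises(DomainError):
        SigmoidParams(a=1.0, b=-1.0, n=2.0)


# -- repression_factor --------------------------------------------------------


@pytest.mark.parametrize(
    "pairs, expected",
    [
        ([], 1.0),
        ([(1.0, 1.0)], 0.5),
        ([(0.5, 2.0), (1.0, 3.0)], 0.2),
    ],
)
def test_repression_factor_values(pairs, expected):
    assert repression_factor(pairs) == pytest.approx(expected, rel=1e-12)


@given(
    d=st.floats(0.01, 5), c1=st.floats(0, 10), delta=st.floats(0.01, 10)
)
@hsettings(max_examples=100, derandomize=True)
def test_repression_factor_strictly_decreasing(d, c1, delta):
    assert repression_factor([(d, c1 + delta)]) < repression_factor([(d, c1)])


def test_repression_factor_rejects_negative():
    with pytest.raises(DomainError):
        repression_factor([(-0.5, 1.0)])
    with pytest.raises(DomainError):
        repression_factor([(0.5, -1.0)])


# -- evaluate_rhs -------------------------------------------------------------


def test_rhs_at_origin_only_constitutive_terms(ref_params):
    """At the all-zero state only Hairy and EMC are produced."""
    d = evaluate_rhs(ProteinState(0, 0, 0, 0, 0, 0, 0), 0.0, ref_params)
    assert d.x == d.z == d.u == d.w == d.p == 0.0
    assert d.y == pytest.approx(ref_params.Cy)
    assert d.E == pytest.approx(ref_params.Ce)


def test_rhs_all_zero_mutation_is_pure_decay(ref_params):
    """k = 0 everywhere removes production; each species decays first-order."""
    state = ProteinState(x=1.3, y=0.7, E=0.4, z=0.2, u=0.9, w=0.1, p=0.5)
    mut = MutationProfile(0, 0, 0, 0, 0, 0, 0)
    d = evaluate_rhs(state, 2.0, ref_params, mut)
    p = ref_params
    # ASC keeps its PHYL-branch degradation in addition to first-order decay
    assert d.x == pytest.approx(-(p.m_x + p.q * p.S * p.U * state.p) * state.x)
    assert d.y == pytest.approx(-p.m_y * state.y)
    assert d.E == pytest.approx(-p.m_e * state.E)
    assert d.z == pytest.approx(-p.m_z * state.z)
    assert d.u == pytest.approx(-p.m_u * state.u)
    assert d.w == pytest.approx(-p.m_w * state.w)
    assert d.p == pytest.approx(-p.m_p * state.p)


def test_rhs_rejects_bad_inputs(ref_params):
    with pytest.raises(DomainError):
        evaluate_rhs(ProteinState(-0.1, 0, 0, 0, 0, 0, 0), 0.0, ref_params)
    with pytest.raises(NumericError) as err:
        evaluate_rhs(ProteinState(math.nan, 0, 0, 0, 0, 0, 0), 0.0, ref_params)
    assert "x" in str(err.value)
    with pytest.raises(DomainError):
        evaluate_rhs(ProteinState(1, 1, 1, 1, 1, 1, 1), -1.0, ref_params)


def _sympy_rhs(state, delayed, p: ParameterSet, k: MutationProfile):
    """Independent symbolic construction of the reference equations."""
    x, y, E, z, u, w, pp = [sp.Float(v, 30) for v in state]
    xd = sp.Float(delayed, 30)

    def hill(v, s: SigmoidParams):
        v = sp.sympify(v)
        return s.a * v ** s.n / (s.b ** s.n + v ** s.n)

    r_asc = 1 / (1 + p.G * y + E * x)
    dax = p.D * x
    dx = (
        k.k_x * (hill(dax, p.sigmoid_asc_auto) + hill(z, p.sigmoid_asc_sens)
                 + hill(w, p.sigmoid_asc_chn)) * r_asc
        - p.m_x * x - p.q * p.S * p.U * pp * x
    )
    dy = k.k_y * p.Cy / (1 + p.d2 * u + p.d3 * w) - p.m_y * y
    dE = k.k_e * p.Ce / (1 + p.d1 * w) - p.m_e * E
    dz = k.k_z * hill(dax, p.sigmoid_sens) - p.m_z * z
    du = k.k_u * hill(dax, p.sigmoid_scrt) - p.m_u * u
    dw = k.k_w * hill(dax, p.sigmoid_chn) - p.m_w * w
    dp = k.k_p * hill(p.D * xd, p.sigmoid_phyl) - p.m_p * pp
    return [float(sp.N(e, 25)) for e in (dx, dy, dE, dz, du, dw, dp)]


def test_rhs_matches_symbolic_oracle():
    """Numeric RHS agrees with a symbolic-algebra evaluation to 1e-12."""
    rng = np.random.default_rng(1234)
    for _ in range(100):
        params = random_parameter_set(rng)
        mut = random_mutation(rng)
        state_vals = rng.uniform(0.0, 3.0, size=7)
        delayed = float(rng.uniform(0.0, 3.0))
        got = evaluate_rhs(
            ProteinState.from_array(state_vals), delayed, params, mut
        ).as_array()
        want = np.array(_sympy_rhs(state_vals, delayed, params, mut))
        scale = np.maximum(np.abs(want), 1.0)
        assert np.all(np.abs(got - want) / scale < 1e-12)


def test_origin_derivative_never_negative():
    """Forward invariance of the non-negative orthant at its corner: no
    species can be driven negative from the all-zero state."""
    rng = np.random.default_rng(99)
    zero = ProteinState(0, 0, 0, 0, 0, 0, 0)
    for _ in range(50):
        d = evaluate_rhs(zero, 0.0, random_parameter_set(rng), random_mutation(rng))
        assert all(v >= 0.0 for v in d.as_array())


def test_asc_production_bound():
    """dx/dt never exceeds k_x times the summed activation amplitudes."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        params = random_parameter_set(rng)
        mut = random_mutation(rng)
        cap = mut.k_x * (
            params.sigmoid_asc_auto.a
            + params.sigmoid_asc_sens.a
            + params.sigmoid_asc_chn.a
        )
        state = ProteinState.from_array(rng.uniform(0, 4, size=7))
        d = evaluate_rhs(state, float(rng.uniform(0, 4)), params, mut)
        assert d.x <= cap + 1e-12


def test_removing_both_asc_repressors_raises_production(ref_params):
    """With Hairy and EMC absent (hairy-/emc- at steady state) ASC
    production at the same ASC level exceeds the wild-type value."""
    state_wt = ProteinState(x=2.0, y=0.8, E=0.5, z=0.5, u=0.5, w=0.5, p=0.0)
    state_ko = ProteinState(x=2.0, y=0.0, E=0.0, z=0.5, u=0.5, w=0.5, p=0.0)
    d_wt = evaluate_rhs(state_wt, 0.0, ref_params)
    d_ko = evaluate_rhs(state_ko, 0.0, ref_params, MutationProfile(k_y=0.0, k_e=0.0))
    assert d_ko.x > d_wt.x


# -- serialization ------------------------------------------------------------


def test_parameter_set_json_round_trip(ref_params, tmp_path):
    path = tmp_path / "params.json"
    ref_params.to_json(path)
    again = ParameterSet.from_json(path)
    assert again == ref_params


def test_parameter_set_rejects_unknown_and_missing_keys(ref_params):
    doc = ref_params.to_dict()
    doc["mystery_rate"] = 1.0
    with pytest.raises(ValueError, match="unknown keys"):
        ParameterSet.from_dict(doc)
    doc2 = ref_params.to_dict()
    doc2.pop("m_x")
    with pytest.raises(ValueError, match="m_x"):
        ParameterSet.from_dict(doc2)
    doc3 = ref_params.to_dict()
    doc3.pop("version")
    with pytest.raises(ValueError, match="version"):
        ParameterSet.from_dict(doc3)


def test_mutation_profile_bounds():
    with pytest.raises(DomainError):
        MutationProfile(k_x=1.5)
    with pytest.raises(DomainError):
        MutationProfile(k_y=-0.1)
    assert MutationProfile.wild_type().is_wild_type()
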