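"""Simulator tests: delay handling, closed-form decay, feature extraction,
and agreement with an independent fixed-step integrator."""

import math

import numpy as np
import pytest

from crcsim import (
    MutationProfile,
    SimulationSettings,
    Trajectory,
    division_time,
    extract_features,
    simulate,
)
from crcsim.model import _rhs_array, _rhs_coefficients

ALL_ZERO = MutationProfile(0, 0, 0, 0, 0, 0, 0)


# -- closed forms -------------------------------------------------------------


def test_all_zero_mutation_decays_exponentially(ref_params):
    """Without production every species follows c0 * exp(-m t) exactly."""
    s = SimulationSettings(t_end=10.0, tau=2.0)
    traj = simulate(ref_params, ALL_ZERO, s)
    p = ref_params
    rates = [p.m_x, p.m_y, p.m_e, p.m_z, p.m_u, p.m_w, p.m_p]
    c0 = ref_params.initial_state().as_array()
    for j, (c, m) in enumerate(zip(c0, rates)):
        expected = c * np.exp(-m * traj.times)
        # PHYL branch adds no decay here because p0 = 0
        assert np.allclose(traj.states[:, j], expected, rtol=1e-5, atol=1e-8)


def test_division_time_closed_form(ref_params):
    """Pure decay from 0.8 AU at rate 0.5/h crosses 0.01 AU at ln(80)/0.5."""
    params = ref_params.with_updates(m_x=0.5)
    s = SimulationSettings(t_end=12.0, tau=1.0, epsilon_zero=0.01)
    traj = simulate(params, ALL_ZERO, s)
    t = division_time(traj)
    assert t == pytest.approx(math.log(80.0) / 0.5, abs=0.02)


def test_division_time_zero_for_flat_zero_trajectory():
    t = np.arange(0.0, 5.0, 0.01)
    traj = Trajectory(times=t, states=np.zeros((len(t), 7)),
                      settings=SimulationSettings(t_end=5.0, tau=0.0))
    assert division_time(traj) == 0.0


# -- delay handling -----------------------------------------------------------


def test_phyl_is_zero_before_tau(ref_params, ref_tau, ref_settings):
    traj = simulate(ref_params, None, ref_settings)
    before = traj.times < ref_tau
    assert np.all(traj.species("PHYL")[before] <= ref_settings.abs_tol * 10)
    after = traj.times > ref_tau + 1.0
    assert traj.species("PHYL")[after].max() > 0.01


def test_division_time_weakly_increasing_in_tau(ref_params, ref_tau):
    """The later PHYL appears, the later the cell divides."""
    taus = np.linspace(3.0, ref_tau, 5)
    t_zeros = []
    for tau in taus:
        s = SimulationSettings(t_end=tau + 12.0, tau=float(tau))
        traj = simulate(ref_params, None, s)
        tz = division_time(traj)
        assert tz is not None
        t_zeros.append(tz)
    assert all(b >= a - 1e-9 for a, b in zip(t_zeros, t_zeros[1:]))


# -- invariants of the reference run ------------------------------------------


def test_wild_type_non_negative_and_finite(wt_run):
    traj, _ = wt_run
    assert np.all(np.isfinite(traj.states))
    assert np.all(traj.states >= 0.0)


def test_wild_type_single_asc_maximum(wt_run):
    """No cyclic behaviour: the ASC curve has exactly one interior local
    maximum (determination is irreversible)."""
    traj, _ = wt_run
    x = traj.x
    # count strict sign changes of the slope on a coarsened grid to avoid
    # counting numerical micro-wiggles near zero concentration
    coarse = x[::25]
    d = np.diff(coarse)
    signs = np.sign(d[np.abs(d) > 1e-6])
    flips = np.nonzero(np.diff(signs) != 0)[0]
    down_flips = sum(
        1 for i in flips if signs[i] > 0 and signs[i + 1] < 0
    )
    assert down_flips == 1


def test_adaptive_agrees_with_fixed_step_rk4(ref_params, ref_tau):
    """Independent fixed-step classical RK4 oracle at h = 0.001 h agrees
    with the adaptive integration within 0.5 % on the ASC course."""
    s = SimulationSettings(t_end=20.0, tau=ref_tau)
    traj = simulate(ref_params, None, s)

    h = 0.001
    coeff = _rhs_coefficients(ref_params, MutationProfile.wild_type())
    n = int(round(s.t_end / h))
    lag = int(round(ref_tau / h))
    states = np.empty((n + 1, 7))
    states[0] = ref_params.initial_state().as_array()
    xs = states[:, 0]

    def delayed(step_idx):
        j = step_idx - lag
        return xs[j] if j >= 0 else 0.0

    for i in range(n):
        y = states[i]
        xd0 = delayed(i)
        xd1 = delayed(i + 1)
        xdm = 0.5 * (xd0 + xd1)
        k1 = _rhs_array(y, xd0, coeff)
        k2 = _rhs_array(y + 0.5 * h * k1, xdm, coeff)
        k3 = _rhs_array(y + 0.5 * h * k2, xdm, coeff)
        k4 = _rhs_array(y + h * k3, xd1, coeff)
        states[i + 1] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.maximum(states[i + 1], 0.0, out=states[i + 1])

    idx = (traj.times / h).round().astype(int)
    x_oracle = states[idx, 0]
    scale = max(x_oracle.max(), 1e-9)
    rel = np.abs(traj.x - x_oracle) / scale
    assert rel.max() < 0.005


def test_verify_peak_accepts_reference_run(ref_params, ref_tau):
    s = SimulationSettings(t_end=28.0, tau=ref_tau, verify_peak=True)
    traj = simulate(ref_params, None, s)
    assert traj.x.max() > 1.0


# -- feature extraction -------------------------------------------------------


def test_features_of_constant_trajectory():
    t = np.arange(0.0, 10.0 + 1e-9, 0.01)
    states = np.zeros((len(t), 7))
    states[:, 0] = 0.8
    traj = Trajectory(times=t, states=states,
                      settings=SimulationSettings(t_end=10.0, tau=0.0))
    f = extract_features(traj)
    assert f.fold_change == pytest.approx(1.0)
    assert f.t_zero is None
    assert f.plateau is True
    assert f.determined is False


def test_features_of_piecewise_fixture():
    """Curve built from its own feature values: rise 0.8->2.0 over 10 h,
    flat to 15 h, linear fall to zero at 18 h."""
    t = np.arange(0.0, 20.0 + 1e-9, 0.01)
    x = np.empty_like(t)
    x[t <= 10] = 0.8 + 1.2 * t[t <= 10] / 10.0
    x[(t > 10) & (t <= 15)] = 2.0
    fall = t > 15
    x[fall] = np.clip(2.0 * (18.0 - t[fall]) / 3.0, 0.0, None)
    states = np.zeros((len(t), 7))
    states[:, 0] = x
    traj = Trajectory(times=t, states=states,
                      settings=SimulationSettings(t_end=20.0, tau=0.0))
    f = extract_features(traj, x0=0.8)
    assert f.x_peak == pytest.approx(2.0)
    assert f.t_peak == pytest.approx(10.0, abs=0.05)
    assert f.fold_change == pytest.approx(2.5)
    assert f.t_zero == pytest.approx(18.0, abs=0.02)
    # decline slope is -2/3 AU/h, well past the onset threshold
    assert f.t_decline_onset == pytest.approx(15.0, abs=0.3)
    assert f.determined is True


def test_features_ordering_invariant(wt_run):
    _, f = wt_run
    assert f.t_peak <= f.t_decline_onset <= f.t_zero


# -- trajectory round trip ----------------------------------------------------


def test_trajectory_csv_round_trip(tmp_path, wt_run):
    traj, _ = wt_run
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "time_h,ASC,Hairy,EMC,SENS,SCRT,CHN,PHYL"
    again = Trajectory.from_csv(path, settings=traj.settings)
    assert np.array_equal(again.times, traj.times)
    assert np.array_equal(again.states, traj.states)
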