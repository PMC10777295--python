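"""Integration of the CRC delay system and extraction of curve features.

The PHYL equation reads the ASC concentration a fixed delay ``tau`` in the
past, with zero history (``x(t - tau) = 0`` for ``t < tau``).  The system
is integrated by the method of steps: on ``[0, tau]`` the delayed term is
zero, and on each subsequent window ``[k*tau, (k+1)*tau]`` the delayed ASC
level is interpolated (cubic) from the already-computed solution.  Each
window is handled by an adaptive Runge-Kutta integrator
(:func:`scipy.integrate.solve_ivp`); output is resampled to a uniform grid
so that extracted features do not depend on adaptive step placement.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .model import (
    MutationProfile,
    NumericError,
    ParameterSet,
    SPECIES,
    _rhs_array,
    _rhs_coefficients,
)

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "CurveFeatures",
    "IntegrationError",
    "simulate",
    "extract_features",
    "division_time",
]

_CSV_HEADER = "time_h,ASC,Hairy,EMC,SENS,SCRT,CHN,PHYL"


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time the solution was valid."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical and interpretation settings for one simulation.

    Parameters
    ----------
    t_end : float
        Horizon of the run (h).
    tau : float
        Delay before PHYL production reads a nonzero ASC history (h).
    rel_tol, abs_tol : float
        Solver tolerances.
    max_step : float
        Upper bound on the adaptive step (h).
    epsilon_zero : float
        ASC level counted as "returned to zero" (AU).  Default 0.01 AU,
        1.25 % of the wild-type initial level.
    fold_threshold : float
        Peak-to-initial fold change required for SOPC determination.
    output_step : float
        Uniform output/resampling grid step (h).
    decline_slope_threshold : float
        Magnitude of the smoothed d[ASC]/dt (AU/h) marking the onset of
        the sharp decline.
    verify_peak : bool
        When true, re-integrate at halved tolerances and require the ASC
        peak to agree within 0.1 %.
    """

    t_end: float
    tau: float
    rel_tol: float = 1e-7
    abs_tol: float = 1e-9
    max_step: float = 0.25
    epsilon_zero: float = 0.01
    fold_threshold: float = 2.5
    output_step: float = 0.01
    decline_slope_threshold: float = 0.1
    verify_peak: bool = False

    def __post_init__(self) -> None:
        if not (self.t_end > 0):
            raise ValueError(f"t_end must be > 0, got {self.t_end!r}")
        if not (self.tau >= 0):
            raise ValueError(f"tau must be >= 0, got {self.tau!r}")
        for name in ("rel_tol", "abs_tol", "max_step", "epsilon_zero", "output_step"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (self.fold_threshold > 1):
            raise ValueError(f"fold_threshold must be > 1, got {self.fold_threshold!r}")


@dataclass(frozen=True)
class Trajectory:
    """Simulated concentrations on a uniform time grid.

    ``states`` has one row per time point and one column per species in
    :data:`crcsim.model.SPECIES` order (ASC, Hairy, EMC, SENS, SCRT, CHN,
    PHYL).
    """

    times: np.ndarray
    states: np.ndarray
    settings: SimulationSettings
    params_id: str = ""

    @property
    def x(self) -> np.ndarray:
        """ASC concentration series."""
        return self.states[:, 0]

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        buf = io.StringIO()
        buf.write(_CSV_HEADER + "\n")
        for i in range(len(self.times)):
            row = [repr(float(self.times[i]))] + [
                repr(float(v)) for v in self.states[i]
            ]
            buf.write(",".join(row) + "\n")
        text = buf.getvalue()
        if isinstance(path, io.TextIOBase):
            path.write(text)
        else:
            Path(path).write_text(text)

    @classmethod
    def from_csv(cls, path: str | Path, settings: SimulationSettings | None = None):
        raw = np.loadtxt(Path(path), delimiter=",", skiprows=1)
        raw = np.atleast_2d(raw)
        settings = settings or SimulationSettings(
            t_end=float(raw[-1, 0]) if raw[-1, 0] > 0 else 1.0, tau=0.0
        )
        return cls(times=raw[:, 0], states=raw[:, 1:8], settings=settings)


@dataclass(frozen=True)
class CurveFeatures:
    """Interpretation of an ASC trajectory.

    Optional fields are ``None`` when the trajectory never exhibits the
    corresponding event (e.g. a knockout that only decays has no decline
    onset; a phyl knockout never returns to zero).
    """

    x_peak: float
    t_peak: float
    fold_change: float
    t_decline_onset: float | None
    t_zero: float | None
    decline_duration: float | None
    plateau: bool
    determined: bool

    def to_dict(self) -> dict:
        return {
            "x_peak": self.x_peak,
            "t_peak": self.t_peak,
            "fold_change": self.fold_change,
            "t_decline_onset": self.t_decline_onset,
            "t_zero": self.t_zero,
            "decline_duration": self.decline_duration,
            "plateau": self.plateau,
            "determined": self.determined,
        }


# -- integration --------------------------------------------------------------


def _integrate_window(
    rhs: Callable, y0: np.ndarray, t0: float, t1: float, s: SimulationSettings
):
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="RK45",
        dense_output=True,
        rtol=s.rel_tol,
        atol=s.abs_tol,
        max_step=s.max_step,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed in [{t0}, {t1}]: {sol.message}",
            last_valid_time=float(sol.t[-1]) if len(sol.t) else t0,
        )
    return sol


def _simulate_once(
    params: ParameterSet, mut: MutationProfile, s: SimulationSettings
) -> tuple[np.ndarray, np.ndarray]:
    coeff = _rhs_coefficients(params, mut)
    y0 = params.initial_state().as_array()

    n_out = int(round(s.t_end / s.output_step))
    t_out = np.linspace(0.0, s.t_end, n_out + 1)
    states = np.empty((n_out + 1, 7))

    if s.tau <= 0.0:
        # No delay: PHYL reads the instantaneous ASC level.
        def rhs(t, y):
            return _rhs_array(y, y[0] if y[0] > 0 else 0.0, coeff)

        sol = _integrate_window(rhs, y0, 0.0, s.t_end, s)
        states[:] = sol.sol(t_out).T
    else:
        # Method of steps.  History of x is sampled on a fine grid and
        # cubic-interpolated for the delayed lookup.
        hist_step = min(s.output_step, s.tau / 8.0)
        hist_t: list[float] = [0.0]
        hist_x: list[float] = [float(y0[0])]
        spline: CubicSpline | None = None

        def delayed(t: float) -> float:
            td = t - s.tau
            if td <= 0.0:
                return 0.0
            v = float(spline(td))
            return v if v > 0.0 else 0.0

        t0 = 0.0
        y = y0
        filled = 0
        while t0 < s.t_end - 1e-12:
            t1 = min(t0 + s.tau, s.t_end)
            if t0 == 0.0:
                def rhs(t, y):
                    return _rhs_array(y, 0.0, coeff)
            else:
                def rhs(t, y):
                    return _rhs_array(y, delayed(t), coeff)
            sol = _integrate_window(rhs, y, t0, t1, s)
            # extend the stored history of x
            n_hist = max(2, int(math.ceil((t1 - t0) / hist_step)))
            th = np.linspace(t0, t1, n_hist + 1)[1:]
            xh = sol.sol(th)[0]
            hist_t.extend(th.tolist())
            hist_x.extend(xh.tolist())
            spline = CubicSpline(np.asarray(hist_t), np.asarray(hist_x))
            # fill the output grid covered by this window
            upto = int(np.searchsorted(t_out, t1, side="right"))
            seg = t_out[filled:upto]
            if len(seg):
                states[filled:upto] = sol.sol(seg).T
            filled = upto
            y = sol.y[:, -1]
            t0 = t1
        if filled <= n_out:
            states[filled:] = y  # t_end boundary point

    low = states.min()
    if low < -(s.abs_tol * 1e3 + 1e-6):
        raise NumericError(
            f"negative concentration beyond tolerance in output: min={low:.3e}"
        )
    np.maximum(states, 0.0, out=states)
    if not np.all(np.isfinite(states)):
        raise NumericError("non-finite concentration in solver output")
    return t_out, states


def simulate(
    params: ParameterSet,
    mut: MutationProfile | None = None,
    settings: SimulationSettings | None = None,
    *,
    params_id: str = "",
) -> Trajectory:
    """Integrate the CRC system over ``[0, t_end]``.

    With ``settings.verify_peak`` enabled the run is repeated at halved
    tolerances and accepted only if the ASC peak changes by less than
    0.1 %.

    Raises
    ------
    IntegrationError
        On solver failure (carries ``last_valid_time``) or when the
        verification re-run disagrees.
    NumericError
        If concentrations leave the admissible range beyond tolerance.
    """
    mut = mut or MutationProfile.wild_type()
    if settings is None:
        raise ValueError("settings are required (t_end and tau have no defaults)")
    t, states = _simulate_once(params, mut, settings)
    if settings.verify_peak:
        tighter = replace(
            settings,
            rel_tol=settings.rel_tol / 2,
            abs_tol=settings.abs_tol / 2,
            verify_peak=False,
        )
        _, states2 = _simulate_once(params, mut, tighter)
        p1, p2 = float(states[:, 0].max()), float(states2[:, 0].max())
        ref = max(abs(p2), 1e-12)
        if abs(p1 - p2) / ref > 1e-3:
            raise IntegrationError(
                f"tolerance verification failed: peak {p1:.6g} vs {p2:.6g} "
                f"at halved tolerances"
            )
    return Trajectory(times=t, states=states, settings=settings, params_id=params_id)


# -- feature extraction -------------------------------------------------------


def _smoothed_slope(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Smoothed d[ASC]/dt on a uniform grid (Savitzky-Golay, ~0.5 h window)."""
    if len(t) < 5:
        return np.gradient(x, t)
    dt = float(t[1] - t[0])
    win = int(round(0.5 / dt)) | 1  # odd
    win = max(5, min(win, len(x) - (1 - len(x) % 2)))
    if win > len(x):
        win = len(x) if len(x) % 2 == 1 else len(x) - 1
    return savgol_filter(x, window_length=win, polyorder=3, deriv=1, delta=dt)


def extract_features(
    traj: Trajectory,
    x0: float | None = None,
    fold_threshold: float | None = None,
) -> CurveFeatures:
    """Summarize an ASC trajectory into determination-relevant features.

    Parameters
    ----------
    traj : Trajectory
    x0 : float, optional
        Baseline for the fold change.  Defaults to the trajectory's own
        initial ASC level; scenario code may pass the wild-type level
        instead (fixed determination band).
    fold_threshold : float, optional
        Defaults to ``traj.settings.fold_threshold``.

    Notes
    -----
    * ``t_peak`` is the first time attaining the global ASC maximum.
    * The decline onset is the first time after the peak at which the
      smoothed slope drops below ``-decline_slope_threshold``.
    * ``t_zero`` is the first time at/after the peak with
      ``x <= epsilon_zero``.
    * The plateau flag requires, over the final 20 % of the horizon, a
      relative ASC range below 2 % at a level above ``epsilon_zero``.
    """
    if len(traj.times) == 0:
        raise ValueError("trajectory is empty")
    s = traj.settings
    fold_threshold = fold_threshold if fold_threshold is not None else s.fold_threshold
    t, x = traj.times, traj.x
    if x0 is None:
        x0 = float(x[0])

    ip = int(np.argmax(x))
    x_peak, t_peak = float(x[ip]), float(t[ip])

    if x0 > 0:
        fold = x_peak / x0
    else:
        fold = math.inf if x_peak > 0 else 0.0

    slope = _smoothed_slope(t, x)
    onset = None
    after = np.nonzero(slope[ip:] < -s.decline_slope_threshold)[0]
    if len(after):
        onset = float(t[ip + after[0]])

    t_zero = None
    zero = np.nonzero(x[ip:] <= s.epsilon_zero)[0]
    if len(zero):
        t_zero = float(t[ip + zero[0]])

    duration = None
    if onset is not None and t_zero is not None and t_zero >= onset:
        duration = t_zero - onset

    tail = t >= t[-1] - 0.2 * (t[-1] - t[0])
    xt = x[tail]
    plateau = bool(
        len(xt) > 0
        and xt.min() > s.epsilon_zero
        and (xt.max() - xt.min()) <= 0.02 * xt.max()
    )

    determined = bool(fold >= fold_threshold and t_zero is not None)
    return CurveFeatures(
        x_peak=x_peak,
        t_peak=t_peak,
        fold_change=float(fold),
        t_decline_onset=onset,
        t_zero=t_zero,
        decline_duration=duration,
        plateau=plateau,
        determined=determined,
    )


def division_time(traj: Trajectory, epsilon_zero: float | None = None) -> float | None:
    """Time at which ASC first returns to (near) zero after its peak.

    ``None`` means the ASC level never comes back down to
    ``epsilon_zero`` -- the cell cannot transit to division.
    """
    if epsilon_zero is not None and epsilon_zero != traj.settings.epsilon_zero:
        traj = Trajectory(
            times=traj.times,
            states=traj.states,
            settings=replace(traj.settings, epsilon_zero=epsilon_zero),
            params_id=traj.params_id,
        )
    return extract_features(traj).t_zero
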