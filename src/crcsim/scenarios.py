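"""The five numerical experiments run on the CRC model.

Each scenario is a plain function over (parameters, settings) returning
dataclasses that serialize to JSON/CSV; the command-line layer only adds
file handling around these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import GENES, MutationProfile, ParameterSet
from .simulate import (
    CurveFeatures,
    SimulationSettings,
    Trajectory,
    extract_features,
    simulate,
)

__all__ = [
    "SweepResult",
    "KnockoutReport",
    "MinTauResult",
    "normal_run",
    "tau_sweep",
    "min_tau_search",
    "asc_dosage_sweep",
    "knockout_panel",
    "KNOCKOUT_GENES",
]

#: Genes probed by the knockout panel (AS-C itself is covered by the
#: dosage sweep instead).
KNOCKOUT_GENES = ("hairy", "emc", "sens", "scrt", "chn", "phyl")


@dataclass(frozen=True)
class SweepResult:
    """Features and verdicts along one swept axis."""

    axis_name: str
    axis_values: tuple[float, ...]
    features: tuple[CurveFeatures, ...]
    verdicts: tuple[bool, ...]
    trajectories: tuple[Trajectory, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.axis_values)
        if len(vals) and not np.all(np.diff(vals) > 0):
            raise ValueError("axis_values must be strictly increasing")
        if len(self.axis_values) != len(self.features):
            raise ValueError("one feature record per axis value required")

    def to_dict(self) -> dict:
        return {
            "axis_name": self.axis_name,
            "axis_values": list(self.axis_values),
            "features": [f.to_dict() for f in self.features],
            "verdicts": list(self.verdicts),
        }


@dataclass(frozen=True)
class KnockoutReport:
    """Effect of one gene knockout relative to the wild-type run.

    ``deviation`` is the integral of |ASC_mut - ASC_wt| dt over the window
    from t = 0 to the wild-type division time (the CRC's operational
    lifetime); ``max_deviation`` is the largest pointwise difference on
    the same window.  ``direction`` states whether the mutant ASC curve
    runs above, below, or on both sides of the wild-type curve.
    """

    gene: str
    profile: MutationProfile
    features: CurveFeatures
    deviation: float
    max_deviation: float
    direction: str  # above | below | mixed

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "profile": self.profile.as_dict(),
            "features": self.features.to_dict(),
            "deviation": self.deviation,
            "max_deviation": self.max_deviation,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class MinTauResult:
    """Outcome of the minimal-delay grid search."""

    found: bool
    tau_star: float | None
    fold_at_tau_star: float | None
    division_time: float | None
    features: CurveFeatures | None = None

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "tau_star": self.tau_star,
            "fold_at_tau_star": self.fold_at_tau_star,
            "division_time": self.division_time,
            "features": self.features.to_dict() if self.features else None,
        }


def normal_run(
    params: ParameterSet,
    settings: SimulationSettings,
    mut: MutationProfile | None = None,
) -> tuple[Trajectory, CurveFeatures]:
    """Reference wild-type run and its curve features."""
    mut = mut or MutationProfile.wild_type()
    traj = simulate(params, mut, settings, params_id="normal")
    return traj, extract_features(traj, x0=params.x0)


def tau_sweep(
    params: ParameterSet,
    tau_values,
    settings: SimulationSettings,
    t_end_values=None,
    keep_trajectories: bool = False,
) -> SweepResult:
    """Re-run the wild type for several PHYL delays.

    ``t_end_values`` optionally gives a horizon per delay (the later PHYL
    appears, the longer the circuit operates); otherwise ``settings.t_end``
    is used throughout.
    """
    tau_values = [float(v) for v in tau_values]
    if any(v < 0 for v in tau_values):
        raise ValueError("tau values must be >= 0")
    if t_end_values is None:
        t_end_values = [settings.t_end] * len(tau_values)
    feats, trajs = [], []
    for tau, t_end in zip(tau_values, t_end_values):
        s = replace(settings, tau=tau, t_end=t_end)
        traj = simulate(params, None, s, params_id=f"tau={tau:g}")
        f = extract_features(traj, x0=params.x0)
        feats.append(f)
        if keep_trajectories:
            trajs.append(traj)
    return SweepResult(
        axis_name="tau",
        axis_values=tuple(tau_values),
        features=tuple(feats),
        verdicts=tuple(f.determined for f in feats),
        trajectories=tuple(trajs),
    )


def min_tau_search(
    params: ParameterSet,
    settings: SimulationSettings,
    tau_grid_step: float = 0.1,
    target_division_time: float = 9.0,
    division_time_tolerance: float = 0.5,
    tau_max: float | None = None,
) -> MinTauResult:
    """Smallest PHYL delay on a uniform grid that permits cell division.

    A delay qualifies when (1) the ASC level returns to ``epsilon_zero``
    after its peak and (2) the resulting division time lies within
    ``division_time_tolerance`` of ``target_division_time``.  Returns the
    first qualifying grid point together with the peak fold change of
    that run, or a not-found result if the grid is exhausted.
    """
    if tau_grid_step <= 0:
        raise ValueError("tau_grid_step must be > 0")
    if tau_max is None:
        tau_max = target_division_time
    # horizon long enough to observe a division near the target time
    t_end = max(settings.t_end, target_division_time + division_time_tolerance + 3.0)
    n = int(np.floor(tau_max / tau_grid_step + 1e-9))
    for i in range(n + 1):
        tau = round(i * tau_grid_step, 10)
        s = replace(settings, tau=tau, t_end=t_end)
        traj = simulate(params, None, s, params_id=f"min-tau {tau:g}")
        f = extract_features(traj, x0=params.x0)
        if f.t_zero is None:
            continue
        if abs(f.t_zero - target_division_time) <= division_time_tolerance:
            return MinTauResult(
                found=True,
                tau_star=tau,
                fold_at_tau_star=f.fold_change,
                division_time=f.t_zero,
                features=f,
            )
    return MinTauResult(found=False, tau_star=None, fold_at_tau_star=None,
                        division_time=None)


def admissible_tau_range(
    params: ParameterSet,
    settings: SimulationSettings,
    division_range: tuple[float, float] = (9.0, 30.0),
    coarse_step: float = 0.5,
    tau_probe: float | None = None,
) -> tuple[float, float]:
    """Delay interval on the monotone branch mapping into a division-time
    range.

    Starting from a delay known to divide (``tau_probe``, default the
    settings' own delay), the lower edge is found by stepping the delay
    down while the division time stays at or above ``division_range[0]``,
    and the upper edge by stepping up until the division time exceeds
    ``division_range[1]``.  Near the minimal viable delay the division
    time is not monotone, so the returned interval deliberately stays on
    the increasing branch.
    """

    def div_time(tau: float) -> float | None:
        s = replace(settings, tau=tau, t_end=tau + 16.0)
        traj = simulate(params, None, s, params_id=f"range tau={tau:g}")
        return extract_features(traj, x0=params.x0).t_zero

    lo_target, hi_target = division_range
    tau = tau_probe if tau_probe is not None else settings.tau
    t0 = div_time(tau)
    if t0 is None:
        raise ValueError(f"no division at probe delay tau={tau}")
    lo = tau
    while lo - coarse_step > 0:
        t = div_time(lo - coarse_step)
        if t is None or t < lo_target:
            break
        lo -= coarse_step
    hi, t = tau, t0
    while t is not None and t < hi_target and hi <= tau + 40.0:
        hi += coarse_step
        t = div_time(hi)
    return lo, hi


def asc_dosage_sweep(
    params: ParameterSet,
    kx_values=None,
    settings: SimulationSettings | None = None,
    keep_trajectories: bool = False,
) -> tuple[SweepResult, float | None]:
    """Proportional AS-C dosage reduction.

    Each run scales both the production coefficient (``k_x = kx``) and the
    initial ASC content (``x0 = kx * x0_wt``).  The determination verdict
    uses the *wild-type* initial level as the fold baseline, i.e. a fixed
    concentration band ``fold_threshold * x0_wt``, and requires the ASC
    level to return to zero.  Returns the sweep plus the smallest
    qualifying ``kx``.
    """
    if settings is None:
        raise ValueError("settings are required")
    if kx_values is None:
        kx_values = [round(0.1 * i, 10) for i in range(11)]
    kx_values = [float(v) for v in kx_values]
    if any(not 0 <= v <= 1 for v in kx_values):
        raise ValueError("kx values must lie in [0, 1]")
    feats, trajs = [], []
    for kx in kx_values:
        p = params.with_updates(x0=params.x0 * kx)
        mut = MutationProfile(k_x=kx)
        traj = simulate(p, mut, settings, params_id=f"kx={kx:g}")
        f = extract_features(traj, x0=params.x0)  # wild-type baseline
        feats.append(f)
        if keep_trajectories:
            trajs.append(traj)
    verdicts = tuple(f.determined for f in feats)
    kx_star = None
    for kx, ok in zip(kx_values, verdicts):
        if ok:
            kx_star = kx
            break
    sweep = SweepResult(
        axis_name="k_x",
        axis_values=tuple(kx_values),
        features=tuple(feats),
        verdicts=verdicts,
        trajectories=tuple(trajs),
    )
    return sweep, kx_star


def knockout_profile(gene: str) -> tuple[MutationProfile, dict]:
    """Mutation profile and zeroed initial concentrations for one null allele."""
    if gene not in GENES:
        raise KeyError(f"unknown gene {gene!r}; expected one of {sorted(GENES)}")
    k_field, init_field = GENES[gene]
    return MutationProfile(**{k_field: 0.0}), {init_field: 0.0}


def knockout_panel(
    params: ParameterSet,
    genes=KNOCKOUT_GENES,
    settings: SimulationSettings | None = None,
    keep_trajectories: bool = False,
) -> list[KnockoutReport]:
    """Null-allele panel ranked by deviation from the wild-type ASC curve.

    A knockout zeroes both the gene's mutation coefficient and the initial
    concentration of its product (a null allele produces no protein).  The
    deviation window runs from t = 0 to the wild-type division time, the
    circuit's operational lifetime.  With ``genes=()`` the list contains
    only the wild-type self-report (deviation 0), which is the normal run.
    """
    if settings is None:
        raise ValueError("settings are required")
    wt_traj, wt_feat = normal_run(params, settings)
    x_wt = wt_traj.x
    t = wt_traj.times
    window = t <= (wt_feat.t_zero if wt_feat.t_zero is not None else t[-1])

    reports: list[KnockoutReport] = []
    reports.append(
        KnockoutReport(
            gene="wild_type",
            profile=MutationProfile.wild_type(),
            features=wt_feat,
            deviation=0.0,
            max_deviation=0.0,
            direction="above",
        )
    )
    for gene in genes:
        mut, init_updates = knockout_profile(gene)
        p = params.with_updates(**init_updates)
        traj = simulate(p, mut, settings, params_id=f"{gene}-")
        f = extract_features(traj, x0=params.x0)
        diff = (traj.x - x_wt)[window]
        dev = float(np.trapezoid(np.abs(diff), t[window]))
        max_dev = float(np.max(np.abs(diff))) if len(diff) else 0.0
        pos = float(np.trapezoid(np.clip(diff, 0, None), t[window]))
        neg = float(np.trapezoid(np.clip(-diff, 0, None), t[window]))
        total = pos + neg
        if total == 0.0:
            direction = "above"
        elif pos / total >= 0.95:
            direction = "above"
        elif neg / total >= 0.95:
            direction = "below"
        else:
            direction = "mixed"
        reports.append(
            KnockoutReport(
                gene=gene,
                profile=mut,
                features=f,
                deviation=dev,
                max_deviation=max_dev,
                direction=direction,
            )
        )
    head, rest = reports[0], reports[1:]
    rest.sort(key=lambda r: -r.deviation)
    return [head] + rest
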