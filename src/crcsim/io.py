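"""Run configuration, serialization, logging and fixture generation."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .model import MutationProfile, ParameterSet, load_reference
from .simulate import SimulationSettings, Trajectory, extract_features, simulate
from .scenarios import knockout_profile, KNOCKOUT_GENES

log = logging.getLogger("crcsim")

SCENARIOS = (
    "normal", "sweep-tau", "min-tau", "dosage-sweep", "knockouts",
    "calibrate", "validate",
)


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class SettingsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_end: float = 28.0
    tau: Optional[float] = None  # None -> reference delay
    rel_tol: float = 1e-7
    abs_tol: float = 1e-9
    max_step: float = 0.25
    epsilon_zero: float = 0.01
    fold_threshold: float = 2.5
    output_step: float = 0.01
    decline_slope_threshold: float = 0.1
    verify_peak: bool = False


class RunConfig(BaseModel):
    """Schema-validated run description (YAML or JSON on disk)."""

    model_config = ConfigDict(extra="forbid")

    parameter_set: str = "reference"  # "reference" or a JSON path
    scenario: Literal[
        "normal", "sweep-tau", "min-tau", "dosage-sweep", "knockouts",
        "calibrate", "validate",
    ] = "normal"
    mutation: dict[str, float] = Field(default_factory=dict)
    settings: SettingsModel = Field(default_factory=SettingsModel)
    options: dict[str, Any] = Field(default_factory=dict)
    output_dir: str = "crcsim-out"
    seed: int = 0
    log_level: str = "info"

    @field_validator("mutation")
    @classmethod
    def _check_mutation(cls, v: dict[str, float]) -> dict[str, float]:
        valid = {f"k_{c}" for c in "xyezuwp"}
        for key, val in v.items():
            if key not in valid:
                raise ValueError(f"unknown mutation coefficient {key!r}")
            if not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"mutation coefficient {key} = {val} not in [0, 1]")
        return v

    def resolve_parameters(self) -> tuple[ParameterSet, float]:
        if self.parameter_set == "reference":
            return load_reference()
        return load_reference(self.parameter_set)

    def resolve_settings(self, tau_reference: float) -> SimulationSettings:
        d = self.settings.model_dump()
        if d["tau"] is None:
            d["tau"] = tau_reference
        return SimulationSettings(**d)

    def mutation_profile(self) -> MutationProfile:
        return MutationProfile(**self.mutation)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Raises :class:`ConfigError` naming the offending key on violations.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    try:
        doc = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as e:
        raise ConfigError(f"cannot parse {p}: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    try:
        cfg = RunConfig.model_validate(doc)
    except Exception as e:  # pydantic.ValidationError
        raise ConfigError(f"invalid configuration {p}: {e}") from e
    for key, default in RunConfig().model_dump().items():
        if key not in doc:
            log.debug("config %s: using default %s=%r", p, key, default)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    p = Path(path)
    doc = cfg.model_dump()
    if p.suffix == ".json":
        p.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    else:
        p.write_text(yaml.safe_dump(doc, sort_keys=True))


def setup_logging(level: str = "info") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)-7s %(name)s: %(message)s",
    )


# -- manifests ----------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: str | Path, cfg: RunConfig | None, extra: dict | None = None):
    """Write ``manifest.json`` describing a results directory.

    Deliberately timestamp-free so that identical runs produce
    byte-identical output directories.
    """
    outdir = Path(outdir)
    outputs = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    doc = {
        "package": "crcsim",
        "version": __version__,
        "config": cfg.model_dump() if cfg is not None else None,
        "seed": cfg.seed if cfg is not None else None,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    if extra:
        doc.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


# -- fixture generation -------------------------------------------------------


def synthetic_feature_curves() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Piecewise test curves with analytically known features (synthetic).

    * ``constant``: flat at 0.8 AU -- fold 1, plateau, undetermined.
    * ``rise_flat_fall``: 0.8 -> 2.0 over 10 h, flat to 15 h, linear to 0
      at 18 h -- peak 2.0 at 10 h, fold 2.5, t_zero 18 h.
    """
    t = np.round(np.arange(0.0, 20.0 + 1e-9, 0.01), 10)
    constant = np.full_like(t, 0.8)
    x = np.empty_like(t)
    rise = t <= 10.0
    x[rise] = 0.8 + (2.0 - 0.8) * t[rise] / 10.0
    flat = (t > 10.0) & (t <= 15.0)
    x[flat] = 2.0
    fall = t > 15.0
    x[fall] = np.clip(2.0 * (18.0 - t[fall]) / 3.0, 0.0, None)
    return {"constant": (t, constant), "rise_flat_fall": (t, x)}


def generate_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write deterministic regression fixtures for the test suite.

    Produces the wild-type, no-delay and per-gene knockout trajectories of
    the shipped reference set (CSV + features JSON) plus synthetic
    piecewise curves whose features are known by construction.  Requires
    the calibrated reference set to be present.
    """
    try:
        params, tau_ref = load_reference()
    except FileNotFoundError as e:
        raise FileNotFoundError(
            "reference parameter set missing; run calibration first"
        ) from e
    outdir = Path(outdir)
    (outdir / "trajectories").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)  # reserved for future noisy fixtures

    features_doc: dict[str, dict] = {}

    def emit(name: str, traj: Trajectory, x0: float):
        traj.to_csv(outdir / "trajectories" / f"{name}.csv")
        features_doc[name] = extract_features(traj, x0=x0).to_dict()

    base = SimulationSettings(t_end=28.0, tau=tau_ref)
    emit("wild_type", simulate(params, None, base), params.x0)
    emit("tau0", simulate(params, None, SimulationSettings(t_end=30.0, tau=0.0)),
         params.x0)
    for gene in KNOCKOUT_GENES:
        mut, init = knockout_profile(gene)
        emit(f"{gene}_knockout", simulate(params.with_updates(**init), mut, base),
             params.x0)

    synth = synthetic_feature_curves()
    for name, (t, x) in synth.items():
        arr = np.zeros((len(t), 7))
        arr[:, 0] = x
        traj = Trajectory(times=t, states=arr,
                          settings=SimulationSettings(t_end=float(t[-1]), tau=0.0))
        traj.to_csv(outdir / "trajectories" / f"synthetic_{name}.csv")
        features_doc[f"synthetic_{name}"] = extract_features(traj).to_dict()

    dump_json(features_doc, outdir / "features.json")
    dump_json({"seed": seed, "tau_reference": tau_ref}, outdir / "fixtures_meta.json")
    return outdir
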