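"""Core state space, parameters and right-hand side of the SOP central
regulatory circuit (CRC).

The circuit couples seven proteins in a single presumptive sensory-organ
precursor cell: the proneural ASC proteins (``x``), the repressors Hairy
(``y``) and EMC (``E``), the ASC-driven targets Senseless (``z``), Scratch
(``u``) and Charlatan (``w``), and the degradation adaptor Phyllopod
(``p``).  Accessory proteins Daughterless (D), Groucho (G), SINA (S) and
Ubiquitin (U) enter as constant concentrations.

Regulatory logic
----------------
* ASC production is driven by three Hill-type activations: autoregulation
  through the ASC/DA heterodimer (argument ``D*x``) plus trans-activation
  by SENS and CHN.  Production is attenuated by the rational repression
  factor ``1 / (1 + G*y + E*x)`` representing the Hairy/GRO and ASC/EMC
  heterodimer repressors.
* Hairy and EMC are produced constitutively (scales ``Cy``, ``Ce``) under
  composite repression by SCRT/CHN and CHN respectively.
* SENS, SCRT, CHN and PHYL production follows Hill activation by the
  ASC/DA heterodimer; the PHYL equation reads the *delayed* ASC level
  ``x(t - tau)`` (zero history before the delay elapses).
* ASC is cleared both by first-order turnover (``m_x``) and by the
  UB/SINA/PHYL degradation branch, ``q * S * U * p * x``.

Per-gene mutation coefficients ``k`` in [0, 1] scale the production term of
the corresponding protein; ``k = 1`` is wild type, ``k = 0`` a null allele.

Concentrations are in arbitrary units (AU), time in hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SigmoidParams",
    "ProteinState",
    "MutationProfile",
    "ParameterSet",
    "hill_activation",
    "repression_factor",
    "evaluate_rhs",
    "load_reference",
    "reference_parameter_path",
    "PARAMETER_SET_VERSION",
    "SPECIES",
    "GENES",
]

#: Order of state variables used throughout the package.
SPECIES = ("ASC", "Hairy", "EMC", "SENS", "SCRT", "CHN", "PHYL")

#: CRC genes addressable in knockout experiments, mapped to the mutation
#: coefficient and the initial-concentration attribute they control.
GENES = {
    "asc": ("k_x", "x0"),
    "hairy": ("k_y", "y0"),
    "emc": ("k_e", "E0"),
    "sens": ("k_z", "z0"),
    "scrt": ("k_u", "u0"),
    "chn": ("k_w", "w0"),
    "phyl": ("k_p", "p0"),
}

PARAMETER_SET_VERSION = "crcsim-parameters-1"


class DomainError(ValueError):
    """Raised when an operation receives an argument outside its domain."""


class NumericError(ArithmeticError):
    """Raised when a numeric quantity is non-finite or out of tolerance."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of a Hill-type activation ``a * v**n / (b**n + v**n)``.

    Attributes
    ----------
    a : float
        Amplitude (maximal production rate, AU/h).  ``a > 0``.
    b : float
        Half-saturation concentration (AU).  ``b > 0``.
    n : float
        Hill steepness (dimensionless).  ``n > 0``.
    """

    a: float
    b: float
    n: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "n"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DomainError(
                    f"SigmoidParams.{name} must be a positive finite number, got {v!r}"
                )


@dataclass(frozen=True)
class ProteinState:
    """Concentrations of the seven CRC proteins at a single time point (AU)."""

    x: float  #: ASC
    y: float  #: Hairy
    E: float  #: EMC
    z: float  #: SENS
    u: float  #: SCRT
    w: float  #: CHN
    p: float  #: PHYL

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.E, self.z, self.u, self.w, self.p])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ProteinState":
        if len(arr) != 7:
            raise ValueError(f"expected 7 concentrations, got {len(arr)}")
        return cls(*map(float, arr))

    def validate(self) -> None:
        for name, v in zip("x y E z u w p".split(), self.as_array()):
            if not math.isfinite(v):
                raise NumericError(f"non-finite concentration in field {name!r}: {v!r}")
            if v < 0:
                raise DomainError(f"negative concentration in field {name!r}: {v!r}")


@dataclass(frozen=True)
class MutationProfile:
    """Per-gene mutation coefficients, each in [0, 1] (1 = wild type)."""

    k_x: float = 1.0
    k_y: float = 1.0
    k_e: float = 1.0
    k_z: float = 1.0
    k_u: float = 1.0
    k_w: float = 1.0
    k_p: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
                raise DomainError(
                    f"mutation coefficient {f.name} must lie in [0, 1], got {v!r}"
                )

    @classmethod
    def wild_type(cls) -> "MutationProfile":
        return cls()

    def is_wild_type(self) -> bool:
        return all(getattr(self, f.name) == 1.0 for f in fields(self))

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


# Scalar fields of ParameterSet, in serialization order.
_SCALAR_FIELDS = (
    "m_x", "m_y", "m_e", "m_z", "m_u", "m_w", "m_p",
    "D", "G", "S", "U",
    "Cy", "Ce", "d1", "d2", "d3", "q",
    "x0", "y0", "z0", "u0", "w0", "p0", "E0",
)
_SIGMOID_FIELDS = (
    "sigmoid_asc_auto", "sigmoid_asc_sens", "sigmoid_asc_chn",
    "sigmoid_sens", "sigmoid_scrt", "sigmoid_chn", "sigmoid_phyl",
)


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization of the CRC dynamical system.

    Sigmoid blocks
        ``sigmoid_asc_auto/asc_sens/asc_chn`` are the three activations
        feeding ASC production (arguments ``D*x``, ``z``, ``w``);
        ``sigmoid_sens/scrt/chn/phyl`` drive the ASC/DA-dependent
        production of SENS, SCRT, CHN and PHYL (argument ``D*x``; the PHYL
        sigmoid reads the delayed ASC level).
    Scalars
        First-order degradation rates ``m_*`` (1/h); constant partner
        concentrations ``D, G, S, U`` (AU); constitutive production scales
        ``Cy, Ce`` (AU/h); repression weights ``d1`` (CHN on emc), ``d2``
        (SCRT on hairy), ``d3`` (CHN on hairy) (1/AU); PHYL-branch coupling
        ``q`` (1/(AU^2 h)); initial concentrations ``x0 ... E0`` (AU).
    """

    sigmoid_asc_auto: SigmoidParams
    sigmoid_asc_sens: SigmoidParams
    sigmoid_asc_chn: SigmoidParams
    sigmoid_sens: SigmoidParams
    sigmoid_scrt: SigmoidParams
    sigmoid_chn: SigmoidParams
    sigmoid_phyl: SigmoidParams
    m_x: float
    m_y: float
    m_e: float
    m_z: float
    m_u: float
    m_w: float
    m_p: float
    D: float
    G: float
    S: float
    U: float
    Cy: float
    Ce: float
    d1: float
    d2: float
    d3: float
    q: float
    x0: float
    y0: float
    z0: float
    u0: float
    w0: float
    p0: float
    E0: float

    def __post_init__(self) -> None:
        for name in ("m_x", "m_y", "m_e", "m_z", "m_u", "m_w", "m_p"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise DomainError(f"degradation rate {name} must be > 0, got {v!r}")
        for name in ("D", "G", "S", "U", "Cy", "Ce", "d1", "d2", "d3", "q"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise DomainError(f"parameter {name} must be >= 0, got {v!r}")
        for name in ("x0", "y0", "z0", "u0", "w0", "p0", "E0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise DomainError(f"initial concentration {name} must be >= 0, got {v!r}")

    # -- construction helpers -------------------------------------------------

    def initial_state(self) -> ProteinState:
        """Initial concentrations in simulator order (ASC ... PHYL)."""
        return ProteinState(
            x=self.x0, y=self.y0, E=self.E0,
            z=self.z0, u=self.u0, w=self.w0, p=self.p0,
        )

    def with_updates(self, **updates: float) -> "ParameterSet":
        """Return a copy with scalar fields or dotted sigmoid fields replaced.

        Dotted keys such as ``"sigmoid_asc_auto.a"`` address one component
        of a sigmoid block.
        """
        plain = {k: v for k, v in updates.items() if "." not in k}
        dotted = {k: v for k, v in updates.items() if "." in k}
        out = replace(self, **plain) if plain else self
        for key, value in dotted.items():
            block_name, comp = key.split(".", 1)
            if block_name not in _SIGMOID_FIELDS or comp not in ("a", "b", "n"):
                raise KeyError(f"unknown parameter path {key!r}")
            block = getattr(out, block_name)
            out = replace(out, **{block_name: replace(block, **{comp: float(value)})})
        return out

    def get(self, path: str) -> float:
        """Read a scalar field or a dotted sigmoid component."""
        if "." in path:
            block, comp = path.split(".", 1)
            return float(getattr(getattr(self, block), comp))
        return float(getattr(self, path))

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {"version": PARAMETER_SET_VERSION}
        for name in _SIGMOID_FIELDS:
            block = getattr(self, name)
            for comp in ("a", "b", "n"):
                doc[f"{name}.{comp}"] = float(getattr(block, comp))
        for name in _SCALAR_FIELDS:
            doc[name] = float(getattr(self, name))
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterSet":
        doc = dict(doc)
        version = doc.pop("version", None)
        if version is None:
            raise ValueError("parameter document lacks required 'version' key")
        if version != PARAMETER_SET_VERSION:
            raise ValueError(
                f"unsupported parameter-set version {version!r}; "
                f"expected {PARAMETER_SET_VERSION!r}"
            )
        kwargs: dict = {}
        for name in _SIGMOID_FIELDS:
            comps = {}
            for comp in ("a", "b", "n"):
                key = f"{name}.{comp}"
                if key not in doc:
                    raise ValueError(f"parameter document missing key {key!r}")
                comps[comp] = float(doc.pop(key))
            kwargs[name] = SigmoidParams(**comps)
        for name in _SCALAR_FIELDS:
            if name not in doc:
                raise ValueError(f"parameter document missing key {name!r}")
            kwargs[name] = float(doc.pop(name))
        if doc:
            raise ValueError(f"unknown keys in parameter document: {sorted(doc)}")
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- elementary regulatory terms ---------------------------------------------


def hill_activation(v: float, params: SigmoidParams) -> float:
    """Hill activation rate ``a * v**n / (b**n + v**n)``.

    Monotone non-decreasing in ``v``, bounded by the amplitude ``a``, and
    equal to ``a / 2`` at the half-saturation point ``v = b``.

    Raises
    ------
    DomainError
        If ``v`` is negative.
    """
    if v < 0:
        raise DomainError(f"hill_activation requires v >= 0, got {v!r}")
    if v == 0.0:
        return 0.0
    vn = v ** params.n
    return params.a * vn / (params.b ** params.n + vn)


def repression_factor(weights: Iterable[tuple[float, float]]) -> float:
    """Composite repression ``1 / (1 + sum(d_i * c_i))``.

    ``weights`` is an iterable of ``(weight, concentration)`` pairs; the
    result lies in (0, 1], equals 1 with no repressors, and is strictly
    decreasing in each concentration carrying a positive weight.
    """
    total = 0.0
    for d, c in weights:
        if d < 0 or c < 0:
            raise DomainError(
                f"repression_factor requires non-negative inputs, got ({d!r}, {c!r})"
            )
        total += d * c
    return 1.0 / (1.0 + total)


# -- right-hand side ----------------------------------------------------------


def _rhs_coefficients(params: ParameterSet, mut: MutationProfile) -> tuple:
    """Flatten parameters into a tuple consumed by :func:`_rhs_array`."""
    s = params
    return (
        s.sigmoid_asc_auto.a, s.sigmoid_asc_auto.b, s.sigmoid_asc_auto.n,
        s.sigmoid_asc_sens.a, s.sigmoid_asc_sens.b, s.sigmoid_asc_sens.n,
        s.sigmoid_asc_chn.a, s.sigmoid_asc_chn.b, s.sigmoid_asc_chn.n,
        s.sigmoid_sens.a, s.sigmoid_sens.b, s.sigmoid_sens.n,
        s.sigmoid_scrt.a, s.sigmoid_scrt.b, s.sigmoid_scrt.n,
        s.sigmoid_chn.a, s.sigmoid_chn.b, s.sigmoid_chn.n,
        s.sigmoid_phyl.a, s.sigmoid_phyl.b, s.sigmoid_phyl.n,
        s.m_x, s.m_y, s.m_e, s.m_z, s.m_u, s.m_w, s.m_p,
        s.D, s.G, s.S, s.U, s.Cy, s.Ce, s.d1, s.d2, s.d3, s.q,
        mut.k_x, mut.k_y, mut.k_e, mut.k_z, mut.k_u, mut.k_w, mut.k_p,
    )


def _hill(v: float, a: float, b: float, n: float) -> float:
    if v <= 0.0:
        return 0.0
    vn = v ** n
    return a * vn / (b ** n + vn)


def _rhs_array(state: np.ndarray, delayed_asc: float, c: tuple) -> np.ndarray:
    """Derivatives of [x, y, E, z, u, w, p]; hot path of the simulator."""
    (a1, b1, n1, a4, b4, n4, a6, b6, n6,
     az, bz, nz, au, bu, nu, aw, bw, nw, ap, bp, npw,
     m_x, m_y, m_e, m_z, m_u, m_w, m_p,
     D, G, S, U, Cy, Ce, d1, d2, d3, q,
     k_x, k_y, k_e, k_z, k_u, k_w, k_p) = c
    x, y, E, z, u, w, p = state
    # state may transiently dip a hair below zero inside a solver step
    xp = x if x > 0.0 else 0.0
    zp = z if z > 0.0 else 0.0
    up = u if u > 0.0 else 0.0
    wp = w if w > 0.0 else 0.0
    dax = D * xp
    drive = _hill(dax, a1, b1, n1) + _hill(zp, a4, b4, n4) + _hill(wp, a6, b6, n6)
    r_asc = 1.0 / (1.0 + G * y + E * xp)
    dx = k_x * drive * r_asc - m_x * x - q * S * U * p * x
    dy = k_y * Cy / (1.0 + d2 * up + d3 * wp) - m_y * y
    dE = k_e * Ce / (1.0 + d1 * wp) - m_e * E
    dz = k_z * _hill(dax, az, bz, nz) - m_z * z
    du = k_u * _hill(dax, au, bu, nu) - m_u * u
    dw = k_w * _hill(dax, aw, bw, nw) - m_w * w
    dp = k_p * _hill(D * delayed_asc, ap, bp, npw) - m_p * p
    return np.array([dx, dy, dE, dz, du, dw, dp])


def evaluate_rhs(
    state: ProteinState,
    delayed_asc: float,
    params: ParameterSet,
    mut: MutationProfile | None = None,
) -> ProteinState:
    """Evaluate the seven derivatives of the CRC system at one state.

    Parameters
    ----------
    state : ProteinState
        Current concentrations; all fields must be finite and >= 0.
    delayed_asc : float
        ASC concentration at time ``t - tau`` (0 while ``t < tau``).
    params : ParameterSet
    mut : MutationProfile, optional
        Defaults to wild type.

    Returns
    -------
    ProteinState
        Field-wise time derivatives (AU/h).
    """
    state.validate()
    if not math.isfinite(delayed_asc) or delayed_asc < 0:
        raise DomainError(f"delayed_asc must be finite and >= 0, got {delayed_asc!r}")
    mut = mut or MutationProfile.wild_type()
    d = _rhs_array(state.as_array(), float(delayed_asc), _rhs_coefficients(params, mut))
    return ProteinState.from_array(d)


# -- shipped reference parameterization ---------------------------------------


def reference_parameter_path() -> Path:
    """Path of the calibrated reference parameter file shipped with crcsim."""
    return Path(__file__).parent / "data" / "reference_params.json"


def load_reference(path: str | Path | None = None) -> tuple[ParameterSet, float]:
    """Load a reference parameter document.

    Returns the :class:`ParameterSet` together with the reference PHYL
    delay ``tau_reference`` (hours) recorded alongside it.  The document is
    a flat parameter-set JSON extended with ``tau_reference`` and an
    optional ``provenance`` block.
    """
    p = Path(path) if path is not None else reference_parameter_path()
    doc = json.loads(p.read_text())
    doc.pop("provenance", None)
    tau = float(doc.pop("tau_reference"))
    return ParameterSet.from_dict(doc), tau
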