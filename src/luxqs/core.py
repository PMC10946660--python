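"""Core domain types and shared kinetic primitives.

The package models quorum-sensing (QS) dynamics of a luminescent bacterium
growing in batch culture with four coupled blocks:

* an ecological block (substrate ``S``, biomass ``N``),
* an energy block (mean intracellular ATP ``a``),
* a QS switch (autoinducer ``A``, receptor LuxR ``R``),
* a luminescence block (luciferase ``L`` and observed intensity ``I``).

All concentrations are in the model's arbitrary units and time is in hours.
This module holds the immutable parameter containers, the state/trajectory
containers, and the saturation / logistic primitives every block shares.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GrowthParams",
    "EnergyParams",
    "QSParams",
    "ReducedQSParams",
    "LumParams",
    "ScaleParams",
    "FullParams",
    "VerhulstParams",
    "FullState",
    "StationaryState",
    "Trajectory",
    "saturation",
    "verhulst_rate",
    "as_reduced",
    "reference_params",
    "FLAT_PARAM_NAMES",
    "get_param",
    "with_param",
]


def _require_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly positive, got {value!r}")


def _require_nonnegative(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"{type(obj).__name__}.{name} must be nonnegative, got {value!r}")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Biomass-synthesis kinetics: ``fg = Vg·S/(Kg+S)·a/(Ka+a)``.

    Vg : maximal specific growth rate (1/h)
    Kg : substrate half-saturation of growth
    Ka : ATP half-saturation of growth
    """

    Vg: float
    Kg: float
    Ka: float

    def __post_init__(self) -> None:
        _require_positive(self, "Vg", "Kg", "Ka")


@dataclass(frozen=True)
class EnergyParams:
    """ATP-metabolism constants.

    Ve   : maximal ATP production rate
    Ke   : substrate half-saturation of ATP production
    Kae  : ATP-activation constant of production (autocatalytic term)
    kd   : generalized-ATPase rate constant
    eps2 : ATPase half-saturation in ATP
    k0   : ATP cost coefficient of biomass synthesis
    a0   : reference / initial intracellular ATP concentration
    """

    Ve: float
    Ke: float
    Kae: float
    kd: float
    eps2: float
    k0: float
    a0: float

    def __post_init__(self) -> None:
        _require_positive(self, "Ve", "Ke", "Kae", "kd", "eps2", "k0", "a0")


@dataclass(frozen=True)
class QSParams:
    """LuxR/autoinducer switch constants.

    VR    : maximal induced LuxR synthesis rate
    CR    : basal LuxR synthesis rate
    CA    : per-biomass autoinducer production rate
    k3    : first-order LuxR loss rate
    gamma : composite dimerization constant (absorbs both binding steps)
    KR    : promoter half-saturation in dimer units
    """

    VR: float
    CR: float
    CA: float
    k3: float
    gamma: float
    KR: float

    def __post_init__(self) -> None:
        _require_positive(self, "VR", "CR", "CA", "k3", "gamma", "KR")


@dataclass(frozen=True)
class ReducedQSParams:
    """Parameters of the reduced stationary LuxR curve.

    alpha : basal stationary LuxR level, CR/k3
    beta  : induction amplitude, VR/k3
    sigma : curve scale, KR·gamma
    """

    alpha: float
    beta: float
    sigma: float

    def __post_init__(self) -> None:
        _require_positive(self, "alpha", "beta", "sigma")


@dataclass(frozen=True)
class LumParams:
    """Luminescence block: ``I = VL·L·a/(KL+a)``; VL and kdL are per-medium."""

    VL: float
    KL: float
    kdL: float

    def __post_init__(self) -> None:
        _require_positive(self, "VL", "KL", "kdL")


@dataclass(frozen=True)
class ScaleParams:
    """Time-scale multipliers.

    eps0 : cell-to-flask volume ratio Vb/Vc (converts intracellular rates to
           flask concentration rates); must be <= 1
    eps1, eps3, eps4 : multipliers of the a, R and L equations
    """

    eps0: float
    eps1: float
    eps3: float
    eps4: float

    def __post_init__(self) -> None:
        _require_positive(self, "eps0", "eps1", "eps3", "eps4")
        if self.eps0 > 1:
            raise ValueError(f"eps0 must be <= 1 (a volume ratio), got {self.eps0!r}")


@dataclass(frozen=True)
class FullParams:
    """Every kinetic constant of the combined six-variable model."""

    growth: GrowthParams
    energy: EnergyParams
    qs: QSParams
    lum: LumParams
    scale: ScaleParams

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "growth": dataclasses.asdict(self.growth),
            "energy": dataclasses.asdict(self.energy),
            "qs": dataclasses.asdict(self.qs),
            "lum": dataclasses.asdict(self.lum),
            "scale": dataclasses.asdict(self.scale),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FullParams":
        return cls(
            growth=GrowthParams(**d["growth"]),
            energy=EnergyParams(**d["energy"]),
            qs=QSParams(**d["qs"]),
            lum=LumParams(**d["lum"]),
            scale=ScaleParams(**d["scale"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FullParams":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FullParams":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class VerhulstParams:
    """Logistic (Verhulst) growth law in one of two equivalent readings.

    ``carrying_capacity`` : dN/dt = mu0·N·(Nmax − N), with Nmax the carrying
        capacity and mu0·Nmax the specific growth rate near N = 0.
    ``competition`` : dN/dt = mu0·N − alpha_v·N², with mu0 the specific growth
        rate and alpha_v an intraspecific-competition coefficient.
    """

    form: str
    mu0: float
    Nmax: float | None = None
    alpha_v: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("carrying_capacity", "competition"):
            raise ValueError(f"unknown Verhulst form {self.form!r}")
        _require_positive(self, "mu0")
        if self.form == "carrying_capacity":
            if self.Nmax is None or not self.Nmax > 0:
                raise ValueError("carrying_capacity form requires Nmax > 0")
        else:
            if self.alpha_v is None or not self.alpha_v > 0:
                raise ValueError("competition form requires alpha_v > 0")


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

STATE_FIELDS = ("S", "N", "a", "A", "R", "L")


@dataclass(frozen=True)
class FullState:
    """Instantaneous values of the six dynamic variables."""

    S: float
    N: float
    a: float
    A: float
    R: float
    L: float

    def __post_init__(self) -> None:
        _require_nonnegative(self, *STATE_FIELDS)

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.N, self.a, self.A, self.R, self.L], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "FullState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class StationaryState:
    """A fixed point of a scalar subsystem with its stability label."""

    value: float
    stability: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"stationary value must be nonnegative, got {self.value!r}")
        if self.stability not in ("stable", "unstable"):
            raise ValueError(f"stability must be 'stable' or 'unstable', got {self.stability!r}")

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution of the full model plus the luminescence signal."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 6), columns in STATE_FIELDS order
    intensity: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "intensity", intensity)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if states.shape != (times.size, 6):
            raise ValueError(f"states must have shape ({times.size}, 6), got {states.shape}")
        if intensity.shape != times.shape:
            raise ValueError("intensity must match times in length")

    def __len__(self) -> int:
        return int(self.times.size)

    def __getattr__(self, name: str):
        # column access: traj.S, traj.N, ...
        if name in STATE_FIELDS:
            return self.states[:, STATE_FIELDS.index(name)]
        raise AttributeError(name)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_h", self.times)
        df["I"] = self.intensity
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            times=df["time_h"].to_numpy(float),
            states=df[list(STATE_FIELDS)].to_numpy(float),
            intensity=df["I"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# shared kinetic primitives
# ---------------------------------------------------------------------------


def saturation(x: float, K: float) -> float:
    """Monod/Michaelis saturation ``x/(K+x)``.

    Monotone increasing in ``x`` and bounded in [0, 1).  Raises ``ValueError``
    on a negative ``x`` or nonpositive ``K``.  Accepts arrays in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("saturation: x must be nonnegative")
    if not K > 0:
        raise ValueError("saturation: K must be positive")
    out = x / (K + x)
    return out if out.ndim else float(out)


def verhulst_rate(N: float, p: VerhulstParams) -> float:
    """Logistic growth rate dN/dt under either parameterization of the law.

    The two forms are algebraically equivalent under
    ``mu0' = mu0·Nmax, alpha_v = mu0``.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("verhulst_rate: N must be nonnegative")
    if p.form == "carrying_capacity":
        out = p.mu0 * N * (p.Nmax - N)
    else:
        out = p.mu0 * N - p.alpha_v * N * N
    return out if out.ndim else float(out)


def as_reduced(qs: QSParams) -> ReducedQSParams:
    """Collapse the QS constants to the stationary-curve parameters
    (alpha = CR/k3, beta = VR/k3, sigma = KR·gamma)."""
    return ReducedQSParams(alpha=qs.CR / qs.k3, beta=qs.VR / qs.k3, sigma=qs.KR * qs.gamma)


# ---------------------------------------------------------------------------
# reference parameter vector
# ---------------------------------------------------------------------------


def reference_params(VL: float = 1.0e4, kdL: float = 0.3) -> FullParams:
    """The common fitted parameter vector for *Photobacterium phosphoreum* 1889
    batch culture, shared between media.

    ``VL`` and ``kdL`` are per-medium luminescence constants and have no
    common value; the defaults here are the rich-medium preset values of
    :mod:`luxqs.synth`.
    """
    return FullParams(
        growth=GrowthParams(Vg=2.18, Kg=3.99, Ka=0.0033),
        energy=EnergyParams(Ve=3.30, Ke=4.02, Kae=0.008, kd=0.0315, eps2=1.54, k0=0.082, a0=1.40),
        qs=QSParams(VR=1.50, CR=0.011, CA=0.14, k3=0.057, gamma=0.331, KR=0.06),
        lum=LumParams(VL=VL, KL=0.17, kdL=kdL),
        scale=ScaleParams(eps0=0.01, eps1=0.001, eps3=0.39, eps4=3.34),
    )


# ---------------------------------------------------------------------------
# flat (name -> value) access for the fitting layer
# ---------------------------------------------------------------------------

_PARAM_PATHS: dict[str, tuple[str, str]] = {
    "Vg": ("growth", "Vg"), "Kg": ("growth", "Kg"), "Ka": ("growth", "Ka"),
    "Ve": ("energy", "Ve"), "Ke": ("energy", "Ke"), "Kae": ("energy", "Kae"),
    "kd": ("energy", "kd"), "eps2": ("energy", "eps2"), "k0": ("energy", "k0"),
    "a0": ("energy", "a0"),
    "VR": ("qs", "VR"), "CR": ("qs", "CR"), "CA": ("qs", "CA"),
    "k3": ("qs", "k3"), "gamma": ("qs", "gamma"), "KR": ("qs", "KR"),
    "VL": ("lum", "VL"), "KL": ("lum", "KL"), "kdL": ("lum", "kdL"),
    "eps0": ("scale", "eps0"), "eps1": ("scale", "eps1"),
    "eps3": ("scale", "eps3"), "eps4": ("scale", "eps4"),
}

#: Documented name <-> location map used by the fitting layer.
FLAT_PARAM_NAMES: tuple[str, ...] = tuple(_PARAM_PATHS)


def get_param(p: FullParams, name: str) -> float:
    """Look up one kinetic constant by its flat name (e.g. ``"Vg"``)."""
    block, fname = _PARAM_PATHS[name]
    return getattr(getattr(p, block), fname)


def with_param(p: FullParams, name: str, value: float) -> FullParams:
    """Return a copy of ``p`` with one constant replaced (containers are
    immutable)."""
    block, fname = _PARAM_PATHS[name]
    sub = dataclasses.replace(getattr(p, block), **{fname: value})
    return dataclasses.replace(p, **{block: sub})
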