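"""Energy (ATP) block: rate laws, stationary states and regime scans.

The intracellular ATP concentration ``a`` is the fast variable of the model
(its equation carries the small multiplier eps1), so its one-dimensional rate
law can be analysed at frozen environmental variables.  Depending on the
parameter set the law exhibits either

* a *bistable* regime — a stable zero state plus, in a window of substrate
  concentrations, an unstable threshold and a stable high-ATP state — or
* a *monostable working* regime — an unstable zero state and exactly one
  stable positive ATP state at every positive substrate concentration,

which is the regime a viable cell needs: its energy charge is restored from
any perturbation.  :func:`bistable_demo` and :func:`monostable_demo` ship
calibrated configurations for the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .core import EnergyParams, GrowthParams, StationaryState, saturation

__all__ = [
    "EnergyRateConfig",
    "fg",
    "fE",
    "atpase",
    "death_rate",
    "atp_rate",
    "stationary_states",
    "regime_scan",
    "EnergyDemo",
    "bistable_demo",
    "monostable_demo",
]


@dataclass(frozen=True)
class EnergyRateConfig:
    """Structural switches of the ATP balance.

    include_growth_cost : include the ATP cost ``k0·fg`` of biomass synthesis
        in the ATP balance.
    activation_exponent : cooperativity n of the ATP activation of its own
        production, ``a^n/(Kae + a^n)``; n in {1, 2}.
    atp_product_inhibition : multiply the production term by a Selkov-style
        inhibition factor ``a0²/(a0² + a²)``.  Energy metabolism then
        stabilizes ATP homeostatically: production falls off once ``a``
        exceeds the reference level ``a0``.  Off by default (the reduced
        single-enzyme form); the combined batch-culture model enables it.
    """

    include_growth_cost: bool = True
    activation_exponent: int = 1
    atp_product_inhibition: bool = False

    def __post_init__(self) -> None:
        if self.activation_exponent not in (1, 2):
            raise ValueError("activation_exponent must be 1 or 2")


def fg(S: float, a: float, p: GrowthParams) -> float:
    """ATP-dependent specific biomass synthesis rate
    ``Vg·S/(Kg+S)·a/(Ka+a)``."""
    return p.Vg * saturation(S, p.Kg) * saturation(a, p.Ka)


def fE(S: float, a: float, p: EnergyParams, cfg: EnergyRateConfig) -> float:
    """ATP production rate.

    ``Ve·S/(Ke+S)·a^n/(Kae+a^n)``, optionally damped by the product-inhibition
    factor ``a0²/(a0²+a²)`` (see :class:`EnergyRateConfig`).  Vanishes at
    a = 0 for any S — ATP production is autocatalytic, which is what makes
    a = 0 a fixed point of the subsystem.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("fE: a must be nonnegative")
    n = cfg.activation_exponent
    an = a_arr ** n
    act = an / (p.Kae + an)
    out = p.Ve * saturation(S, p.Ke) * act
    if cfg.atp_product_inhibition:
        out = out * p.a0 ** 2 / (p.a0 ** 2 + a_arr ** 2)
    return out if np.ndim(out) else float(out)


def atpase(a: float, p: EnergyParams) -> float:
    """Generalized-ATPase consumption ``kd·a/(eps2+a)``.

    For eps2 << a the activity is within eps2/a of kd, i.e. nearly constant
    over a wide range of ATP levels and dropping only at low ``a``.
    """
    return p.kd * saturation(a, p.eps2)


def death_rate(a: float, d0: float = 0.05, K_d0: float = 0.5) -> float:
    """Energy-starvation death intensity ``d0·K_d0/(K_d0+a)``.

    Nonincreasing in ``a`` (high energy charge, low mortality) and equal to
    d0/2 at a = K_d0.  Kept for completeness of the ecological block; the
    combined batch-culture model covers inoculation through the logarithmic
    phase only, where mortality is not observable, so this term is excluded
    there.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("death_rate: a must be nonnegative")
    if not (d0 > 0 and K_d0 > 0):
        raise ValueError("death_rate: d0 and K_d0 must be positive")
    out = d0 * K_d0 / (K_d0 + a_arr)
    return out if np.ndim(out) else float(out)


def atp_rate(
    S: float,
    a: float,
    p: EnergyParams,
    g: GrowthParams,
    cfg: EnergyRateConfig,
) -> float:
    """Net ATP balance ``fE − [k0·fg] − ATPase`` at frozen S.

    Exactly zero at a = 0 for every S: production, growth cost and ATPase all
    vanish with ATP itself.
    """
    out = fE(S, a, p, cfg) - atpase(a, p)
    if cfg.include_growth_cost:
        out = out - p.k0 * fg(S, a, g)
    return out if np.ndim(out) else float(out)


def _bisect(f, lo: float, hi: float, tol: float = 1e-10) -> float:
    flo = f(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            return mid
        fmid = f(mid)
        if fmid == 0.0:
            return mid
        if (flo > 0) == (fmid > 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stationary_states(
    S: float,
    p: EnergyParams,
    g: GrowthParams,
    cfg: EnergyRateConfig,
    a_max: float | None = None,
    n_grid: int = 2000,
) -> list[StationaryState]:
    """All fixed points of the ATP rate law in [0, a_max] with stability.

    Roots are bracketed by sign changes on a uniform grid and refined by
    bisection (absolute tolerance 1e-10), deduplicated at 1e-6.  A root is
    stable iff the rate is positive immediately below and negative
    immediately above it (central step 1e-6); the boundary root a = 0, which
    always exists, is classified one-sidedly.
    """
    if a_max is None:
        a_max = 4.0 * max(1.0, p.a0)
    if not a_max > 0:
        raise ValueError("a_max must be positive")
    if n_grid < 100:
        raise ValueError("n_grid must be at least 100")

    def rate(a: float) -> float:
        return atp_rate(S, a, p, g, cfg)

    grid = np.linspace(0.0, a_max, n_grid + 1)
    vals = atp_rate(S, grid, p, g, cfg)

    roots = [0.0]
    for i in range(1, n_grid):
        lo, hi = grid[i], grid[i + 1]
        flo, fhi = vals[i], vals[i + 1]
        if flo == 0.0:
            roots.append(float(lo))
        elif flo * fhi < 0:
            roots.append(_bisect(rate, float(lo), float(hi)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or r - dedup[-1] > 1e-6:
            dedup.append(r)

    h = 1e-6
    out = []
    for r in dedup:
        above = rate(r + h)
        if r - h < 0:
            stable = above < 0
        else:
            below = rate(r - h)
            stable = below > 0 and above < 0
        out.append(StationaryState(value=r, stability="stable" if stable else "unstable"))
    return out


def regime_scan(
    p: EnergyParams,
    g: GrowthParams,
    cfg: EnergyRateConfig,
    S_grid: Sequence[float],
    a_max: float | None = None,
    n_grid: int = 2000,
) -> dict:
    """Scan stationary ATP states over a grid of substrate concentrations.

    Returns a JSON-serializable report with a per-S table (root count, zero
    stability, largest stable root) and a summary (maximal root count,
    whether zero is stable at every S, whether every S > 0 has exactly one
    stable positive state).
    """
    if len(S_grid) == 0:
        raise ValueError("S_grid must be nonempty")
    per_S = []
    for S in S_grid:
        states = stationary_states(S, p, g, cfg, a_max=a_max, n_grid=n_grid)
        pos_stable = [s.value for s in states if s.is_stable and s.value > 0]
        per_S.append(
            {
                "S": float(S),
                "n_roots": len(states),
                "zero_stable": states[0].is_stable,
                "n_positive_stable": len(pos_stable),
                "largest_stable_root": max(pos_stable) if pos_stable else None,
                "roots": [[s.value, s.stability] for s in states],
            }
        )
    positive_rows = [row for row in per_S if row["S"] > 0]
    summary = {
        "max_root_count": max(row["n_roots"] for row in per_S),
        "zero_stable_everywhere": all(row["zero_stable"] for row in per_S),
        "unique_positive_stable_everywhere": bool(positive_rows)
        and all(
            row["n_positive_stable"] == 1 and not row["zero_stable"] for row in positive_rows
        ),
    }
    return {"per_S": per_S, "summary": summary}


class EnergyDemo(NamedTuple):
    """A documented energy-block configuration plus the scan it is shown on."""

    params: EnergyParams
    growth: GrowthParams
    config: EnergyRateConfig
    S_grid: tuple[float, ...]
    a_max: float


def bistable_demo() -> EnergyDemo:
    """Configuration exhibiting the bistable regime.

    Cooperative ATP activation (n = 2) keeps the zero state stable; within
    S in roughly (0.25, 0.33) the positive fixed-point equation
    ``(Ve·sS − kd)·a² + Ve·sS·eps2·a − kd·Kae = 0`` (sS = S/(Ke+S)) gains two
    positive roots, giving the stable-zero / unstable / stable pattern.  The
    parameters are the bistable reference set with eps2 raised to 0.5, which
    widens the bistable substrate window from a sliver to a robust interval.
    """
    return EnergyDemo(
        params=EnergyParams(Ve=2.0, Ke=1.0, Kae=0.2, kd=0.5, eps2=0.5, k0=0.082, a0=1.0),
        growth=GrowthParams(Vg=1.22, Kg=1.94, Ka=0.01),
        config=EnergyRateConfig(include_growth_cost=False, activation_exponent=2),
        S_grid=(0.05, 0.1, 0.2, 0.28, 0.30),
        a_max=8.0,
    )


def monostable_demo() -> EnergyDemo:
    """Configuration exhibiting the working (monostable) regime.

    With n = 1 the zero state is unstable whenever the production slope
    ``Ve·sS/Kae`` exceeds the consumption slope ``kd/eps2 + k0·Vg·sS/Ka``, and
    the growth-cost channel (k0 = 1.6, Ka = 0.04 here) caps production at
    large ``a`` so exactly one stable positive root exists at every S > 0 in
    the scan: the cell's energy charge is homeostatic.
    """
    return EnergyDemo(
        params=EnergyParams(Ve=3.299, Ke=4.0, Kae=0.008, kd=0.026, eps2=0.85, k0=1.6, a0=1.0),
        growth=GrowthParams(Vg=2.18, Kg=4.0, Ka=0.04),
        config=EnergyRateConfig(include_growth_cost=True, activation_exponent=1),
        S_grid=(0.5, 1.0, 2.0, 4.0, 8.0),
        a_max=4.0,
    )
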