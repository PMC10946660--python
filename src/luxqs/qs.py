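"""Quorum-sensing switch: reduced LuxR dynamics, bistability and hysteresis.

The autoinducer A and the receptor LuxR (R) form a complex whose dimer D
activates the lux operon.  With the two binding steps at quasi-steady state
the dimer collapses to ``D = (R·A)²/gamma`` and LuxR obeys a single ODE in
which A acts as an external parameter:

    dR/dt = CR + VR·D/(KR + D) − k3·R.

Setting the rate to zero and solving for A gives the explicit stationary
curve A(R) on alpha < R < alpha + beta (alpha = CR/k3, beta = VR/k3,
sigma = KR·gamma):

    A(R) = sqrt( sigma·(R − alpha) / (alpha + beta − R) ) / R.

When A(R) is non-monotone the switch is bistable: the interior local maximum
and minimum of A(R) are the fold (saddle-node) points, the up-switch and
down-switch thresholds of the hysteresis loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import QSParams, ReducedQSParams, StationaryState, as_reduced

__all__ = [
    "dimer_qss",
    "luxr_rate",
    "stationary_autoinducer",
    "stationary_branches",
    "FoldReport",
    "fold_points",
    "hysteresis_loop",
]


def dimer_qss(R: float, A: float, gamma: float) -> float:
    """Quasi-steady-state dimer concentration ``D = (R·A)²/gamma``."""
    R = np.asarray(R, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(R < 0) or np.any(A < 0):
        raise ValueError("dimer_qss: R and A must be nonnegative")
    if not gamma > 0:
        raise ValueError("dimer_qss: gamma must be positive")
    out = (R * A) ** 2 / gamma
    return out if np.ndim(out) else float(out)


def luxr_rate(R: float, A: float, qs: QSParams) -> float:
    """dR/dt of the reduced LuxR equation at autoinducer level ``A``.

    At A = 0 the unique fixed point is the basal level R = CR/k3.
    """
    D = dimer_qss(R, A, qs.gamma)
    out = qs.CR + qs.VR * D / (qs.KR + D) - qs.k3 * np.asarray(R, dtype=float)
    return out if np.ndim(out) else float(out)


def stationary_autoinducer(R: float, rp: ReducedQSParams) -> float:
    """Autoinducer level at which ``R`` is stationary (the explicit inverse
    of the stationary condition).

    Defined only on the open interval alpha < R < alpha + beta; outside it
    the stationary condition has no solution and a ``ValueError`` signals
    the domain restriction.
    """
    if not (rp.alpha < R < rp.alpha + rp.beta):
        raise ValueError(
            f"stationary_autoinducer: R={R!r} outside the domain "
            f"(alpha, alpha+beta) = ({rp.alpha!r}, {rp.alpha + rp.beta!r})"
        )
    return math.sqrt(rp.sigma * (R - rp.alpha) / (rp.alpha + rp.beta - R)) / R


def _luxr_roots(A: float, qs: QSParams, n_grid: int = 4000) -> list[float]:
    rp = as_reduced(qs)
    lo = rp.alpha * (1.0 - 1e-9)
    hi = rp.alpha + rp.beta
    grid = np.linspace(lo, hi, n_grid + 1)
    vals = luxr_rate(grid, A, qs)
    roots: list[float] = []
    for i in range(n_grid):
        f0, f1 = vals[i], vals[i + 1]
        if f0 == 0.0:
            roots.append(float(grid[i]))
        elif f0 * f1 < 0:
            a, b = float(grid[i]), float(grid[i + 1])
            fa = f0
            for _ in range(200):
                m = 0.5 * (a + b)
                if b - a < 1e-12 * max(1.0, hi):
                    break
                fm = luxr_rate(m, A, qs)
                if fm == 0.0:
                    a = b = m
                    break
                if (fa > 0) == (fm > 0):
                    a, fa = m, fm
                else:
                    b = m
            roots.append(0.5 * (a + b))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    dedup: list[float] = []
    for r in sorted(roots):
        if not dedup or r - dedup[-1] > 1e-9 * max(1.0, hi):
            dedup.append(r)
    return dedup


def stationary_branches(
    qs: QSParams, A_grid: Sequence[float], n_grid: int = 4000
) -> list[list[StationaryState]]:
    """Fixed points of the LuxR equation, with stability, for each A in the
    grid.

    Stability is read off the sign of the rate on either side of each root;
    counts are 1 or 3 away from the folds (2 exactly at a fold).
    """
    if len(A_grid) == 0:
        raise ValueError("A_grid must be nonempty")
    out: list[list[StationaryState]] = []
    for A in A_grid:
        if A < 0:
            raise ValueError("A values must be nonnegative")
        states = []
        for r in _luxr_roots(float(A), qs, n_grid=n_grid):
            h = 1e-7 * max(1.0, r)
            below = luxr_rate(max(r - h, 0.0), A, qs)
            above = luxr_rate(r + h, A, qs)
            stable = below > 0 and above < 0
            states.append(StationaryState(value=r, stability="stable" if stable else "unstable"))
        out.append(states)
    return out


@dataclass(frozen=True)
class FoldReport:
    """Fold (saddle-node) structure of the stationary curve A(R).

    When bistable, ``A_switch_up`` (the local maximum of A(R) on the low-R
    side) is the threshold at which the basal branch disappears and the
    switch ignites; ``A_switch_down`` (the local minimum) is where the
    induced branch disappears on the way down.
    """

    is_bistable: bool
    R_fold_low: float | None = None
    R_fold_high: float | None = None
    A_switch_up: float | None = None
    A_switch_down: float | None = None


def fold_points(rp: ReducedQSParams, n_grid: int = 10_000) -> FoldReport:
    """Locate the interior extrema of A(R) on (alpha, alpha + beta).

    Sign changes of the central finite-difference derivative on a uniform
    grid are refined by bisection.  A monotone curve yields
    ``is_bistable=False`` with the fold fields absent.
    """
    lo = rp.alpha * (1 + 1e-9) + 1e-12
    hi = rp.alpha + rp.beta
    span = hi - lo
    eps = 1e-6 * span
    grid = np.linspace(lo + eps, hi - eps, n_grid)
    h = 1e-7 * span

    def dA(R: float) -> float:
        return stationary_autoinducer(R + h, rp) - stationary_autoinducer(R - h, rp)

    deriv = np.array([dA(R) for R in grid])
    extrema: list[tuple[float, str]] = []
    for i in range(n_grid - 1):
        if deriv[i] == 0.0:
            extrema.append((float(grid[i]), "max" if (i > 0 and deriv[i - 1] > 0) else "min"))
        elif deriv[i] * deriv[i + 1] < 0:
            a, b = float(grid[i]), float(grid[i + 1])
            da = deriv[i]
            for _ in range(200):
                m = 0.5 * (a + b)
                if b - a < 1e-13 * span:
                    break
                dm = dA(m)
                if dm == 0.0:
                    a = b = m
                    break
                if (da > 0) == (dm > 0):
                    a, da = m, dm
                else:
                    b = m
            kind = "max" if deriv[i] > 0 else "min"
            extrema.append((0.5 * (a + b), kind))

    # bistable iff a local max is followed by a local min
    for j in range(len(extrema) - 1):
        if extrema[j][1] == "max" and extrema[j + 1][1] == "min":
            R_lo, R_hi = extrema[j][0], extrema[j + 1][0]
            return FoldReport(
                is_bistable=True,
                R_fold_low=R_lo,
                R_fold_high=R_hi,
                A_switch_up=stationary_autoinducer(R_lo, rp),
                A_switch_down=stationary_autoinducer(R_hi, rp),
            )
    return FoldReport(is_bistable=False)


def hysteresis_loop(
    qs: QSParams,
    times: Sequence[float],
    A_path: Sequence[float] | Callable[[float], float],
    R0: float,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate dR/dt = luxr_rate(R, A(t)) along a prescribed autoinducer
    path and return R at the given times.

    For a slow up-then-down ramp crossing both folds the trajectory switches
    up near ``A_switch_up`` and back down near ``A_switch_down``, tracing the
    hysteresis loop of the switch.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with at least two points")
    if callable(A_path):
        A_of_t = A_path
    else:
        A_vals = np.asarray(A_path, dtype=float)
        if A_vals.shape != times.shape:
            raise ValueError("A_path must match times in length")

        def A_of_t(t: float) -> float:
            return float(np.interp(t, times, A_vals))

    def rhs(t, y):
        return [luxr_rate(max(y[0], 0.0), max(A_of_t(t), 0.0), qs)]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [float(R0)],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"hysteresis_loop: integration failed: {sol.message}")
    return sol.y[0]
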