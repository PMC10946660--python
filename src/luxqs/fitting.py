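"""Two-stage derivative-free parameter estimation.

Stage 1 adjusts the ecological/energy side of the model against the biomass
(OD660) series; stage 2 then adjusts the QS/luminescence side against the
luminescence series with every stage-1 parameter frozen.  Both stages
minimize a weighted sum of squared residuals with an in-package Nelder–Mead
simplex: biomass residuals are taken on the linear scale, luminescence on
log10 (its dynamic range spans orders of magnitude).

Free parameters are log-transformed by default and constrained to positive
boxes via a finite penalty.  This directly suppresses the classic pathology
of local simplex search on Monod-type laws — half-saturation constants
drifting to zero (or below) on sparse data — while keeping the goal function
finite and deterministic everywhere.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FullParams, FullState, get_param, with_param
from .dynamics import DEFAULT_CONFIG, simulate
from .energy import EnergyRateConfig
from .synth import MediumScenario

__all__ = [
    "PENALTY",
    "STAGE1_FREE_DEFAULT",
    "STAGE2_FREE_DEFAULT",
    "FitSpec",
    "FitResult",
    "true_value",
    "set_values",
    "goal_function",
    "nelder_mead",
    "simplex_minimize",
    "fit_stage1",
    "fit_stage2",
    "multistart",
]

PENALTY = 1.0e12

#: Default free sets.  Stage 1 frees the parameters a biomass curve actually
#: constrains (growth kinetics and initial conditions); the ATP-block
#: constants are held at their reference values because sat(a, Ka) ~ 1 along
#: trajectories makes them unidentifiable from OD data alone.
STAGE1_FREE_DEFAULT: tuple[str, ...] = ("Vg", "Kg", "S0", "N0")
STAGE2_FREE_DEFAULT: tuple[str, ...] = ("VL", "kdL", "CA", "VR")

_SCENARIO_NAMES = ("S0", "N0", "L0")


def true_value(p: FullParams, scenario: MediumScenario, name: str) -> float:
    """Current value of a free parameter, whether it lives in the kinetic
    vector or in the scenario (S0, N0, L0)."""
    if name in _SCENARIO_NAMES:
        return getattr(scenario, name)
    return get_param(p, name)


def set_values(
    p: FullParams, scenario: MediumScenario, values: Mapping[str, float]
) -> tuple[FullParams, MediumScenario]:
    """Return copies of the parameter vector and scenario with the named
    values replaced."""
    scen_kw = {k: v for k, v in values.items() if k in _SCENARIO_NAMES}
    if scen_kw:
        scenario = scenario.replace(**scen_kw)
    for k, v in values.items():
        if k not in _SCENARIO_NAMES:
            p = with_param(p, k, v)
    return p, scenario


@dataclass(frozen=True)
class FitSpec:
    """Everything the goal function needs besides the trial point.

    bounds map each free name to a positive interval; transform is applied
    to the free parameters before the simplex sees them ("log" recommended).
    loss_scale chooses per-series residual scale ("linear" or "log10", the
    latter with a floor to keep zero observations finite).
    """

    free_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    data: pd.DataFrame
    transform: str = "log"
    weights: Mapping[str, float] = field(default_factory=dict)
    loss_scale: Mapping[str, str] = field(default_factory=dict)
    cfg: EnergyRateConfig = DEFAULT_CONFIG
    rtol: float = 1e-6
    atol: float = 1e-9
    #: detection limit for the log10 luminescence residual; None = 1e-6 of
    #: the brightest observation (signals below it are dark noise, and after
    #: the ATP crash the model's intensity underflows toward round-off)
    lum_floor: float | None = None

    def __post_init__(self) -> None:
        if not self.free_names:
            raise ValueError("free_names must be nonempty")
        if self.transform not in ("log", "linear"):
            raise ValueError("transform must be 'log' or 'linear'")
        for name in self.free_names:
            lo, hi = self.bounds[name]
            if not (0 < lo < hi) and self.transform == "log":
                raise ValueError(f"bounds for {name} must be positive for log transform")
        t = self.data["time_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("data times must be increasing")

    # -- transforms ---------------------------------------------------------

    def encode(self, values: Mapping[str, float]) -> np.ndarray:
        raw = np.array([values[n] for n in self.free_names], dtype=float)
        return np.log(raw) if self.transform == "log" else raw

    def decode(self, x: Sequence[float]) -> dict[str, float]:
        x = np.asarray(x, dtype=float)
        raw = np.exp(x) if self.transform == "log" else x
        return dict(zip(self.free_names, raw))

    def bound_violation(self, x: Sequence[float]) -> float:
        """Squared distance to the (transformed) bound box; 0 inside."""
        total = 0.0
        x = np.asarray(x, dtype=float)
        for xi, name in zip(x, self.free_names):
            lo, hi = self.bounds[name]
            if self.transform == "log":
                lo, hi = math.log(lo), math.log(hi)
            if xi < lo:
                total += (lo - xi) ** 2
            elif xi > hi:
                total += (xi - hi) ** 2
        return total


def default_bounds(
    start_values: Mapping[str, float], factor: float = 1.0e3
) -> dict[str, tuple[float, float]]:
    """Positive box bounds spanning ``factor`` on either side of the start."""
    return {k: (v / factor, v * factor) for k, v in start_values.items()}


def _series_residuals(spec: FitSpec, pred: np.ndarray, obs: np.ndarray, series: str) -> float:
    w = float(spec.weights.get(series, 1.0))
    scale = spec.loss_scale.get(series, "linear")
    if scale == "log10":
        floor = spec.lum_floor
        if floor is None:
            floor = 1e-6 * float(np.max(obs)) if np.max(obs) > 0 else 1e-12
        r = np.log10(np.maximum(pred, floor)) - np.log10(np.maximum(obs, floor))
    else:
        r = pred - obs
    return w * float(np.dot(r, r))


def goal_function(
    x: Sequence[float],
    spec: FitSpec,
    base: FullParams,
    scenario: MediumScenario,
) -> float:
    """Weighted SSR between the simulated and observed series at trial point
    ``x`` (in transformed coordinates).

    Out-of-bounds points and failed integrations map to the finite penalty
    ``PENALTY + squared bound distance`` so the simplex can always retreat.
    Deterministic given its inputs.
    """
    violation = spec.bound_violation(x)
    if violation > 0:
        return PENALTY + violation
    values = spec.decode(x)
    p, scen = set_values(base, scenario, values)
    t = spec.data["time_h"].to_numpy(float)
    try:
        init = FullState(
            S=scen.S0, N=scen.N0, a=p.energy.a0, A=0.0, R=p.qs.CR / p.qs.k3, L=scen.L0
        )
        traj = simulate(p, spec.cfg, init=init, t_grid=t, rtol=spec.rtol, atol=spec.atol)
    except (RuntimeError, ValueError, OverflowError):
        return PENALTY
    loss = 0.0
    if "od660" in spec.data:
        loss += _series_residuals(spec, traj.N, spec.data["od660"].to_numpy(float), "od660")
    if "substrate" in spec.data:
        loss += _series_residuals(
            spec, traj.S, spec.data["substrate"].to_numpy(float), "substrate"
        )
    if "lum" in spec.data:
        loss += _series_residuals(
            spec, traj.intensity, spec.data["lum"].to_numpy(float), "lum"
        )
    return loss


# ---------------------------------------------------------------------------
# Nelder–Mead simplex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    best_params: dict[str, float]
    loss: float
    n_eval: int
    converged: bool
    trace: tuple[float, ...]
    start_index: int = 0
    fitted_params: FullParams | None = None
    fitted_scenario: MediumScenario | None = None
    all_losses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.loss):
            raise ValueError("FitResult.loss must be finite")


def nelder_mead(
    f: Callable[[np.ndarray], float],
    x0: Sequence[float],
    initial_step: float | Sequence[float] = 0.25,
    xatol: float = 1e-8,
    fatol: float = 1e-10,
    maxiter: int = 5000,
) -> dict:
    """Plain Nelder–Mead with the textbook coefficients
    (reflection 1, expansion 2, contraction 0.5, shrink 0.5).

    Declares convergence when the simplex diameter has fallen below
    ``xatol`` and the spread of goal values below ``fatol`` (the usual
    fminsearch-style joint test, which actually localizes the minimizer and
    not merely the minimum), else stops at ``maxiter`` iterations.  Fully
    deterministic given the start point.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("nelder_mead: x0 must be finite")
    n = x0.size
    steps = np.broadcast_to(np.asarray(initial_step, dtype=float), (n,))
    simplex = [x0.copy()]
    for i in range(n):
        v = x0.copy()
        v[i] += steps[i] if steps[i] != 0 else 1e-4
        simplex.append(v)
    simplex = np.array(simplex)
    fvals = np.array([f(v) for v in simplex])
    if not math.isfinite(fvals[0]):
        raise ValueError("nelder_mead: goal not finite at x0")
    n_eval = n + 1
    trace = []
    converged = False
    for _ in range(maxiter):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        trace.append(float(fvals[0]))
        diameter = np.max(np.abs(simplex[1:] - simplex[0]))
        if diameter < xatol and fvals[-1] - fvals[0] < fatol:
            converged = True
            break
        centroid = simplex[:-1].mean(axis=0)
        xr = centroid + (centroid - simplex[-1])  # reflection
        fr = f(xr); n_eval += 1
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - simplex[-1])  # expansion
            fe = f(xe); n_eval += 1
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:
                xc = centroid + 0.5 * (xr - centroid)  # outside contraction
            else:
                xc = centroid + 0.5 * (simplex[-1] - centroid)  # inside
            fc = f(xc); n_eval += 1
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, n + 1):
                    simplex[i] = simplex[0] + 0.5 * (simplex[i] - simplex[0])
                    fvals[i] = f(simplex[i])
                n_eval += n
    order = np.argsort(fvals, kind="stable")
    simplex, fvals = simplex[order], fvals[order]
    return {
        "x": simplex[0],
        "fun": float(fvals[0]),
        "n_eval": n_eval,
        "converged": converged,
        "trace": tuple(trace),
    }


#: alias matching the operation name used in configs and docs
simplex_minimize = nelder_mead


# ---------------------------------------------------------------------------
# staged fits
# ---------------------------------------------------------------------------


def _run_stage(
    data: pd.DataFrame,
    base: FullParams,
    scenario: MediumScenario,
    free_names: tuple[str, ...],
    series_scales: dict[str, str],
    required: str,
    cfg: EnergyRateConfig,
    start_values: Mapping[str, float] | None,
    bounds: Mapping[str, tuple[float, float]] | None,
    transform: str,
    weights: Mapping[str, float] | None,
    rtol: float,
    atol: float,
    maxiter: int,
    initial_step: float,
    xatol: float,
    fatol: float,
) -> FitResult:
    if required not in data:
        raise ValueError(f"data must contain a {required!r} column for this stage")
    if start_values is None:
        start_values = {n: true_value(base, scenario, n) for n in free_names}
    else:
        start_values = dict(start_values)
        for n in free_names:
            start_values.setdefault(n, true_value(base, scenario, n))
    if bounds is None:
        bounds = default_bounds(start_values)
    keep = [c for c in ("time_h",) + tuple(series_scales) if c in data]
    spec = FitSpec(
        free_names=tuple(free_names),
        bounds=bounds,
        data=data[keep],
        transform=transform,
        weights=weights or {},
        loss_scale=series_scales,
        cfg=cfg,
        rtol=rtol,
        atol=atol,
    )
    x0 = spec.encode(start_values)
    res = nelder_mead(
        lambda x: goal_function(x, spec, base, scenario),
        x0,
        initial_step=initial_step,
        xatol=xatol,
        fatol=fatol,
        maxiter=maxiter,
    )
    best = spec.decode(res["x"])
    fitted_params, fitted_scenario = set_values(base, scenario, best)
    return FitResult(
        best_params=best,
        loss=res["fun"],
        n_eval=res["n_eval"],
        converged=res["converged"],
        trace=res["trace"],
        fitted_params=fitted_params,
        fitted_scenario=fitted_scenario,
    )


def fit_stage1(
    data: pd.DataFrame,
    base: FullParams,
    scenario: MediumScenario,
    cfg: EnergyRateConfig = DEFAULT_CONFIG,
    free_names: tuple[str, ...] = STAGE1_FREE_DEFAULT,
    start_values: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    transform: str = "log",
    weights: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    maxiter: int = 500,
    initial_step: float = 0.25,
    xatol: float = 1e-4,
    fatol: float = 1e-9,
) -> FitResult:
    """Fit the ecological/energy side to the biomass series.

    Only the names in ``free_names`` move; every QS/luminescence constant is
    left bit-identical.  Residuals are linear in OD660; a ``substrate``
    column, if the data provide one, is fitted alongside on the linear
    scale.
    """
    return _run_stage(
        data, base, scenario, tuple(free_names),
        {"od660": "linear", "substrate": "linear"}, "od660",
        cfg, start_values, bounds, transform, weights, rtol, atol,
        maxiter, initial_step, xatol, fatol,
    )


def fit_stage2(
    data: pd.DataFrame,
    base: FullParams,
    scenario: MediumScenario,
    cfg: EnergyRateConfig = DEFAULT_CONFIG,
    free_names: tuple[str, ...] = STAGE2_FREE_DEFAULT,
    start_values: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    transform: str = "log",
    weights: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    maxiter: int = 500,
    initial_step: float = 0.25,
    xatol: float = 1e-4,
    fatol: float = 1e-9,
) -> FitResult:
    """Fit the QS/luminescence side to the luminescence series.

    ``base``/``scenario`` should carry the stage-1 result (pass
    ``res1.fitted_params`` and ``res1.fitted_scenario``); the ecological and
    energy values are frozen here.  Residuals are log10 in luminescence.
    """
    return _run_stage(
        data, base, scenario, tuple(free_names), {"lum": "log10"}, "lum",
        cfg, start_values, bounds, transform, weights, rtol, atol,
        maxiter, initial_step, xatol, fatol,
    )


def multistart(
    fit: Callable[..., FitResult],
    start_values: Mapping[str, float],
    n_starts: int = 1,
    dispersion: float = 0.3,
    seed: int = 0,
    **fit_kwargs,
) -> FitResult:
    """Run a staged fit from log-normally jittered starts; keep the best.

    The first start is the unjittered ``start_values`` (so n_starts=1 equals
    a single fit), and the jitter stream depends only on ``seed`` — start
    sets are nested across increasing ``n_starts``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    best_index = 0
    losses = []
    for i in range(n_starts):
        if i == 0:
            starts = dict(start_values)
        else:
            starts = {
                k: v * rng.lognormal(0.0, dispersion) for k, v in start_values.items()
            }
        res = fit(start_values=starts, **fit_kwargs)
        losses.append(res.loss)
        if best is None or res.loss < best.loss:
            best, best_index = res, i
    return dataclasses.replace(best, start_index=best_index, all_losses=tuple(losses))
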