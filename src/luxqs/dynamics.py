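"""The combined six-variable batch-culture model and its diagnostics.

State ``(S, N, a, A, R, L)``: substrate, biomass, intracellular ATP,
autoinducer, LuxR, luciferase.  The right-hand side couples the four blocks:

    dS/dt      = −eps0·N·(fE + k0·fg)                  substrate consumption
    dN/dt      = fg·N                                  growth
    eps1·da/dt = fE − k0·fg − ATPase                   fast energy balance
    dA/dt      = CA·N                                  background autoinducer
    eps3·dR/dt = CR + VR·sat(a,a0)·D/(KR+D) − k3·R     QS switch
    eps4·dL/dt = sat(a,KL)·D/(KR+D) − kdL·L            luciferase turnover

with D = (R·A)²/gamma and the observed luminescence I = VL·L·sat(a,KL).
The induced LuxR and luciferase synthesis terms are energy-dependent (their
promoter activity D/(KR+D) is throttled by ATP), while the basal LuxR and
autoinducer production are energy-independent — their cost is folded into
the generalized ATPase.  Autoinducer concentrations in the medium and the
cell are taken to coincide, and no death term is carried: the model covers
inoculation through the end of the logarithmic phase.

eps0 converts intracellular rates to flask-concentration rates (volume
ratio), and eps1 = 0.001 makes ATP the fast variable: after a short initial
layer ``a`` rides the stable root of the energy block at the instantaneous
substrate level, which is why luminescence collapses sharply — faster than
luciferase inactivation alone — once the substrate runs out.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .core import FullParams, FullState, Trajectory, saturation
from .energy import EnergyRateConfig, atpase, fE, fg
from .qs import dimer_qss

__all__ = [
    "DEFAULT_CONFIG",
    "full_rhs",
    "luminescence",
    "simulate",
    "default_initial_state",
    "qs_onset_time",
    "lum_peak",
    "atp_tracking_error",
    "lum_signature",
]

#: Structural configuration of the combined model: first-order ATP activation
#: with Selkov-style product inhibition (homeostatic energy block) and the
#: growth cost k0·fg included in both the substrate and the ATP balance.
DEFAULT_CONFIG = EnergyRateConfig(
    include_growth_cost=True, activation_exponent=1, atp_product_inhibition=True
)


def full_rhs(state, p: FullParams, cfg: EnergyRateConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Time derivative of ``(S, N, a, A, R, L)``.

    Accepts a :class:`FullState` or a length-6 array.  Stiff integrators
    probe slightly negative values near the axes; components are clamped at
    zero for rate evaluation, while excursions beyond −1e-6 raise.
    """
    y = state.as_array() if isinstance(state, FullState) else np.asarray(state, dtype=float)
    if np.any(y < -1e-6):
        raise ValueError(f"full_rhs: state strongly negative: {y}")
    S, N, a, A, R, L = np.maximum(y, 0.0)

    growth = fg(S, a, p.growth)
    production = fE(S, a, p.energy, cfg)
    cost = p.energy.k0 * growth
    D = dimer_qss(R, A, p.qs.gamma)
    promoter = D / (p.qs.KR + D)
    sat_a0 = saturation(a, p.energy.a0)
    sat_KL = saturation(a, p.lum.KL)

    dS = -p.scale.eps0 * N * (production + cost)
    dN = growth * N
    da = (production - cost - atpase(a, p.energy)) / p.scale.eps1
    dA = p.qs.CA * N
    dR = (p.qs.CR + p.qs.VR * sat_a0 * promoter - p.qs.k3 * R) / p.scale.eps3
    dL = (sat_KL * promoter - p.lum.kdL * L) / p.scale.eps4
    out = np.array([dS, dN, da, dA, dR, dL])
    # non-finite or absurdly large derivatives mean an overflowing
    # configuration; failing here (rather than letting the integrator shrink
    # its steps indefinitely) surfaces the error to the caller
    if not np.all(np.isfinite(out)) or np.max(np.abs(out)) > 1e100:
        raise RuntimeError(f"full_rhs: runaway derivative at state {y}")
    return out


def luminescence(L: float, a: float, lum) -> float:
    """Observed light emission ``I = VL·L·a/(KL+a)``.

    Emission needs both the enzyme and energy: it vanishes with either L or
    ATP, and the ATP factor — not luciferase decay — is what produces the
    sharp post-peak collapse.
    """
    L_arr = np.asarray(L, dtype=float)
    if np.any(L_arr < 0):
        raise ValueError("luminescence: L must be nonnegative")
    out = lum.VL * L_arr * saturation(a, lum.KL)
    return out if np.ndim(out) else float(out)


def simulate(
    p: FullParams,
    cfg: EnergyRateConfig = DEFAULT_CONFIG,
    init: FullState | None = None,
    t_grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full model on ``t_grid`` and attach the luminescence
    signal.

    The eps1 = 0.001 time-scale separation makes the system stiff, so a
    stiff-capable method with tight tolerances is the default.  Outputs are
    clipped to zero where round-off produced tiny negative values; the
    integrator state itself is never clipped.
    """
    if init is None:
        raise ValueError("simulate: init state required")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    y0 = init.as_array()

    def rhs(t, y):
        return full_rhs(y, p, cfg)

    t0 = float(t_grid[0])
    t1 = float(t_grid[-1]) if t_grid.size > 1 else t0
    if t1 == t0:
        ys = y0[None, :]
    else:
        sol = solve_ivp(rhs, (t0, t1), y0, method=method, t_eval=t_grid, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"simulate: integration failed at t={sol.t[-1] if sol.t.size else t0:.4g} h: "
                f"{sol.message}"
            )
        ys = sol.y.T
    states = np.clip(ys, 0.0, None)
    intensity = luminescence(states[:, 5], states[:, 2], p.lum)
    return Trajectory(times=t_grid, states=states, intensity=np.asarray(intensity, dtype=float))


def default_initial_state(p: FullParams, scenario) -> FullState:
    """Fresh-medium initial condition for a scenario.

    Substrate and inoculum from the scenario, ATP at the reference level a0,
    no autoinducer, LuxR at the basal fixed point CR/k3, and the small
    luciferase stock L0 brought in with the inoculum (this is what emits the
    pre-ignition glow).
    """
    return FullState(
        S=scenario.S0,
        N=scenario.N0,
        a=p.energy.a0,
        A=0.0,
        R=p.qs.CR / p.qs.k3,
        L=scenario.L0,
    )


def qs_onset_time(traj: Trajectory, qs, rel_threshold: float = 0.5) -> float | None:
    """First time the LuxR trace exceeds ``alpha + rel_threshold·beta``.

    Returns ``None`` when the switch never ignites within the trajectory.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise ValueError("rel_threshold must be in (0, 1)")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    threshold = qs.CR / qs.k3 + rel_threshold * qs.VR / qs.k3
    above = traj.R > threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return float(traj.times[idx[0]])


def atp_tracking_error(
    traj: Trajectory,
    p: FullParams,
    cfg: EnergyRateConfig = DEFAULT_CONFIG,
    t_layer: float = 0.5,
    substrate_floor_frac: float = 0.1,
    a_max: float = 10.0,
) -> dict:
    """Quasi-steady-state consistency of the fast ATP variable.

    Compares a(t) with the largest stable positive root of the energy block
    at the instantaneous substrate level, on the window from ``t_layer``
    (past the initial relaxation layer) to the last time with
    ``S >= substrate_floor_frac·S(0)``.  Beyond substrate exhaustion the
    stable root is destroyed at a fold — a non-hyperbolic point where
    Tikhonov-style tracking necessarily degrades for any finite eps1 — so
    the collapse itself is outside the reduction's domain of validity.

    Returns max/mean relative tracking error and the window actually used.
    """
    from .energy import stationary_states

    S0 = traj.S[0]
    in_window = (traj.times >= t_layer) & (traj.S >= substrate_floor_frac * S0)
    errors = []
    for i in np.flatnonzero(in_window):
        roots = stationary_states(traj.S[i], p.energy, p.growth, cfg, a_max=a_max)
        positive = [s.value for s in roots if s.is_stable and s.value > 0]
        if not positive:
            continue
        root = max(positive)
        errors.append(abs(traj.a[i] - root) / root)
    if not errors:
        raise ValueError("atp_tracking_error: no usable window in trajectory")
    times = traj.times[in_window]
    return {
        "max_rel_error": float(max(errors)),
        "mean_rel_error": float(np.mean(errors)),
        "t_start": float(times[0]),
        "t_end": float(times[-1]),
        "n_points": len(errors),
    }


def lum_signature(traj: Trajectory, kdL: float, t_layer: float = 0.5) -> dict:
    """Qualitative luminescence signature of a batch culture with QS.

    Checks, past the initial ATP-relaxation layer: (1) the glow brought in
    with the inoculum decays strictly on an initial window; (2) the trace
    has a unique interior maximum; (3) the post-peak log-slope is steeper
    than first-order luciferase inactivation −kdL alone, i.e. the collapse
    cannot be attributed to enzyme decay (it is the ATP crash).
    """
    mask = traj.times >= t_layer
    t = traj.times[mask]
    I = traj.intensity[mask]
    if t.size < 5:
        raise ValueError("lum_signature: trajectory too short")
    ipk = int(np.argmax(I))
    t_peak, I_peak = float(t[ipk]), float(I[ipk])
    # initial decline: strictly decreasing from the window start to the
    # pre-ignition minimum
    imin = int(np.argmin(I[: ipk + 1])) if ipk > 0 else 0
    initial_decline = imin > 0 and bool(np.all(np.diff(I[: imin + 1]) < 0))
    interior_maxima = [
        i for i in range(1, t.size - 1) if I[i] > I[i - 1] and I[i] >= I[i + 1]
    ]
    # post-peak log-slope over up to 1 h past the peak
    jend = int(np.searchsorted(t, t_peak + 1.0, side="right"))
    post_slope = None
    if jend - ipk >= 2:
        seg_t = t[ipk:jend]
        seg_I = np.log(np.maximum(I[ipk:jend], 1e-300))
        post_slope = float(np.polyfit(seg_t, seg_I, 1)[0])
    return {
        "initial_decline": initial_decline,
        "t_min": float(t[imin]),
        "n_interior_maxima": len(interior_maxima),
        "t_peak": t_peak,
        "I_peak": I_peak,
        "post_peak_log_slope": post_slope,
        "faster_than_luciferase_decay": post_slope is not None and post_slope < -kdL,
    }


def lum_peak(traj: Trajectory) -> tuple[float, float]:
    """Time and height of the luminescence maximum (earliest on ties)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmax(traj.intensity))
    return float(traj.times[i]), float(traj.intensity[i])
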