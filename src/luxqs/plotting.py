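"""Static diagnostic panels (matplotlib).

Small helpers for the three standard views of the switch and the culture:
the LuxR rate law at several autoinducer levels, the stationary branches
R(A) with stability, and a full batch-culture trajectory with its
luminescence signal.
"""

from __future__ import annotations

import numpy as np

from .core import QSParams, Trajectory, as_reduced
from .qs import luxr_rate, stationary_branches


def plot_luxr_rate_curves(qs: QSParams, A_values, ax=None):
    """dR/dt versus R for a set of autoinducer levels (phase-line view)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rp = as_reduced(qs)
    R = np.linspace(0.0, (rp.alpha + rp.beta) * 1.05, 400)
    for A in A_values:
        ax.plot(R, [luxr_rate(r, A, qs) for r in R], label=f"A = {A:g}")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("LuxR concentration R")
    ax.set_ylabel("dR/dt")
    ax.legend(fontsize="small")
    return ax


def plot_stationary_branches(qs: QSParams, A_grid, ax=None):
    """Stationary LuxR levels versus autoinducer, stable branches as filled
    markers and unstable ones as open markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for A, states in zip(A_grid, stationary_branches(qs, A_grid)):
        for s in states:
            if s.is_stable:
                ax.plot(A, s.value, "o", color="tab:red", ms=3)
            else:
                ax.plot(A, s.value, "o", mfc="none", color="k", ms=3)
    ax.set_xlabel("autoinducer concentration A")
    ax.set_ylabel("stationary LuxR concentration")
    return ax


def plot_trajectory(traj: Trajectory, axes=None):
    """Biomass, ATP and luminescence panels of one simulation."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(3, 1, sharex=True, figsize=(6, 7))
    axes[0].plot(traj.times, traj.N)
    axes[0].set_ylabel("biomass N")
    axes[0].set_yscale("log")
    axes[1].plot(traj.times, traj.a)
    axes[1].set_ylabel("ATP a")
    axes[2].plot(traj.times, np.maximum(traj.intensity, 1e-12))
    axes[2].set_ylabel("luminescence I")
    axes[2].set_yscale("log")
    axes[2].set_xlabel("time (h)")
    return axes
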