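# luxqs

Quorum-sensing (QS) and luminescence dynamics of luminescent bacteria in
batch culture: a four-block ODE model — ecology, ATP metabolism, a
LuxR/autoinducer switch, and a luminescence block — together with its
stationary-state/bistability analyses, a two-stage Nelder–Mead fitting
pipeline, and a synthetic-data harness for parameter-recovery experiments.

The package is for systems-biology modelers and microbiologists who want to
analyze (or emulate) OD660/luminescence time series of batch cultures of
luminescent bacteria such as *Photobacterium phosphoreum*, where the glow
is switched on by quorum sensing and switched off by the collapse of energy
metabolism at substrate exhaustion.

## The model

Six variables — substrate S, biomass N, intracellular ATP a, autoinducer A,
LuxR R, luciferase L — with observed luminescence I = V_L·L·a/(K_L+a):

    dS/dt      = −ε₀·N·(f_E + k₀·f_g)
    dN/dt      = f_g·N                       f_g = V_g·S/(K_g+S)·a/(K_a+a)
    ε₁·da/dt   = f_E − k₀·f_g − k_d·a/(ε₂+a)
    dA/dt      = C_A·N
    ε₃·dR/dt   = C_R + V_R·a/(a₀+a)·D/(K_R+D) − k₃·R
    ε₄·dL/dt   = a/(K_L+a)·D/(K_R+D) − k_dL·L

where D = (R·A)²/γ is the quasi-steady-state dimer of the (LuxR–AHL)
complex. ATP is the fast variable (ε₁ = 0.001): it rides the stable root of
its own one-dimensional rate law, which — depending on parameters — is
either bistable (stable zero / threshold / stable high-energy state) or
homeostatic (one stable positive state at every substrate level). The
reduced LuxR equation has the exact stationary curve

    A(R) = sqrt( σ·(R−α) / (α+β−R) ) / R ,   α = C_R/k₃,  β = V_R/k₃,  σ = K_Rγ

whose folds are the ignition and release thresholds of a hysteretic switch.
See `docs/methods.md` for assumptions, parameter meanings and numerical
choices.

## Worked example

Simulate the rich-medium preset and read off the QS diagnostics:

```python
from luxqs import reference_params
from luxqs.dynamics import (DEFAULT_CONFIG, default_initial_state,
                            lum_signature, qs_onset_time, simulate)
from luxqs.synth import apply_scenario, make_scenario

scenario = make_scenario("rich")
p = apply_scenario(reference_params(), scenario)
traj = simulate(p, DEFAULT_CONFIG, init=default_initial_state(p, scenario),
                t_grid=scenario.t_grid)
sig = lum_signature(traj, scenario.kdL)
print("QS onset [h]:", qs_onset_time(traj, p.qs))
print("lum peak [h], intensity:", sig["t_peak"], round(sig["I_peak"]))
print("post-peak log-slope [1/h] vs -kdL:",
      round(sig["post_peak_log_slope"], 2), -scenario.kdL)
```

prints

```
QS onset [h]: 11.0
lum peak [h], intensity: 11.5 15615
post-peak log-slope [1/h] vs -kdL: -9.15 -0.3
```

i.e. the receptor crosses the half-induction level at 11 h, luminescence
peaks half an hour later, and then collapses thirty times faster than
luciferase inactivation alone — the collapse is the ATP crash at substrate
exhaustion, not enzyme decay. The poor-medium preset
(`make_scenario("poor")`) ignites two hours earlier (onset 9.0 h).

The same steps are scripted as a narrative pipeline under `analysis/`
(`01_energy_regimes.py`, `02_qs_switch.py`, `03_batch_dynamics.py`,
`04_parameter_recovery.py`), each writing its tables under `results/`, and
as a CLI:

```sh
luxqs --out-dir results simulate --scenario rich
luxqs --out-dir results analyze-qs
luxqs --out-dir results synth --scenario poor --seed 1
luxqs --out-dir results fit --data results/synth_poor_clean.csv --scenario poor
```

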