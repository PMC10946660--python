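"""ATP block: rate laws, stationary states and their brute-force oracle."""

import numpy as np
import pytest

from luxqs.core import EnergyParams, GrowthParams
from luxqs.energy import (
    EnergyRateConfig,
    atp_rate,
    atpase,
    bistable_demo,
    death_rate,
    fE,
    fg,
    monostable_demo,
    regime_scan,
    stationary_states,
)

CFG1 = EnergyRateConfig(include_growth_cost=False, activation_exponent=1)


def _growth(Vg=2.18, Kg=3.99, Ka=0.0033):
    return GrowthParams(Vg=Vg, Kg=Kg, Ka=Ka)


def _energy(Ve=3.30, Ke=4.02, Kae=0.008, kd=0.0315, eps2=1.54, k0=0.082, a0=1.40):
    return EnergyParams(Ve=Ve, Ke=Ke, Kae=Kae, kd=kd, eps2=eps2, k0=k0, a0=a0)


class TestRateFunctions:
    def test_growth_needs_both_substrate_and_atp(self):
        g = _growth()
        assert fg(0.0, 2.0, g) == 0.0
        assert fg(5.0, 0.0, g) == 0.0

    def test_growth_half_saturation_product(self):
        g = _growth(Vg=2.18)
        assert fg(g.Kg, g.Ka, g) == pytest.approx(2.18 * 0.25, rel=1e-12)

    def test_production_vanishes_without_atp(self):
        p = _energy()
        for cfg in (CFG1, EnergyRateConfig(include_growth_cost=False, activation_exponent=2)):
            for S in (0.0, 1.0, 100.0):
                assert fE(S, 0.0, p, cfg) == 0.0

    def test_production_saturates_at_ve(self):
        p = _energy(Ve=3.30)
        assert fE(1e9, 1e6, p, CFG1) == pytest.approx(3.30, rel=1e-3)

    def test_production_half_saturation_product(self):
        p = _energy(Ve=3.30)
        cfg2 = EnergyRateConfig(include_growth_cost=False, activation_exponent=2)
        assert fE(p.Ke, p.Kae, p, CFG1) == pytest.approx(3.30 * 0.25, rel=1e-12)
        assert fE(p.Ke, np.sqrt(p.Kae), p, cfg2) == pytest.approx(3.30 * 0.25, rel=1e-12)

    def test_product_inhibition_halves_at_a0(self):
        p = _energy(a0=1.4)
        cfg = EnergyRateConfig(include_growth_cost=False, activation_exponent=1,
                               atp_product_inhibition=True)
        assert fE(p.Ke, p.a0, p, cfg) == pytest.approx(0.5 * fE(p.Ke, p.a0, p, CFG1))

    def test_atpase(self):
        p = _energy(kd=0.5, eps2=0.05)
        assert atpase(0.0, p) == 0.0
        assert atpase(p.eps2, p) == pytest.approx(0.25)
        assert atpase(10 * p.eps2, p) == pytest.approx(0.5 * 10 / 11, rel=1e-12)
        # near-constancy at eps2 << a: within eps2/a of kd
        a = 100 * p.eps2
        assert abs(atpase(a, p) - p.kd) / p.kd <= p.eps2 / a + 1e-12

    def test_death_rate_contract(self):
        a = np.linspace(0, 10, 50)
        d = death_rate(a, d0=0.05, K_d0=0.5)
        assert np.all(np.diff(d) <= 0)
        assert death_rate(1e9) == pytest.approx(0.0, abs=1e-9)
        assert death_rate(0.5, d0=0.05, K_d0=0.5) == pytest.approx(0.025)
        with pytest.raises(ValueError):
            death_rate(-1.0)


class TestAtpRate:
    def test_zero_atp_is_always_a_fixed_point(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            Ve, Ke, Kae, kd, eps2, k0, a0, Vg, Kg, Ka = 10.0 ** rng.uniform(-1, 1, 10)
            p = _energy(Ve, Ke, Kae, kd, eps2, k0, a0)
            g = _growth(Vg, Kg, Ka)
            for cfg in (
                CFG1,
                EnergyRateConfig(include_growth_cost=True, activation_exponent=2),
                EnergyRateConfig(True, 1, True),
            ):
                for S in (0.0, 0.3, 5.0):
                    assert atp_rate(S, 0.0, p, g, cfg) == 0.0

    def test_monostable_caption_regime_has_unstable_zero(self):
        # reported monostable-regime constants: production outruns
        # consumption at small ATP, so the zero state repels
        p = EnergyParams(Ve=3.299, Ke=4.0, Kae=0.008, kd=0.026, eps2=0.85, k0=0.082, a0=1.0)
        g = GrowthParams(Vg=2.18, Kg=4.0, Ka=0.004)
        cfg = EnergyRateConfig(include_growth_cost=True, activation_exponent=1)
        for S in (0.5, 1.0, 4.0):
            assert atp_rate(S, 1e-4, p, g, cfg) > 0

    def test_rate_negative_at_large_atp_when_production_capped(self):
        # Ve*sat(S,Ke) < kd + k0*Vg*sat(S,Kg) forces a negative tail
        p = _energy(Ve=0.5, Ke=1.0, kd=0.4, k0=1.0)
        g = _growth(Vg=0.5, Kg=1.0)
        cfg = EnergyRateConfig(include_growth_cost=True, activation_exponent=1)
        S = 1.0
        assert 0.5 * 0.5 < 0.4 + 1.0 * 0.5 * 0.5  # limit inequality
        assert atp_rate(S, 1e4, p, g, cfg) < 0


def _brute_force_states(S, p, g, cfg, a_max, n_fine):
    """Independent oracle: dense sign scan at n_fine resolution."""
    grid = np.linspace(0.0, a_max, n_fine + 1)
    vals = atp_rate(S, grid, p, g, cfg)
    roots = [0.0]
    for i in range(1, n_fine):
        if vals[i] * vals[i + 1] < 0:
            roots.append(0.5 * (grid[i] + grid[i + 1]))
        elif vals[i] == 0.0:
            roots.append(grid[i])
    labels = []
    h = a_max / n_fine
    for r in roots:
        above = atp_rate(S, r + h, p, g, cfg)
        if r - h < 0:
            labels.append("stable" if above < 0 else "unstable")
        else:
            below = atp_rate(S, r - h, p, g, cfg)
            labels.append("stable" if (below > 0 and above < 0) else "unstable")
    return list(zip(roots, labels))


class TestStationaryStates:
    def test_zero_always_included(self):
        d = monostable_demo()
        states = stationary_states(1.0, d.params, d.growth, d.config)
        assert states[0].value == 0.0

    def test_agrees_with_dense_scan_oracle_on_random_draws(self):
        rng = np.random.default_rng(12345)
        mismatches = 0
        for _ in range(50):
            Ve, Ke, Kae, kd, eps2, k0, a0, Vg, Kg, Ka = 10.0 ** rng.uniform(-1, 1, 10)
            p = _energy(Ve, Ke, Kae, kd, eps2, k0, a0)
            g = _growth(Vg, Kg, Ka)
            cfg = EnergyRateConfig(
                include_growth_cost=bool(rng.integers(2)),
                activation_exponent=int(rng.integers(1, 3)),
            )
            S = float(10.0 ** rng.uniform(-1, 1))
            a_max = 4.0 * max(1.0, a0)
            got = stationary_states(S, p, g, cfg, a_max=a_max)
            want = _brute_force_states(S, p, g, cfg, a_max, 20000)
            if len(got) != len(want) or any(
                s.stability != lab for s, (_, lab) in zip(got, want)
            ):
                mismatches += 1
        assert mismatches == 0

    def test_rate_sign_constant_between_roots(self):
        d = bistable_demo()
        S = 0.30
        states = stationary_states(S, d.params, d.growth, d.config, a_max=d.a_max)
        roots = [s.value for s in states] + [d.a_max]
        for lo, hi in zip(roots[:-1], roots[1:]):
            a = np.linspace(lo + 1e-4, hi - 1e-4, 200)
            vals = atp_rate(S, a, d.params, d.growth, d.config)
            assert np.all(vals > 0) or np.all(vals < 0)

    def test_stability_alternates_along_root_sequence(self):
        d = bistable_demo()
        states = stationary_states(0.30, d.params, d.growth, d.config, a_max=d.a_max)
        labels = [s.stability for s in states]
        assert labels == ["stable", "unstable", "stable"]

    def test_closed_form_quadratic_limit(self):
        # with cost off and n=1, clearing denominators gives
        # a * [(Ve sS - kd) a - (kd Kae - Ve sS eps2)] = 0: besides a = 0 the
        # fixed points solve a closed-form linear equation
        p = _energy(Ve=1.0, Ke=1.0, Kae=0.05, kd=0.6, eps2=2.0, k0=1.0, a0=1.0)
        S = 1.0
        sS = S / (p.Ke + S)
        analytic = (p.kd * p.Kae - p.Ve * sS * p.eps2) / (p.Ve * sS - p.kd)
        assert analytic > 0
        states = stationary_states(S, p, _growth(), CFG1, a_max=20.0)
        positive = [s.value for s in states if s.value > 0]
        assert len(positive) == 1
        assert positive[0] == pytest.approx(analytic, abs=1e-8)

    def test_domain_errors(self):
        d = monostable_demo()
        with pytest.raises(ValueError):
            stationary_states(1.0, d.params, d.growth, d.config, a_max=-1.0)
        with pytest.raises(ValueError):
            stationary_states(1.0, d.params, d.growth, d.config, n_grid=10)


class TestRegimeScan:
    def test_no_substrate_leaves_only_the_zero_state(self):
        d = monostable_demo()
        report = regime_scan(d.params, d.growth, d.config, [0.0], a_max=d.a_max)
        assert report["per_S"][0]["n_roots"] == 1
        assert report["per_S"][0]["roots"][0][0] == 0.0

    def test_empty_grid_rejected(self):
        d = monostable_demo()
        with pytest.raises(ValueError):
            regime_scan(d.params, d.growth, d.config, [])

    def test_report_is_json_serializable(self):
        import json

        d = bistable_demo()
        report = regime_scan(d.params, d.growth, d.config, d.S_grid, a_max=d.a_max)
        assert json.loads(json.dumps(report))["summary"]["max_root_count"] == 3
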