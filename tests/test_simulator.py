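"""Unit and oracle tests for the agent/macro simulator."""

from dataclasses import replace

import numpy as np
import pytest

import segresim as sg
from segresim.simulator import MAX_EVENT_PROB, _rebalance


def params(**kw):
    defaults = dict(mu_max=0.6, Ks=0.05, yield_=0.4)
    defaults.update(kw)
    return sg.KineticParams(**defaults)


# ---------------------------------------------------------------------------
# Monod kinetics and growth rates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "S, expected",
    [(0.0, 0.0), (0.05, 0.3), (5.0, 0.594059405940594)],
)
def test_monod_rate_closed_form(S, expected):
    p = params(mu_max=0.6, Ks=0.05)
    assert sg.monod_rate(S, p) == pytest.approx(expected, rel=1e-12)


def test_monod_rate_monotone_and_bounded():
    p = params(mu_max=0.6, Ks=0.05)
    S = np.linspace(0, 50, 200)
    mu = sg.monod_rate(S, p)
    assert np.all(np.diff(mu) >= 0)
    assert np.all(mu <= p.mu_max)


def test_monod_rate_rejects_negative_substrate():
    with pytest.raises(ValueError):
        sg.monod_rate(-0.1, params())


def test_cell_growth_rate_cost_applies_only_when_on():
    p = params(cost=0.5)
    env = sg.EnvironmentState(S=0.05, S_in=5.0)  # mu = 0.3
    off = sg.Cell(phenotype=0)
    on = sg.Cell(phenotype=1)
    assert sg.cell_growth_rate(off, env, p) == pytest.approx(0.3)
    assert sg.cell_growth_rate(on, env, p) == pytest.approx(0.15)
    assert sg.cell_growth_rate(on, env, replace(p, cost=1.0)) == 0.0


def test_cost_monotonicity_for_on_cells():
    env = sg.EnvironmentState(S=1.0, S_in=5.0)
    on = sg.Cell(phenotype=1, gfp=5e4)
    for form in ("linear", "inhibitory"):
        rates = [
            sg.cell_growth_rate(on, env, params(cost=c, cost_form=form))
            for c in np.linspace(0, 1, 11)
        ]
        assert np.all(np.diff(rates) <= 1e-12)


def test_inhibitory_cost_interpolates_with_gfp_load():
    p = params(cost=0.9, cost_form="inhibitory", K_i=1e4)
    env = sg.EnvironmentState(S=5.0, S_in=5.0)
    mu = sg.monod_rate(5.0, p)
    light = sg.cell_growth_rate(sg.Cell(phenotype=1, gfp=0.0), env, p)
    half = sg.cell_growth_rate(sg.Cell(phenotype=1, gfp=1e4), env, p)
    heavy = sg.cell_growth_rate(sg.Cell(phenotype=1, gfp=1e9), env, p)
    assert light == pytest.approx(mu)  # no load, no burden
    assert half == pytest.approx(mu * np.sqrt(0.1))
    assert heavy == pytest.approx(mu * 0.1, rel=1e-3)


# ---------------------------------------------------------------------------
# Switching propensities
# ---------------------------------------------------------------------------


def test_switch_propensities_inducer_and_starvation():
    cell = sg.Cell()
    p_ind = params(k_on_max=4.0, K_on=0.05, k_off=0.7, switch_signal="inducer")
    assert sg.switch_propensities(cell, sg.EnvironmentState(I=0.0), p_ind) == (0.0, 0.7)
    k_on, _ = sg.switch_propensities(cell, sg.EnvironmentState(I=0.05), p_ind)
    assert k_on == pytest.approx(2.0)  # half-saturation

    p_starve = params(k_on_max=4.0, K_on=0.05, switch_signal="starvation")
    k_on, _ = sg.switch_propensities(cell, sg.EnvironmentState(S=0.05), p_starve)
    assert k_on == pytest.approx(2.0)
    k_on_fed, _ = sg.switch_propensities(cell, sg.EnvironmentState(S=1e6), p_starve)
    assert k_on_fed < 1e-4  # glucose excess represses the response


# ---------------------------------------------------------------------------
# Division
# ---------------------------------------------------------------------------


def test_divide_cell_conserves_gfp_and_halves_size(rng):
    mother = sg.Cell(phenotype=1, gfp=1234.5, size=2.0)
    a, b = sg.divide_cell(mother, rng)
    assert a.gfp + b.gfp == pytest.approx(1234.5, rel=1e-12)
    assert a.size == b.size == 1.0
    assert a.phenotype == b.phenotype == 1
    z1, z2 = sg.divide_cell(sg.Cell(gfp=0.0, size=2.0), rng)
    assert z1.gfp == z2.gfp == 0.0


def test_divide_cell_requires_division_size(rng):
    with pytest.raises(ValueError):
        sg.divide_cell(sg.Cell(size=1.5), rng)


def test_partition_moments_match_binomial_like_half(rng):
    """Daughter-A share over many divisions is centred on g/2."""
    g = 1e6
    draws = np.array(
        [sg.divide_cell(sg.Cell(gfp=g, size=2.0), rng)[0].gfp for _ in range(10_000)]
    )
    sd = draws.std(ddof=1)
    se = sd / np.sqrt(len(draws))
    assert abs(draws.mean() - g / 2) < 3 * se
    # Beta(50,50) partition: sd of the fraction is ~0.0497
    assert sd / g == pytest.approx(0.0497, rel=0.1)


# ---------------------------------------------------------------------------
# Population stepping
# ---------------------------------------------------------------------------


def test_step_population_no_dynamics_is_identity():
    p = params(mu_max=1e-9, k_on_max=0.0, k_off=0.0, q_gfp=0.0)
    pop = sg.AgentPopulation.initial(200, seed=1)
    pop.gfp[:] = 7.0
    before = (pop.phenotype.copy(), pop.gfp.copy(), pop.size.copy())
    mu_bar = sg.step_population(pop, sg.EnvironmentState(S=0.0, D=0.0), p, dt=0.1)
    assert mu_bar == 0.0
    assert np.array_equal(pop.phenotype, before[0])
    assert np.allclose(pop.gfp, before[1])
    assert np.allclose(pop.size, before[2])


def test_step_population_division_threshold():
    """Cells crossing size 2 divide into two daughters of half size."""
    p = params(mu_max=1.0, Ks=1e-12)
    rng = np.random.default_rng(2)
    pop = sg.AgentPopulation(
        np.zeros(100, bool), np.zeros(100), np.full(100, 1.995),
        n_target=200, rng=rng,
    )
    sg.step_population(pop, sg.EnvironmentState(S=1e6, D=0.0), p, dt=0.01)
    assert len(pop) == 200  # every cell divided exactly once
    assert pop.size.min() >= 1.0 and pop.size.max() < 2.0


def test_step_population_empty_ensemble_signals_extinction():
    pop = sg.AgentPopulation(
        np.zeros(0, bool), np.zeros(0), np.zeros(0), n_target=10,
        rng=np.random.default_rng(0),
    )
    with pytest.raises(sg.ExtinctionError):
        sg.step_population(pop, sg.EnvironmentState(S=1.0), params(), 0.01)


def test_step_population_rejects_oversized_dt():
    p = params(mu_max=5.0)
    pop = sg.AgentPopulation.initial(10, seed=0)
    with pytest.raises(ValueError):
        sg.step_population(pop, sg.EnvironmentState(S=1e6), p, dt=0.1)


def test_gfp_never_negative_under_strong_degradation():
    p = params(mu_max=0.1, d_gfp=1.5, q_gfp=0.0)
    pop = sg.AgentPopulation.initial(100, seed=3)
    pop.gfp[:] = 1.0
    for _ in range(200):
        sg.step_population(pop, sg.EnvironmentState(S=0.01), p, dt=0.1)
    assert np.all(pop.gfp >= 0)


def test_rebalance_bounds_ensemble_size():
    rng = np.random.default_rng(4)
    pop = sg.AgentPopulation(
        np.zeros(450, bool), np.zeros(450), np.ones(450), n_target=100, rng=rng
    )
    _rebalance(pop)
    assert len(pop) == 100
    small = sg.AgentPopulation(
        np.ones(30, bool), np.full(30, 2.0), np.ones(30), n_target=100, rng=rng
    )
    _rebalance(small)
    assert len(small) == 60  # duplication preserves composition
    assert small.phenotype.all() and np.all(small.gfp == 2.0)


def test_markov_equilibrium_on_fraction():
    """Stationary ON fraction equals k_on/(k_on+k_off) without growth or
    dilution (two-state Markov chain oracle)."""
    p = params(
        mu_max=1e-9, k_on_max=2.0, K_on=0.05, k_off=1.0,
        switch_signal="inducer",
    )
    env = sg.EnvironmentState(S=0.0, I=1e9, D=0.0)  # k_on ~ 2.0
    pop = sg.AgentPopulation.initial(10_000, seed=5)
    for _ in range(150):  # 15 time units >> 1/(k_on+k_off)
        sg.step_population(pop, env, p, dt=0.09)
    expect = 2.0 / 3.0
    se = np.sqrt(expect * (1 - expect) / len(pop))
    assert abs(pop.on_fraction - expect) < 3 * se + 0.005


def test_washout_survival_matches_exponential_decay():
    """With frozen propensities and no growth, cells are removed at rate D;
    survival after time T follows exp(-D*T)."""
    p = params(mu_max=1e-9, k_on_max=0.0, k_off=0.0)
    D, T, dt = 0.5, 0.6, 0.01
    pop = sg.AgentPopulation.initial(10_000, seed=6)
    pop.phenotype[:] = True
    env = sg.EnvironmentState(S=0.0, D=D)
    for _ in range(int(T / dt)):
        sg.step_population(pop, env, p, dt=dt)
    expect = np.exp(-D * T)  # ~0.74, above the duplication threshold
    frac = len(pop) / 10_000
    se = np.sqrt(expect * (1 - expect) / 10_000)
    assert abs(frac - expect) < 3 * se


# ---------------------------------------------------------------------------
# Environment ODEs
# ---------------------------------------------------------------------------


def test_chemostat_balance_keeps_biomass_constant():
    env = sg.EnvironmentState(S=0.05, D=0.3, S_in=5.0, X=2.0)
    out = sg.step_environment(env, mu_bar=0.3, dt=0.01)
    assert out.X == pytest.approx(2.0)


def test_substrate_relaxes_to_feed_without_biomass():
    """X = 0: S(t) = S_in + (S0 - S_in) exp(-D t), checked against the
    closed-form linear ODE solution."""
    D, S0, S_in, T = 0.2, 1.0, 5.0, 0.5
    dt = 1e-5
    env = sg.EnvironmentState(S=S0, D=D, S_in=S_in, X=0.0)
    for _ in range(int(T / dt)):
        env = sg.step_environment(env, mu_bar=0.0, dt=dt)
    expect = S_in + (S0 - S_in) * np.exp(-D * T)
    assert env.S == pytest.approx(expect, rel=1e-5)


def test_pulse_is_instantaneous_bolus():
    env = sg.EnvironmentState(S=0.0, I=0.0, D=0.0, S_in=5.0)
    out = sg.step_environment(
        env, mu_bar=0.0, dt=1e-9, pulses=(sg.Pulse("inducer", 0.5),)
    )
    assert out.I == pytest.approx(0.5)
    out2 = sg.step_environment(
        env, mu_bar=0.0, dt=1e-9, pulses=(sg.Pulse("glucose", 0.3),)
    )
    assert out2.S == pytest.approx(0.3)


def test_concentrations_clip_at_zero():
    env = sg.EnvironmentState(S=0.001, D=0.0, S_in=0.0, X=10.0)
    out = sg.step_environment(env, mu_bar=1.0, dt=0.1)
    assert out.S == 0.0


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def test_measure_degenerate_no_noise(rng):
    pop = sg.AgentPopulation.initial(50, seed=7)
    snap = sg.measure(pop, n_events=1_000, noise_cv=0.0, background=100.0)
    assert np.all(snap.values == 100.0)


def test_measure_event_count_and_clamp():
    pop = sg.AgentPopulation.initial(50, seed=8)
    pop.gfp[:] = 1e12  # beyond the instrument range
    snap = sg.measure(pop, n_events=20_000, noise_cv=0.25)
    assert len(snap) == 20_000
    assert snap.values.min() >= 1.0 and snap.values.max() <= 1e7


def test_measure_empty_ensemble_raises():
    pop = sg.AgentPopulation(
        np.zeros(0, bool), np.zeros(0), np.zeros(0), 10, np.random.default_rng(0)
    )
    with pytest.raises(sg.ExtinctionError):
        sg.measure(pop)


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "bad",
    [
        dict(mu_max=0.0),
        dict(Ks=-1.0),
        dict(cost=1.5),
        dict(k_off=-0.1),
        dict(switch_signal="voltage"),
        dict(cost_form="quadratic"),
    ],
)
def test_kinetic_params_validation(bad):
    with pytest.raises(ValueError):
        params(**bad)


def test_environment_state_validation():
    with pytest.raises(ValueError):
        sg.EnvironmentState(S=-0.1)


def test_choose_dt_respects_event_probability_cap():
    p = params(mu_max=0.6, k_on_max=16.0, k_off=0.8, d_gfp=0.1)
    dt = sg.choose_dt(p, D_max=0.5, sampling_interval_h=0.2)
    fastest = max(p.mu_max, p.k_on_max, p.k_off, 0.5, p.d_gfp + p.mu_max)
    assert dt * fastest < MAX_EVENT_PROB
    assert (0.2 / dt) == pytest.approx(round(0.2 / dt))
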