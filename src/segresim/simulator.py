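"""Hybrid macro/agent stochastic simulator of phenotypic switching in continuous culture.

The population is represented at two coupled levels:

* a **macroscopic** chemostat state (biomass ``X``, limiting substrate ``S``,
  inducer ``I``) integrated as ODEs with Monod growth kinetics, and
* an **agent ensemble** of ~10,000 tracked cells, each carrying a binary
  phenotype (OFF/ON), a continuous GFP content and a relative size, driven by
  a two-state Markov switching process, GFP synthesis/degradation/dilution,
  growth, division and washout.

Coupling is one-way: the ensemble's number-weighted mean growth rate feeds the
macroscopic biomass ODE, while the macroscopic substrate/inducer state sets the
per-cell growth and switching propensities.  Cells in the ON state pay a
fitness cost ``c`` — a fractional reduction of their Monod growth rate — which
is the single knob that moves the population across the diversification
regimes (constrained, dispersed, bursty, washout).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "EnvironmentState",
    "Cell",
    "AgentPopulation",
    "Snapshot",
    "Pulse",
    "ExtinctionError",
    "monod_rate",
    "cell_growth_rate",
    "switch_propensities",
    "step_population",
    "divide_cell",
    "step_environment",
    "measure",
    "choose_dt",
]

#: Maximum allowed per-event probability rate*dt in one explicit step.
MAX_EVENT_PROB = 0.2

#: Seven-decade instrument range for fluorescence values.
FLUO_MIN = 1.0
FLUO_MAX = 1.0e7

#: Fraction of the initial macroscopic biomass below which the culture is
#: declared washed out.
EXTINCTION_BIOMASS_FRACTION = 1.0e-4


class ExtinctionError(RuntimeError):
    """Raised when an operation requires a non-empty cell ensemble."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set for one reporter system.

    Parameters
    ----------
    mu_max
        Maximal specific growth rate (1/h).
    Ks
        Monod half-saturation constant for glucose (g/L).
    yield_
        Biomass yield on substrate (g biomass / g substrate).
    k_on_max
        Maximal OFF->ON switching propensity (1/h).
    K_on
        Half-saturation of the switching signal (g/L).
    k_off
        ON->OFF switching propensity (1/h), constant.
    q_gfp
        GFP synthesis rate in the ON state (fluorescence units/h per cell).
    d_gfp
        First-order GFP degradation rate (1/h); growth dilution is added on
        top of this.
    cost
        Fitness cost c in [0, 1]: fractional growth-rate reduction in the ON
        state.
    cost_form
        ``"linear"`` (default) — every ON cell grows at (1 - cost) times the
        Monod rate.  ``"inhibitory"`` — the reduction follows an inhibitory
        kinetics in the cell's GFP content,
        mu_on = mu * (1 - cost)**(gfp/(gfp + K_i)):
        the burden compounds multiplicatively with the GFP load, so freshly
        switched cells still grow near the uninduced rate while
        burden-saturated cells (gfp >> K_i) are reduced by the full cost.
    K_i
        Half-inhibition GFP content for the inhibitory cost form
        (fluorescence units).
    switch_signal
        ``"inducer"`` — OFF->ON propensity saturates in the inducer
        concentration I (carbon-utilization and T7 systems);
        ``"starvation"`` — propensity is released by glucose limitation
        (stress/sporulation systems), k_on = k_on_max*K_on/(K_on+S).
    inducer_uptake
        Specific inducer consumption rate of ON biomass at saturation
        (g inducer / g biomass / h); only active in inducer mode.
    partition_conc
        Concentration (a = b) of the symmetric Beta law used to partition
        GFP between daughters at division.  The default a = b = 50 gives a
        standard deviation of ~0.05 around the even split, comparable to
        binomial partitioning of ~100 independent units.
    """

    mu_max: float
    Ks: float
    yield_: float = 0.4
    k_on_max: float = 0.0
    K_on: float = 0.05
    k_off: float = 0.0
    q_gfp: float = 0.0
    d_gfp: float = 0.0
    cost: float = 0.0
    switch_signal: Literal["inducer", "starvation"] = "inducer"
    inducer_uptake: float = 0.0
    partition_conc: float = 50.0
    cost_form: Literal["linear", "inhibitory"] = "linear"
    K_i: float = 1.0e4

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not self.Ks > 0:
            raise ValueError(f"Ks must be > 0, got {self.Ks}")
        if not self.yield_ > 0:
            raise ValueError(f"yield_ must be > 0, got {self.yield_}")
        if not 0.0 <= self.cost <= 1.0:
            raise ValueError(f"cost must lie in [0, 1], got {self.cost}")
        for name in ("k_on_max", "k_off", "d_gfp", "q_gfp", "inducer_uptake"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.switch_signal not in ("inducer", "starvation"):
            raise ValueError(f"unknown switch_signal {self.switch_signal!r}")
        if self.cost_form not in ("linear", "inhibitory"):
            raise ValueError(f"unknown cost_form {self.cost_form!r}")
        if not self.K_i > 0:
            raise ValueError("K_i must be > 0")
        if not self.K_on > 0:
            raise ValueError(f"K_on must be > 0, got {self.K_on}")
        if not self.partition_conc > 0:
            raise ValueError("partition_conc must be > 0")


@dataclass
class EnvironmentState:
    """Macroscopic chemostat state.

    ``S`` is the limiting substrate (glucose), ``I`` a secondary
    nutrient/inducer (arabinose, lactose, ...).  ``S_in``/``I_in`` are the
    feed concentrations; ``I_in`` is zero whenever the inducer is only pulsed.
    """

    t: float = 0.0  # h
    S: float = 0.0  # g/L
    I: float = 0.0  # g/L
    D: float = 0.0  # 1/h
    S_in: float = 5.0  # g/L
    X: float = 0.0  # g/L biomass
    I_in: float = 0.0  # g/L

    def __post_init__(self) -> None:
        for name in ("S", "I", "D", "X", "S_in", "I_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Cell:
    """A single tracked cell: binary phenotype, GFP content, relative size."""

    phenotype: int = 0  # 0 = OFF, 1 = ON
    gfp: float = 0.0
    size: float = 1.0

    def __post_init__(self) -> None:
        if self.gfp < 0:
            raise ValueError("gfp must be >= 0")
        if not 1.0 <= self.size:
            raise ValueError("size must be >= 1")


class AgentPopulation:
    """Stochastic ensemble of tracked cells, stored as parallel numpy arrays.

    The ensemble is kept within ``[0.5, 2] * n_target`` by constant-number
    resampling: uniform down-sampling to ``n_target`` when it doubles,
    whole-ensemble duplication when it halves.  Both operations preserve the
    composition of the population; absolute abundance lives in the
    macroscopic biomass, not in the agent count.
    """

    def __init__(
        self,
        phenotype: np.ndarray,
        gfp: np.ndarray,
        size: np.ndarray,
        n_target: int,
        rng: np.random.Generator,
    ) -> None:
        self.phenotype = np.asarray(phenotype, dtype=bool)
        self.gfp = np.asarray(gfp, dtype=float)
        self.size = np.asarray(size, dtype=float)
        self.n_target = int(n_target)
        self.rng = rng
        self._validate()

    def _validate(self) -> None:
        if not (len(self.phenotype) == len(self.gfp) == len(self.size)):
            raise ValueError("phenotype, gfp and size must have equal length")
        if np.any(self.gfp < 0):
            raise ValueError("gfp must be >= 0 for every cell")
        if len(self.size) and (self.size.min() < 1.0):
            raise ValueError("cell size must be >= 1")

    @classmethod
    def initial(
        cls, n_target: int = 10_000, seed: int | np.random.Generator = 0
    ) -> "AgentPopulation":
        """All-OFF founder ensemble with desynchronised cell sizes.

        Sizes are drawn uniformly on [1, 2) so the ensemble does not divide
        in lockstep.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        size = rng.uniform(1.0, 2.0, n_target)
        return cls(
            phenotype=np.zeros(n_target, dtype=bool),
            gfp=np.zeros(n_target),
            size=size,
            n_target=n_target,
            rng=rng,
        )

    def __len__(self) -> int:
        return len(self.phenotype)

    @property
    def on_fraction(self) -> float:
        if len(self) == 0:
            raise ExtinctionError("empty ensemble has no ON fraction")
        return float(self.phenotype.mean())

    def cells(self) -> Iterable[Cell]:
        """Iterate over the ensemble as :class:`Cell` objects (views by value)."""
        for p, g, s in zip(self.phenotype, self.gfp, self.size):
            yield Cell(phenotype=int(p), gfp=float(g), size=float(s))


@dataclass(frozen=True)
class Snapshot:
    """One flow-cytometry measurement: fluorescence per analysed event."""

    t: float  # h
    values: np.ndarray  # fluorescence, clamped to [1, 1e7]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Pulse:
    """A bolus addition into the vessel at the start of a step."""

    actuator: Literal["inducer", "glucose"]
    dose: float  # g/L added

    def __post_init__(self) -> None:
        if self.actuator not in ("inducer", "glucose"):
            raise ValueError(f"unknown actuator {self.actuator!r}")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def monod_rate(S: float | np.ndarray, params: KineticParams) -> float | np.ndarray:
    """Monod specific growth rate mu(S) = mu_max * S / (Ks + S), in 1/h."""
    if np.any(np.asarray(S) < 0):
        raise ValueError("substrate concentration S must be >= 0")
    return params.mu_max * S / (params.Ks + S)


def cell_growth_rate(
    cell: Cell, env: EnvironmentState, params: KineticParams
) -> float:
    """Specific growth rate of one cell; ON cells pay the fitness cost.

    OFF cells grow at the Monod rate.  ON cells grow at ``(1 - cost)``
    times it (linear form) or at ``1 - cost * gfp/(gfp + K_i)`` times it
    (inhibitory form).
    """
    rates = _growth_rates(
        np.array([bool(cell.phenotype)]), np.array([cell.gfp]), env.S, params
    )
    return float(rates[0])


def _growth_rates(
    phenotype: np.ndarray, gfp: np.ndarray, S: float, params: KineticParams
) -> np.ndarray:
    mu = float(monod_rate(S, params))
    if params.cost_form == "linear":
        factor = 1.0 - params.cost
    else:
        load = gfp / (gfp + params.K_i)
        factor = np.power(1.0 - params.cost, load) if params.cost < 1.0 else (
            np.where(load > 0, 0.0, 1.0)
        )
    return np.where(phenotype, mu * factor, mu)


def switch_propensities(
    cell: Cell, env: EnvironmentState, params: KineticParams
) -> tuple[float, float]:
    """(k_on, k_off) switching propensities given the environment.

    Inducer mode: k_on = k_on_max * I / (K_on + I) — induction saturates in
    the inducer.  Starvation mode: k_on = k_on_max * K_on / (K_on + S) —
    glucose represses the stress/sporulation response.  k_off is constant.
    """
    del cell  # propensities depend only on the environment in this model
    if params.switch_signal == "inducer":
        k_on = params.k_on_max * env.I / (params.K_on + env.I)
    else:
        k_on = params.k_on_max * params.K_on / (params.K_on + env.S)
    return float(k_on), float(params.k_off)


def choose_dt(
    params: KineticParams,
    D_max: float,
    sampling_interval_h: float,
    max_prob: float = MAX_EVENT_PROB,
) -> float:
    """Largest step (h) dividing the sampling interval with all event
    probabilities below ``max_prob``.

    The binding rates are the switching propensities, the growth rate, the
    dilution rate and the GFP relaxation rate d_gfp + mu.
    """
    fastest = max(
        params.mu_max,
        params.k_on_max,
        params.k_off,
        D_max,
        params.d_gfp + params.mu_max,
        1e-9,
    )
    dt_max = 0.95 * max_prob / fastest  # strict margin below the cap
    n_sub = max(1, int(np.ceil(sampling_interval_h / dt_max)))
    return sampling_interval_h / n_sub


# ---------------------------------------------------------------------------
# Agent dynamics
# ---------------------------------------------------------------------------


def divide_cell(cell: Cell, rng: np.random.Generator, partition_conc: float = 50.0) -> tuple[Cell, Cell]:
    """Split one cell of size >= 2 into two daughters.

    Each daughter receives half the size; the GFP content is partitioned by a
    symmetric Beta(a, a) fraction (mean 1/2), conserving the total exactly.
    Both daughters inherit the mother's phenotype.
    """
    if cell.size < 2.0:
        raise ValueError(f"cannot divide a cell of size {cell.size} < 2")
    f = float(rng.beta(partition_conc, partition_conc))
    g_a = cell.gfp * f
    g_b = cell.gfp - g_a
    half = cell.size / 2.0
    return (
        Cell(phenotype=cell.phenotype, gfp=g_a, size=half),
        Cell(phenotype=cell.phenotype, gfp=g_b, size=half),
    )


def step_population(
    pop: AgentPopulation,
    env: EnvironmentState,
    params: KineticParams,
    dt: float,
) -> float:
    """Advance every cell by one step of length ``dt`` (h), in place.

    Per cell and per step, using start-of-step propensities (tau-leap style):

    1. phenotype flips with probability 1 - exp(-k*dt);
    2. GFP gains q_gfp*dt if ON and loses (d_gfp + mu_i)*gfp*dt
       (degradation plus growth dilution), floored at 0;
    3. size grows as size*exp(mu_i*dt); cells reaching size 2 divide;
    4. the cell is washed out with probability 1 - exp(-D*dt).

    Returns the ensemble's number-weighted mean growth rate (1/h) computed
    before removal, for coupling into the macroscopic biomass ODE.

    Raises :class:`ExtinctionError` if the ensemble is empty on entry.
    """
    n = len(pop)
    if n == 0:
        raise ExtinctionError("cannot step an empty ensemble")

    k_on, k_off = switch_propensities(Cell(), env, params)
    mu = float(monod_rate(env.S, params))
    worst = max(k_on, k_off, mu, env.D, (params.d_gfp + mu)) * dt
    if worst >= MAX_EVENT_PROB:
        raise ValueError(
            f"dt={dt} too large: max per-step event probability {worst:.3f} "
            f">= {MAX_EVENT_PROB}"
        )

    rng = pop.rng
    on = pop.phenotype
    mu_i = _growth_rates(on, pop.gfp, env.S, params)
    mu_bar = float(mu_i.mean())

    # 1. switching (probabilities from start-of-step state)
    u = rng.random(n)
    p_flip = np.where(on, -np.expm1(-k_off * dt), -np.expm1(-k_on * dt))
    flip = u < p_flip
    new_on = np.logical_xor(on, flip)

    # 2. GFP synthesis, degradation and growth dilution (explicit Euler on
    #    the pre-flip state; rates per step are bounded by MAX_EVENT_PROB)
    gfp = pop.gfp
    gfp = gfp + (params.q_gfp * on - (params.d_gfp + mu_i) * gfp) * dt
    np.maximum(gfp, 0.0, out=gfp)

    # 3. growth and division
    size = pop.size * np.exp(mu_i * dt)
    dividing = size >= 2.0
    if np.any(dividing):
        idx = np.flatnonzero(dividing)
        f = rng.beta(params.partition_conc, params.partition_conc, len(idx))
        g_mother = gfp[idx]
        g_a = g_mother * f
        g_b = g_mother - g_a
        half = size[idx] / 2.0
        gfp[idx] = g_a
        size[idx] = half
        new_on = np.concatenate([new_on, new_on[idx]])
        gfp = np.concatenate([gfp, g_b])
        size = np.concatenate([size, half])

    # 4. washout
    if env.D > 0:
        keep = rng.random(len(gfp)) >= -np.expm1(-env.D * dt)
        new_on, gfp, size = new_on[keep], gfp[keep], size[keep]

    pop.phenotype, pop.gfp, pop.size = new_on, gfp, size
    _rebalance(pop)
    return mu_bar


def _rebalance(pop: AgentPopulation) -> None:
    """Constant-number resampling keeping the ensemble in [0.5, 2]*n_target."""
    n = len(pop)
    if n == 0:
        return
    if n > 2 * pop.n_target:
        keep = pop.rng.choice(n, size=pop.n_target, replace=False)
        pop.phenotype = pop.phenotype[keep]
        pop.gfp = pop.gfp[keep]
        pop.size = pop.size[keep]
    elif n < pop.n_target // 2:
        pop.phenotype = np.concatenate([pop.phenotype, pop.phenotype])
        pop.gfp = np.concatenate([pop.gfp, pop.gfp])
        pop.size = np.concatenate([pop.size, pop.size])


# ---------------------------------------------------------------------------
# Macroscopic environment
# ---------------------------------------------------------------------------


def step_environment(
    env: EnvironmentState,
    mu_bar: float,
    dt: float,
    pulses: Sequence[Pulse] = (),
    params: KineticParams | None = None,
    on_biomass: float = 0.0,
) -> EnvironmentState:
    """One explicit Euler step of the chemostat ODEs.

    dX/dt = (mu_bar - D) X
    dS/dt = D (S_in - S) - mu_bar X / yield
    dI/dt = D (I_in - I) - uptake(I) * X_on

    Pulses add their dose instantaneously at the start of the step.  Inducer
    uptake is Monod in I and proportional to the ON biomass ``on_biomass``
    (inducer mode only).  Concentrations are clipped at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    S, I = env.S, env.I
    for p in pulses:
        if p.actuator == "inducer":
            I += p.dose
        else:
            S += p.dose

    yield_ = params.yield_ if params is not None else 0.4
    uptake = 0.0
    if params is not None and params.switch_signal == "inducer" and params.inducer_uptake > 0:
        uptake = params.inducer_uptake * on_biomass * I / (params.K_on + I)

    X_new = env.X + (mu_bar - env.D) * env.X * dt
    S_new = S + (env.D * (env.S_in - S) - mu_bar * env.X / yield_) * dt
    I_new = I + (env.D * (env.I_in - I) - uptake) * dt
    return replace(
        env,
        t=env.t + dt,
        X=max(X_new, 0.0),
        S=max(S_new, 0.0),
        I=max(I_new, 0.0),
    )


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def measure(
    pop: AgentPopulation,
    n_events: int = 20_000,
    noise_cv: float = 0.25,
    rng: np.random.Generator | None = None,
    background: float = 100.0,
    t: float = 0.0,
) -> Snapshot:
    """Simulated flow-cytometry analysis of the ensemble.

    Samples ``n_events`` cells with replacement; each event's fluorescence is
    (gfp + autofluorescence background) times a multiplicative lognormal
    noise factor with coefficient of variation ``noise_cv`` and unit mean,
    clamped to the instrument's seven-decade range [1, 1e7].
    """
    if len(pop) == 0:
        raise ExtinctionError("cannot measure an empty ensemble")
    rng = pop.rng if rng is None else rng
    idx = rng.integers(0, len(pop), n_events)
    values = pop.gfp[idx] + background
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        values = values * rng.lognormal(-0.5 * sigma**2, sigma, n_events)
    np.clip(values, FLUO_MIN, FLUO_MAX, out=values)
    return Snapshot(t=t, values=values)
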