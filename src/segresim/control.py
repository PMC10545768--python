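"""Environment programs and the Segregostat feedback controller.

A run alternates simulation advances of one sampling interval (12 min by
default) with a measure -> gate -> decide -> pulse cycle: the ensemble is
"analysed" by simulated flow cytometry, gated into GFP-negative and
GFP-positive groups at a fluorescence threshold, and — in closed-loop modes —
a nutrient/inducer pulse is injected whenever the gated ON fraction violates
the setpoint.  Environment programs cover the constant-D chemostat, the
A-stat dilution ramp and the dMSCC square-wave glucose alternation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .simulator import (
    EXTINCTION_BIOMASS_FRACTION,
    AgentPopulation,
    EnvironmentState,
    ExtinctionError,
    KineticParams,
    Pulse,
    Snapshot,
    choose_dt,
    measure,
    step_environment,
    step_population,
)

__all__ = [
    "ControllerConfig",
    "EnvironmentProgram",
    "SimulationResult",
    "gate_fraction",
    "decide_pulse",
    "program_dilution",
    "program_substrate",
    "run_closed_loop",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Feedback-controller settings.

    ``maintain_on`` pulses the actuator when the gated ON fraction drops
    below the setpoint (inducer-driven systems, 50/50 threshold);
    ``suppress_on`` pulses when the ON fraction exceeds the setpoint
    (sporulation control, triggered above 20% switched cells);
    ``open_loop`` never pulses.
    """

    mode: Literal["open_loop", "maintain_on", "suppress_on"] = "open_loop"
    setpoint: float = 0.5
    gate_threshold: float = 1_000.0
    sampling_interval: float = 12.0  # minutes between FC analyses
    actuator: Literal["inducer", "glucose"] = "inducer"
    dose: float = 0.5  # g/L per pulse

    def __post_init__(self) -> None:
        if self.mode not in ("open_loop", "maintain_on", "suppress_on"):
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if not 0.0 < self.setpoint < 1.0:
            raise ValueError("setpoint must lie strictly in (0, 1)")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.mode != "open_loop" and self.dose <= 0:
            raise ValueError("dose must be > 0 for closed-loop modes")


@dataclass(frozen=True)
class EnvironmentProgram:
    """Time program of the cultivation environment.

    ``constant_D``: fixed dilution rate (chemostat / Segregostat vessel).
    ``astat``: accelerostat — D ramps by ``D_step`` every ``step_period``
    hours, D(t) = D0 + D_step*floor(t/step_period).
    ``square_wave``: dMSCC growth-chamber semantics — no washout (D = 0) and
    perfect media exchange forcing the glucose concentration to alternate
    between ``S_high`` (for ``dwell_high`` minutes) and ``S_low``
    (for ``dwell_low`` minutes).
    """

    kind: Literal["constant_D", "astat", "square_wave"] = "constant_D"
    D0: float = 0.2
    D_step: float = 0.002
    step_period: float = 2.0  # h
    S_high: float = 0.18  # g/L (1 mM glucose)
    S_low: float = 0.018  # g/L (0.1 mM glucose)
    dwell_high: float = 180.0  # min
    dwell_low: float = 48.0  # min

    def __post_init__(self) -> None:
        if self.kind not in ("constant_D", "astat", "square_wave"):
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.D0 < 0 or self.D_step < 0:
            raise ValueError("dilution rates must be >= 0")
        if self.kind == "astat" and self.step_period <= 0:
            raise ValueError("step_period must be > 0")
        if self.kind == "square_wave" and (self.dwell_high <= 0 or self.dwell_low <= 0):
            raise ValueError("dwell times must be > 0")


def gate_fraction(snapshot: Snapshot, gate_threshold: float) -> float:
    """Fraction of events strictly above the GFP-positive gate threshold."""
    if len(snapshot) == 0:
        raise ValueError("cannot gate an empty snapshot")
    return float(np.mean(snapshot.values > gate_threshold))


def decide_pulse(fraction: float, cfg: ControllerConfig) -> Optional[Pulse]:
    """Pulse decision from the gated ON fraction.

    ``maintain_on`` pulses iff fraction < setpoint; ``suppress_on`` iff
    fraction > setpoint; ties never pulse; ``open_loop`` never pulses.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if cfg.mode == "maintain_on" and fraction < cfg.setpoint:
        return Pulse(actuator=cfg.actuator, dose=cfg.dose)
    if cfg.mode == "suppress_on" and fraction > cfg.setpoint:
        return Pulse(actuator=cfg.actuator, dose=cfg.dose)
    return None


def program_dilution(program: EnvironmentProgram, t: float) -> float:
    """Dilution rate at time ``t`` (h) under the program."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if program.kind == "constant_D":
        return program.D0
    if program.kind == "astat":
        return program.D0 + program.D_step * math.floor(t / program.step_period)
    return 0.0  # square_wave: growth chamber, no dilution-driven washout


def program_substrate(program: EnvironmentProgram, t: float) -> Optional[float]:
    """Forced glucose concentration (g/L) for square-wave programs, else None."""
    if program.kind != "square_wave":
        return None
    period = program.dwell_high + program.dwell_low
    phase = (t * 60.0) % period
    return program.S_high if phase < program.dwell_high else program.S_low


@dataclass
class SimulationResult:
    """Output of one run: snapshot series, pulse log and environment trace.

    ``pulses`` has columns (time_h, actuator, dose_g_per_L); ``trace`` has
    columns (time_h, S_g_per_L, I_g_per_L, D_per_h, X_g_per_L,
    on_fraction_truth, gated_fraction).  ``extinct`` flags washout — the
    macroscopic biomass fell below 1e-4 of its initial value (or the agent
    ensemble emptied) and the traces are truncated at that point.
    """

    snapshots: list[Snapshot]
    pulses: pd.DataFrame
    trace: pd.DataFrame
    extinct: bool
    seed: int

    def events(self) -> pd.DataFrame:
        """Flatten the snapshot series into an event table."""
        if not self.snapshots:
            return pd.DataFrame(columns=["time_h", "fluorescence"])
        return pd.DataFrame(
            {
                "time_h": np.repeat(
                    [s.t for s in self.snapshots], [len(s) for s in self.snapshots]
                ),
                "fluorescence": np.concatenate([s.values for s in self.snapshots]),
            }
        )


def run_closed_loop(
    scenario,
    cfg: ControllerConfig | None = None,
    program: EnvironmentProgram | None = None,
    *,
    seed: int | None = None,
    store_snapshots: bool = True,
    dt_max: float | None = None,
) -> SimulationResult:
    """Run one chemostat / Segregostat / dMSCC simulation.

    ``scenario`` is a :class:`segresim.scenarios.ScenarioPreset` (anything
    with params/env0/controller/program/duration_h/seed/n_target and
    measurement fields works).  ``cfg``/``program``/``seed`` override the
    scenario's own settings.  Runs are deterministic for a fixed seed.
    """
    cfg = cfg if cfg is not None else scenario.controller
    program = program if program is not None else scenario.program
    seed = scenario.seed if seed is None else seed

    params: KineticParams = scenario.params
    rng = np.random.default_rng(seed)
    pop = AgentPopulation.initial(scenario.n_target, rng)
    env: EnvironmentState = replace(scenario.env0)
    x0 = env.X if env.X > 0 else 1.0

    interval_h = cfg.sampling_interval / 60.0
    duration = scenario.duration_h
    n_samples = int(round(duration / interval_h)) + 1
    d_max = max(
        program.D0 + program.D_step * math.ceil(duration / max(program.step_period, 1e-9)),
        program.D0,
    )
    dt = choose_dt(params, d_max, interval_h)
    if dt_max is not None and dt_max < dt:
        # finer stepping on request (convergence checks)
        n_sub = int(np.ceil(interval_h / dt_max))
        dt = interval_h / n_sub
    n_sub = int(round(interval_h / dt))

    snapshots: list[Snapshot] = []
    pulse_rows: list[tuple[float, str, float]] = []
    trace_rows: list[tuple] = []
    extinct = False

    pending: Optional[Pulse] = None
    for i_sample in range(n_samples):
        t = i_sample * interval_h
        snap = measure(
            pop,
            n_events=scenario.n_events,
            noise_cv=scenario.noise_cv,
            rng=rng,
            background=scenario.background,
            t=t,
        )
        frac = gate_fraction(snap, cfg.gate_threshold)
        if store_snapshots:
            snapshots.append(snap)
        trace_rows.append(
            (t, env.S, env.I, env.D, env.X, pop.on_fraction, frac)
        )
        pending = decide_pulse(frac, cfg)
        if pending is not None:
            pulse_rows.append((t, pending.actuator, pending.dose))
        if i_sample == n_samples - 1:
            break

        # advance one sampling interval
        for i_sub in range(n_sub):
            t_sub = t + i_sub * dt
            env = replace(env, D=program_dilution(program, t_sub))
            forced_S = program_substrate(program, t_sub)
            if forced_S is not None:
                env = replace(env, S=forced_S)
            try:
                mu_bar = step_population(pop, env, params, dt)
            except ExtinctionError:
                extinct = True
                break
            on_biomass = env.X * pop.on_fraction if len(pop) else 0.0
            env = step_environment(
                env,
                mu_bar,
                dt,
                pulses=(pending,) if (pending is not None and i_sub == 0) else (),
                params=params,
                on_biomass=on_biomass,
            )
            if forced_S is not None:
                env = replace(env, S=forced_S)
            if env.X < EXTINCTION_BIOMASS_FRACTION * x0:
                extinct = True
                break
        pending = None
        if extinct:
            break

    if not store_snapshots:
        snapshots = []
    pulses = pd.DataFrame(pulse_rows, columns=["time_h", "actuator", "dose_g_per_L"])
    trace = pd.DataFrame(
        trace_rows,
        columns=[
            "time_h",
            "S_g_per_L",
            "I_g_per_L",
            "D_per_h",
            "X_g_per_L",
            "on_fraction_truth",
            "gated_fraction",
        ],
    )
    return SimulationResult(
        snapshots=snapshots, pulses=pulses, trace=trace, extinct=extinct, seed=seed
    )
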