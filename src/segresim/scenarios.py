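"""Scenario presets emulating the six reporter systems, and the cost sweep.

The six presets (araB, lacZ, bolA, glc3, T7, spoIIE) are nominal parameter
sets calibrated so that each reproduces the qualitative phenomenology of its
reporter system class — they are fixture values, not measured constants:

* ``araB``/``lacZ`` — inducer-driven carbon-utilization operons in E. coli,
  negligible switching cost, constrained regime (~2.2-bit basal entropy).
* ``bolA`` — sigma-S general stress response in E. coli, starvation-driven,
  low cost, constrained regime.
* ``glc3`` — glycogen/bet-hedging reporter in S. cerevisiae,
  starvation-driven with an intermediate cost, dispersed regime (>3 bits);
  its kinetics anchor the fitness-cost sweep.
* ``T7`` — lactose-inducible T7 expression in E. coli BL21 at D = 0.5/h,
  very high cost, bursty regime.
* ``spoIIE`` — early sporulation reporter in B. subtilis at D = 0.1/h,
  very high cost, bursty regime, controlled by suppressing the switched
  fraction above 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .analysis import RegimeThresholds, classify_regime, compute_metrics
from .control import ControllerConfig, EnvironmentProgram, run_closed_loop
from .simulator import EnvironmentState, KineticParams

__all__ = ["ScenarioPreset", "PRESET_NAMES", "load_preset", "cost_sweep"]


@dataclass(frozen=True)
class ScenarioPreset:
    """A complete, validated simulation scenario."""

    name: str
    params: KineticParams
    env0: EnvironmentState
    controller: ControllerConfig
    program: EnvironmentProgram
    duration_h: float = 60.0
    seed: int = 1
    n_target: int = 10_000
    n_events: int = 20_000
    noise_cv: float = 0.25
    background: float = 100.0
    chemostat_I_in: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.n_target < 2 or self.n_events < 1:
            raise ValueError("n_target and n_events must be positive")

    def open_loop(self) -> "ScenarioPreset":
        """The uncontrolled chemostat reference for this scenario.

        Disables the feedback controller and, for inducer-driven systems,
        feeds the inducer continuously (``chemostat_I_in``): experimentally
        the alternative carbon source is co-fed in chemostat mode but only
        pulsed in Segregostat mode.
        """
        return replace(
            self,
            controller=replace(self.controller, mode="open_loop"),
            env0=replace(self.env0, I_in=self.chemostat_I_in),
        )


def _chemostat_env(
    D: float, S_in: float = 5.0, yield_: float = 0.4, I_in: float = 0.0
) -> EnvironmentState:
    """Post-batch initial state: glucose nearly exhausted, biomass at the
    chemostat carrying capacity yield*(S_in - S0)."""
    S0 = 0.02
    return EnvironmentState(
        t=0.0, S=S0, I=0.0, D=D, S_in=S_in, X=yield_ * (S_in - S0), I_in=I_in
    )


def _presets() -> dict[str, ScenarioPreset]:
    presets: dict[str, ScenarioPreset] = {}

    # --- constrained, inducer-driven carbon utilization (E. coli) ---------
    # Fast coordinated switching and slow GFP turnover keep the activated
    # population narrow; diversification cycles under feedback stay shallow.
    ara_params = KineticParams(
        mu_max=0.6,
        Ks=0.05,
        yield_=0.4,
        k_on_max=16.0,
        K_on=0.05,
        k_off=0.8,
        q_gfp=3.0e4,
        d_gfp=0.1,
        cost=0.0,
        switch_signal="inducer",
        inducer_uptake=0.1,
    )
    presets["araB"] = ScenarioPreset(
        name="araB",
        params=ara_params,
        env0=_chemostat_env(D=0.2),
        controller=ControllerConfig(
            mode="maintain_on",
            setpoint=0.5,
            gate_threshold=3.0e4,
            actuator="inducer",
            dose=0.25,
        ),
        program=EnvironmentProgram(kind="constant_D", D0=0.2),
        chemostat_I_in=0.25,
    )
    presets["lacZ"] = replace(
        presets["araB"],
        name="lacZ",
        params=replace(ara_params, cost=0.05, k_off=0.6),
    )

    # --- constrained, starvation-driven stress response (E. coli) --------
    presets["bolA"] = ScenarioPreset(
        name="bolA",
        params=KineticParams(
            mu_max=0.6,
            Ks=0.05,
            yield_=0.4,
            k_on_max=6.0,
            K_on=0.02,
            k_off=0.8,
            q_gfp=2.5e4,
            d_gfp=0.1,
            cost=0.05,
            switch_signal="starvation",
        ),
        env0=_chemostat_env(D=0.2),
        controller=ControllerConfig(
            mode="suppress_on",
            setpoint=0.5,
            gate_threshold=3_000.0,
            actuator="glucose",
            dose=0.5,
        ),
        program=EnvironmentProgram(kind="constant_D", D0=0.2),
    )

    # --- dispersed, starvation-driven bet-hedging (S. cerevisiae) --------
    # High switching cost with inhibitory (GFP-load) kinetics: selection
    # along the fluorescence axis sustains a broad distribution, and the
    # population washes out only when the saturated-load growth reduction
    # becomes complete.
    presets["glc3"] = ScenarioPreset(
        name="glc3",
        params=KineticParams(
            mu_max=0.7,
            Ks=0.1,
            yield_=0.4,
            k_on_max=3.6,
            K_on=1.0,
            k_off=0.3,
            q_gfp=4.0e3,
            d_gfp=0.0,
            cost=0.96,
            switch_signal="starvation",
            cost_form="inhibitory",
            K_i=1.0e4,
        ),
        env0=_chemostat_env(D=0.5),
        controller=ControllerConfig(
            mode="suppress_on",
            setpoint=0.5,
            gate_threshold=3_000.0,
            actuator="glucose",
            dose=25.0,
        ),
        program=EnvironmentProgram(kind="constant_D", D0=0.5),
        noise_cv=0.35,
    )

    # --- bursty, lactose-inducible T7 expression (E. coli BL21) ----------
    presets["T7"] = ScenarioPreset(
        name="T7",
        params=KineticParams(
            mu_max=2.0,
            Ks=0.05,
            yield_=0.4,
            k_on_max=3.5,
            K_on=0.05,
            k_off=0.3,
            q_gfp=4.0e3,
            d_gfp=0.0,
            cost=0.9,
            switch_signal="inducer",
            inducer_uptake=1.0,
            cost_form="inhibitory",
            K_i=1.0e4,
        ),
        env0=_chemostat_env(D=0.5),
        controller=ControllerConfig(
            mode="maintain_on",
            setpoint=0.5,
            gate_threshold=3_000.0,
            actuator="inducer",
            dose=0.5,
        ),
        program=EnvironmentProgram(kind="constant_D", D0=0.5),
        chemostat_I_in=0.2,
        noise_cv=0.35,
    )

    # --- bursty, sporulation trigger (B. subtilis) ------------------------
    presets["spoIIE"] = ScenarioPreset(
        name="spoIIE",
        params=KineticParams(
            mu_max=0.5,
            Ks=0.05,
            yield_=0.4,
            k_on_max=5.0,
            K_on=0.005,
            k_off=1.5,
            q_gfp=2.0e4,
            d_gfp=0.3,
            cost=0.9,
            switch_signal="starvation",
            cost_form="inhibitory",
            K_i=1.0e4,
        ),
        env0=_chemostat_env(D=0.1),
        controller=ControllerConfig(
            mode="suppress_on",
            setpoint=0.2,
            gate_threshold=3_000.0,
            actuator="glucose",
            dose=1.0,
        ),
        program=EnvironmentProgram(kind="constant_D", D0=0.1),
        noise_cv=0.35,
    )
    return presets


PRESET_NAMES = ("araB", "lacZ", "bolA", "glc3", "T7", "spoIIE")


def load_preset(name: str, **overrides) -> ScenarioPreset:
    """Load a named preset, optionally overriding top-level scenario fields.

    ``load_preset("glc3", n_target=2000, seed=7)`` returns the glc3 scenario
    with a reduced ensemble and a new seed.
    """
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    preset = presets[name]
    return replace(preset, **overrides) if overrides else preset


def cost_sweep(
    base: ScenarioPreset,
    costs: Sequence[float],
    mode: Literal["open_loop", "closed_loop"] = "open_loop",
    base_seed: int = 1,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> pd.DataFrame:
    """Run one simulation per fitness cost and summarise regime statistics.

    Each cost i runs with seed ``base_seed + i`` (recorded in the output).
    Returns one row per cost: cost, seed, mean_H_bits, mean_F_cells_per_min,
    n_bursts, max_amplitude_ratio, extinct, regime.
    """
    costs = list(costs)
    for c in costs:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"cost {c} outside [0, 1]")
    scenario = base.open_loop() if mode == "open_loop" else base
    rows = []
    for i, c in enumerate(costs):
        seed = base_seed + i
        run = run_closed_loop(
            replace(scenario, params=replace(scenario.params, cost=c)), seed=seed
        )
        metrics = compute_metrics(run)
        label = classify_regime(metrics, thresholds=thresholds)
        rows.append(
            {
                "cost": c,
                "seed": seed,
                "mean_H_bits": label.mean_H,
                "mean_F_cells_per_min": float(np.mean(metrics.F_total))
                if len(metrics.F_total)
                else float("nan"),
                "n_bursts": label.n_bursts,
                "max_amplitude_ratio": label.max_amplitude_ratio,
                "extinct": run.extinct,
                "regime": label.regime,
            }
        )
    return pd.DataFrame(rows)
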