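"""Time integration, steady states, and the dark-to-light stimulation protocol.

The trajectory solver is a stiff-capable adaptive method (LSODA) at
rtol=1e-8 / atol=1e-10: the positive-feedback loop can become stiff near the
ignition threshold, where the slow manifold and fast Src-driven
phosphorylation separate by several orders of magnitude in timescale.

A steady state is defined operationally as ``max|rhs| < atol`` after long
integration (at least ten times the slowest dephosphorylation timescale)
followed by Newton polishing of the algebraic balance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import ModelState, equilibrium_pools, rhs
from .params import ModelParameters, ParameterError, ScenarioConfig

__all__ = [
    "LightProtocol",
    "Timecourse",
    "IntegrationError",
    "SteadyStateError",
    "integrate",
    "steady_state",
    "hysteresis_probe",
    "initial_state",
    "remap_state_across_switch",
    "light_switch_experiment",
]

#: default solver tolerances (recorded in timecourse metadata)
RTOL = 1e-8
ATOL = 1e-10
#: steady-state residual criterion, µM/s
SS_ATOL = 1e-9


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g} s)")
        self.t_fail = t_fail


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge within its step budget."""


@dataclass(frozen=True)
class LightProtocol:
    """A single dark equilibration followed by constant illumination.

    Defaults match the blot-stimulation protocol of constant blue light for
    20 min (1200 s).
    """

    pre_dark_duration: float = 3600.0
    light_duration: float = 1200.0
    sample_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.pre_dark_duration < 0 or self.light_duration < 0:
            raise ParameterError("durations must be >= 0")
        if self.sample_interval <= 0:
            raise ParameterError("sample_interval must be > 0")
        if self.light_duration > 0 and self.sample_interval > self.light_duration:
            raise ParameterError("sample_interval must be <= light_duration")


@dataclass(frozen=True)
class Timecourse:
    """A sampled trajectory with derived phospho-fractions.

    ``states`` has one row per time point, columns ordered as
    (pzap70_mem, pzap70_cyt, plat_free, plat_bound).  Fractions are the
    phosphorylated amount over the matching total pool:
    pLAT fraction = (plat_free + plat_bound) / (K * [LAT]0),
    pZap70 fraction = pzap70_mem / total membrane Zap70.
    """

    time: np.ndarray
    states: np.ndarray
    plat_fraction: np.ndarray
    pzap_fraction: np.ndarray
    light_on: bool
    metadata: dict = field(default_factory=dict)

    @property
    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        """Tidy long-format table (time_s, scenario, light, variable, value)."""
        cols = {
            "pzap70_mem": self.states[:, 0],
            "pzap70_cyt": self.states[:, 1],
            "plat_free": self.states[:, 2],
            "plat_bound": self.states[:, 3],
            "plat_fraction": self.plat_fraction,
            "pzap_fraction": self.pzap_fraction,
        }
        frames = [
            pd.DataFrame(
                {
                    "time_s": self.time,
                    "scenario": scenario,
                    "light": self.light_on,
                    "variable": name,
                    "value": values,
                }
            )
            for name, values in cols.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path: str | Path, scenario: str = "") -> None:
        """Write the tidy table plus a JSON sidecar with run metadata."""
        path = Path(path)
        self.to_frame(scenario).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")


def _fractions(
    states: np.ndarray,
    params: ModelParameters,
    config: ScenarioConfig,
    light_on: bool,
) -> tuple[np.ndarray, np.ndarray]:
    pools = equilibrium_pools(params, config, light_on)
    plat = states[:, 2] + states[:, 3]
    plat_frac = plat / pools.lat_conc if pools.lat_conc > 0 else np.zeros(len(states))
    zap_tot = pools.zap70_mem_total
    pzap_frac = states[:, 0] / zap_tot if zap_tot > 0 else np.zeros(len(states))
    return plat_frac, pzap_frac


def integrate(
    params: ModelParameters,
    config: ScenarioConfig,
    initial: ModelState,
    t_span: float,
    sample_interval: float = 5.0,
    light_on: bool | None = None,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Timecourse:
    """Integrate the four phospho-pool ODEs over ``[0, t_span]``.

    The trajectory is reported on the requested uniform sampling grid (the
    end point is always included).  Deterministic: identical inputs and
    tolerances give bit-identical output.
    """
    if light_on is None:
        light_on = config.light_on
    if t_span < 0:
        raise ParameterError("t_span must be >= 0")
    t_eval = np.arange(0.0, t_span, sample_interval)
    if len(t_eval) == 0 or t_eval[-1] < t_span:
        t_eval = np.append(t_eval, t_span)

    y0 = initial.as_array()
    # validate the initial state against the pool bounds (raises DomainError)
    rhs(y0, params, config, light_on)

    if t_span == 0:
        states = y0[None, :]
        plat_frac, pzap_frac = _fractions(states, params, config, light_on)
        return Timecourse(
            time=np.array([0.0]),
            states=states,
            plat_fraction=plat_frac,
            pzap_fraction=pzap_frac,
            light_on=light_on,
            metadata=_metadata(params, config, light_on, rtol, atol),
        )

    sol = solve_ivp(
        lambda t, y: rhs(y, params, config, light_on, check=False),
        (0.0, t_span),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    states = sol.y.T
    plat_frac, pzap_frac = _fractions(states, params, config, light_on)
    return Timecourse(
        time=sol.t,
        states=states,
        plat_fraction=plat_frac,
        pzap_fraction=pzap_frac,
        light_on=light_on,
        metadata=_metadata(params, config, light_on, rtol, atol),
    )


def _metadata(params, config, light_on, rtol, atol) -> dict:
    return {
        "params": params.to_dict(),
        "config": config.to_dict(),
        "light_on": light_on,
        "rtol": rtol,
        "atol": atol,
        "solver": "LSODA",
    }


def steady_state(
    params: ModelParameters,
    config: ScenarioConfig,
    initial: ModelState | None = None,
    light_on: bool | None = None,
    *,
    ss_atol: float = SS_ATOL,
    max_rounds: int = 8,
    min_horizon: float = 0.0,
) -> ModelState:
    """Steady state reached from ``initial``: long integration + root polish.

    The integration horizon starts at ten times the slowest dephosphorylation
    timescale (or ``min_horizon`` if longer) and doubles until the polished
    state satisfies ``max|rhs| < ss_atol`` (µM/s).  Which basin is reached
    depends on the initial condition; callers probing bistability should pass
    both a low and a high initial state and compare
    (see :func:`hysteresis_probe`).
    """
    if light_on is None:
        light_on = config.light_on
    if initial is None:
        initial = initial_state(params, config, light_on)
    slowest = min(
        r for r in (params.kdeph_zap70, params.kdeph_lat) if r > 0
    ) if max(params.kdeph_zap70, params.kdeph_lat) > 0 else 0.01
    horizon = max(10.0 / slowest, min_horizon)
    state = initial
    pools = equilibrium_pools(params, config, light_on)
    caps = np.array(
        [
            pools.zap70_mem_total,
            params.zap70_cyt,
            pools.lat_free_total,
            pools.lat_bound_total,
        ]
    )
    for _ in range(max_rounds):
        tc = integrate(
            params, config, state, horizon, sample_interval=horizon, light_on=light_on
        )
        y = np.clip(tc.states[-1], 0.0, caps)
        sol = root(
            lambda v: rhs(v, params, config, light_on, check=False), y, method="hybr"
        )
        cand = np.clip(sol.x, 0.0, caps) if sol.success else y
        res = float(np.max(np.abs(rhs(cand, params, config, light_on, check=False))))
        if res < ss_atol:
            return ModelState.from_array(cand)
        state = ModelState.from_array(y)
        horizon *= 2.0
    raise SteadyStateError(
        f"no steady state with max|rhs| < {ss_atol:g} within "
        f"{max_rounds} doubling rounds (last residual {res:g} µM/s)"
    )


def hysteresis_probe(
    params: ModelParameters,
    config: ScenarioConfig,
    light_on: bool | None = None,
    *,
    rel_tol: float = 1e-3,
) -> tuple[ModelState, ModelState, bool]:
    """Steady states from a dark-like (all-zero phospho) and a fully
    phosphorylated initial condition.

    Positive feedback can make the model bistable; this reports both branch
    endpoints and whether they disagree (``bistable=True``), so callers can
    surface the disagreement rather than average it away.
    """
    if light_on is None:
        light_on = config.light_on
    pools = equilibrium_pools(params, config, light_on)
    low = steady_state(params, config, ModelState(), light_on=light_on)
    high0 = ModelState(
        pzap70_mem=pools.zap70_mem_total,
        pzap70_cyt=params.zap70_cyt,
        plat_free=pools.lat_free_total,
        plat_bound=pools.lat_bound_total,
    )
    high = steady_state(params, config, high0, light_on=light_on)
    scale = max(pools.lat_conc, 1e-12)
    gap = abs(high.plat_total - low.plat_total) / scale
    return low, high, bool(gap > rel_tol)


def initial_state(
    params: ModelParameters, config: ScenarioConfig, light_on: bool = False
) -> ModelState:
    """Default pre-equilibration initial condition.

    All phospho-pools start at zero, except the no-recruitment scenario,
    which seeds the pZap70 pools at ``basal_pzap70_frac`` of their totals
    (a pre-existing basal pool of phosphorylated Zap70).
    """
    if config.name != "jurkat_no_recruitment":
        return ModelState()
    pools = equilibrium_pools(params, config, light_on)
    f = config.basal_pzap70_frac
    return ModelState(
        pzap70_mem=f * pools.zap70_mem_total, pzap70_cyt=f * params.zap70_cyt
    )


def remap_state_across_switch(
    state: ModelState,
    params: ModelParameters,
    config: ScenarioConfig,
    light_before: bool,
    light_after: bool,
) -> ModelState:
    """Carry the phospho-pools across an instantaneous light switch.

    Compartment shrinkage concentrates every LAT species K-fold, so the total
    pLAT concentration is scaled by ``K_after / K_before`` (molecule
    conservation; the phospho-fraction of LAT is continuous across the
    switch) and redistributed between the bound and free pools in proportion
    to the new equilibrium bound fraction.  Membrane pZap70 keeps its
    concentration, with Zap70 newly recruited by the tighter lit-state tether
    arriving with the cytosolic phospho-fraction; the result is clipped to
    the new pool bounds.
    """
    before = equilibrium_pools(params, config, light_before)
    after = equilibrium_pools(params, config, light_after)

    k_ratio = after.partition_k / before.partition_k
    plat_total = (state.plat_free + state.plat_bound) * k_ratio
    plat_total = min(plat_total, after.lat_conc)
    plat_bound = plat_total * after.bound_fraction
    plat_free = plat_total - plat_bound

    pzap_mem = state.pzap70_mem
    recruited = after.zap70_mem_total - before.zap70_mem_total
    if recruited > 0 and params.zap70_cyt > 0:
        pzap_mem += recruited * (state.pzap70_cyt / params.zap70_cyt)
    pzap_mem = min(max(pzap_mem, 0.0), after.zap70_mem_total)

    # no-recruitment scenario: the basal pool floor applies at light onset
    if config.name == "jurkat_no_recruitment":
        f = config.basal_pzap70_frac
        pzap_mem = max(pzap_mem, f * after.zap70_mem_total)

    return ModelState(
        pzap70_mem=pzap_mem,
        pzap70_cyt=state.pzap70_cyt,
        plat_free=plat_free,
        plat_bound=plat_bound,
    )


def light_switch_experiment(
    params: ModelParameters,
    config: ScenarioConfig,
    protocol: LightProtocol | None = None,
) -> tuple[ModelState, Timecourse]:
    """Dark equilibration followed by the scenario's lit-state integration.

    The system is equilibrated in the dark (K = 1, dark iLID affinity), the
    light is switched on (lit affinity, and K = partition_k_light for
    clustering constructs) with the pools remapped across the switch, and
    the lit phase is integrated for ``protocol.light_duration``.

    Returns the dark steady state and the lit timecourse.
    """
    if protocol is None:
        protocol = LightProtocol()
    dark = steady_state(
        params,
        config,
        initial_state(params, config, False),
        light_on=False,
        min_horizon=protocol.pre_dark_duration,
    )
    lit_initial = remap_state_across_switch(dark, params, config, False, True)
    if protocol.light_duration == 0:
        tc = integrate(
            params, config, lit_initial, 0.0, protocol.sample_interval, light_on=True
        )
    else:
        tc = integrate(
            params,
            config,
            lit_initial,
            protocol.light_duration,
            protocol.sample_interval,
            light_on=True,
        )
    return dark, tc
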