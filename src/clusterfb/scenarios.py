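"""Experimental-regime scenarios, parameter scans, and the PP2 dose-response.

Seven regimes are supported: the base clustering construct (``ilid_drop``),
its non-clustering control (``ilid_only``), the weakly constitutively active
kinase in the non-clustering configuration (``zap70_k362e``), kinase-dead
Zap70 (``zap70_kd``), non-phosphorylatable LAT (``lat_fff``), the
feedback-disconnected SFK (``src_dsh2dsh3``), and LAT clustering without a
Zap70 tether seeded with basal pZap70 (``jurkat_no_recruitment``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .dynamics import (
    LightProtocol,
    Timecourse,
    initial_state,
    light_switch_experiment,
    remap_state_across_switch,
    steady_state,
)
from .model import ModelState, equilibrium_pools
from .params import SCENARIO_NAMES, ModelParameters, ParameterError, ScenarioConfig

__all__ = [
    "ScanResult",
    "DoseResponse",
    "FitResult",
    "apply_scenario",
    "run_six_scenarios",
    "six_scenario_summary",
    "scan",
    "k_at_fraction_of_plateau",
    "src_contrast_range",
    "pp2_titration",
    "effective_dose_range",
    "fit_dose_response",
    "ScaledResponseCurve",
    "SIX_SCENARIOS",
]

#: the six figure-level simulation regimes, in display order
SIX_SCENARIOS = (
    "ilid_drop",
    "ilid_only",
    "zap70_k362e",
    "zap70_kd",
    "lat_fff",
    "src_dsh2dsh3",
)


@dataclass(frozen=True)
class ScanResult:
    """Steady-state outputs versus one swept parameter."""

    swept_parameter: str
    units: str
    values: np.ndarray
    dark_plat_frac: np.ndarray
    lit_plat_frac: np.ndarray
    dark_pzap_frac: np.ndarray
    lit_pzap_frac: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.values)
        for name in ("dark_plat_frac", "lit_plat_frac", "dark_pzap_frac",
                     "lit_pzap_frac"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"{name} length != number of scan values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.swept_parameter: self.values,
                "dark_plat_frac": self.dark_plat_frac,
                "lit_plat_frac": self.lit_plat_frac,
                "dark_pzap_frac": self.dark_pzap_frac,
                "lit_pzap_frac": self.lit_pzap_frac,
            }
        )


@dataclass(frozen=True)
class DoseResponse:
    """Steady lit pLAT fraction versus inhibitor dose."""

    pp2_concs: np.ndarray
    plat_frac: np.ndarray
    fitted_ki: float | None = None
    fit_residual: float = float("nan")

    def __post_init__(self) -> None:
        c = np.asarray(self.pp2_concs, float)
        if np.any(c < 0):
            raise ParameterError("pp2_concs must be non-negative")
        if np.any(np.diff(c) <= 0):
            raise ParameterError("pp2_concs must be strictly increasing")
        if len(self.plat_frac) != len(c):
            raise ParameterError("plat_frac length != pp2_concs length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pp2_um": self.pp2_concs, "plat_frac": self.plat_frac}
        )


def apply_scenario(
    name: str,
    params: ModelParameters,
    overrides: Mapping[str, Any] | None = None,
) -> tuple[ModelParameters, ScenarioConfig]:
    """Build the (parameters, config) pair for a named scenario.

    ``overrides`` may contain base-parameter fields (e.g. ``src_cyt``) and/or
    scenario-factor fields (e.g. ``k362e_kcat_factor``); unknown keys raise.
    The scenario's equation modifications are applied lazily by
    :func:`clusterfb.model.effective_parameters`, so this transform is a pure
    function of its inputs and is idempotent on its own output.
    """
    if name not in SCENARIO_NAMES:
        raise ParameterError(
            f"unknown scenario {name!r}; valid names: {list(SCENARIO_NAMES)}"
        )
    param_fields = set(params.to_dict())
    config_fields = set(ScenarioConfig().to_dict()) - {"name", "light_on"}
    p_over: dict[str, Any] = {}
    c_over: dict[str, Any] = {}
    for key, value in (overrides or {}).items():
        if key in param_fields:
            p_over[key] = value
        elif key in config_fields:
            c_over[key] = value
        else:
            raise ParameterError(
                f"unknown override {key!r}; valid keys: "
                f"{sorted(param_fields | config_fields)}"
            )
    return params.replace(**p_over), ScenarioConfig(name=name, **c_over)


def run_six_scenarios(
    params: ModelParameters | None = None,
    protocol: LightProtocol | None = None,
) -> dict[str, tuple[ModelState, Timecourse]]:
    """Dark steady state and lit timecourse for each of the six regimes."""
    params = params or ModelParameters()
    protocol = protocol or LightProtocol()
    out: dict[str, tuple[ModelState, Timecourse]] = {}
    for name in SIX_SCENARIOS:
        p, config = apply_scenario(name, params)
        out[name] = light_switch_experiment(p, config, protocol)
    return out


def six_scenario_summary(
    results: Mapping[str, tuple[ModelState, Timecourse]],
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """End-point phospho-fractions per scenario (dark vs 20-min light)."""
    params = params or ModelParameters()
    rows = []
    for name, (dark, lit_tc) in results.items():
        _, config = apply_scenario(name, params)
        pools_dark = equilibrium_pools(params, config, light_on=False)
        dark_plat = (
            (dark.plat_free + dark.plat_bound) / pools_dark.lat_conc
            if pools_dark.lat_conc > 0
            else 0.0
        )
        dark_pzap = (
            dark.pzap70_mem / pools_dark.zap70_mem_total
            if pools_dark.zap70_mem_total > 0
            else 0.0
        )
        rows.append(
            {
                "scenario": name,
                "dark_plat_frac": dark_plat,
                "lit_plat_frac": float(lit_tc.plat_fraction[-1]),
                "dark_pzap_frac": dark_pzap,
                "lit_pzap_frac": float(lit_tc.pzap_fraction[-1]),
            }
        )
    df = pd.DataFrame(rows)
    df["lit_dark_plat_ratio"] = df["lit_plat_frac"] / df["dark_plat_frac"]
    return df


def _steady_fracs(
    params: ModelParameters, config: ScenarioConfig, light_on: bool,
    initial: ModelState | None = None,
) -> tuple[float, float, ModelState]:
    ss = steady_state(params, config, initial, light_on=light_on)
    pools = equilibrium_pools(params, config, light_on)
    plat = (ss.plat_free + ss.plat_bound) / pools.lat_conc if pools.lat_conc else 0.0
    pzap = (
        ss.pzap70_mem / pools.zap70_mem_total if pools.zap70_mem_total else 0.0
    )
    return plat, pzap, ss


def _lit_steady_from_dark(
    params: ModelParameters, config: ScenarioConfig, dark: ModelState
) -> tuple[float, float]:
    lit0 = remap_state_across_switch(dark, params, config, False, True)
    plat, pzap, _ = _steady_fracs(params, config, True, lit0)
    return plat, pzap


def scan(
    param_name: str,
    values: Sequence[float],
    params: ModelParameters | None = None,
    protocol: LightProtocol | None = None,
    scenario: str = "ilid_drop",
    overrides: Mapping[str, Any] | None = None,
) -> ScanResult:
    """Steady dark/lit phospho-fractions over a swept parameter.

    Supports ``partition_k_light`` (degree of clustering; the dark state is
    independent of it and computed once) and ``src_cyt`` (the dark state is
    recomputed per value).  The lit steady state is always reached from the
    dark state through the light switch, i.e. along the physically accessible
    branch.
    """
    if param_name not in ("partition_k_light", "src_cyt"):
        raise ParameterError(
            f"unsupported scan parameter {param_name!r}; "
            "supported: partition_k_light, src_cyt"
        )
    values = np.asarray(values, float)
    if np.any(np.diff(values) <= 0):
        raise ParameterError("scan values must be strictly increasing")
    params = params or ModelParameters()

    dark_plat = np.empty_like(values)
    lit_plat = np.empty_like(values)
    dark_pzap = np.empty_like(values)
    lit_pzap = np.empty_like(values)

    if param_name == "partition_k_light":
        base, config = apply_scenario(scenario, params, overrides)
        dp, dz, dark_ss = _steady_fracs(
            base, config, False, initial_state(base, config, False)
        )
        dark_plat[:] = dp
        dark_pzap[:] = dz
        for i, v in enumerate(values):
            p = base.replace(partition_k_light=float(v))
            lit_plat[i], lit_pzap[i] = _lit_steady_from_dark(p, config, dark_ss)
    else:
        for i, v in enumerate(values):
            over = dict(overrides or {})
            over["src_cyt"] = float(v)
            p, config = apply_scenario(scenario, params, over)
            dark_plat[i], dark_pzap[i], dark_ss = _steady_fracs(
                p, config, False, initial_state(p, config, False)
            )
            lit_plat[i], lit_pzap[i] = _lit_steady_from_dark(p, config, dark_ss)

    units = "fold LAT concentration" if param_name == "partition_k_light" else "µM"
    return ScanResult(
        swept_parameter=param_name,
        units=units,
        values=values,
        dark_plat_frac=dark_plat,
        lit_plat_frac=lit_plat,
        dark_pzap_frac=dark_pzap,
        lit_pzap_frac=lit_pzap,
    )


def k_at_fraction_of_plateau(result: ScanResult, frac: float = 0.9) -> float:
    """Smallest scanned K whose lit pLAT fraction reaches ``frac`` of the
    large-K asymptote (the value at the top of the scan)."""
    asymptote = result.lit_plat_frac[-1]
    target = frac * asymptote
    idx = np.nonzero(result.lit_plat_frac >= target)[0]
    if len(idx) == 0:
        raise ValueError("scan never reaches the requested fraction of plateau")
    return float(result.values[idx[0]])


def src_contrast_range(
    result: ScanResult, min_contrast: float = 10.0
) -> tuple[float, float, float]:
    """Widest contiguous swept-value range with lit/dark pLAT contrast >=
    ``min_contrast``.

    Returns ``(lo, hi, decades)``; ``(nan, nan, 0)`` if no value qualifies.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = result.lit_plat_frac / result.dark_plat_frac
    ok = np.asarray(contrast >= min_contrast)
    if not ok.any():
        return float("nan"), float("nan"), 0.0
    best = (0, -1)  # (length, start)
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[0]:
                best = (i - start, start)
            start = None
    lo = float(result.values[best[1]])
    hi = float(result.values[best[1] + best[0] - 1])
    return lo, hi, math.log10(hi / lo) if lo > 0 else float("inf")


def pp2_titration(
    pp2_concs: Sequence[float],
    params: ModelParameters | None = None,
    protocol: LightProtocol | None = None,
    scenario: str = "ilid_drop",
    overrides: Mapping[str, Any] | None = None,
) -> DoseResponse:
    """Lit steady pLAT fraction per PP2 dose (drug present before and during
    illumination, as in the blot experiments)."""
    pp2_concs = np.asarray(pp2_concs, float)
    params = params or ModelParameters()
    fracs = np.empty_like(pp2_concs)
    for i, dose in enumerate(pp2_concs):
        p, config = apply_scenario(scenario, params, overrides)
        p = p.replace(pp2=float(dose))
        _, _, dark_ss = _steady_fracs(
            p, config, False, initial_state(p, config, False)
        )
        fracs[i], _ = _lit_steady_from_dark(p, config, dark_ss)
    return DoseResponse(pp2_concs=pp2_concs, plat_frac=fracs)


def effective_dose_range(response: DoseResponse) -> float:
    """Largest dose at which pLAT stays above half its drug-free value.

    The drug-free reference is the first point of the (strictly increasing)
    dose grid, which should be 0 or the lowest dose probed.  Interpolates
    log-linearly between the bracketing grid points; returns 0.0 if even the
    first dose is below half-reference, and the top of the grid if the curve
    never falls below it.
    """
    ref = response.plat_frac[0]
    half = 0.5 * ref
    below = np.nonzero(response.plat_frac < half)[0]
    if len(below) == 0:
        return float(response.pp2_concs[-1])
    j = below[0]
    if j == 0:
        return 0.0
    d0, d1 = response.pp2_concs[j - 1], response.pp2_concs[j]
    f0, f1 = response.plat_frac[j - 1], response.plat_frac[j]
    if d0 <= 0 or f0 == f1:
        return float(d0)
    # log-dose linear interpolation to the half-crossing
    x = (half - f0) / (f1 - f0)
    return float(10 ** (np.log10(d0) + x * (np.log10(d1) - np.log10(d0))))


@dataclass(frozen=True)
class FitResult:
    """Least-squares dose-response fit of (ki_pp2, amplitude)."""

    ki_pp2: float
    amplitude: float
    residual: float          # sum of squared residuals
    at_bound: dict = field(default_factory=dict)
    n_starts: int = 0


class ScaledResponseCurve:
    """Steady lit pLAT fraction as a function of the PP2 catalytic scale
    s = K_I/(K_I + [PP2]), precomputed on a dense grid and monotonically
    interpolated.

    Because PP2 enters the model only through this single scale factor on
    both Src catalytic constants, the entire (ki, dose) family of model
    curves collapses onto one function of s; fitting then needs no further
    ODE solves.
    """

    def __init__(
        self,
        params: ModelParameters,
        scenario: str = "ilid_drop",
        overrides: Mapping[str, Any] | None = None,
        n_grid: int = 160,
    ):
        # s-grid from ~1 (no drug) down to ~0 (full inhibition), log-spaced
        # in the equivalent dose to resolve the feedback-collapse cliff
        dose_over_ki = np.concatenate(
            ([0.0], np.logspace(-3, 3, n_grid - 1))
        )
        s = 1.0 / (1.0 + dose_over_ki)
        fracs = np.empty_like(s)
        p0, config = apply_scenario(scenario, params, overrides)
        for i, si in enumerate(s):
            p = p0.replace(
                kcat_src_active=p0.kcat_src_active * si,
                kcat_src_inactive=p0.kcat_src_inactive * si,
                pp2=0.0,
            )
            _, _, dark_ss = _steady_fracs(
                p, config, False, initial_state(p, config, False)
            )
            fracs[i], _ = _lit_steady_from_dark(p, config, dark_ss)
        # interpolate in log(dose/ki); prepend the drug-free value
        self._x = np.log10(dose_over_ki[1:])
        self._y = fracs[1:]
        self._f0 = float(fracs[0])
        self._interp = PchipInterpolator(self._x, self._y, extrapolate=False)

    def __call__(self, doses: np.ndarray, ki: float) -> np.ndarray:
        doses = np.asarray(doses, float)
        out = np.empty_like(doses)
        zero = doses == 0
        out[zero] = self._f0
        x = np.log10(np.where(zero, 1.0, doses) / ki)
        inside = ~zero & (x >= self._x[0]) & (x <= self._x[-1])
        out[inside] = self._interp(x[inside])
        out[~zero & (x < self._x[0])] = self._f0
        out[~zero & (x > self._x[-1])] = self._y[-1]
        return out


def fit_dose_response(
    observed: DoseResponse,
    params: ModelParameters | None = None,
    free: Sequence[str] = ("ki_pp2", "amplitude"),
    scenario: str = "ilid_drop",
    overrides: Mapping[str, Any] | None = None,
    curve: ScaledResponseCurve | None = None,
    exact_polish: bool = False,
) -> FitResult:
    """Least-squares fit of the model dose-response to observed points.

    Free parameters: ``ki_pp2`` (µM) and ``amplitude``, a single
    multiplicative readout-scale factor mapping the model pLAT fraction onto
    the observation units.  Initialization is a deterministic multi-start
    over the nonzero dose grid (each dose is tried as the starting K_I);
    each start is optimized against the precomputed response interpolant.
    With ``exact_polish=True`` the best start is then re-optimized against
    direct steady-state model evaluations (slower, but removes the
    interpolation error -- noiseless data are then recovered to solver
    precision).
    """
    params = params or ModelParameters()
    free = tuple(free)
    if set(free) - {"ki_pp2", "amplitude"}:
        raise ParameterError(f"unsupported free parameters: {free}")
    doses = np.asarray(observed.pp2_concs, float)
    obs = np.asarray(observed.plat_frac, float)
    if len(doses) < 3:
        raise ParameterError("need >= 3 doses to fit")
    if len(doses) < len(free):
        raise ParameterError("fewer doses than free parameters")

    if curve is None:
        curve = ScaledResponseCurve(params, scenario, overrides)

    fit_ki = "ki_pp2" in free
    fit_amp = "amplitude" in free
    ki_fixed = params.ki_pp2
    amp_fixed = 1.0
    ki_bounds = (1e-6, 1e6)
    amp_bounds = (1e-12, 1e3)

    def unpack(theta):
        idx = 0
        ki = 10 ** theta[idx] if fit_ki else ki_fixed
        idx += fit_ki
        amp = theta[idx] if fit_amp else amp_fixed
        return ki, amp

    def residuals(theta):
        ki, amp = unpack(theta)
        return amp * curve(doses, ki) - obs

    f0 = curve(np.array([doses[0]]), ki_fixed)[0]
    amp0 = float(np.max(obs) / max(curve(np.array([0.0]), 1.0)[0], 1e-9))
    starts = [d for d in doses if d > 0] or [ki_fixed]
    best = None
    for ki0 in starts:
        theta0, lo, hi = [], [], []
        if fit_ki:
            theta0.append(math.log10(ki0))
            lo.append(math.log10(ki_bounds[0]))
            hi.append(math.log10(ki_bounds[1]))
        if fit_amp:
            theta0.append(max(amp0, amp_bounds[0]))
            lo.append(amp_bounds[0])
            hi.append(amp_bounds[1])
        sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, sol, (lo, hi))
    ssr, sol, bnds = best

    if exact_polish:
        p0, config = apply_scenario(scenario, params, overrides)

        def exact_residuals(theta):
            ki, amp = unpack(theta)
            pred = np.empty_like(doses)
            for j, dose in enumerate(doses):
                p = p0.replace(ki_pp2=ki, pp2=float(dose))
                _, _, dark_ss = _steady_fracs(
                    p, config, False, initial_state(p, config, False)
                )
                pred[j], _ = _lit_steady_from_dark(p, config, dark_ss)
            return amp * pred - obs

        sol = least_squares(
            exact_residuals, sol.x, bounds=bnds, method="trf", xtol=1e-12
        )
        ssr = float(np.sum(sol.fun**2))

    ki, amp = unpack(sol.x)
    at_bound = {}
    if fit_ki:
        at_bound["ki_pp2"] = bool(
            ki <= ki_bounds[0] * 1.01 or ki >= ki_bounds[1] * 0.99
        )
    if fit_amp:
        at_bound["amplitude"] = bool(
            amp <= amp_bounds[0] * 1.01 or amp >= amp_bounds[1] * 0.99
        )
    return FitResult(
        ki_pp2=float(ki),
        amplitude=float(amp),
        residual=ssr,
        at_bound=at_bound,
        n_starts=len(starts),
    )
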