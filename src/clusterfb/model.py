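"""Algebraic layer and ODE right-hand side of the clustering-feedback model.

Model structure
---------------
Light-induced clustering is represented as a shrinkage of the membrane
compartment volume by a partition coefficient ``K``, so the LAT concentration
referred to that compartment is ``K * [LAT]0``.  Zap70 tethering to LAT by the
iLID/SspB pair and Src binding to phospho-LAT through its SH2 domain are both
treated as fast equilibria with the cytosolic concentrations of Zap70 and Src
held constant; both proteins also diffuse freely into the cluster, so the
cluster additionally contains a free (unbound) pool of each at its cytosolic
concentration.

Four phospho-pools are integrated in time: membrane/cluster pZap70, cytosolic
pZap70, and phospho-LAT split into a Zap70-bound pool (eligible for tethered
first-order phosphorylation) and a free pool.  Zap70 is phosphorylated by
pLAT-activated Src (fast Michaelis-Menten branch) and by autoinhibited free
Src (slow branch, the "leaky" basal activity); LAT is phosphorylated by
membrane pZap70 (Michaelis-Menten) and, when tethered, by its own bound
pZap70 at a first-order rate.  Both species dephosphorylate constitutively at
first order.  The Src inhibitor PP2 acts non-competitively, scaling both Src
catalytic constants by ``K_I / (K_I + [PP2])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, ParameterError, ScenarioConfig

__all__ = [
    "ModelState",
    "EquilibriumPools",
    "cluster_concentration",
    "zap70_partition",
    "src_partition",
    "pp2_scale",
    "effective_parameters",
    "equilibrium_pools",
    "rhs",
    "DomainError",
]

#: relative slack allowed when checking state-vs-pool bounds
_BOUND_RTOL = 1e-6


class DomainError(ValueError):
    """State outside the physical pool bounds beyond numerical tolerance."""


@dataclass(frozen=True)
class ModelState:
    """The four phospho-pool state variables (concentrations, µM).

    LAT pools are referred to the (possibly shrunken) cluster compartment.
    """

    pzap70_mem: float = 0.0
    pzap70_cyt: float = 0.0
    plat_free: float = 0.0
    plat_bound: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pzap70_mem, self.pzap70_cyt, self.plat_free, self.plat_bound]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in y))

    @property
    def plat_total(self) -> float:
        return self.plat_free + self.plat_bound

    def replace(self, **kw: float) -> "ModelState":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EquilibriumPools:
    """Derived equilibrium quantities for one (params, config, light) context."""

    partition_k: float          # compartment shrinkage factor in effect
    ka_ilid: float              # iLID/SspB association constant in effect (1/µM)
    lat_conc: float             # K * [LAT]0, cluster-referred total LAT (µM)
    bound_fraction: float       # fraction of LAT carrying an iLID-tethered Zap70
    zap70_bound: float          # tethered Zap70 concentration in the cluster (µM)
    zap70_free: float           # freely diffusing Zap70 in the cluster (µM)
    zap70_mem_total: float      # total membrane-compartment Zap70 (µM)
    lat_bound_total: float      # Zap70-bound LAT pool total (µM)
    lat_free_total: float       # unbound LAT pool total (µM)


def cluster_concentration(partition_k: float, lat_total: float) -> float:
    """LAT concentration in the membrane compartment after K-fold shrinkage.

    Cluster formation is modeled as the membrane compartment volume dropping
    by a factor K, so the compartment-referred LAT concentration is
    ``K * [LAT]0``.
    """
    if partition_k <= 0:
        raise ParameterError(f"partition_k must be > 0, got {partition_k}")
    if lat_total < 0:
        raise ParameterError(f"lat_total must be >= 0, got {lat_total}")
    return partition_k * lat_total


def zap70_partition(
    lat_conc: float, zap70_cyt: float, ka_ilid: float
) -> tuple[float, float, float, float]:
    """Equilibrium Zap70 partitioning into the membrane compartment.

    With the cytosolic Zap70 concentration held constant, a fraction
    ``f = [Zap70]0*KA / (1 + [Zap70]0*KA)`` of LAT molecules carry a tethered
    Zap70, and free Zap70 additionally diffuses into the compartment at its
    cytosolic concentration.

    Returns ``(total_mem, bound, free, bound_fraction)``.
    """
    if min(lat_conc, zap70_cyt, ka_ilid) < 0:
        raise ParameterError("zap70_partition inputs must be >= 0")
    f = zap70_cyt * ka_ilid / (1.0 + zap70_cyt * ka_ilid)
    bound = lat_conc * f
    free = zap70_cyt
    return bound + free, bound, free, f


def src_partition(
    plat_conc: float, src_cyt: float, ka_sh2: float
) -> tuple[float, float]:
    """Equilibrium active/inactive Src in the cluster.

    Src binds phosphorylated LAT through its SH2 domain, which releases
    autoinhibition; free Src also diffuses into the cluster but remains
    autoinhibited.  Returns ``(active, inactive)``.
    """
    if min(plat_conc, src_cyt, ka_sh2) < 0:
        raise ParameterError("src_partition inputs must be >= 0")
    active = plat_conc * src_cyt * ka_sh2 / (1.0 + src_cyt * ka_sh2)
    return active, src_cyt


def pp2_scale(kcat: float, ki: float, pp2: float) -> float:
    """Non-competitive inhibition: kcat * K_I / (K_I + [PP2])."""
    if ki <= 0:
        raise ParameterError(f"ki must be > 0, got {ki}")
    if pp2 < 0:
        raise ParameterError(f"pp2 must be >= 0, got {pp2}")
    if kcat < 0:
        raise ParameterError(f"kcat must be >= 0, got {kcat}")
    return kcat * ki / (ki + pp2)


def effective_parameters(
    params: ModelParameters, config: ScenarioConfig, light_on: bool | None = None
) -> ModelParameters:
    """Parameters with the scenario's equation modifications applied.

    The scenario transforms are applied at evaluation time so that building a
    scenario never mutates the base parameter set:

    * ``zap70_k362e``: kcat_pzap70 and k_tethered scaled down, km_pzap70
      scaled up (weak constitutive kinase; the constitutive-activity flag
      itself is read from the config by :func:`rhs`).
    * ``zap70_kd``: LAT phosphorylation by Zap70 switched off.
    * ``lat_fff``: non-phosphorylatable LAT -- no Src binding to pLAT and no
      LAT phosphorylation.
    * ``src_dsh2dsh3``: no Src binding to pLAT, boosted free-Src activity,
      reduced total Src.
    * ``jurkat_no_recruitment``: no iLID tether in either light state.
    """
    name = config.name
    if name in ("ilid_drop", "ilid_only"):
        return params
    if name == "zap70_k362e":
        return params.replace(
            kcat_pzap70=params.kcat_pzap70 * config.k362e_kcat_factor,
            km_pzap70=params.km_pzap70 * config.k362e_km_factor,
            k_tethered=params.k_tethered * config.k362e_kcat_factor,
        )
    if name == "zap70_kd":
        return params.replace(kcat_pzap70=0.0, k_tethered=0.0)
    if name == "lat_fff":
        return params.replace(ka_sh2=0.0, kcat_pzap70=0.0, k_tethered=0.0)
    if name == "src_dsh2dsh3":
        return params.replace(
            ka_sh2=0.0,
            kcat_src_inactive=params.kcat_src_inactive * config.dsh2_kcat_free_factor,
            src_cyt=params.src_cyt * config.dsh2_src_conc_factor,
        )
    if name == "jurkat_no_recruitment":
        return params.replace(ka_ilid_dark=0.0, ka_ilid_light=0.0)
    raise ParameterError(f"unknown scenario {name!r}")  # pragma: no cover


def equilibrium_pools(
    params: ModelParameters, config: ScenarioConfig, light_on: bool | None = None
) -> EquilibriumPools:
    """Derived pool totals for the given light state.

    ``light_on`` defaults to ``config.light_on``.  K rises to
    ``partition_k_light`` only for clustering constructs under illumination;
    the iLID association constant takes its lit value under illumination.
    """
    if light_on is None:
        light_on = config.light_on
    eff = effective_parameters(params, config, light_on)
    k = eff.partition_k_light if (light_on and config.clusters_in_light) else 1.0
    ka = eff.ka_ilid_light if light_on else eff.ka_ilid_dark
    lat_conc = cluster_concentration(k, eff.lat_total)
    total, bound, free, f = zap70_partition(lat_conc, eff.zap70_cyt, ka)
    return EquilibriumPools(
        partition_k=k,
        ka_ilid=ka,
        lat_conc=lat_conc,
        bound_fraction=f,
        zap70_bound=bound,
        zap70_free=free,
        zap70_mem_total=total,
        lat_bound_total=f * lat_conc,
        lat_free_total=(1.0 - f) * lat_conc,
    )


def _check_bounds(y: np.ndarray, pools: EquilibriumPools, zap70_cyt: float) -> None:
    caps = np.array(
        [pools.zap70_mem_total, zap70_cyt, pools.lat_free_total, pools.lat_bound_total]
    )
    tol = _BOUND_RTOL * np.maximum(caps, 1.0)
    if np.any(y < -tol) or np.any(y > caps + tol):
        raise DomainError(
            f"state {y.tolist()} outside pool bounds {caps.tolist()}"
        )


def rhs(
    state: ModelState | np.ndarray,
    params: ModelParameters,
    config: ScenarioConfig,
    light_on: bool | None = None,
    *,
    check: bool = True,
) -> np.ndarray:
    """Time-derivatives of the four phospho-pools (µM/s).

    Order: (pzap70_mem, pzap70_cyt, plat_free, plat_bound).
    """
    if light_on is None:
        light_on = config.light_on
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
    eff = effective_parameters(params, config, light_on)
    pools = equilibrium_pools(params, config, light_on)
    if check:
        _check_bounds(y, pools, eff.zap70_cyt)

    pzap_mem, pzap_cyt, plat_free, plat_bound = y
    zap_n = max(pools.zap70_mem_total - pzap_mem, 0.0)
    zap_n_cyt = max(eff.zap70_cyt - pzap_cyt, 0.0)
    latn_free = max(pools.lat_free_total - plat_free, 0.0)
    latn_bound = max(pools.lat_bound_total - plat_bound, 0.0)

    src_a, src_i = src_partition(
        max(plat_free + plat_bound, 0.0), eff.src_cyt, eff.ka_sh2
    )
    kcat_a = pp2_scale(eff.kcat_src_active, eff.ki_pp2, eff.pp2)
    kcat_i = pp2_scale(eff.kcat_src_inactive, eff.ki_pp2, eff.pp2)

    # Zap70 phosphorylation: fast branch by pLAT-activated Src (cluster only),
    # slow leaky branch by autoinhibited Src (cluster and cytosol).
    d_pzap_mem = (
        kcat_a * src_a * zap_n / (eff.km_src_active + zap_n)
        + kcat_i * src_i * zap_n / (eff.km_src_inactive + zap_n)
        - eff.kdeph_zap70 * pzap_mem
    )
    d_pzap_cyt = (
        kcat_i * src_i * zap_n_cyt / (eff.km_src_inactive + zap_n_cyt)
        - eff.kdeph_zap70 * pzap_cyt
    )

    # LAT phosphorylation by membrane Zap70.  For the K362E constitutive
    # mutant both phospho-forms are catalytically competent, so the kinase
    # concentration is the whole membrane Zap70 pool and every tethered
    # complex supports the first-order mechanism.
    if config.zap70_constitutive:
        kinase = pools.zap70_mem_total
        tether_frac = 1.0
    else:
        kinase = pzap_mem
        tether_frac = (
            pzap_mem / pools.zap70_mem_total if pools.zap70_mem_total > 0 else 0.0
        )

    d_plat_free = (
        eff.kcat_pzap70 * kinase * latn_free / (eff.km_pzap70 + latn_free)
        - eff.kdeph_lat * plat_free
    )
    # tethered term: first-order phosphorylation of the iLID-bound
    # (unphosphorylated-LAT : pZap70) complex pool
    d_plat_bound = (
        eff.kcat_pzap70 * kinase * latn_bound / (eff.km_pzap70 + latn_bound)
        + eff.k_tethered * latn_bound * tether_frac
        - eff.kdeph_lat * plat_bound
    )

    return np.array([d_pzap_mem, d_pzap_cyt, d_plat_free, d_plat_bound])
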