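"""Unit tests for the algebraic layer and the ODE right-hand side."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterfb import (
    ModelParameters,
    ModelState,
    ParameterError,
    ScenarioConfig,
    cluster_concentration,
    equilibrium_pools,
    pp2_scale,
    rhs,
    src_partition,
    zap70_partition,
)
from clusterfb.model import DomainError, effective_parameters

from conftest import random_params, random_state_in_box

# --- cluster concentration -------------------------------------------------


@pytest.mark.parametrize(
    "k, lat, expected",
    [(1.0, 0.5, 0.5), (10.0, 0.5, 5.0), (10.0, 0.0, 0.0)],
)
def test_cluster_concentration(k, lat, expected):
    assert cluster_concentration(k, lat) == expected


@pytest.mark.parametrize("bad_k", [0.0, -1.0])
def test_cluster_concentration_rejects_nonpositive_k(bad_k):
    with pytest.raises(ParameterError):
        cluster_concentration(bad_k, 0.5)


# --- equilibrium binding partitions ---------------------------------------


def test_zap70_partition_no_binding_limit():
    total, bound, free, f = zap70_partition(10.0, 1.0, 0.0)
    assert (total, bound, free, f) == (1.0, 0.0, 1.0, 0.0)


def test_zap70_partition_matches_exact_rational_arithmetic():
    # bound = lat * zap * KA / (1 + zap * KA), evaluated with Fractions
    lat, zap, ka = Fraction(10), Fraction(1), Fraction(10)
    exact_bound = lat * zap * ka / (1 + zap * ka)
    total, bound, free, f = zap70_partition(10.0, 1.0, 10.0)
    assert bound == pytest.approx(float(exact_bound), rel=1e-15)
    assert free == 1.0
    assert total == pytest.approx(float(exact_bound + 1), rel=1e-15)
    assert f == pytest.approx(float(zap * ka / (1 + zap * ka)), rel=1e-15)


def test_zap70_partition_saturation_limit():
    # KA -> infinity: every LAT carries a Zap70, bound -> [LAT]
    _, bound, _, f = zap70_partition(10.0, 1.0, 1e12)
    assert bound == pytest.approx(10.0, rel=1e-9)
    assert f == pytest.approx(1.0, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    lat=st.floats(0, 100),
    zap=st.floats(0, 10),
    ka1=st.floats(0, 1e3),
    ka2=st.floats(0, 1e3),
)
def test_zap70_bound_monotone_in_ka_and_capped_by_lat(lat, zap, ka1, ka2):
    lo, hi = sorted((ka1, ka2))
    _, bound_lo, _, _ = zap70_partition(lat, zap, lo)
    _, bound_hi, _, _ = zap70_partition(lat, zap, hi)
    assert bound_lo <= bound_hi + 1e-12
    assert bound_hi <= lat + 1e-9 * max(lat, 1.0)


@pytest.mark.parametrize(
    "plat, src, ka, expected",
    [(0.0, 1.0, 5.0, (0.0, 1.0)), (2.0, 1.0, 1.0, (1.0, 1.0)),
     (2.0, 0.0, 1.0, (0.0, 0.0))],
)
def test_src_partition(plat, src, ka, expected):
    active, inactive = src_partition(plat, src, ka)
    assert active == pytest.approx(expected[0], abs=1e-15)
    assert inactive == expected[1]


# --- PP2 non-competitive scaling ------------------------------------------


@pytest.mark.parametrize(
    "kcat, ki, pp2, expected",
    [(3.0, 1.0, 0.0, 3.0), (3.0, 1.0, 1.0, 1.5), (3.0, 1.0, 1e12, 3e-12)],
)
def test_pp2_scale(kcat, ki, pp2, expected):
    assert pp2_scale(kcat, ki, pp2) == pytest.approx(expected, rel=1e-9)


def test_pp2_scale_rejects_zero_ki():
    with pytest.raises(ParameterError):
        pp2_scale(1.0, 0.0, 1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    ki=st.floats(1e-3, 1e3),
    d1=st.floats(0, 1e4),
    d2=st.floats(0, 1e4),
)
def test_pp2_scale_strictly_decreasing_and_half_at_ki(ki, d1, d2):
    lo, hi = sorted((d1, d2))
    assert pp2_scale(2.0, ki, ki) == 1.0  # exactly half-inhibited at [PP2]=K_I
    if hi > lo:
        assert pp2_scale(2.0, ki, hi) < pp2_scale(2.0, ki, lo)


# --- the right-hand side ---------------------------------------------------


def literal_rhs(y, p: ModelParameters, config: ScenarioConfig, light_on: bool):
    """Independent term-by-term transcription of the model equations.

    Written as a literal sum of each displayed reaction term, separately from
    the implementation, for oracle comparison.
    """
    eff = effective_parameters(p, config, light_on)
    K = eff.partition_k_light if (light_on and config.clusters_in_light) else 1.0
    ka = eff.ka_ilid_light if light_on else eff.ka_ilid_dark
    lat = K * eff.lat_total
    f = eff.zap70_cyt * ka / (1 + eff.zap70_cyt * ka)
    zap_mem = lat * f + eff.zap70_cyt

    pzap_m, pzap_c, pl_f, pl_b = y
    zap_n = zap_mem - pzap_m
    zap_nc = eff.zap70_cyt - pzap_c
    latn_f = (1 - f) * lat - pl_f
    latn_b = f * lat - pl_b

    scale = eff.ki_pp2 / (eff.ki_pp2 + eff.pp2)
    src_a = (pl_f + pl_b) * eff.src_cyt * eff.ka_sh2 / (1 + eff.src_cyt * eff.ka_sh2)
    src_i = eff.src_cyt

    term_fast = scale * eff.kcat_src_active * src_a * zap_n / (
        eff.km_src_active + zap_n
    )
    term_slow = scale * eff.kcat_src_inactive * src_i * zap_n / (
        eff.km_src_inactive + zap_n
    )
    d_pzap_m = term_fast + term_slow - eff.kdeph_zap70 * pzap_m

    d_pzap_c = (
        scale * eff.kcat_src_inactive * src_i * zap_nc
        / (eff.km_src_inactive + zap_nc)
        - eff.kdeph_zap70 * pzap_c
    )

    kinase = zap_mem if config.zap70_constitutive else pzap_m
    complex_pool = latn_b * (
        1.0 if config.zap70_constitutive else (pzap_m / zap_mem if zap_mem else 0.0)
    )
    d_pl_f = (
        eff.kcat_pzap70 * kinase * latn_f / (eff.km_pzap70 + latn_f)
        - eff.kdeph_lat * pl_f
    )
    d_pl_b = (
        eff.kcat_pzap70 * kinase * latn_b / (eff.km_pzap70 + latn_b)
        + eff.k_tethered * complex_pool
        - eff.kdeph_lat * pl_b
    )
    return np.array([d_pzap_m, d_pzap_c, d_pl_f, d_pl_b])


def test_rhs_pure_dephosphorylation(params):
    p = params.replace(
        kcat_src_active=0, kcat_src_inactive=0, kcat_pzap70=0, k_tethered=0
    )
    config = ScenarioConfig(name="ilid_drop")
    d = rhs(ModelState(plat_free=0.3), p, config, light_on=False)
    assert d[2] == pytest.approx(-p.kdeph_lat * 0.3, rel=1e-14)
    assert d[0] == d[1] == d[3] == 0.0


def test_rhs_kinase_dead_has_no_lat_gain(params, rng):
    """With the kinase-dead Zap70 scenario, pLAT only decays."""
    config = ScenarioConfig(name="zap70_kd", light_on=True)
    for _ in range(10):
        y = random_state_in_box(rng, params, config, True)
        d = rhs(y, params, config, True)
        assert d[2] == pytest.approx(-params.kdeph_lat * y[2], rel=1e-12, abs=1e-15)
        assert d[3] == pytest.approx(-params.kdeph_lat * y[3], rel=1e-12, abs=1e-15)


def test_rhs_matches_independent_oracle_on_random_draws(rng):
    """Implementation equals a literal transcription of each equation,
    term by term, to 1e-12 relative on 100 random draws."""
    names = ("ilid_drop", "ilid_only", "zap70_k362e", "zap70_kd", "lat_fff",
             "src_dsh2dsh3", "jurkat_no_recruitment")
    for i in range(100):
        p = random_params(rng)
        config = ScenarioConfig(name=names[i % len(names)])
        light = bool(i % 2)
        y = random_state_in_box(rng, p, config, light)
        got = rhs(y, p, config, light)
        want = literal_rhs(y, p, config, light)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)


def test_rhs_forward_invariance_of_physical_box(rng):
    """At full phosphorylation every derivative is <= 0; at zero
    phosphorylation every derivative is >= 0 (no pool can escape)."""
    for i in range(50):
        p = random_params(rng)
        config = ScenarioConfig(name="ilid_drop")
        light = bool(i % 2)
        pools = equilibrium_pools(p, config, light)
        top = np.array(
            [pools.zap70_mem_total, p.zap70_cyt, pools.lat_free_total,
             pools.lat_bound_total]
        )
        assert np.all(rhs(top, p, config, light) <= 1e-12)
        assert np.all(rhs(np.zeros(4), p, config, light) >= -1e-12)


def test_rhs_rejects_states_outside_pool_bounds(params):
    config = ScenarioConfig(name="ilid_drop")
    pools = equilibrium_pools(params, config, False)
    bad = ModelState(pzap70_mem=2 * pools.zap70_mem_total + 1)
    with pytest.raises(DomainError):
        rhs(bad, params, config, light_on=False)


# --- scenario parameter transforms at the model layer ----------------------


def test_effective_parameters_per_scenario(params):
    kd = effective_parameters(params, ScenarioConfig(name="zap70_kd"))
    assert kd.kcat_pzap70 == 0 and kd.k_tethered == 0

    fff = effective_parameters(params, ScenarioConfig(name="lat_fff"))
    assert fff.ka_sh2 == 0 and fff.kcat_pzap70 == 0 and fff.k_tethered == 0

    dsh2 = effective_parameters(params, ScenarioConfig(name="src_dsh2dsh3"))
    assert dsh2.ka_sh2 == 0
    assert dsh2.kcat_src_inactive == pytest.approx(10 * params.kcat_src_inactive)
    assert dsh2.src_cyt == pytest.approx(0.1 * params.src_cyt)

    k362e = effective_parameters(params, ScenarioConfig(name="zap70_k362e"))
    assert k362e.kcat_pzap70 == pytest.approx(0.1 * params.kcat_pzap70)
    assert k362e.km_pzap70 == pytest.approx(10 * params.km_pzap70)

    jk = effective_parameters(params, ScenarioConfig(name="jurkat_no_recruitment"))
    assert jk.ka_ilid_dark == 0 and jk.ka_ilid_light == 0

    assert effective_parameters(params, ScenarioConfig(name="ilid_drop")) == params


def test_partition_k_applies_only_to_lit_clustering_constructs(params):
    for name, lit_k in [("ilid_drop", 10.0), ("ilid_only", 1.0),
                        ("zap70_k362e", 1.0), ("jurkat_no_recruitment", 10.0)]:
        config = ScenarioConfig(name=name)
        assert equilibrium_pools(params, config, False).partition_k == 1.0
        assert equilibrium_pools(params, config, True).partition_k == lit_k
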