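import numpy as np
import pytest

from clusterfb import LightProtocol, ModelParameters, ScenarioConfig


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The package's calibrated default parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def protocol() -> LightProtocol:
    return LightProtocol()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210622)


def random_params(rng: np.random.Generator) -> ModelParameters:
    """A random but physically plausible parameter draw (log-uniform around
    the defaults) for oracle and invariance tests."""
    d = ModelParameters().to_dict()

    def jitter(key, lo=0.25, hi=4.0):
        d[key] = d[key] * float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for key in (
        "lat_total", "zap70_cyt", "src_cyt", "ka_sh2", "kcat_src_active",
        "km_src_active", "kcat_src_inactive", "km_src_inactive",
        "kdeph_zap70", "kcat_pzap70", "km_pzap70", "k_tethered",
        "kdeph_lat", "ki_pp2",
    ):
        jitter(key)
    jitter("ka_ilid_dark", 0.5, 2.0)
    d["ka_ilid_light"] = max(d["ka_ilid_dark"], 10.0 * d["ka_ilid_light"] / 10.0)
    d["pp2"] = float(rng.uniform(0.0, 2.0))
    d["partition_k_light"] = float(rng.uniform(1.0, 20.0))
    return ModelParameters.from_dict(d)


def random_state_in_box(
    rng: np.random.Generator, params: ModelParameters, config: ScenarioConfig,
    light_on: bool,
) -> np.ndarray:
    """A random state drawn uniformly inside the physical pool bounds."""
    from clusterfb import equilibrium_pools

    pools = equilibrium_pools(params, config, light_on)
    caps = np.array(
        [
            pools.zap70_mem_total,
            params.zap70_cyt,
            pools.lat_free_total,
            pools.lat_bound_total,
        ]
    )
    return caps * rng.uniform(0.0, 1.0, size=4)
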