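"""Synthetic biosensor traces, membrane images, and noisy model readouts.

Every generator is a pure function of its spec (seed included): a fixed seed
regenerates byte-identical output.  The generators emulate the statistical
structure the quantification code assumes -- sustained calcium responders,
transient single-frame "blinkers" and non-responders sampled every 5 s over
3 min; KTR cytoplasm/nucleus pairs sampled every 15 s over 15 min (61
points); membrane-plane images before/after punctate cluster formation; and
noisy steady-state model readouts for parameter-recovery studies.

Fluorescence noise is multiplicative log-normal (intensities stay positive
and noise scales with signal); trace shapes (rise times, plateau levels) are
synthetic conventions chosen to match the described kinetics (calcium
maximal in 2-3 min, Erk within 10 min), not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, ParameterError
from .quantify import CellTrace, MaskedStack
from .scenarios import pp2_titration

__all__ = [
    "SynthSpec",
    "gen_gcamp_traces",
    "gen_ktr_traces",
    "gen_cluster_images",
    "gen_noisy_readouts",
    "traces_to_frame",
]

_DEFAULT_IMAGE = {
    "shape": (64, 64),
    "n_clusters": 20,
    "cluster_amplitude": 5.0,
    "cluster_sigma": 1.5,
    "mask_radius": 24,
}


@dataclass(frozen=True)
class SynthSpec:
    """Specification for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_cells: int = 100
    responder_fraction: float = 0.3
    blinker_fraction: float = 0.3
    noise_sd: float = 0.05
    dt: float = 5.0
    duration: float = 180.0
    image: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ParameterError("seed must be an integer (no implicit entropy)")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.responder_fraction < 0 or self.blinker_fraction < 0:
            raise ParameterError("fractions must be >= 0")
        if self.responder_fraction + self.blinker_fraction > 1:
            raise ParameterError("responder_fraction + blinker_fraction must be <= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ParameterError("dt and duration must be > 0")
        merged = dict(_DEFAULT_IMAGE)
        unknown = set(self.image) - set(merged)
        if unknown:
            raise ParameterError(f"unknown image spec keys: {sorted(unknown)}")
        merged.update(self.image)
        object.__setattr__(self, "image", merged)

    @property
    def n_points(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dt


def _lognormal_noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    # unit-mean multiplicative log-normal
    return rng.lognormal(mean=-0.5 * sd**2, sigma=sd, size=shape)


def _labels(spec: SynthSpec, rng: np.random.Generator) -> list[str]:
    n_resp = int(round(spec.responder_fraction * spec.n_cells))
    n_blink = int(round(spec.blinker_fraction * spec.n_cells))
    n_blink = min(n_blink, spec.n_cells - n_resp)
    labels = (
        ["responder"] * n_resp
        + ["blinker"] * n_blink
        + ["nonresponder"] * (spec.n_cells - n_resp - n_blink)
    )
    rng.shuffle(labels)
    return labels


def gen_gcamp_traces(
    spec: SynthSpec,
    *,
    baseline: float = 100.0,
    background: float = 10.0,
    response_amplitude: float = 3.0,
) -> tuple[list[CellTrace], list[str]]:
    """Labeled Jurkat-style GCaMP traces (default: 5 s interval over 3 min).

    Responders rise sigmoidally to a plateau held for the rest of the
    recording (well over 30 s); blinkers show one or two isolated
    single-sample spikes; non-responders stay at baseline.  Returns the raw
    traces (baseline + background, multiplicative log-normal noise) and the
    ground-truth label per cell.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.time
    labels = _labels(spec, rng)
    traces: list[CellTrace] = []
    for i, label in enumerate(labels):
        shape = np.ones_like(t)
        if label == "responder":
            # calcium reaches maximum within ~2-3 min: onset 20-60 s,
            # ~15 s rise, plateau held to the end of the recording
            t0 = rng.uniform(20.0, 60.0)
            shape = 1.0 + response_amplitude / (1.0 + np.exp(-(t - t0) / 8.0))
        elif label == "blinker":
            n_spikes = rng.integers(1, 3)
            candidates = np.arange(2, len(t) - 2)
            idx = rng.choice(candidates, size=n_spikes, replace=False)
            # keep spikes isolated so runs never span two frames
            idx = idx[np.argsort(idx)]
            keep = [idx[0]]
            for j in idx[1:]:
                if j - keep[-1] > 2:
                    keep.append(j)
            shape[np.array(keep)] += response_amplitude
        noise = _lognormal_noise(rng, spec.noise_sd, len(t))
        value = background + baseline * shape * noise
        traces.append(
            CellTrace(
                cell_id=f"cell{i:04d}",
                time=t,
                value=value,
                background=background,
                channel="gcamp",
            )
        )
    return traces, labels


def _ktr_ratio_shape(t: np.ndarray, plateau: float, tau: float) -> np.ndarray:
    return 1.0 + (plateau - 1.0) * (1.0 - np.exp(-t / tau))


def gen_ktr_traces(
    spec: SynthSpec | None = None,
    *,
    plateau: float = 3.0,
    tau: float = 150.0,
    baseline: float = 200.0,
    background: float = 20.0,
) -> tuple[list[tuple[CellTrace, CellTrace]], list[str], np.ndarray]:
    """KTR cytoplasm/nucleus trace pairs with analytic ground-truth AUCs.

    Default protocol: 61 points at 15 s (15 min).  Responder C/N ratio rises
    exponentially from 1 toward ``plateau`` with timescale ``tau`` (maximal
    within ~10 min); non-responders stay at 1.  Returns (pairs, labels,
    true_aucs) where the true AUC is the baselined plain sum of the
    noiseless ratio.
    """
    if spec is None:
        spec = SynthSpec(seed=0, dt=15.0, duration=900.0)
    rng = np.random.default_rng(spec.seed)
    t = spec.time
    n_resp = int(round(spec.responder_fraction * spec.n_cells))
    labels = ["responder"] * n_resp + ["nonresponder"] * (spec.n_cells - n_resp)
    rng.shuffle(labels)
    pairs: list[tuple[CellTrace, CellTrace]] = []
    true_aucs = np.empty(spec.n_cells)
    for i, label in enumerate(labels):
        ratio = (
            _ktr_ratio_shape(t, plateau, tau)
            if label == "responder"
            else np.ones_like(t)
        )
        true_aucs[i] = float(np.sum(ratio - ratio[0]))
        nuc_noise = _lognormal_noise(rng, spec.noise_sd, len(t))
        cyt_noise = _lognormal_noise(rng, spec.noise_sd, len(t))
        nuc = background + baseline * nuc_noise
        cyt = background + baseline * ratio * cyt_noise
        pairs.append(
            (
                CellTrace(f"cell{i:04d}", t, cyt, background, "ktr_cyto"),
                CellTrace(f"cell{i:04d}", t, nuc, background, "ktr_nuc"),
            )
        )
    return pairs, labels, true_aucs


def gen_cluster_images(
    spec: SynthSpec, *, base_intensity: float = 100.0
) -> tuple[MaskedStack, MaskedStack]:
    """Membrane-plane image pair before and after cluster formation.

    Pre-frames are uniform membrane intensity with multiplicative noise;
    post-frames redistribute the same total masked intensity into Gaussian
    puncta (conserving the masked sum exactly), so the change in CV isolates
    spatial reorganization rather than a brightness change.
    """
    rng = np.random.default_rng(spec.seed)
    img = spec.image
    ny, nx = img["shape"]
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= img["mask_radius"] ** 2

    pre = base_intensity * _lognormal_noise(rng, spec.noise_sd, (ny, nx))

    spots = np.zeros((ny, nx))
    sig = img["cluster_sigma"]
    n_clusters = int(img["n_clusters"])
    if n_clusters > 0:
        inside = np.argwhere(mask)
        centers = inside[rng.choice(len(inside), size=n_clusters, replace=False)]
        for (py, px) in centers:
            spots += np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sig**2))
    structure = 1.0 + img["cluster_amplitude"] * spots
    post = base_intensity * structure * _lognormal_noise(rng, spec.noise_sd, (ny, nx))
    # conserve the total masked intensity exactly: redistribution, not addition
    post[mask] *= pre[mask].sum() / post[mask].sum()

    return (
        MaskedStack(frames=pre[None], membrane_mask=mask),
        MaskedStack(frames=post[None], membrane_mask=mask),
    )


def gen_noisy_readouts(
    params: ModelParameters,
    scenario: str,
    doses: Sequence[float],
    noise_sd: float,
    seed: int,
    overrides: Mapping[str, Any] | None = None,
    response=None,
) -> pd.DataFrame:
    """Noisy steady-state pLAT dose-response observations from the model.

    Model outputs are perturbed by multiplicative Gaussian noise
    (1 + noise_sd * N) and truncated to [0, 1].  The returned table carries
    the noiseless truth per dose and the ground-truth parameters in
    ``DataFrame.attrs``.  A precomputed noiseless ``response`` (from
    :func:`clusterfb.scenarios.pp2_titration` on the same dose grid) may be
    passed to avoid re-solving the model across replicates.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if response is None:
        response = pp2_titration(doses, params, scenario=scenario,
                                 overrides=overrides)
    elif len(response.pp2_concs) != len(doses) or not np.allclose(
        response.pp2_concs, np.asarray(doses, float)
    ):
        raise ParameterError("precomputed response does not match the dose grid")
    observed = response.plat_frac * (1.0 + noise_sd * rng.standard_normal(len(doses)))
    observed = np.clip(observed, 0.0, 1.0)
    df = pd.DataFrame(
        {
            "pp2_um": response.pp2_concs,
            "observed": observed,
            "true_plat_frac": response.plat_frac,
        }
    )
    df.attrs["true_ki_pp2"] = params.ki_pp2
    df.attrs["scenario"] = scenario
    df.attrs["seed"] = seed
    df.attrs["noise_sd"] = noise_sd
    return df


def traces_to_frame(
    traces: Sequence[CellTrace], field_id: str = "field00"
) -> pd.DataFrame:
    """Tidy long-format table (cell_id, field_id, channel, time_s, value,
    background) for a collection of traces."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "field_id": field_id,
                "channel": tr.channel,
                "time_s": tr.time,
                "value": tr.value,
                "background": np.broadcast_to(
                    np.asarray(tr.background, float), tr.time.shape
                ),
            }
        )
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)
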