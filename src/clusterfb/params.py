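"""Parameter sets and scenario configurations for the clustering-feedback model.

The model tracks three proteins -- the scaffold LAT, its kinase Zap70, and an
Src-family kinase (SFK) -- in two well-mixed compartments: a membrane/cluster
compartment holding LAT and everything bound to it, and a cytosol holding free
Zap70 and Src.  Light does two things: it tightens the iLID/SspB association
that tethers Zap70 to LAT, and (in clustering constructs) shrinks the membrane
compartment volume by a partition coefficient K, concentrating LAT and all
LAT-bound species K-fold.

Concentrations are in µM, time in seconds.  Association constants are in
1/µM (so K_D = 1/KA in µM).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "ParameterError",
]


class ParameterError(ValueError):
    """Invalid parameter value or malformed parameter/config mapping."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate/binding constants and species totals of the kinetic model.

    Defaults are the package's calibrated wild-type set.  The binding
    constants follow the measured affinities of the optogenetic parts:
    the lit iLID-SspB pair binds with K_D ~ 0.1 µM and light tightens the
    dissociation constant ~100-fold, and the Src SH2/phosphotyrosine
    interaction has K_D ~ 1 µM.
    """

    #: total LAT referred to the unclustered membrane compartment (µM)
    lat_total: float = 1.0
    #: cytosolic Zap70, held constant (µM)
    zap70_cyt: float = 0.3
    #: cytosolic Src, held constant (µM)
    src_cyt: float = 0.05
    #: iLID/SspB association constant in the dark (1/µM)
    ka_ilid_dark: float = 0.1
    #: iLID/SspB association constant under blue light (1/µM)
    ka_ilid_light: float = 10.0
    #: SH2/pY association constant for Src binding pLAT (1/µM)
    ka_sh2: float = 1.0
    #: catalytic rate of active (pLAT-bound) Src on Zap70 (1/s)
    kcat_src_active: float = 5.2
    #: Michaelis constant of active Src for Zap70 (µM)
    km_src_active: float = 10.0
    #: catalytic rate of autoinhibited (free) Src on Zap70 (1/s)
    kcat_src_inactive: float = 0.002
    #: Michaelis constant of inactive Src for Zap70 (µM)
    km_src_inactive: float = 0.02
    #: first-order Zap70 dephosphorylation rate (1/s)
    kdeph_zap70: float = 0.1
    #: catalytic rate of pZap70 on LAT (1/s)
    kcat_pzap70: float = 8.0
    #: Michaelis constant of pZap70 for LAT (µM)
    km_pzap70: float = 100.0
    #: first-order phosphorylation rate of iLID-tethered LAT by bound pZap70 (1/s)
    k_tethered: float = 0.05
    #: first-order LAT dephosphorylation rate (1/s)
    kdeph_lat: float = 0.05
    #: non-competitive inhibition constant of PP2 on Src (µM)
    ki_pp2: float = 1.0
    #: ambient PP2 concentration (µM)
    pp2: float = 0.0
    #: lit-state partition coefficient K (fold-concentration of LAT, >= 1)
    partition_k_light: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "lat_total", "zap70_cyt", "src_cyt", "ka_ilid_dark", "ka_ilid_light",
            "ka_sh2", "kcat_src_active", "km_src_active", "kcat_src_inactive",
            "km_src_inactive", "kdeph_zap70", "kcat_pzap70", "km_pzap70",
            "k_tethered", "kdeph_lat", "ki_pp2", "pp2", "partition_k_light",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ParameterError(f"{name} must be a number, got {v!r}")
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        if self.partition_k_light < 1:
            raise ParameterError(
                f"partition_k_light must be >= 1, got {self.partition_k_light}"
            )
        if self.ka_ilid_light < self.ka_ilid_dark:
            raise ParameterError(
                "ka_ilid_light must be >= ka_ilid_dark (light tightens binding): "
                f"{self.ka_ilid_light} < {self.ka_ilid_dark}"
            )
        if self.ki_pp2 == 0:
            raise ParameterError("ki_pp2 must be > 0")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (validates)."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter field(s): {sorted(unknown)}; "
                f"valid fields: {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in data.items()})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParameters":
        return cls.from_dict(_load_mapping(source, json.loads))

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ModelParameters":
        return cls.from_dict(_load_mapping(source, yaml.safe_load))


#: supported scenario names, mirroring the experimental regimes
SCENARIO_NAMES = (
    "ilid_drop",
    "ilid_only",
    "zap70_k362e",
    "zap70_kd",
    "lat_fff",
    "src_dsh2dsh3",
    "jurkat_no_recruitment",
)

#: scenarios whose construct clusters LAT under illumination (K > 1 when lit)
_CLUSTERING = frozenset(
    {"ilid_drop", "zap70_kd", "lat_fff", "src_dsh2dsh3", "jurkat_no_recruitment"}
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Which experimental-regime modifications and light state apply.

    The scenario name deterministically selects a set of equation
    modifications (see :func:`clusterfb.scenarios.apply_scenario`); the
    factor fields parameterize modifications whose magnitudes the model
    leaves free:

    * ``zap70_k362e`` -- a weakly constitutively active Zap70: both phospho-
      forms phosphorylate LAT, with kcat scaled down by ``k362e_kcat_factor``
      and KM scaled up by ``k362e_km_factor``; simulated in the non-clustering
      (iLID-Only) configuration.
    * ``src_dsh2dsh3`` -- feedback-disconnected Src: SH2 binding to pLAT is
      abolished, free-Src activity is boosted by ``dsh2_kcat_free_factor``
      and total Src reduced by ``dsh2_src_conc_factor``.
    * ``jurkat_no_recruitment`` -- LAT clustering without direct Zap70
      recruitment (no iLID tether); phospho-Zap70 pools start at
      ``basal_pzap70_frac`` of their totals.
    """

    name: str = "ilid_drop"
    light_on: bool = False
    k362e_kcat_factor: float = 0.1
    k362e_km_factor: float = 10.0
    dsh2_kcat_free_factor: float = 10.0
    dsh2_src_conc_factor: float = 0.1
    basal_pzap70_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ParameterError(
                f"unknown scenario {self.name!r}; valid names: {list(SCENARIO_NAMES)}"
            )
        if not (0 < self.k362e_kcat_factor < 1):
            raise ParameterError("k362e_kcat_factor must be in (0, 1)")
        if self.k362e_km_factor <= 1:
            raise ParameterError("k362e_km_factor must be > 1")
        if self.dsh2_kcat_free_factor <= 1:
            raise ParameterError("dsh2_kcat_free_factor must be > 1")
        if not (0 < self.dsh2_src_conc_factor < 1):
            raise ParameterError("dsh2_src_conc_factor must be in (0, 1)")
        if not (0 <= self.basal_pzap70_frac <= 1):
            raise ParameterError("basal_pzap70_frac must be in [0, 1]")

    @property
    def clusters_in_light(self) -> bool:
        """Whether K rises above 1 under illumination for this construct."""
        return self.name in _CLUSTERING

    @property
    def zap70_constitutive(self) -> bool:
        """Whether unphosphorylated Zap70 also phosphorylates LAT (K362E)."""
        return self.name == "zap70_k362e"

    def with_light(self, light_on: bool) -> "ScenarioConfig":
        return dataclasses.replace(self, light_on=light_on)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown scenario-config field(s): {sorted(unknown)}; "
                f"valid fields: {sorted(known)}"
            )
        return cls(**dict(data))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScenarioConfig":
        return cls.from_dict(_load_mapping(source, json.loads))

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ScenarioConfig":
        return cls.from_dict(_load_mapping(source, yaml.safe_load))


def _load_mapping(source: str | Path, parse) -> Mapping[str, Any]:
    def _is_path(s):
        try:
            return "\n" not in s and Path(s).is_file()
        except OSError:
            return False

    if isinstance(source, Path) or (isinstance(source, str) and _is_path(source)):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = parse(text)
    if not isinstance(data, Mapping):
        raise ParameterError(f"expected a mapping, got {type(data).__name__}")
    return data
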