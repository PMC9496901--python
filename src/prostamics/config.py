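"""Pipeline configuration: one YAML-serializable object for a full run.

Every analysis knob lives here — grid, ring thickness, feature toggles,
AIF constants, fit options, onset-detection rule, selection thresholds,
LOO mode, and seeds — and every artifact a run writes records the
configuration hash, so each numeric output is traceable to a
(config, seed) pair.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dce import ParkerAif
from .preprocess import GridSpec
from .synthetic import CohortSpec, LabelModel, PhantomSpec, TissueClass

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    aif: ParkerAif = field(default_factory=ParkerAif)
    ring_thickness_mm: float = 5.0
    pz_tolerance_frac: float = 0.01
    min_voxels: int = 10
    include_min_max: bool = True
    resample_dce: bool = True
    onset_k_sd: float = 3.0
    onset_n_consecutive: int = 2
    fit_polish: bool = True
    fit_dt_fine: float = 0.5
    vp_max: float = 0.3
    p_pass: float = 0.05
    r_max: float = 0.85
    max_k: int = 4
    nested_loo: bool = False
    threshold: float = 0.5
    write_volumes: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tissue_params(d: dict) -> dict[str, TissueClass]:
    return {
        cls: TissueClass(**{k: tuple(v) if isinstance(v, list) else v for k, v in tp.items()})
        for cls, tp in d.items()
    }


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "phantom" in d:
        ph = _tuplify(d["phantom"], ("grid_shape", "spacing_mm", "prostate_radius_mm"))
        if "tissue_params" in ph:
            ph["tissue_params"] = _tissue_params(ph["tissue_params"])
        d["phantom"] = PhantomSpec(**ph)
    if "cohort" in d:
        co = _tuplify(d["cohort"], ("scan_points",))
        if "label_model" in co:
            co["label_model"] = LabelModel(**co["label_model"])
        if "trajectories" in co:
            co["trajectories"] = {
                cls: {p: tuple(m) for p, m in params.items()}
                for cls, params in co["trajectories"].items()
            }
        d["cohort"] = CohortSpec(**co)
    if "grid" in d:
        d["grid"] = GridSpec(**d["grid"])
    if "aif" in d:
        d["aif"] = ParkerAif(**_tuplify(d["aif"], ("A", "T", "sigma")))
    return PipelineConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
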