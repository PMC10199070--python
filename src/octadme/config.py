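"""Pipeline configuration: YAML-backed, strict about unknown keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .magnification import DEFAULT_ASSUMED_AXIAL_LENGTH_MM


@dataclass
class Thresholds:
    binarize: float = 0.5
    signal: float = 50.0
    vd: float = 0.1
    ldl: float = 2.6
    excellent_bcva: float = 70.0
    alpha_stay: float = 0.05


#: predictors screened by `octadme analyze` unless the config lists its own
DEFAULT_PREDICTORS = [
    "age", "male", "dm_type1", "insulin_use", "hypertension", "lipid_therapy",
    "smoking", "stroke", "mi", "pseudophakic", "prior_prp", "prior_anti_vegf",
    "prior_steroid", "prior_vitrectomy", "hba1c", "egfr", "creatinine",
    "ldl_ge_26", "hdl_mmol_l", "microaneurysm_class", "exudates",
    "leakage_pattern", "peripheral_nonperfusion", "srf", "inl_cysts",
    "onl_cysts", "dril", "intact_elm_ez", "hrf", "intact_terminal_ring",
    "perifoveal_capillary_loss", "vd",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    assumed_axial_length_mm: float = DEFAULT_ASSUMED_AXIAL_LENGTH_MM
    max_bridge_px: int = 2
    group_var: str = "vd_ge_01"
    n_patients: int = 48
    p_second_eye: float = 28.0 / 48.0
    n_angiograms: int | None = None  # default: one per simulated eye
    angiogram_shape: tuple[int, int] = (256, 256)
    vessel_width_px: int = 2
    noise_sd: float = 0.05
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    out_dir: str = "octadme_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            tdict = kwargs["thresholds"]
            tknown = {f.name for f in fields(Thresholds)}
            tunknown = set(tdict) - tknown
            if tunknown:
                raise ValueError(f"unknown threshold keys: {sorted(tunknown)}")
            kwargs["thresholds"] = Thresholds(**tdict)
        if "angiogram_shape" in kwargs:
            kwargs["angiogram_shape"] = tuple(kwargs["angiogram_shape"])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        """Config as a plain dict (echoed into the run manifest)."""
        return asdict(self)
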