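"""File formats: 16-bit grayscale images + JSON sidecars, cohort CSVs,
and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometrics import EnFaceAngiogram
from .synth.angiogram import AngiogramTruth

EYES_REQUIRED_COLUMNS = ("patient_id", "eye")
VISITS_REQUIRED_COLUMNS = ("patient_id", "eye", "month", "bcva_letters",
                           "crt1_um", "crt3_um", "crt6_um")


class SchemaError(ValueError):
    """Input table violates the expected schema."""


def write_angiogram(
    base: str | Path, angiogram: EnFaceAngiogram, truth: AngiogramTruth | None = None
) -> tuple[Path, Path]:
    """Write ``<base>.png`` (16-bit grayscale) and ``<base>.json`` sidecar."""
    base = Path(base)
    png = base.with_suffix(".png")
    iio.imwrite(png, np.round(angiogram.pixels * 65535).astype(np.uint16))
    sidecar = {
        "nominal_scan_width_mm": angiogram.nominal_scan_width_mm,
        "signal_strength": angiogram.signal_strength,
        "axial_length_mm": angiogram.axial_length_mm,
        "eye_id": angiogram.eye_id,
    }
    if truth is not None:
        (center, axes, rot) = truth.faz_ellipse
        sidecar["truth"] = {
            "true_skeleton_density": truth.true_skeleton_density,
            "faz_center_px": list(center),
            "faz_semi_axes_px": list(axes),
            "faz_rotation_rad": rot,
            "vessel_width_px": truth.vessel_width_px,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
        }
    meta = base.with_suffix(".json")
    meta.write_text(json.dumps(sidecar, indent=1))
    return png, meta


def read_angiogram(png_path: str | Path) -> EnFaceAngiogram:
    """Read an image + sidecar pair; pixel values are rescaled to [0, 1]."""
    png_path = Path(png_path)
    sidecar_path = png_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = iio.imread(png_path)
    if raw.ndim == 3:  # collapse any accidental channel axis
        raw = raw[..., 0]
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    pixels = raw.astype(float) / (info.max if info else 1.0)
    return EnFaceAngiogram(
        pixels=np.clip(pixels, 0.0, 1.0),
        nominal_scan_width_mm=meta.get("nominal_scan_width_mm", 3.0),
        signal_strength=meta.get("signal_strength"),
        axial_length_mm=meta.get("axial_length_mm"),
        eye_id=meta.get("eye_id"),
    )


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def write_cohort(out_dir: str | Path, eyes: pd.DataFrame, visits: pd.DataFrame) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eyes_path, visits_path = out / "eyes.csv", out / "visits.csv"
    eyes.to_csv(eyes_path, index=False)
    visits.to_csv(visits_path, index=False)
    return {"eyes": eyes_path, "visits": visits_path}


def read_eyes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EYES_REQUIRED_COLUMNS, "eyes table")
    if df.duplicated(subset=["patient_id", "eye"]).any():
        bad = df[df.duplicated(subset=["patient_id", "eye"], keep=False)]
        raise SchemaError(f"duplicate (patient_id, eye) rows:\n{bad[['patient_id', 'eye']]}")
    return df


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, VISITS_REQUIRED_COLUMNS, "visits table")
    bad = df[~df["month"].between(0, 6) | (df[["crt1_um", "crt3_um", "crt6_um"]] <= 0).any(axis=1)]
    if len(bad):
        raise SchemaError(f"invalid visit rows (month outside 0..6 or CRT <= 0):\n{bad}")
    return df


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            digest.update(block)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Audit record: config snapshot, artifact hashes, per-eye exclusions."""

    config: dict
    version: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def exclude(self, eye_id: str, reason: str) -> None:
        self.exclusions.append({"eye": eye_id, "reason": reason})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=str))
        return path
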