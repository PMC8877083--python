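"""NIfTI / CSV / YAML input-output and run configuration."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, SchemaError


def write_nifti(path, volume: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    affine = np.diag(list(spacing) + [1.0]).astype(float)
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_nifti(path):
    """Read a NIfTI volume; returns ``(array, spacing, origin)``."""
    p = Path(path)
    if not p.exists():
        raise ParameterError(f"no such file: {p}")
    img = nib.load(str(p))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ParameterError(f"{p}: non-positive voxel spacing in header")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, spacing, origin


def read_mask(path):
    """Read a binary mask; nonzero values are coerced to 1 with a warning."""
    data, spacing, origin = read_nifti(path)
    vals = np.unique(data)
    if not set(vals.tolist()) <= {0.0, 1.0}:
        warnings.warn(f"{path}: mask values {vals[:5]} coerced to {{0,1}}", stacklevel=2)
    return (data > 0).astype(np.uint8), spacing, origin


def write_features(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest: one row per patient with the final response label.

    Required columns: patient_id (unique), label in {R, NR}. Optional:
    early_recist, per-modality file paths, delta_volume.
    """
    df = pd.read_csv(path)
    if "patient_id" not in df.columns or "label" not in df.columns:
        raise SchemaError("manifest needs 'patient_id' and 'label' columns")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id in manifest: {dup}")
    if df["label"].isna().any():
        raise SchemaError("manifest label missing for some patients")
    bad = set(df["label"].unique()) - {"R", "NR"}
    if bad:
        raise SchemaError(f"labels must be R/NR, got {bad}")
    return df.set_index("patient_id")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (validated on construction)."""

    out_dir: str = "deltarad_out"
    # cohort
    n_patients: int = 50
    responder_fraction: float = 0.5
    effect_size: float = 1.5
    n_informative: int = 54
    missing_adc_fraction: float = 0.32
    volume_change: tuple[float, float] = (-0.4, -0.05)
    noise_sd: float = 1.0
    seed: int = 0
    source: str = "synthetic-features"  # or "synthetic-images"
    # features
    n_bins: int = 32
    wavelet: str = "coif1"
    target_spacing: float = 2.0
    # model
    alpha: float = 0.05
    var_threshold: float = 0.97
    fractions: tuple[float, float, float] = (0.55, 0.25, 0.20)
    n_reps: int = 25  # reduced-scale default; 100 for trial-faithful runs
    svm_C: float = 1.0
    modalities: tuple[str, ...] = ("t1w", "t2w", "adc")
    whitelists: dict = field(default_factory=dict)  # modality -> path of name list

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ParameterError("fractions must sum to 1")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.source not in ("synthetic-features", "synthetic-images"):
            raise ParameterError(f"unknown source {self.source!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        if "volume_change" in raw:
            raw["volume_change"] = tuple(raw["volume_change"])
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        return cls(**raw)
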