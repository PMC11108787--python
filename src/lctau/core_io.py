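"""Volumes, tables, configuration, seeds and run manifests.

Conventions used throughout the pipeline:

* voxel indexing is 0-based; the affine maps voxel indices (i, j, k, 1)
  to mm coordinates;
* inter-volume operations require matching shape and affine — there is no
  resampling anywhere in the package;
* all randomness flows from one root seed per run; sub-stage generators are
  derived deterministically with :func:`derive_rng`.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    MaskError,
    SchemaError,
    TableParseError,
    VolumeFormatError,
    VolumeMismatchError,
    VolumeShapeError,
)

__all__ = [
    "BrainVolume",
    "PipelineConfig",
    "ColumnSpec",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "derive_rng",
    "write_manifest",
]

_AFFINE_ATOL = 1e-6


@dataclass
class BrainVolume:
    """A 3-D scalar grid with an affine voxel-to-mm mapping.

    Carrier type for MRI slabs, SUVR maps, masks, z-maps and atlases.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeShapeError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise VolumeShapeError(f"degenerate shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise VolumeFormatError(
                f"affine must be 4x4, got {self.affine.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Column norms of the linear part of the affine."""
        m = self.affine[:3, :3]
        return tuple(float(np.linalg.norm(m[:, i])) for i in range(3))

    def is_mask(self) -> bool:
        vals = np.unique(self.data)
        return bool(np.all(np.isin(vals, (0, 1))))

    def require_mask(self) -> np.ndarray:
        """Return the boolean array, raising if values are not in {0, 1}."""
        if not self.is_mask():
            raise MaskError("mask contains values outside {0, 1}")
        return self.data.astype(bool)

    def check_compatible(self, other: "BrainVolume") -> None:
        if self.shape != other.shape:
            raise VolumeMismatchError(
                f"shape mismatch: {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.affine, other.affine, atol=_AFFINE_ATOL):
            raise VolumeMismatchError("affine mismatch between volumes")

    def with_data(self, data: np.ndarray) -> "BrainVolume":
        """New volume sharing this volume's affine."""
        return BrainVolume(np.asarray(data), self.affine.copy())


@dataclass
class PipelineConfig:
    """Tunable constants shared across pipeline stages."""

    voxel_z_threshold: float = 1.64
    cluster_alpha: float = 0.05
    n_mc_iterations: int = 10_000
    n_boot: int = 5_000
    n_perm: int = 10_000
    smoothing_fwhm_mm: float = 8.0
    top_fraction: float = 0.05
    sample_assign_max_dist_mm: float = 3.0
    abeta_cutoff_dvr: float = 1.324
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        for name in ("n_mc_iterations", "n_boot", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def read_volume(path: str | Path) -> BrainVolume:
    """Read a single-volume NIfTI-1 image.

    Raises :class:`VolumeFormatError` on malformed files and
    :class:`VolumeShapeError` on 4-D input.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except VolumeShapeError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeShapeError(
            f"{path}: expected 3-D single volume, got {data.ndim}-D"
        )
    return BrainVolume(data, np.asarray(img.affine))


def write_volume(vol: BrainVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; float64 on disk so round-trips are exact."""
    path = Path(path)
    data = vol.data
    if data.dtype.kind in "uib":
        on_disk = data.astype(np.int32)
    else:
        on_disk = data.astype(np.float64)
    img = nib.Nifti1Image(on_disk, vol.affine)
    nib.save(img, str(path))
    return path


@dataclass(frozen=True)
class ColumnSpec:
    """Declared column of a table schema."""

    name: str
    dtype: str = "float"  # float | int | str
    required: bool = True
    unit: str | None = None


def read_table(path: str | Path,
               schema: Sequence[ColumnSpec] | None = None) -> pd.DataFrame:
    """Read a delimited text table with a header row.

    The delimiter is taken from the extension (``.tsv`` → tab, else comma).
    Missing values stay as NaN; they are never dropped here. Numeric columns
    that contain unparseable text raise :class:`TableParseError` naming the
    offending rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if schema is None:
        return df
    for col in schema:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(
                    f"{path}: required column {col.name!r} is missing"
                )
            continue
        if col.dtype in ("float", "int"):
            raw = df[col.name]
            coerced = pd.to_numeric(raw, errors="coerce")
            bad = raw.notna() & coerced.isna()
            if bad.any():
                rows = df.index[bad].tolist()
                raise TableParseError(
                    f"{path}: non-numeric value(s) in column {col.name!r} "
                    f"at row(s) {rows}",
                    column=col.name,
                    rows=rows,
                )
            df[col.name] = coerced
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False)
    return path


def derive_rng(root_seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one root seed."""
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), tag]))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_manifest(out_dir: str | Path, *, stage: str,
                   config: PipelineConfig | None = None,
                   seed: int | None = None,
                   extra: Mapping[str, Any] | None = None) -> Path:
    """Write a run manifest embedding config and seed next to stage outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
        "extra": _jsonable(extra) if extra is not None else None,
    }
    path = out_dir / f"{stage}_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def json_dump(obj: Any, path: str | Path) -> Path:
    """JSON writer tolerant of numpy scalars/arrays and dataclasses."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
    return path
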