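"""Shared I/O: NIfTI volume panels, statistical maps, configs, manifests.

Conventions: voxel indices are 0-based; world coordinates come from the
NIfTI affine; micrometres for microscopy, millimetres for MRI.  Volume
files are named ``<subject>_day<day>.nii.gz``; subject metadata is a CSV
with columns ``id, group, tiv_mm3, days_present`` (days separated by
semicolons) and optionally ``learning_rate``.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .timecourse import (
    SESSION_DAYS,
    DEFAULT_VOXEL_SIZE_MM,
    SubjectRecord,
    VolumeSeries,
    VoxelFitMaps,
    cluster_volume,
)

__all__ = [
    "RunConfig",
    "volume_filename",
    "read_volume_series",
    "write_volume_series",
    "write_stat_maps",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Pipeline thresholds and geometry, serializable to YAML.

    Defaults are the study settings: 99th-percentile labeling cutoff of
    75/255, 2 um minimum labeled depth, 0.5 um border correction, 0.2
    tissue-probability mask threshold, FDR q, the AIC margin for
    preferred-model maps, and the decisive AICc margin.
    """

    seed: int = 0
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    spacing_um: tuple[float, float, float] = (0.48, 0.18, 0.18)
    session_days: tuple[float, ...] = SESSION_DAYS
    q99_cutoff: float = 75.0
    min_depth_um: float = 2.0
    border_correction_um: float = 0.5
    tpm_threshold: float = 0.2
    fdr_q: float = 0.05
    delta_aic: float = 10.0
    delta_aicc_decisive: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.tpm_threshold < 1):
            raise ValueError("tpm_threshold must lie in (0, 1)")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.q99_cutoff < 0 or self.q99_cutoff > 255:
            raise ValueError("q99_cutoff must lie in [0, 255]")
        if self.min_depth_um < 0 or self.border_correction_um < 0:
            raise ValueError("depths must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["spacing_um"] = list(d["spacing_um"])
        d["session_days"] = list(d["session_days"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["spacing_um"] = tuple(d["spacing_um"])
        d["session_days"] = tuple(d["session_days"])
        return cls(**d)


def volume_filename(subject_id: str, day: float) -> str:
    day_str = f"{day:g}"
    return f"{subject_id}_day{day_str}.nii.gz"


def _read_meta(meta_csv: str | Path) -> list[SubjectRecord]:
    meta = pd.read_csv(meta_csv)
    subjects = []
    for _, row in meta.iterrows():
        days = tuple(float(d) for d in str(row["days_present"]).split(";"))
        lr = row.get("learning_rate")
        subjects.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                tiv=float(row["tiv_mm3"]),
                days_present=days,
                learning_rate=None if lr is None or pd.isna(lr) else float(lr),
            )
        )
    return subjects


def read_volume_series(
    volumes_dir: str | Path,
    meta_csv: str | Path,
    session_days: Sequence[float] = SESSION_DAYS,
) -> tuple[VolumeSeries, list[SubjectRecord], np.ndarray]:
    """Assemble a panel from one NIfTI per subject-session plus metadata.

    A file absent from disk marks that subject-session missing rather
    than failing; a grid or affine mismatch is a hard error naming the
    offending file.  Returns ``(series, subjects, affine)``.
    """
    volumes_dir = Path(volumes_dir)
    subjects = _read_meta(meta_csv)
    days = tuple(float(d) for d in session_days)
    ref_shape = None
    ref_affine = None
    data = None
    missing = np.zeros((len(subjects), len(days)), dtype=bool)
    voxel_size = DEFAULT_VOXEL_SIZE_MM
    for i, subj in enumerate(subjects):
        for j, day in enumerate(days):
            path = volumes_dir / volume_filename(subj.id, day)
            if not path.exists():
                alt = path.with_suffix("").with_suffix(".nii")
                if alt.exists():
                    path = alt
                else:
                    missing[i, j] = True
                    continue
            img = nib.load(str(path))
            arr = np.asarray(img.dataobj, dtype=float)
            if ref_shape is None:
                ref_shape = arr.shape
                ref_affine = img.affine
                voxel_size = float(np.abs(img.affine[0, 0]))
                data = np.full((len(subjects), len(days)) + ref_shape, np.nan)
            if arr.shape != ref_shape:
                raise ValueError(
                    f"grid mismatch in {path.name}: {arr.shape} vs {ref_shape}"
                )
            if not np.allclose(img.affine, ref_affine, atol=1e-6):
                raise ValueError(f"affine mismatch in {path.name}")
            data[i, j] = arr
    if data is None:
        raise ValueError(f"no volumes found under {volumes_dir}")
    # sessions a subject never had (per metadata) are missing too
    for i, subj in enumerate(subjects):
        for j, day in enumerate(days):
            if day not in subj.days_present:
                missing[i, j] = True
    series = VolumeSeries(
        data=data, voxel_size=voxel_size, session_days=days, missing=missing
    )
    return series, subjects, ref_affine


def write_volume_series(
    series: VolumeSeries,
    subjects: Sequence[SubjectRecord],
    out_dir: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write one NIfTI per subject-session plus the metadata CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([series.voxel_size] * 3 + [1.0])
    for i, subj in enumerate(subjects):
        for j, day in enumerate(series.session_days):
            if series.missing[i, j]:
                continue
            img = nib.Nifti1Image(
                series.data[i, j].astype(np.float32), affine
            )
            nib.save(img, str(out_dir / volume_filename(subj.id, day)))
    rows = []
    for subj in subjects:
        rows.append(
            {
                "id": subj.id,
                "group": subj.group,
                "tiv_mm3": subj.tiv,
                "days_present": ";".join(f"{d:g}" for d in subj.days_present),
                "learning_rate": subj.learning_rate,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "meta.csv", index=False)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def cluster_table(
    maps: VoxelFitMaps,
) -> pd.DataFrame:
    """Connected-component table of significant voxels per shape and sign.

    Columns: shape, sign, label, n_voxels, volume_mm3 (via the voxel-size
    cube), peak_x/y/z (voxel indices of the largest |interaction|).
    """
    rows = []
    for (shape, sign), mask in maps.significant.items():
        labels, n_clusters = ndimage.label(mask, structure=_STRUCT_26)
        for lab in range(1, n_clusters + 1):
            sel = labels == lab
            count = int(sel.sum())
            b = np.where(sel, np.abs(maps.beta3[shape]), -np.inf)
            peak = np.unravel_index(np.nanargmax(b), b.shape)
            rows.append(
                {
                    "shape": shape,
                    "sign": sign,
                    "label": lab,
                    "n_voxels": count,
                    "volume_mm3": cluster_volume(count, maps.voxel_size),
                    "peak_x": int(peak[0]),
                    "peak_y": int(peak[1]),
                    "peak_z": int(peak[2]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "shape", "sign", "label", "n_voxels", "volume_mm3",
            "peak_x", "peak_y", "peak_z",
        ],
    )


def write_stat_maps(
    maps: VoxelFitMaps,
    out_dir: str | Path,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Write per-shape statistical maps (float32 NIfTI) and the cluster TSV.

    Returns the cluster table that was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([maps.voxel_size] * 3 + [1.0])

    def _save(arr, name):
        nib.save(
            nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
            str(out_dir / f"{name}.nii.gz"),
        )

    for shape in maps.shapes:
        _save(maps.beta3[shape], f"beta3_{shape}")
        _save(maps.pvalue[shape], f"p_{shape}")
        _save(maps.aic[shape], f"aic_{shape}")
        _save(maps.aicc[shape], f"aicc_{shape}")
    for (shape, sign), mask in maps.significant.items():
        _save(mask.astype(np.float32), f"sig_{shape}_{sign}")
    _save(maps.preferred.astype(np.float32), "preferred_model")
    table = cluster_table(maps)
    table.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    if len(maps.qc):
        maps.qc.to_csv(out_dir / "qc.tsv", sep="\t", index=False)
    return table


def write_manifest(out_dir: str | Path, config: object, seed: int) -> Path:
    """Write a run manifest (config hash, package versions, seed)."""
    import scipy
    import skimage

    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        cfg_dict = asdict(config)  # type: ignore[arg-type]
    else:
        cfg_dict = dict(config) if config is not None else {}
    blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "plastimap": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
        "units": {"mri": "mm", "microscopy": "um"},
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
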