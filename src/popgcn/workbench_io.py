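"""Readers, writers, reslicing, and run configuration.

On-disk layout of a cohort: a JSON manifest recording the generating spec and
file paths; a clinical CSV with the fixed header
``subject_id,label,age,education,mmse,cdrsb,gds,sgdeps`` (labels NC/MCI/AD,
encoded 0/1/2 in memory); an optional latent-feature CSV (subject_id + one
column per feature); optional one NIfTI volume per subject. All file indices
are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix

from .synthetic_cohort import CLINICAL_COLUMNS, Cohort, CohortSpec, LABELS

__all__ = [
    "RunConfig",
    "load_run_config",
    "write_cohort",
    "read_cohort",
    "reslice_volume",
    "write_adjacency",
    "write_features_csv",
]

_CSV_HEADER = ("subject_id", "label") + CLINICAL_COLUMNS


def write_cohort(cohort: Cohort, out_dir: str | Path, write_volumes: bool = True) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = cohort.clinical.copy()
    table.insert(0, "label", [LABELS[i] for i in cohort.labels])
    table.insert(0, "subject_id", cohort.subject_ids)
    clinical_path = out_dir / "clinical.csv"
    table.to_csv(clinical_path, index=False)
    manifest = {
        "clinical": clinical_path.name,
        "n_subjects": cohort.n,
        "spec": None if cohort.spec is None else asdict(cohort.spec),
    }
    if cohort.latent_features is not None:
        latent_path = out_dir / "latent_features.csv"
        lf = pd.DataFrame(
            cohort.latent_features,
            columns=[f"f{i}" for i in range(cohort.latent_features.shape[1])],
        )
        lf.insert(0, "subject_id", cohort.subject_ids)
        lf.to_csv(latent_path, index=False)
        manifest["latent_features"] = latent_path.name
    if write_volumes and cohort.volumes is not None:
        vol_dir = out_dir / "volumes"
        vol_dir.mkdir(exist_ok=True)
        paths = []
        for sid, vol in zip(cohort.subject_ids, cohort.volumes):
            p = vol_dir / f"{sid}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), p)
            paths.append(str(p.relative_to(out_dir)))
        manifest["volumes"] = paths
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from its manifest; volumes load lazily on first access."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    table = pd.read_csv(root / manifest["clinical"])
    missing = [c for c in _CSV_HEADER if c not in table.columns]
    if missing:
        raise ValueError(f"clinical CSV is missing required column(s): {missing}")
    extra = [c for c in table.columns if c not in _CSV_HEADER]
    if extra:
        warnings.warn(f"ignoring unknown clinical column(s): {extra}")
    bad = set(table["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"labels outside {LABELS}: {sorted(bad)}")
    labels = np.array([LABELS.index(l) for l in table["label"]])
    latent = None
    if "latent_features" in manifest:
        lf = pd.read_csv(root / manifest["latent_features"])
        latent = lf.drop(columns=["subject_id"]).to_numpy(dtype=float)
    volume_paths = None
    if "volumes" in manifest:
        volume_paths = [str(root / p) for p in manifest["volumes"]]
        for p in volume_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing volume file: {p}")
    spec = None
    if manifest.get("spec"):
        d = dict(manifest["spec"])
        for key in ("n_per_class", "volume_shape"):
            d[key] = tuple(d[key])
        spec = CohortSpec(**d)
    return Cohort(
        subject_ids=list(table["subject_id"]),
        labels=labels,
        clinical=table[list(CLINICAL_COLUMNS)].copy(),
        latent_features=latent,
        volume_paths=volume_paths,
        spec=spec,
    )


def reslice_volume(volume: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear reslice to ``target_shape`` on a center-aligned grid.

    Voxel centers of the target grid are mapped into source coordinates as
    ``src = (i + 0.5) * S / T - 0.5`` per axis, so the two grids share their
    physical extent; values are trilinearly interpolated (edge-clamped).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if any(s < 2 for s in volume.shape) or any(t < 2 for t in target_shape):
        raise ValueError("source and target shapes must be >= 2 per axis")
    grids = [
        (np.arange(t) + 0.5) * s / t - 0.5 for s, t in zip(volume.shape, target_shape)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    return map_coordinates(volume, coords, order=1, mode="nearest")


def write_adjacency(A: np.ndarray, path: str | Path, fmt: str = "mtx") -> Path:
    """Write an adjacency matrix as Matrix Market or 0-based triplet text."""
    path = Path(path)
    sparse = coo_matrix(A)
    if fmt == "mtx":
        mmwrite(str(path), sparse)
    elif fmt == "coo":
        with open(path, "w") as fh:
            fh.write("# i j weight (0-based)\n")
            for i, j, v in zip(sparse.row, sparse.col, sparse.data):
                fh.write(f"{i} {j} {v:.10g}\n")
    else:
        raise ValueError(f"fmt must be 'mtx' or 'coo', got {fmt!r}")
    return path


def write_features_csv(X: np.ndarray, subject_ids: list[str], path: str | Path) -> Path:
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False)
    return Path(path)


@dataclass
class RunConfig:
    """One experiment: task, model family, grids, seeds, cohort source."""

    task: str = "3class"
    family: str = "gcn-ed"
    seed: int = 0
    outer_k: int = 5
    inner_k: int = 4
    cohort_manifest: str | None = None
    cohort_spec: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    output_dir: str = "popgcn-output"


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    if cfg.cohort_manifest is not None and not Path(cfg.cohort_manifest).exists():
        raise FileNotFoundError(f"cohort manifest not found: {cfg.cohort_manifest}")
    return cfg
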