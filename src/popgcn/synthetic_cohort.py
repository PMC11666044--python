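"""Synthetic multimodal cohort generator.

Real amyloid-PET cohorts with matched clinical indicators are access
restricted, so this module generates cohorts with the *statistical* structure
the downstream pipeline exploits, not anatomically realistic scans:

* clinical indicators are class-conditional Gaussians whose per-class means
  and SDs default to published hospital-cohort statistics (76 NC / 155 MCI /
  237 AD subjects; six indicators: age, education years, MMSE, CDR-SB, GDS,
  SGDepS), clipped post-draw to clinically meaningful ranges;
* latent imaging features are isotropic Gaussian clouds whose class centroids
  are spaced so that NC and MCI overlap heavily while AD separates — the
  geometry seen when PET imaging features of such cohorts are projected onto
  their first principal components;
* PET-like volumes are background noise plus a spherical cortical shell whose
  mean intensity carries the class signal, with a fixed reference region held
  at mean 1 so voxel values read as uptake ratios against a cerebellar
  reference.

All randomness flows through ``CohortSpec.seed``; identical specs yield
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "CLINICAL_COLUMNS",
    "ClassSpec",
    "CohortSpec",
    "Cohort",
    "default_class_specs",
    "generate_clinical",
    "generate_latent_features",
    "generate_volumes",
    "generate_cohort",
]

LABELS = ("NC", "MCI", "AD")
CLINICAL_COLUMNS = ("age", "education", "mmse", "cdrsb", "gds", "sgdeps")

# (lower, upper) clipping bounds per indicator; clinical scores cannot leave
# their instrument ranges regardless of the Gaussian draw.
CLINICAL_BOUNDS = (
    (1.0, np.inf),   # age (years, > 0)
    (0.0, np.inf),   # education (years)
    (0.0, 30.0),     # MMSE
    (0.0, 18.0),     # CDR-SB (sum of boxes, 6 domains x 3)
    (1.0, 7.0),      # GDS stage
    (0.0, 15.0),     # SGDepS (15-item short form)
)


@dataclass(frozen=True)
class ClassSpec:
    """Per-diagnosis generating distribution."""

    label: str
    clinical_mean: np.ndarray
    clinical_sd: np.ndarray
    volume_signal: float
    latent_centroid: np.ndarray  # unit-scale offset; scaled by CohortSpec.separation

    def __post_init__(self):
        object.__setattr__(self, "clinical_mean", np.asarray(self.clinical_mean, float))
        object.__setattr__(self, "clinical_sd", np.asarray(self.clinical_sd, float))
        object.__setattr__(self, "latent_centroid", np.asarray(self.latent_centroid, float))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.clinical_mean.shape != (6,) or self.clinical_sd.shape != (6,):
            raise ValueError("clinical_mean and clinical_sd must have 6 entries")
        if np.any(self.clinical_sd < 0):
            raise ValueError("clinical_sd must be non-negative")
        if self.volume_signal < 0:
            raise ValueError("volume_signal must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    n_per_class: tuple[int, int, int] = (76, 155, 237)
    seed: int = 0
    separation: float = 2.0
    noise_sd: float = 1.0
    latent_dim: int = 256
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    volume_noise_sd: float = 0.05

    def __post_init__(self):
        if len(self.n_per_class) != 3 or any(n <= 0 for n in self.n_per_class):
            raise ValueError(f"n_per_class must be three positive ints, got {self.n_per_class}")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0 or self.volume_noise_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if any(s < 8 for s in self.volume_shape):
            raise ValueError("volume_shape axes must all be >= 8")


@dataclass
class Cohort:
    subject_ids: list[str]
    labels: np.ndarray  # NC=0, MCI=1, AD=2
    clinical: pd.DataFrame  # N x 6, columns CLINICAL_COLUMNS
    volumes: np.ndarray | None = None  # N x D x H x W
    latent_features: np.ndarray | None = None  # N x latent_dim
    spec: CohortSpec | None = None
    volume_paths: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(self.labels) != n or len(self.clinical) != n:
            raise ValueError("per-subject containers must share length")
        if self.volumes is not None and len(self.volumes) != n:
            raise ValueError("volumes length mismatch")
        if self.latent_features is not None and len(self.latent_features) != n:
            raise ValueError("latent_features length mismatch")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def get_volumes(self) -> np.ndarray:
        """Return volumes, loading them from recorded NIfTI paths on demand."""
        if self.volumes is None:
            if not self.volume_paths:
                raise ValueError("cohort has neither in-memory volumes nor paths")
            import nibabel as nib

            self.volumes = np.stack(
                [np.asanyarray(nib.load(p).dataobj, dtype=np.float64) for p in self.volume_paths]
            )
        return self.volumes

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=self.labels[idx],
            clinical=self.clinical.iloc[idx].reset_index(drop=True),
            volumes=None if self.volumes is None else self.volumes[idx],
            latent_features=None
            if self.latent_features is None
            else self.latent_features[idx],
            spec=self.spec,
            volume_paths=None
            if self.volume_paths is None
            else [self.volume_paths[i] for i in idx],
        )


def default_class_specs(latent_dim: int = 256) -> list[ClassSpec]:
    """Generating distributions mirroring the published cohort statistics.

    Latent centroids sit along one fixed unit direction at unit-scale offsets
    0 (NC), 0.5 (MCI), 2.0 (AD), so the NC-MCI gap is a quarter of the NC-AD
    gap: NC and MCI overlap heavily while AD separates once the separation
    dial exceeds the noise SD.
    """
    e = np.ones(latent_dim) / np.sqrt(latent_dim)
    rows = [
        # label,  age,        edu,        MMSE,        CDR-SB,      GDS,        SGDepS
        ("NC", (69.34, 9.12, 27.65, 0.83, 2.03, 5.01), (7.11, 4.23, 1.72, 0.63, 0.47, 4.54), 1.1, 0.0),
        ("MCI", (68.50, 9.80, 25.11, 1.49, 3.01, 4.94), (8.74, 4.13, 2.99, 0.70, 0.27, 3.84), 1.3, 0.5),
        ("AD", (69.83, 9.99, 19.28, 4.72, 4.20, 6.24), (9.16, 4.36, 4.23, 2.65, 0.67, 4.94), 1.6, 2.0),
    ]
    return [
        ClassSpec(
            label=lab,
            clinical_mean=np.array(mean),
            clinical_sd=np.array(sd),
            volume_signal=sig,
            latent_centroid=off * e,
        )
        for lab, mean, sd, sig, off in rows
    ]


def _check_specs(spec: CohortSpec, class_specs: list[ClassSpec]) -> list[ClassSpec]:
    if class_specs is None:
        class_specs = default_class_specs(spec.latent_dim)
    if len(class_specs) != 3 or tuple(cs.label for cs in class_specs) != LABELS:
        raise ValueError(f"need one ClassSpec per class in order {LABELS}")
    return class_specs


def _stream_rng(seed: int, stream_id: int) -> np.random.Generator:
    # independent, reproducible streams per modality
    return np.random.default_rng([seed, stream_id])


def generate_clinical(
    spec: CohortSpec,
    class_specs: list[ClassSpec] | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Draw the N x 6 clinical-indicator table.

    Each indicator is drawn from its class-conditional Gaussian, then (by
    default) clipped to the instrument's valid range. ``clip=False`` exposes
    the raw draws so sample moments can be compared against the specified
    moments without truncation bias.
    """
    class_specs = _check_specs(spec, class_specs)
    rng = _stream_rng(spec.seed, 1)
    blocks = []
    for cs, n in zip(class_specs, spec.n_per_class):
        x = rng.normal(cs.clinical_mean, cs.clinical_sd, size=(n, 6))
        blocks.append(x)
    x = np.vstack(blocks)
    if clip:
        for j, (lo, hi) in enumerate(CLINICAL_BOUNDS):
            x[:, j] = np.clip(x[:, j], lo, hi)
    return pd.DataFrame(x, columns=list(CLINICAL_COLUMNS))


def generate_latent_features(
    spec: CohortSpec, class_specs: list[ClassSpec] | None = None
) -> np.ndarray:
    """Draw the N x latent_dim imaging-feature matrix.

    Features are isotropic Gaussians (SD ``noise_sd``) around class centroids
    ``separation * latent_centroid``; with ``separation=0`` all three class
    distributions coincide.
    """
    class_specs = _check_specs(spec, class_specs)
    rng = _stream_rng(spec.seed, 2)
    blocks = []
    for cs, n in zip(class_specs, spec.n_per_class):
        if cs.latent_centroid.shape != (spec.latent_dim,):
            raise ValueError(
                f"latent_centroid dim {cs.latent_centroid.shape} != latent_dim {spec.latent_dim}"
            )
        centroid = spec.separation * cs.latent_centroid
        blocks.append(rng.normal(centroid, spec.noise_sd, size=(n, spec.latent_dim)))
    return np.vstack(blocks)


def _volume_masks(shape: tuple[int, int, int]):
    """Boolean masks for the cortical shell and the cerebellar reference."""
    d, h, w = shape
    zz, yy, xx = np.meshgrid(
        np.arange(d), np.arange(h), np.arange(w), indexing="ij"
    )
    center = ((d - 1) / 2.0, (h - 1) / 2.0, (w - 1) / 2.0)
    r = np.sqrt(
        ((zz - center[0]) / d) ** 2
        + ((yy - center[1]) / h) ** 2
        + ((xx - center[2]) / w) ** 2
    )  # normalised radius in [0, ~0.87]
    shell = (r >= 0.30) & (r <= 0.45)
    # "cerebellum": a small sphere low in the volume, outside the shell band
    cz, cy, cx = 0.85 * (d - 1), center[1], center[2]
    rc = np.sqrt(((zz - cz) / d) ** 2 + ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2)
    cereb = rc <= 0.10
    shell = shell & ~cereb
    return shell, cereb


def generate_volumes(
    spec: CohortSpec, class_specs: list[ClassSpec] | None = None
) -> np.ndarray:
    """Draw N PET-like volumes of shape ``spec.volume_shape``.

    Each volume is 0.5 background + Gaussian noise everywhere, with the
    cortical-shell voxels set to the class ``volume_signal`` plus a
    subject-level jitter, and the reference-region voxels set to 1, so shell
    intensities read as uptake ratios against the reference.
    """
    class_specs = _check_specs(spec, class_specs)
    rng = _stream_rng(spec.seed, 3)
    shell, cereb = _volume_masks(spec.volume_shape)
    vols = []
    for cs, n in zip(class_specs, spec.n_per_class):
        for _ in range(n):
            v = 0.5 + rng.normal(0.0, spec.volume_noise_sd, size=spec.volume_shape)
            jitter = rng.normal(0.0, spec.volume_noise_sd)
            v[shell] += cs.volume_signal + jitter - 0.5
            v[cereb] += 1.0 - 0.5
            vols.append(v)
    return np.stack(vols)


def generate_cohort(
    spec: CohortSpec,
    class_specs: list[ClassSpec] | None = None,
    with_volumes: bool = False,
    with_latent: bool = True,
) -> Cohort:
    """Generate a full cohort (clinical table, labels, optional modalities)."""
    class_specs = _check_specs(spec, class_specs)
    labels = np.concatenate(
        [np.full(n, i, dtype=int) for i, n in enumerate(spec.n_per_class)]
    )
    ids = [f"sub-{i:04d}" for i in range(len(labels))]
    clinical = generate_clinical(spec, class_specs)
    latent = generate_latent_features(spec, class_specs) if with_latent else None
    volumes = generate_volumes(spec, class_specs) if with_volumes else None
    return Cohort(
        subject_ids=ids,
        labels=labels,
        clinical=clinical,
        volumes=volumes,
        latent_features=latent,
        spec=spec,
    )
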