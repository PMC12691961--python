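"""Synthetic two-cohort pelvic CT phantom generator.

Produces CT-like volumes with a labeled rectum so that the whole pipeline
(classification, sex-conditioned segmentation, metrics, statistics) can be
exercised end to end on data with exact, analytic ground truth.

The phantom emulates a radiotherapy-planning pelvic CT cohort of two strata:
male subjects with prostate cancer and female subjects with cervical cancer.
Anatomy is built from analytic implicit shapes rasterized on the grid:

* an elliptic-cylinder soft-tissue "pelvis" whose lateral half-width is
  sex-dependent (female wider) — the learnable sex cue,
* two ellipsoidal bony landmarks (iliac stand-ins, label 2),
* a curved rectal tube (label 3) swept along a sinusoidal centerline, an
  air-filled lumen inside a wall whose thickness is sex-dependent (thicker
  in males) and whose intensity matches surrounding soft tissue — as in
  clinical CT, the outer rectal contour has essentially no intensity
  contrast against perirectal soft tissue, so the segmenter must combine
  the visible lumen with a (sex-specific) wall-thickness prior.

The rectal tube's cross-section is a disc in each axial plane, so the
rasterized volume is ``pi * r^2 * length`` independent of centerline
curvature; the radius is solved from a per-subject volume drawn from a
sex-specific truncated normal (mean 98.4, sd 14.3 cm^3 for the prostate
cohort; mean 86.3, sd 13.2 cm^3 for the cervical cohort; truncation at
3 sd).  Normality is an assumption: the source cohort reports only the
per-stratum mean +/- sd and median of the manually contoured rectal volume.

Label scheme: 0 background air, 1 soft tissue, 2 bone, 3 rectum — chosen so
that rectum-mask extraction is "take label 3".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .imgio import SegMask, SubjectRecord, VolumeGrid, write_manifest, write_volume

__all__ = ["PhantomConfig", "generate_subject", "generate_cohort", "LABEL_RECTUM"]

#: Integer label carried by rectum voxels in the multi-class label map.
LABEL_RECTUM = 3
LABEL_BACKGROUND, LABEL_SOFT, LABEL_BONE = 0, 1, 2


@dataclass
class PhantomConfig:
    """Geometry, calibration and intensity model of the phantom cohort.

    Volume distribution parameters are in cm^3 and default to the
    per-stratum rectal-volume calibration of the emulated cohort
    (male/prostate 98.4 +/- 14.3, female/cervical 86.3 +/- 13.2).
    ``pelvis_width_shift`` is the sex-dependent increment (mm) of the
    pelvis lateral half-width (female wider).  ``hu_means``/``hu_sds``
    give the intensity model per tissue class in Hounsfield units.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    acquisition_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    rectum_volume_mean_male: float = 98.4
    rectum_volume_sd_male: float = 14.3
    rectum_volume_mean_female: float = 86.3
    rectum_volume_sd_female: float = 13.2
    pelvis_width_shift: float = 12.0
    wall_thickness_mean_male: float = 4.5
    wall_thickness_mean_female: float = 3.0
    wall_thickness_sd: float = 0.3
    hu_means: dict = field(
        default_factory=lambda: {
            "air": -1000.0,
            "soft": 40.0,
            "bone": 700.0,
            # the outer rectal contour is not intensity-visible in CT:
            # wall tissue matches surrounding soft tissue by default
            "rectal_wall": 40.0,
        }
    )
    hu_sds: dict = field(
        default_factory=lambda: {
            "air": 0.0,
            "soft": 0.0,
            "bone": 0.0,
            "rectal_wall": 0.0,
        }
    )
    noise_sd: float = 15.0
    max_retries: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rectum_volume_mean_male",
            "rectum_volume_sd_male",
            "rectum_volume_mean_female",
            "rectum_volume_sd_female",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(s <= 0 for s in self.acquisition_spacing):
            raise ValueError("acquisition_spacing must be strictly positive per axis")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small to accommodate pelvic anatomy")

    def volume_params(self, sex: str) -> tuple[float, float]:
        if sex == "male":
            return self.rectum_volume_mean_male, self.rectum_volume_sd_male
        return self.rectum_volume_mean_female, self.rectum_volume_sd_female


def fullscale_config(seed: int = 0) -> PhantomConfig:
    """Acquisition-scale configuration (256^3 grid at 1x1x3 mm)."""
    return PhantomConfig(grid_shape=(256, 256, 96), seed=seed)


def _sample_volume_cm3(config: PhantomConfig, sex: str, rng: np.random.Generator) -> float:
    """Draw a rectal volume from the sex-specific truncated normal (+-3 sd)."""
    mean, sd = config.volume_params(sex)
    return float(truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng))


def _world_grids(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.acquisition_spacing
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    return np.meshgrid(x, y, z, indexing="ij"), (x[-1], y[-1], z[-1])


def _build_label_map(config: PhantomConfig, sex: str, rng: np.random.Generator):
    """Rasterize one subject's anatomy; returns (labels, lumen mask, volume)."""
    (X, Y, Z), (ex, ey, ez) = _world_grids(config)
    cx, cy = ex / 2.0, ey / 2.0

    # Soft-tissue pelvis: elliptic cylinder, female laterally wider.
    half_w = 0.34 * ex + (config.pelvis_width_shift if sex == "female" else 0.0)
    half_w += rng.normal(0.0, 1.5)  # per-subject anatomical variability
    half_h = 0.36 * ey + rng.normal(0.0, 1.5)
    soft = ((X - cx) / half_w) ** 2 + ((Y - cy) / half_h) ** 2 <= 1.0

    # Two bony landmarks (iliac stand-ins): ellipsoids placed laterally,
    # separation follows pelvis width.
    bone = np.zeros_like(soft)
    bone_dx = 0.62 * half_w
    for side in (-1.0, 1.0):
        bx = cx + side * bone_dx
        by = cy - 0.12 * ey + rng.normal(0.0, 1.0)
        bz = ez / 2.0
        bone |= (
            ((X - bx) / 9.0) ** 2 + ((Y - by) / 14.0) ** 2 + ((Z - bz) / (0.42 * ez)) ** 2
            <= 1.0
        )
    bone &= soft

    # Rectal tube: disc cross-section in each axial plane around a
    # sinusoidal centerline, so the rasterized volume is pi r^2 times the
    # z-extent actually covered by slice centers (computed exactly below);
    # the radius is solved from the sampled per-subject volume.
    target_cm3 = _sample_volume_cm3(config, sex, rng)
    z0, z1 = 0.08 * ez, 0.92 * ez
    sz = config.acquisition_spacing[2]
    z_centers = np.arange(config.grid_shape[2]) * sz
    n_slices = int(np.count_nonzero((z_centers >= z0) & (z_centers <= z1)))
    effective_length = n_slices * sz
    radius = np.sqrt(target_cm3 * 1000.0 / (np.pi * effective_length))

    rect_dx = -2.0 if sex == "female" else 2.0  # subtle sex-dependent offset
    amp = 3.0 + rng.uniform(0.0, 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    center_x = cx + rect_dx + amp * np.sin(2.0 * np.pi * Z / (z1 - z0) + phase)
    center_y = cy + 0.08 * ey + rng.normal(0.0, 2.0)

    in_z = (Z >= z0) & (Z <= z1)
    rectum = in_z & ((X - center_x) ** 2 + (Y - center_y) ** 2 <= radius ** 2)
    # The visible structure is the air lumen; the contoured outer boundary
    # lies one wall thickness beyond it.  Wall thickness is sex-dependent
    # with small per-subject jitter, so the sex prior carries boundary
    # information that the image intensity alone does not.
    wall_mean = (
        config.wall_thickness_mean_male if sex == "male"
        else config.wall_thickness_mean_female
    )
    wall = max(1.0, wall_mean + rng.normal(0.0, config.wall_thickness_sd))
    lumen_radius = max(0.25 * radius, radius - wall)
    lumen = in_z & (
        (X - center_x) ** 2 + (Y - center_y) ** 2 <= lumen_radius ** 2
    )

    # Containment check: the tube must stay inside the soft-tissue pelvis.
    if np.any(rectum & ~soft):
        return None

    labels = np.zeros(config.grid_shape, dtype=np.uint8)
    labels[soft] = LABEL_SOFT
    labels[bone] = LABEL_BONE
    labels[rectum] = LABEL_RECTUM
    return labels, lumen, radius


def _render_intensities(
    config: PhantomConfig, labels: np.ndarray, lumen: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    hu = config.hu_means
    img = np.full(labels.shape, hu["air"], dtype=np.float32)
    img[labels == LABEL_SOFT] = hu["soft"]
    img[labels == LABEL_BONE] = hu["bone"]
    img[labels == LABEL_RECTUM] = hu["rectal_wall"]
    img[lumen] = hu["air"]  # air-filled lumen inside the contoured rectum
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=labels.shape).astype(np.float32)
    return img


def generate_subject(
    config: PhantomConfig,
    sex: Literal["male", "female"],
    subject_seed: int,
    subject_id: str | None = None,
) -> tuple[VolumeGrid, VolumeGrid, SubjectRecord]:
    """Generate one phantom subject.

    Returns the CT-like image, the integer label map (rectum = label 3) and
    a :class:`SubjectRecord` whose ``true_rectum_volume_cm3`` is the
    rasterized label-3 voxel count times the voxel volume.  Deterministic
    for a fixed ``(config, sex, subject_seed)``.

    If a sampled organ geometry leaves the pelvis, generation is retried
    with jittered parameters up to ``config.max_retries`` times before
    raising a configuration error.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex: {sex!r}")
    rng = np.random.default_rng(subject_seed)
    result = None
    for _ in range(config.max_retries):
        result = _build_label_map(config, sex, rng)
        if result is not None:
            break
    if result is None:
        raise RuntimeError(
            "phantom configuration error: organ exceeded grid bounds after "
            f"{config.max_retries} retries (grid too small for the sampled volumes?)"
        )
    labels, lumen, _ = result
    image = _render_intensities(config, labels, lumen, rng)

    spacing = config.acquisition_spacing
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    volume = float((labels == LABEL_RECTUM).sum()) * voxel_cm3

    diagnosis = "prostate" if sex == "male" else "cervical"
    record = SubjectRecord(
        subject_id=subject_id or f"{sex}-{subject_seed}",
        sex=sex,
        diagnosis=diagnosis,
        image_path="",
        label_path="",
        true_rectum_volume_cm3=volume,
    )
    return (
        VolumeGrid(values=image, spacing=spacing),
        VolumeGrid(values=labels, spacing=spacing),
        record,
    )


def generate_cohort(
    config: PhantomConfig,
    n_male: int,
    n_female: int,
    out_dir,
) -> list[SubjectRecord]:
    """Generate a cohort, write NIfTI image/label pairs and a manifest.

    Subject seeds are derived reproducibly from ``config.seed`` via
    :class:`numpy.random.SeedSequence` spawning, so the cohort is
    byte-identical for a fixed master seed.
    """
    if n_male < 1 or n_female < 1:
        raise ValueError("cohort counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_total = n_male + n_female
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]

    records: list[SubjectRecord] = []
    sexes = ["male"] * n_male + ["female"] * n_female
    for i, sex in enumerate(sexes):
        sid = f"P{i:03d}" if sex == "male" else f"C{i:03d}"
        image, labels, record = generate_subject(config, sex, seeds[i], subject_id=sid)
        image_path = out_dir / f"{sid}_image.nii.gz"
        label_path = out_dir / f"{sid}_label.nii.gz"
        write_volume(image, image_path)
        write_volume(labels, label_path)
        record.image_path = str(image_path)
        record.label_path = str(label_path)
        records.append(record)

    write_manifest(records, out_dir / "manifest.csv")
    return records


def rectum_component_count(labels: np.ndarray, connectivity: int = 3) -> int:
    """Number of connected components of label 3 (26-connectivity default)."""
    structure = ndimage.generate_binary_structure(3, connectivity)
    _, n = ndimage.label(labels == LABEL_RECTUM, structure=structure)
    return int(n)
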