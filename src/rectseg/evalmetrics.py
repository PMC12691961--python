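"""Segmentation and classification evaluation metrics.

Segmentation metrics follow the radiotherapy-QA conventions:

* Dice similarity coefficient with a smoothing constant,
  ``DSC = (2|X ∩ Y| + ε) / (|X| + |Y| + ε)`` with ε = 1 by default,
* average symmetric surface distance (ASD): the mean over both surfaces of
  each surface point's minimum Euclidean distance to the other surface,
* Hausdorff distance (HD): the exact (100th percentile) symmetric maximum
  of those minimum distances,
* precision and recall with the manual/reference mask Y as the reference.

Surfaces are the mask voxels with at least one background neighbour under
a 6-neighbourhood (configurable), taken as point sets of voxel centers in
world millimetres.  Because surface distances on anisotropic lattices are
geometrically biased by the slice thickness, ASD/HD refuse anisotropic
input by default: volumes are expected to be resampled to an isotropic
1 mm lattice first (see :func:`rectseg.prep.resample_isotropic`).

Classification metrics treat **male as the positive class** throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

from .imgio import SegMask

__all__ = [
    "MetricConfig",
    "MetricRow",
    "SurfacePointSet",
    "dice",
    "surface_points",
    "asd",
    "hausdorff",
    "precision_recall",
    "classification_report",
    "evaluate_pair",
]


@dataclass
class MetricConfig:
    """Evaluation knobs: Dice smoothing ε, isotropy enforcement, surface
    connectivity (1 = 6-neighbourhood, 2 = 18, 3 = 26)."""

    epsilon: float = 1.0
    require_isotropic: bool = True
    connectivity: int = 1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class SurfacePointSet:
    """World-mm coordinates (n, d) of a mask's boundary voxel centers."""

    points: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MetricRow:
    """Per-subject evaluation record."""

    subject_id: str
    dsc: float
    precision: float
    recall: float
    hd_mm: float
    asd_mm: float
    volume_pred_cm3: float
    volume_ref_cm3: float


def _check_same_lattice(x: SegMask, y: SegMask) -> None:
    if x.values.shape != y.values.shape:
        raise ValueError("mask lattice mismatch: shapes differ")
    if not np.allclose(x.spacing, y.spacing):
        raise ValueError("mask lattice mismatch: spacings differ")


def dice(x: SegMask, y: SegMask, epsilon: float = 1.0) -> float:
    """Smoothed Dice coefficient (2|X∩Y|+ε)/(|X|+|Y|+ε); symmetric in X, Y."""
    _check_same_lattice(x, y)
    inter = int(np.count_nonzero(x.values & y.values))
    return (2.0 * inter + epsilon) / (x.voxel_count + y.voxel_count + epsilon)


def _check_isotropic(mask: SegMask, config: MetricConfig) -> None:
    if config.require_isotropic and not mask.is_isotropic():
        raise ValueError(
            f"anisotropic lattice {mask.spacing}: resample to isotropic voxels "
            "before computing surface-based metrics"
        )


def surface_points(mask: SegMask, config: MetricConfig = MetricConfig()) -> SurfacePointSet:
    """Boundary voxel centers of a mask, in world mm.

    A voxel is on the surface if it belongs to the mask and has at least one
    background neighbour under the configured connectivity; voxels on the
    grid border count as surface.
    """
    _check_isotropic(mask, config)
    values = mask.values
    if not values.any():
        raise ValueError("undefined surface: empty mask")
    # Singleton axes (e.g. a single axial slice stored as (H, W, 1)) are
    # squeezed so that the boundary is taken in the remaining dimensions.
    keep = [a for a, n in enumerate(values.shape) if n > 1]
    values = np.squeeze(values)
    ndim = values.ndim
    structure = ndimage.generate_binary_structure(ndim, min(config.connectivity, ndim))
    interior = ndimage.binary_erosion(values, structure=structure, border_value=0)
    boundary = values & ~interior
    idx = np.argwhere(boundary)
    spacing = np.asarray([mask.spacing[a] for a in keep])
    origin = np.asarray([mask.origin[a] for a in keep])
    return SurfacePointSet(points=idx * spacing + origin)


def _directed_min_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cKDTree(b).query(a, k=1)[0]


def asd(x: SegMask, y: SegMask, config: MetricConfig = MetricConfig()) -> float:
    """Average symmetric surface distance in mm:
    ``[Σ_{x∈S_X} d(x,S_Y) + Σ_{y∈S_Y} d(y,S_X)] / (|S_X| + |S_Y|)``."""
    _check_same_lattice(x, y)
    sx = surface_points(x, config).points
    sy = surface_points(y, config).points
    dxy = _directed_min_distances(sx, sy)
    dyx = _directed_min_distances(sy, sx)
    return float((dxy.sum() + dyx.sum()) / (len(sx) + len(sy)))


def hausdorff(x: SegMask, y: SegMask, config: MetricConfig = MetricConfig()) -> float:
    """Exact symmetric Hausdorff distance in mm:
    ``max{sup_{x∈S_X} d(x,S_Y), sup_{y∈S_Y} d(y,S_X)}``."""
    _check_same_lattice(x, y)
    sx = surface_points(x, config).points
    sy = surface_points(y, config).points
    return float(max(
        _directed_min_distances(sx, sy).max(),
        _directed_min_distances(sy, sx).max(),
    ))


def precision_recall(x: SegMask, y: SegMask) -> tuple[float, float]:
    """(precision, recall) of prediction X against reference Y.

    precision = |X∩Y|/|X|, recall = |X∩Y|/|Y|; an empty X makes precision
    undefined (NaN, with a warning), an empty Y likewise for recall.
    """
    import warnings

    _check_same_lattice(x, y)
    tp = int(np.count_nonzero(x.values & y.values))
    nx, ny = x.voxel_count, y.voxel_count
    if nx == 0:
        warnings.warn("empty prediction: precision undefined")
        precision = float("nan")
    else:
        precision = tp / nx
    if ny == 0:
        warnings.warn("empty reference: recall undefined")
        recall = float("nan")
    else:
        recall = tp / ny
    return precision, recall


def classification_report(
    true_sexes: Sequence[str],
    predicted_sexes: Sequence[str],
    probabilities: Optional[Sequence[float]] = None,
) -> dict:
    """Confusion-matrix metrics for the sex-prediction task, male positive.

    Returns accuracy, sensitivity (male), specificity (female), PPV, NPV,
    F1 and — when male-probabilities are given — AUC over the empirical ROC
    (trapezoidal, tie-averaged).  A single-class truth makes AUC undefined
    (NaN, flagged with a warning).
    """
    import warnings

    t = np.asarray([s == "male" for s in true_sexes])
    p = np.asarray([s == "male" for s in predicted_sexes])
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    n = len(t)

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    report = {
        "accuracy": _ratio(tp + tn, n),
        "sensitivity_male": recall,
        "specificity_female": _ratio(tn, tn + fp),
        "ppv": precision,
        "npv": _ratio(tn, tn + fn),
        "f1": _ratio(2 * precision * recall, precision + recall)
        if precision + recall > 0
        else float("nan"),
        "n": n,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }
    if probabilities is not None:
        probs = np.asarray(probabilities, dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(np.unique(t)) < 2:
            warnings.warn("single-class truth: AUC undefined")
            report["auc"] = float("nan")
        else:
            report["auc"] = float(roc_auc_score(t.astype(int), probs))
    return report


def evaluate_pair(
    subject_id: str,
    pred: SegMask,
    ref: SegMask,
    config: MetricConfig = MetricConfig(),
    resample_for_surfaces: bool = True,
) -> MetricRow:
    """Full per-subject metric row.

    Overlap metrics (DSC, precision, recall) and volumes are computed on
    the native lattice; surface metrics (HD, ASD) on the isotropic 1 mm
    resample when the native lattice is anisotropic and
    ``resample_for_surfaces`` is enabled.
    """
    from .prep import resample_isotropic

    _check_same_lattice(pred, ref)
    dsc = dice(pred, ref, config.epsilon)
    precision, recall = precision_recall(pred, ref)
    if resample_for_surfaces and not pred.is_isotropic():
        pred_iso = resample_isotropic(pred, 1.0)
        ref_iso = resample_isotropic(ref, 1.0)
    else:
        pred_iso, ref_iso = pred, ref
    if pred_iso.voxel_count == 0 or ref_iso.voxel_count == 0:
        hd_mm = asd_mm = float("nan")
    else:
        hd_mm = hausdorff(pred_iso, ref_iso, config)
        asd_mm = asd(pred_iso, ref_iso, config)
    return MetricRow(
        subject_id=subject_id,
        dsc=dsc,
        precision=precision,
        recall=recall,
        hd_mm=hd_mm,
        asd_mm=asd_mm,
        volume_pred_cm3=pred.volume_cm3,
        volume_ref_cm3=ref.volume_cm3,
    )
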