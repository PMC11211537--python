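"""Segmentation metrics: Dice overlap and average surface distance.

ASD is the symmetric average surface distance in millimetres: surface
voxels are mask voxels with at least one face-adjacent background
voxel; each surface voxel contributes its Euclidean distance (under the
anisotropic voxel spacing) to the other mask's surface, and the two
directed means are averaged.  Distances use the exact Euclidean
distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["SegScore", "dsc", "asd", "score_case", "score_cohort", "summarize"]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegScore:
    """Per-case segmentation agreement."""

    case_id: str
    dsc: float
    asd_mm: float | None       # None when undefined (an empty mask)
    n_pred: int
    n_truth: int
    n_overlap: int


def dsc(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity 2|A∩G| / (|A| + |G|); 1.0 when both masks are empty."""
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"shape mismatch {pred_mask.shape} vs {truth_mask.shape}")
    a = pred_mask.astype(bool)
    g = truth_mask.astype(bool)
    na, ng = int(a.sum()), int(g.sum())
    if na + ng == 0:
        return 1.0
    return 2.0 * int((a & g).sum()) / (na + ng)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face-adjacent background voxel (6-connectivity)."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~eroded


def asd(pred_mask: np.ndarray, truth_mask: np.ndarray,
        spacing: tuple[float, float, float]) -> float:
    """Symmetric average surface distance in mm under anisotropic spacing."""
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"shape mismatch {pred_mask.shape} vs {truth_mask.shape}")
    a = pred_mask.astype(bool)
    g = truth_mask.astype(bool)
    if not a.any() or not g.any():
        raise ValueError("ASD undefined for an empty mask")
    sa, sg = _surface(a), _surface(g)
    # distance from every voxel to the nearest surface voxel of the other mask
    dist_to_sg = ndimage.distance_transform_edt(~sg, sampling=spacing)
    dist_to_sa = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ag = dist_to_sg[sa]
    d_ga = dist_to_sa[sg]
    return 0.5 * (float(d_ag.mean()) + float(d_ga.mean()))


def score_case(case_id: str, pred_mask: np.ndarray, truth_mask: np.ndarray,
               spacing: tuple[float, float, float]) -> SegScore:
    a = pred_mask.astype(bool)
    g = truth_mask.astype(bool)
    value = dsc(a, g)
    surface_dist = asd(a, g, spacing) if (a.any() and g.any()) else None
    return SegScore(case_id=case_id, dsc=value, asd_mm=surface_dist,
                    n_pred=int(a.sum()), n_truth=int(g.sum()), n_overlap=int((a & g).sum()))


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    return float(np.median(values)), float(q3 - q1)


def _bootstrap_median_ci(values: np.ndarray, level: float, n_boot: int,
                         seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(medians, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def summarize(values: list[float], level: float = 0.95, n_boot: int = 10_000,
              seed: int = 0) -> dict:
    """Median, IQR and a bootstrap CI of the median."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    med, iqr = _quartiles(arr)
    lo, hi = _bootstrap_median_ci(arr, level, n_boot, seed)
    return {"median": med, "iqr": iqr, "ci": (lo, hi), "n": int(arr.size)}


def score_cohort(cases: list[tuple[str, np.ndarray, np.ndarray, tuple[float, float, float]]],
                 level: float = 0.95, n_boot: int = 10_000, seed: int = 0) -> dict:
    """Per-case DSC/ASD plus cohort summaries (median, IQR, bootstrap CI).

    Cases with an undefined ASD (empty prediction or truth) are excluded
    from the ASD aggregate but still contribute their DSC.
    """
    scores = [score_case(cid, pred, truth, spacing) for cid, pred, truth, spacing in cases]
    if not scores:
        raise ValueError("no cases to score")
    dscs = [s.dsc for s in scores]
    asds = [s.asd_mm for s in scores if s.asd_mm is not None]
    report = {
        "scores": scores,
        "dsc": summarize(dscs, level, n_boot, seed),
        "asd_mm": summarize(asds, level, n_boot, seed) if asds else None,
        "n_asd_undefined": sum(1 for s in scores if s.asd_mm is None),
    }
    return report
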