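"""Image preprocessing chain and stratified cross-validation splits.

The chain mirrors common practice for anisotropic MR volumes: resample
to a target spacing (third-order spline in-plane, nearest neighbour
along the slice axis — masks nearest-neighbour on all axes), z-score
normalise, then centre crop / zero-pad to a fixed grid.  The internal
axis order is (slice, row, column) with 0-based voxel indexing; spacing
triples follow the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "VolumeRecord",
    "FoldAssignment",
    "DegenerateVolumeError",
    "SplitError",
    "resample",
    "znormalize",
    "crop_or_pad",
    "stratified_kfold",
    "median_spacing",
    "preprocess_case",
]


class DegenerateVolumeError(ValueError):
    """Input volume unusable (e.g. constant intensity)."""


class SplitError(ValueError):
    """Invalid cross-validation split request."""


@dataclass(frozen=True)
class VolumeRecord:
    """A 3D volume with voxel spacing in mm, axis order (slice, row, column)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise DegenerateVolumeError("volume contains non-finite values")


def resample(vol: VolumeRecord, target_spacing: tuple[float, float, float],
             is_mask: bool = False) -> VolumeRecord:
    """Resample to ``target_spacing``.

    Output size per axis is round(size * spacing / target).  Coordinates
    are origin-aligned (voxel i sits at i * spacing mm).  In-plane axes
    use third-order spline interpolation, the slice axis nearest
    neighbour; masks use nearest neighbour everywhere so they remain
    strictly binary.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    in_shape = vol.data.shape
    out_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(in_shape, vol.spacing, target_spacing))
    if out_shape == in_shape and tuple(vol.spacing) == tuple(target_spacing):
        return vol
    axes_coords = []
    for n_out, n_in, s, t in zip(out_shape, in_shape, vol.spacing, target_spacing):
        c = np.arange(n_out) * (t / s)
        axes_coords.append(np.clip(c, 0, n_in - 1))
    # nearest neighbour along slices: snap the slice coordinate to the grid
    axes_coords[0] = np.round(axes_coords[0])
    if is_mask:
        axes_coords = [np.round(c) for c in axes_coords]
    grids = np.meshgrid(*axes_coords, indexing="ij")
    order = 0 if is_mask else 3
    data = ndimage.map_coordinates(vol.data.astype(np.float64), np.stack(grids), order=order,
                                   mode="nearest")
    if is_mask:
        data = data.round().astype(vol.data.dtype)
    return VolumeRecord(data=data, spacing=tuple(target_spacing))


def znormalize(vol: VolumeRecord) -> VolumeRecord:
    """Zero-mean, unit-sd (population) intensity normalisation."""
    sd = float(vol.data.std())
    if sd == 0:
        raise DegenerateVolumeError("cannot z-normalise a constant volume")
    return replace(vol, data=(vol.data - vol.data.mean()) / sd)


def crop_or_pad(vol: VolumeRecord, target_shape: tuple[int, int, int],
                center: tuple[int, int, int] | None = None) -> VolumeRecord:
    """Centre crop when larger, symmetric zero-pad when smaller.

    ``center`` (voxel indices) overrides the geometric centre, e.g. the
    mask centroid at training time; the window is shifted to stay
    inside the volume.
    """
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    data = vol.data
    out = data
    for ax, t in enumerate(target_shape):
        n = out.shape[ax]
        if n > t:
            c = (n // 2) if center is None else int(center[ax])
            start = int(np.clip(c - t // 2, 0, n - t))
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + t)
            out = out[tuple(sl)]
        elif n < t:
            before = (t - n) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, t - n - before)
            out = np.pad(out, pad)
    return replace(vol, data=out)


def mask_centroid(mask: np.ndarray) -> tuple[int, int, int]:
    idx = np.argwhere(mask > 0)
    if len(idx) == 0:
        return tuple(s // 2 for s in mask.shape)
    return tuple(int(round(v)) for v in idx.mean(axis=0))


@dataclass(frozen=True)
class FoldAssignment:
    """case_id -> fold index; folds partition the cohort, stage-stratified."""

    folds: dict[str, int]
    k: int

    def cases_in_fold(self, fold: int) -> list[str]:
        return [cid for cid, f in self.folds.items() if f == fold]

    def counts(self, labels: dict[str, int]) -> np.ndarray:
        """Per-fold per-stage counts, shape (k, 4)."""
        out = np.zeros((self.k, 4), dtype=int)
        for cid, f in self.folds.items():
            out[f, labels[cid] - 1] += 1
        return out


def stratified_kfold(labels: dict[str, int], k: int, seed: int) -> FoldAssignment:
    """Stage-stratified k-fold assignment; per-stage fold counts differ by <= 1."""
    if k < 2:
        raise SplitError("k must be >= 2")
    ids = sorted(labels)
    if k > len(ids):
        raise SplitError(f"k={k} exceeds cohort size {len(ids)}")
    y = np.array([labels[c] for c in ids])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), y)):
        for i in test_idx:
            folds[ids[i]] = fold
    return FoldAssignment(folds=folds, k=k)


def median_spacing(spacings: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Per-axis median voxel spacing across a cohort."""
    arr = np.asarray(spacings, dtype=float)
    return tuple(float(v) for v in np.median(arr, axis=0))


def preprocess_case(image: np.ndarray, mask: np.ndarray | None,
                    spacing: tuple[float, float, float],
                    target_spacing: tuple[float, float, float],
                    target_shape: tuple[int, int, int],
                    normalize: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """Full chain: resample -> z-normalise -> crop/pad (mask transformed identically).

    The crop window is centred on the mask centroid when a mask is
    given, otherwise on the volume centre.
    """
    img = resample(VolumeRecord(np.asarray(image, dtype=np.float64), spacing), target_spacing)
    msk = None
    if mask is not None:
        msk = resample(VolumeRecord(np.asarray(mask), spacing), target_spacing, is_mask=True)
    if normalize:
        img = znormalize(img)
    center = mask_centroid(msk.data) if msk is not None else None
    img = crop_or_pad(img, target_shape, center)
    if msk is not None:
        msk = crop_or_pad(msk, target_shape, center)
    return img.data.astype(np.float32), None if msk is None else msk.data.astype(np.uint8)
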