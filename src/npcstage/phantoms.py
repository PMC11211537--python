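"""Synthetic 3D head phantoms with a stage-labelled tumor.

Real cohorts for this problem are private, so the package ships a
generator that reproduces the *statistical structure* the multi-task
model must exploit: an anisotropic single-channel volume (fine
in-plane, coarse between slices), a bright connected tumor grown from a
central cavity, and a four-level stage label determined by how deep the
tumor extends into nested anatomical shells — the same
"stage = deepest structure invaded" logic clinical T-staging applies.
Stage prevalences default to the imbalanced mixture of a representative
320-case cohort (8/44/27/21%).

The shells are concentric ellipsoids in physical (mm) coordinates:
label 1 is the core cavity where every tumor is seeded, labels 2-4 are
successively deeper bands, label 0 is outside the head.  Tumors grow by
seeded randomized breadth-first accretion with 6-connectivity, so a
target voxel volume is hit exactly and the region is guaranteed
connected.
"""

from __future__ import annotations

import csv
import heapq
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ShellAtlas",
    "PhantomCase",
    "PhantomConfig",
    "AtlasSizingError",
    "TumorGrowthError",
    "InvalidCaseError",
    "build_atlas",
    "grow_tumor",
    "stage_from_overlap",
    "synthesize_image",
    "generate_case",
    "generate_cohort",
    "save_case",
    "load_case",
    "read_manifest",
]

_NEIGHBOR_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=np.int64)


class AtlasSizingError(ValueError):
    """Grid too small to host nested shells."""


class TumorGrowthError(RuntimeError):
    """Requested tumor volume cannot be grown."""


class InvalidCaseError(ValueError):
    """A case violates a structural invariant (e.g. empty mask)."""


@dataclass(frozen=True)
class ShellAtlas:
    """Nested-shell anatomy: 0 outside, 1 core cavity, 2..4 deeper bands."""

    regions: np.ndarray                    # int8 label volume
    spacing: tuple[float, float, float]    # mm per voxel (slice, row, column)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.regions.shape

    def band_mask(self, label: int) -> np.ndarray:
        return self.regions == label


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic case: image, ground-truth mask, stage label, metadata."""

    case_id: str
    image: np.ndarray
    mask: np.ndarray
    stage: int
    spacing: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise InvalidCaseError("image and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise InvalidCaseError("mask is not binary")
        if self.mask.sum() == 0:
            raise InvalidCaseError("tumor mask is empty")
        if self.stage not in (1, 2, 3, 4):
            raise InvalidCaseError(f"stage {self.stage} outside 1..4")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults are the package's study conditions.

    ``stage_mixture`` mirrors the T1..T4 prevalences of a representative
    clinical cohort.  ``volume_ranges`` (voxels) increase with stage so
    that anatomical invasion depth — and hence the stage label — is
    statistically tied to tumor bulk.  ``invasion_thresholds`` give the
    fraction of tumor voxels that must lie inside a band for the band
    to count as invaded.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    spacing: tuple[float, float, float] = (6.0, 0.5, 0.5)
    stage_mixture: tuple[float, ...] = (0.08, 0.44, 0.27, 0.21)
    volume_ranges: tuple[tuple[int, int], ...] = ((30, 80), (90, 220), (400, 1100), (1600, 3200))
    invasion_thresholds: tuple[float, float, float] = (0.05, 0.05, 0.05)
    noise_sd: float = 0.15
    tumor_contrast: float = 1.0
    texture_amplitude: float = 0.3
    bias_amplitude: float = 0.2
    max_attempts: int = 60

    def __post_init__(self):
        mix = np.asarray(self.stage_mixture, dtype=float)
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("stage mixture must be nonnegative and sum to 1")
        los = [r[0] for r in self.volume_ranges]
        his = [r[1] for r in self.volume_ranges]
        if any(a > b for a, b in self.volume_ranges) or los != sorted(los) or his != sorted(his):
            raise ValueError("volume ranges must be nondecreasing with stage")


# fractional ellipsoid radii (of the half-extent) delimiting core and bands
_BAND_FRACTIONS = (0.34, 0.46, 0.60, 0.74)


def build_atlas(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                seed: int) -> ShellAtlas:
    """Construct the nested ellipsoidal shell atlas, jittered per seed."""
    if any(s < 8 for s in shape):
        raise AtlasSizingError(f"all grid dimensions must be >= 8, got {shape}")
    rng = np.random.default_rng(seed)
    half_mm = np.array([(s - 1) * sp / 2.0 for s, sp in zip(shape, spacing)])
    centre = half_mm * (1.0 + rng.uniform(-0.03, 0.03, size=3))
    jitter = 1.0 + rng.uniform(-0.04, 0.04, size=3)
    coords = np.meshgrid(*(np.arange(s) * sp for s, sp in zip(shape, spacing)), indexing="ij")
    rho = np.zeros(shape, dtype=np.float64)
    for ax in range(3):
        rho += ((coords[ax] - centre[ax]) / (half_mm[ax] * jitter[ax])) ** 2
    rho = np.sqrt(rho)
    regions = np.zeros(shape, dtype=np.int8)
    bounds = (0.0,) + _BAND_FRACTIONS
    for label in (1, 2, 3, 4):
        regions[(rho > bounds[label - 1]) & (rho <= bounds[label])] = label
    if not (regions == 1).any():
        raise AtlasSizingError("core cavity empty; grid too coarse for the shell geometry")
    return ShellAtlas(regions=regions, spacing=tuple(spacing))


def grow_tumor(atlas: ShellAtlas, target_volume: int, seed: int,
               start: tuple[int, int, int] | None = None) -> np.ndarray:
    """Grow a 6-connected tumor of exactly ``target_volume`` voxels.

    Growth starts at a seeded random voxel of the core cavity and
    accretes from the 6-neighbourhood frontier, restricted to the head
    (labels 1-4).  The frontier is consumed in order of jittered
    *physical* (mm) distance from the seed, so blobs are roughly
    spherical in patient space despite the coarse slice spacing, with a
    randomized irregular boundary.
    """
    if target_volume < 1:
        raise TumorGrowthError("target volume must be >= 1")
    rng = np.random.default_rng(seed)
    inside = atlas.regions > 0
    reachable = int(inside.sum())
    if target_volume > reachable:
        raise TumorGrowthError(
            f"target volume {target_volume} exceeds {reachable} voxels reachable from the core")
    core = np.argwhere(atlas.regions == 1)
    if start is None:
        start = tuple(int(v) for v in core[rng.integers(len(core))])
    shape = atlas.shape
    spacing = np.asarray(atlas.spacing)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[start] = 1
    queued = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, tuple[int, int, int]]] = []

    def push_neighbors(vox):
        for off in _NEIGHBOR_OFFSETS:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]
                    and inside[nb] and not mask[nb] and not queued[nb]):
                queued[nb] = True
                dist = float(np.linalg.norm((np.subtract(nb, start)) * spacing))
                heapq.heappush(heap, (dist * (1.0 + 0.35 * rng.random()), nb))

    push_neighbors(start)
    grown = 1
    while grown < target_volume:
        if not heap:
            raise TumorGrowthError(f"growth exhausted at {grown} of {target_volume} voxels")
        _, vox = heapq.heappop(heap)
        if mask[vox]:
            continue
        mask[vox] = 1
        grown += 1
        push_neighbors(vox)
    return mask


def stage_from_overlap(mask: np.ndarray, atlas: ShellAtlas,
                       thresholds: tuple[float, float, float] = (0.05, 0.05, 0.05)) -> int:
    """Stage = deepest band whose overlap fraction meets its threshold.

    The overlap fraction of band b is |mask ∩ band_b| / |mask|; the
    stage is the largest b in {2, 3, 4} whose fraction reaches
    ``thresholds[b-2]``, or 1 when the tumor is effectively confined to
    the core.  Monotone by construction: adding deeper-band voxels can
    only raise the deepest qualifying band.
    """
    if mask.shape != atlas.shape:
        raise InvalidCaseError("mask and atlas shapes differ")
    total = int(mask.sum())
    if total == 0:
        raise InvalidCaseError("cannot stage an empty mask")
    stage = 1
    for band, thr in zip((2, 3, 4), thresholds):
        frac = int(mask[atlas.regions == band].sum()) / total
        if frac >= thr:
            stage = band
    return stage


def _smooth_field(shape, spacing, rng, correlation_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with physical correlation length."""
    noise = rng.standard_normal(shape)
    sigma_vox = [correlation_mm / sp for sp in spacing]
    field_ = ndimage.gaussian_filter(noise, sigma_vox, mode="nearest")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def synthesize_image(atlas: ShellAtlas, mask: np.ndarray, config: PhantomConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Image = head baseline + low-frequency texture + tumor contrast
    + smooth additive bias field + voxelwise Gaussian noise."""
    inside = atlas.regions > 0
    image = np.where(inside, 1.0, 0.0)
    image = image + 0.05 * atlas.regions  # mild per-shell intensity gradient
    if config.texture_amplitude > 0:
        image += config.texture_amplitude * _smooth_field(atlas.shape, atlas.spacing, rng, 4.0) * inside
    image += config.tumor_contrast * mask
    if config.bias_amplitude > 0:
        image += config.bias_amplitude * _smooth_field(atlas.shape, atlas.spacing, rng, 20.0)
    if config.noise_sd > 0:
        image += config.noise_sd * rng.standard_normal(atlas.shape)
    return image.astype(np.float32)


def generate_case(atlas: ShellAtlas, stage: int, config: PhantomConfig, case_id: str,
                  seed: int) -> PhantomCase:
    """Grow a tumor whose overlap-derived stage equals ``stage``.

    Volumes are drawn from the stage's configured range; growth is
    retried with fresh sub-seeds until the realized invasion depth
    matches the requested stage (bounded by ``config.max_attempts``).
    """
    rng = np.random.default_rng(seed)
    for _ in range(config.max_attempts):
        lo, hi = config.volume_ranges[stage - 1]
        target = int(rng.integers(lo, hi + 1))
        sub_seed = int(rng.integers(2 ** 31))
        mask = grow_tumor(atlas, target, sub_seed)
        realized = stage_from_overlap(mask, atlas, config.invasion_thresholds)
        if realized == stage:
            image = synthesize_image(atlas, mask, config, rng)
            return PhantomCase(case_id=case_id, image=image, mask=mask.astype(np.uint8),
                               stage=stage, spacing=config.spacing, seed=seed)
    raise TumorGrowthError(
        f"could not realize stage {stage} within {config.max_attempts} attempts; "
        "volume ranges and invasion thresholds are inconsistent with the atlas geometry")


def generate_cohort(config: PhantomConfig, n: int, seed: int,
                    out_dir: str | Path | None = None) -> list[PhantomCase]:
    """Generate ``n`` cases with stages drawn from the configured mixture.

    When ``out_dir`` is given, images and masks are written as NIfTI
    pairs plus a ``manifest.csv`` (case_id, stage, seed, volume_voxels).
    """
    if n < 4:
        raise ValueError("cohort size must be at least 4")
    rng = np.random.default_rng(seed)
    atlas = build_atlas(config.shape, config.spacing, seed)
    stages = rng.choice(np.arange(1, 5), size=n, p=np.asarray(config.stage_mixture))
    cases = []
    for i, stage in enumerate(stages):
        case_seed = int(rng.integers(2 ** 31))
        cases.append(generate_case(atlas, int(stage), config, f"case_{i:04d}", case_seed))
    if out_dir is not None:
        write_cohort(cases, out_dir)
    return cases


# ---------------------------------------------------------------------
# NIfTI / manifest I/O
# ---------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_case(case: PhantomCase, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(case.image.astype(np.float32), _affine(case.spacing)),
             out / f"{case.case_id}_image.nii.gz")
    nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), _affine(case.spacing)),
             out / f"{case.case_id}_mask.nii.gz")


def load_case(out_dir: str | Path, case_id: str, stage: int, seed: int) -> PhantomCase:
    out = Path(out_dir)
    img = nib.load(out / f"{case_id}_image.nii.gz")
    msk = nib.load(out / f"{case_id}_mask.nii.gz")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomCase(case_id=case_id, image=np.asarray(img.dataobj, dtype=np.float32),
                       mask=np.asarray(msk.dataobj, dtype=np.uint8), stage=stage,
                       spacing=spacing, seed=seed)


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "stage", "seed", "volume_voxels"])
        for case in cases:
            save_case(case, out)
            writer.writerow([case.case_id, case.stage, case.seed, int(case.mask.sum())])
    return manifest


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return [
            {"case_id": row["case_id"], "stage": int(row["stage"]),
             "seed": int(row["seed"]), "volume_voxels": int(row["volume_voxels"])}
            for row in csv.DictReader(fh)
        ]
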