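"""Semiautomated high-signal-plaque (HSP) segmentation.

The method has two sequential stages:

1. **Plaque extraction by region growing.** A manually placed seed is
   corrected to the brightest voxel of a 7x7x7 window; the image is
   smoothed with a Gaussian (sigma = 0.5 voxels); starting from the
   window maximum, the intensity threshold is lowered step by step
   (default 1 intensity unit) and at each threshold every voxel that is
   connected to the current region and strictly brighter than the
   threshold is added. Growth terminates when the region can no longer
   grow, when one pass suddenly more than doubles the region (the
   pre-doubling region is kept — this is the guard against flooding
   into background), or when the threshold falls below a floor.

2. **HSP thresholding against adjacent muscle.** The mean intensity of a
   muscle-reference ROI on the *original* (unsmoothed) image, multiplied
   by a contrast-ratio coefficient (1.3 for unstable plaque; 1.52
   selects IPH-like signal only), defines the HSP threshold; the HSP
   mask is the part of the plaque region strictly brighter than it.

Volumes are reported in mm^3, either as voxel count x voxel volume or as
the per-slice area sum x slice thickness (identical on a regular grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .io import ContractError, Mask3D, SeedPoint, Volume3D

__all__ = [
    "RegionGrowParams",
    "TraceStep",
    "RegionGrowTrace",
    "SegmentationResult",
    "correct_seed",
    "smooth_volume",
    "initial_threshold",
    "grow_plaque_region",
    "muscle_mean",
    "segment_hsp",
    "compute_volume",
    "segment",
]

#: contrast-ratio cutoffs vs adjacent muscle (unstable plaque / IPH-only)
DEFAULT_COEFFICIENT = 1.3
IPH_COEFFICIENT = 1.52

_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class RegionGrowParams:
    """Tunable parameters of the region-growing stage.

    window_radius
        Half-width of the seed-correction / initial-threshold window in
        voxels; 3 gives the 7x7x7 window.
    sigma
        Gaussian smoothing width in voxel units, applied per axis.
    connectivity
        Voxel neighborhood: 6 (faces), 18 (+edges) or 26 (+corners).
    threshold_step
        Intensity decrement per growing pass, on the native stored scale.
    doubling_factor
        A pass whose result exceeds ``doubling_factor`` x the previous
        region size triggers the flooding stop.
    doubling_min_size
        The flooding stop is armed only once the previous region has at
        least this many voxels, so legitimate early growth from a
        near-singleton region is not mistaken for flooding.
    threshold_floor
        Lowest threshold at which a pass is still run; ``None`` means
        the minimum of the smoothed volume.
    """

    window_radius: int = 3
    sigma: float = 0.5
    connectivity: int = 26
    threshold_step: float = 1.0
    doubling_factor: float = 2.0
    doubling_min_size: int = 10
    threshold_floor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window_radius < 0:
            raise ContractError("window_radius must be >= 0")
        if self.sigma < 0:
            raise ContractError("sigma must be >= 0")
        if self.connectivity not in _STRUCTURE_RANK:
            raise ContractError("connectivity must be 6, 18 or 26")
        if self.threshold_step <= 0:
            raise ContractError("threshold_step must be > 0")
        if self.doubling_factor <= 1:
            raise ContractError("doubling_factor must be > 1")
        if self.doubling_min_size < 1:
            raise ContractError("doubling_min_size must be >= 1")

    def structure(self) -> np.ndarray:
        return ndi.generate_binary_structure(3, _STRUCTURE_RANK[self.connectivity])


@dataclass(frozen=True)
class TraceStep:
    """One threshold pass: (threshold, cumulative region size, voxels added)."""

    threshold: float
    cumulative: int
    added: int


@dataclass
class RegionGrowTrace:
    """Audit log of the growing loop and the reason it stopped.

    ``steps`` records every threshold pass, including the pass that
    triggered a ``volume_doubled`` stop (whose voxels are *not* part of
    the returned mask). ``stop_reason`` is one of ``no_new_voxels``,
    ``volume_doubled`` or ``floor_reached``.
    """

    initial_threshold: float
    floor: float
    steps: List[TraceStep] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def final_threshold(self) -> float:
        """Threshold of the pass whose region is the returned mask."""
        if self.stop_reason == "volume_doubled":
            kept = self.steps[:-1]
        else:
            kept = self.steps
        return kept[-1].threshold if kept else self.initial_threshold

    @property
    def n_iterations(self) -> int:
        return len(self.steps)

    def to_dict(self) -> dict:
        return {
            "initial_threshold": self.initial_threshold,
            "floor": self.floor,
            "stop_reason": self.stop_reason,
            "final_threshold": self.final_threshold,
            "steps": [
                {"threshold": s.threshold, "cumulative": s.cumulative, "added": s.added}
                for s in self.steps
            ],
        }


@dataclass
class SegmentationResult:
    """Everything the two-stage segmentation produced."""

    plaque_mask: Mask3D
    hsp_mask: Mask3D
    corrected_seed: SeedPoint
    initial_threshold: float
    final_threshold: float
    muscle_mean: float
    hsp_threshold: float
    plaque_volume_mm3: float
    hsp_volume_mm3: float
    trace: RegionGrowTrace
    coefficient: float = DEFAULT_COEFFICIENT

    def summary(self) -> dict:
        return {
            "corrected_seed": list(self.corrected_seed.as_tuple()),
            "initial_threshold": self.initial_threshold,
            "final_threshold": self.final_threshold,
            "muscle_mean": self.muscle_mean,
            "coefficient": self.coefficient,
            "hsp_threshold": self.hsp_threshold,
            "plaque_voxels": self.plaque_mask.count(),
            "hsp_voxels": self.hsp_mask.count(),
            "plaque_volume_mm3": self.plaque_volume_mm3,
            "hsp_volume_mm3": self.hsp_volume_mm3,
            "stop_reason": self.trace.stop_reason,
            "n_iterations": self.trace.n_iterations,
        }


def _window_slices(
    center: Tuple[int, int, int], radius: int, shape: Tuple[int, int, int]
) -> Tuple[slice, slice, slice]:
    return tuple(
        slice(max(0, c - radius), min(n, c + radius + 1))
        for c, n in zip(center, shape)
    )


def correct_seed(volume: Volume3D, manual_seed: SeedPoint, window_radius: int = 3) -> SeedPoint:
    """Snap the manual seed to the brightest voxel of the surrounding window.

    The window is ``(2*window_radius+1)^3`` centered on the manual seed,
    clipped at the volume borders. Ties are broken toward the lowest
    ``(i, j, k)`` in lexicographic order, which makes the correction
    deterministic on plateaus.
    """
    manual_seed.check_in_bounds(volume.shape)
    sl = _window_slices(manual_seed.as_tuple(), int(window_radius), volume.shape)
    win = volume.data[sl]
    # np.argmax scans in C order, i.e. picks the lexicographically lowest tie
    local = np.unravel_index(int(np.argmax(win)), win.shape)
    i, j, k = (s.start + off for s, off in zip(sl, local))
    return SeedPoint(int(i), int(j), int(k), kind="corrected")


def smooth_volume(volume: Volume3D, sigma: float = 0.5) -> Volume3D:
    """Gaussian-smooth a volume; ``sigma`` is in voxel units, per axis.

    ``sigma = 0`` is the identity (a copy of the input data).
    """
    if sigma < 0:
        raise ContractError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        data = volume.data.copy()
    else:
        data = ndi.gaussian_filter(volume.data, sigma=sigma)
    return Volume3D(data=data, spacing=volume.spacing, affine=volume.affine)


def initial_threshold(
    smoothed: Volume3D, corrected_seed: SeedPoint, window_radius: int = 3
) -> float:
    """Highest smoothed intensity in the window centered on the corrected seed."""
    corrected_seed.check_in_bounds(smoothed.shape)
    sl = _window_slices(corrected_seed.as_tuple(), int(window_radius), smoothed.shape)
    return float(smoothed.data[sl].max())


def grow_plaque_region(
    smoothed: Volume3D,
    corrected_seed: SeedPoint,
    params: Optional[RegionGrowParams] = None,
) -> Tuple[Mask3D, RegionGrowTrace]:
    """Grow the plaque region from the corrected seed on the smoothed image.

    Starting from the initial threshold (the window maximum around the
    seed), each pass at threshold ``t`` adds every voxel connected to
    the current region through voxels strictly brighter than ``t``; the
    threshold then drops by ``threshold_step``. The region at a given
    threshold is therefore the connected component of
    ``{v > t} | {seed}`` that contains the seed, so successive regions
    are nested.

    Stop conditions, checked after each pass:

    * ``volume_doubled`` — the pass grew the region beyond
      ``doubling_factor`` x its previous size (with the previous size at
      least ``doubling_min_size``). The region reverts to the previous
      pass; this is the flooding guard.
    * ``no_new_voxels`` — the pass added nothing and no voxel adjacent
      to the region exceeds the threshold floor, so no later pass could
      ever add a voxel.
    * ``floor_reached`` — the next threshold would fall below the floor.

    Returns the plaque mask (a single connected component containing
    the seed) and the per-pass trace.
    """
    params = params or RegionGrowParams()
    corrected_seed.check_in_bounds(smoothed.shape)
    data = smoothed.data
    structure = params.structure()

    t0 = initial_threshold(smoothed, corrected_seed, params.window_radius)
    floor = float(data.min()) if params.threshold_floor is None else float(params.threshold_floor)
    tol = 1e-9 * max(1.0, abs(t0), abs(floor))

    trace = RegionGrowTrace(initial_threshold=t0, floor=floor)
    region = np.zeros(smoothed.shape, dtype=bool)
    region[corrected_seed.as_tuple()] = True
    prev_count = 1

    k = 0
    while True:
        t = t0 - k * params.threshold_step
        if t < floor - tol:
            trace.stop_reason = "floor_reached"
            break
        supra = data > t
        labels, _ = ndi.label(supra, structure=structure)
        dilated = ndi.binary_dilation(region, structure=structure)
        touching = np.unique(labels[dilated & supra])
        touching = touching[touching != 0]
        if touching.size:
            new_region = region | np.isin(labels, touching)
        else:
            new_region = region
        new_count = int(new_region.sum())
        added = new_count - prev_count
        trace.steps.append(TraceStep(threshold=float(t), cumulative=new_count, added=added))

        if (
            prev_count >= params.doubling_min_size
            and new_count > params.doubling_factor * prev_count
        ):
            # flooding: keep the region from before this pass
            trace.stop_reason = "volume_doubled"
            break
        region = new_region
        if added == 0:
            frontier = dilated & ~region
            if not np.any(data[frontier] > floor):
                trace.stop_reason = "no_new_voxels"
                break
        prev_count = new_count
        k += 1

    mask = Mask3D(data=region, spacing=smoothed.spacing, affine=smoothed.affine)
    return mask, trace


def muscle_mean(volume: Volume3D, muscle_roi: Mask3D) -> float:
    """Mean original-image intensity over the muscle-reference ROI."""
    if muscle_roi.shape != volume.shape:
        raise ContractError(
            f"muscle ROI shape {muscle_roi.shape} != volume shape {volume.shape}"
        )
    n = muscle_roi.count()
    if n == 0:
        raise ContractError("muscle ROI is empty")
    return float(volume.data[muscle_roi.data].mean())


def segment_hsp(
    volume: Volume3D,
    plaque_mask: Mask3D,
    muscle_mean_value: float,
    coefficient: float = DEFAULT_COEFFICIENT,
) -> Tuple[Mask3D, float]:
    """Threshold the plaque region at ``coefficient x muscle mean``.

    Keeps the plaque voxels whose *original* intensity strictly exceeds
    the contrast-ratio threshold. Returns ``(hsp_mask, hsp_threshold)``.
    """
    if coefficient <= 0:
        raise ContractError(f"coefficient must be > 0, got {coefficient}")
    if plaque_mask.shape != volume.shape:
        raise ContractError(
            f"plaque mask shape {plaque_mask.shape} != volume shape {volume.shape}"
        )
    hsp_threshold = float(muscle_mean_value) * float(coefficient)
    hsp = plaque_mask.data & (volume.data > hsp_threshold)
    return (
        Mask3D(data=hsp, spacing=volume.spacing, affine=volume.affine),
        hsp_threshold,
    )


def compute_volume(
    mask: Mask3D,
    spacing: Optional[Tuple[float, float, float]] = None,
    method: str = "voxel_sum",
) -> float:
    """Lesion volume in mm^3.

    ``voxel_sum`` multiplies the voxel count by the voxel volume;
    ``slice_area`` sums the in-plane area per slice and multiplies by
    the slice thickness (the manual-reading convention). On a regular
    grid the two coincide.
    """
    dx, dy, dz = spacing if spacing is not None else mask.spacing
    if min(dx, dy, dz) <= 0:
        raise ContractError("spacing must be positive")
    if method == "voxel_sum":
        return float(mask.count() * (dx * dy * dz))
    if method == "slice_area":
        per_slice = mask.data.sum(axis=(0, 1))  # voxel count per k-slice
        return float(np.sum(per_slice * (dx * dy)) * dz)
    raise ContractError(f"unknown volume method {method!r}")


def segment(
    volume: Volume3D,
    manual_seed: SeedPoint,
    muscle_roi: Mask3D,
    params: Optional[RegionGrowParams] = None,
    coefficient: float = DEFAULT_COEFFICIENT,
    seed_on_smoothed: bool = True,
    volume_method: str = "voxel_sum",
) -> SegmentationResult:
    """Run the full two-stage pipeline on one lesion.

    Seed correction and region growing run on the smoothed image
    (``seed_on_smoothed=False`` corrects the seed on the raw image
    instead); the muscle mean and the contrast-ratio threshold always
    use the original intensities.
    """
    params = params or RegionGrowParams()
    smoothed = smooth_volume(volume, params.sigma)
    seed_image = smoothed if seed_on_smoothed else volume
    corrected = correct_seed(seed_image, manual_seed, params.window_radius)
    plaque_mask, trace = grow_plaque_region(smoothed, corrected, params)
    mm = muscle_mean(volume, muscle_roi)
    hsp_mask, hsp_threshold = segment_hsp(volume, plaque_mask, mm, coefficient)
    return SegmentationResult(
        plaque_mask=plaque_mask,
        hsp_mask=hsp_mask,
        corrected_seed=corrected,
        initial_threshold=trace.initial_threshold,
        final_threshold=trace.final_threshold,
        muscle_mean=mm,
        hsp_threshold=hsp_threshold,
        plaque_volume_mm3=compute_volume(plaque_mask, volume.spacing, volume_method),
        hsp_volume_mm3=compute_volume(hsp_mask, volume.spacing, volume_method),
        trace=trace,
        coefficient=float(coefficient),
    )
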