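"""Synthetic vessel-wall phantoms with ground-truth masks.

The phantom emulates the signal configuration the segmentation method
relies on: a bright plaque core (contrast ratio vs muscle above the 1.3
unstable-plaque cutoff, by default also above the 1.52 IPH-like cutoff)
inside a dimmer fibrous rim (below 1.3x muscle), a homogeneous muscle
block nearby for the reference ROI, all on a dark background with
additive Gaussian noise, at the anisotropic spacing of a reconstructed
3D TSE black-blood acquisition (0.45 x 0.45 x 0.9 mm).

Ellipsoids and blocks are rasterized by voxel-center inclusion, and the
ground-truth volumes are those of the rasterized masks, so volume
recovery can be tested exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .io import ContractError, Mask3D, SeedPoint, Volume3D

__all__ = ["PhantomSpec", "PhantomResult", "generate_phantom", "dice"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal levels of a synthetic plaque scene.

    Intensities are in arbitrary scanner-like units with the muscle mean
    at 400; the defaults place the core at contrast ratio 1.6 (IPH-like,
    above both the 1.3 and 1.52 cutoffs) and the rim at 1.1
    (fibrous-like, below 1.3). The scale is chosen so that the grower's
    unit threshold decrement is fine-grained relative to tissue contrast
    and noise, as it is on stored scanner units that span hundreds to
    thousands. ``noise_sd`` defaults to 2% of the muscle mean. All
    lengths are mm; centers/semiaxes are in world mm along the three
    voxel axes (no rotation).
    """

    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (0.45, 0.45, 0.9)
    background_mean: float = 240.0
    muscle_mean: float = 400.0
    rim_intensity: float = 440.0
    core_intensity: float = 640.0
    core_center_mm: Optional[Tuple[float, float, float]] = None  # None = grid center
    core_semiaxes_mm: Tuple[float, float, float] = (1.9, 1.9, 2.6)
    rim_semiaxes_mm: Tuple[float, float, float] = (2.8, 2.8, 3.4)
    muscle_center_mm: Tuple[float, float, float] = (7.0, 22.0, 14.0)
    muscle_halfsize_mm: Tuple[float, float, float] = (3.2, 3.2, 3.2)
    muscle_roi_margin_mm: float = 1.2
    noise_sd: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")
        if any(n < 8 for n in self.shape):
            raise ContractError("phantom grid must be at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ContractError("spacing must be positive")
        if not self.core_intensity > 1.3 * self.muscle_mean:
            raise ContractError("core intensity must exceed 1.3 x muscle mean")
        if not self.rim_intensity < 1.3 * self.muscle_mean:
            raise ContractError("rim intensity must stay below 1.3 x muscle mean")
        if any(
            c >= r for c, r in zip(self.core_semiaxes_mm, self.rim_semiaxes_mm)
        ):
            raise ContractError("core semiaxes must be strictly inside the rim")

    def center_mm(self) -> Tuple[float, float, float]:
        if self.core_center_mm is not None:
            return self.core_center_mm
        return tuple((n - 1) / 2.0 * d for n, d in zip(self.shape, self.spacing))


@dataclass
class PhantomResult:
    """A generated scene plus its ground truth."""

    volume: Volume3D
    plaque_truth: Mask3D  # rim union core
    hsp_truth: Mask3D  # core only
    muscle_roi: Mask3D
    manual_seed: SeedPoint
    spec: PhantomSpec = field(repr=False, default=None)

    def __iter__(self):
        yield from (
            self.volume,
            self.plaque_truth,
            self.hsp_truth,
            self.muscle_roi,
            self.manual_seed,
        )


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in shape]]
    q = sum(
        ((g * s - c) / a) ** 2
        for g, s, c, a in zip(grids, spacing, center_mm, semiaxes_mm)
    )
    return q <= 1.0


def _block(shape, spacing, center_mm, halfsize_mm) -> np.ndarray:
    grids = np.ogrid[[slice(0, n) for n in shape]]
    inside = [
        np.abs(g * s - c) <= h
        for g, s, c, h in zip(grids, spacing, center_mm, halfsize_mm)
    ]
    return inside[0] & inside[1] & inside[2]


def generate_phantom(spec: Optional[PhantomSpec] = None) -> PhantomResult:
    """Build a phantom volume with truth masks and a manual seed.

    Deterministic for a fixed ``spec.rng_seed``. The manual seed is a
    random core voxel perturbed by up to 2 voxels per axis (re-drawn
    until it stays inside the plaque), mimicking an imprecise operator
    click near the plaque center.
    """
    spec = spec or PhantomSpec()
    center = spec.center_mm()
    core = _ellipsoid(spec.shape, spec.spacing, center, spec.core_semiaxes_mm)
    rim = _ellipsoid(spec.shape, spec.spacing, center, spec.rim_semiaxes_mm)
    if not core.any():
        raise ContractError("core ellipsoid rasterizes to an empty mask")
    if not np.all(rim[core]):
        raise ContractError("rasterized core is not contained in the rim")

    muscle = _block(spec.shape, spec.spacing, spec.muscle_center_mm, spec.muscle_halfsize_mm)
    if not muscle.any():
        raise ContractError("muscle block rasterizes to an empty mask")
    if (muscle & ndi.binary_dilation(rim, iterations=2)).any():
        raise ContractError("muscle block overlaps or touches the plaque")
    roi_half = tuple(h - spec.muscle_roi_margin_mm for h in spec.muscle_halfsize_mm)
    if any(h <= 0 for h in roi_half):
        raise ContractError("muscle ROI margin leaves no interior")
    muscle_roi = _block(spec.shape, spec.spacing, spec.muscle_center_mm, roi_half)

    data = np.full(spec.shape, float(spec.background_mean))
    data[muscle] = spec.muscle_mean
    data[rim] = spec.rim_intensity
    data[core] = spec.core_intensity

    rng = np.random.default_rng(spec.rng_seed)

    # manual seed: random core voxel, jittered by <= 2 voxels, kept inside plaque
    core_idx = np.argwhere(core)
    base = core_idx[rng.integers(len(core_idx))]
    while True:
        cand = base + rng.integers(-2, 3, size=3)
        if np.all(cand >= 0) and np.all(cand < spec.shape) and rim[tuple(cand)]:
            break
    manual_seed = SeedPoint(int(cand[0]), int(cand[1]), int(cand[2]), kind="manual")

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = Volume3D(data=data, spacing=spec.spacing)
    mk = lambda m: Mask3D(data=m, spacing=spec.spacing)
    return PhantomResult(
        volume=volume,
        plaque_truth=mk(rim),
        hsp_truth=mk(core),
        muscle_roi=mk(muscle_roi),
        manual_seed=manual_seed,
        spec=spec,
    )


def dice(a: Mask3D, b: Mask3D) -> float:
    """Dice overlap ``2|A&B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)
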