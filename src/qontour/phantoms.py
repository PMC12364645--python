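"""Synthetic abdominal phantoms with ground-truth liver masks and markers.

The restricted multi-phase abdominal MR dataset that motivated this
package is not publicly available, so every method here is exercised on
synthetic phantoms that emulate its statistical structure: a single
bright ellipsoidal organ ("liver") over darker background tissue, with
additive Gaussian noise, a smooth multiplicative bias field, and three
contrast phases realized as liver-intensity rescalings.

Phase multipliers (applied to the liver mean only) are fixtures, not
claims about MR physics: pre-contrast 1.0, arterial 1.3, venous 1.15.

Markers stand in for the AI predictions the original study used to mark
quantum states: ``oracle`` returns the truth, ``eroded``/``dilated``
shrink/grow it by one voxel, and ``noisy`` flips a seeded fraction of
boundary voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, ImageVolume

__all__ = [
    "PHASE_MULTIPLIERS",
    "PhantomSpec",
    "MarkerSpec",
    "generate_phantom",
    "make_marker",
    "save_case",
]

PHASE_MULTIPLIERS = {"pre-contrast": 1.0, "arterial": 1.3, "venous": 1.15}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom volume.

    ``shape`` may be 2D or 3D. The liver is the interior of an analytic
    ellipsoid; an optional dark distractor sphere exercises
    largest-connected-component post-processing. Intensities are in
    arbitrary units; ``bias_amplitude`` is the peak relative deviation of
    the multiplicative bias field (0 disables it).
    """

    shape: tuple[int, ...] = (24, 64, 64)
    liver_center: tuple[float, ...] | None = None
    liver_axes: tuple[float, ...] | None = None
    liver_intensity: float = 180.0
    background_intensity: float = 80.0
    distractor_intensity: float | None = None
    distractor_center: tuple[float, ...] | None = None
    distractor_radius: float = 4.0
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    phase: str = "pre-contrast"
    spacing: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ndim = len(self.shape)
        if ndim not in (2, 3) or min(self.shape) < 1:
            raise ValueError("shape must be 2D or 3D with positive axes")
        if self.phase not in PHASE_MULTIPLIERS:
            raise ValueError(f"phase must be one of {sorted(PHASE_MULTIPLIERS)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if min(self.liver_intensity, self.background_intensity) < 0:
            raise ValueError("intensities must be >= 0")
        center = self.liver_center or tuple(s / 2.0 for s in self.shape)
        axes = self.liver_axes or tuple(s / 3.5 for s in self.shape)
        if len(center) != ndim or len(axes) != ndim:
            raise ValueError("liver_center/axes must match shape dimensionality")
        for c, a, s in zip(center, axes, self.shape):
            if a <= 0:
                raise ValueError("ellipsoid axes must be positive")
            if c - a < 0 or c + a > s:
                raise ValueError("ellipsoid must fit inside the grid")
        object.__setattr__(self, "liver_center", tuple(float(c) for c in center))
        object.__setattr__(self, "liver_axes", tuple(float(a) for a in axes))
        object.__setattr__(
            self, "spacing", tuple(self.spacing) or (1.0,) * ndim
        )


@dataclass(frozen=True)
class MarkerSpec:
    """How to corrupt a ground-truth mask into a marker mask."""

    mode: str = "oracle"  # oracle | eroded | dilated | noisy
    error_rate: float = 0.0
    iterations: int = 1  # structuring-element passes for eroded/dilated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "eroded", "dilated", "noisy"):
            raise ValueError(f"unknown marker mode: {self.mode}")
        if not 0 <= self.error_rate <= 0.5:
            raise ValueError("error_rate must be in [0, 0.5]")


def _ellipsoid_mask(
    shape: tuple[int, ...], center: tuple[float, ...], axes: tuple[float, ...]
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def _bias_field(shape: tuple[int, ...], amplitude: float) -> np.ndarray:
    """Smooth multiplicative field in [1-amplitude, 1+amplitude].

    Product of one half-period cosine per axis, rescaled so the field's
    extremes hit exactly 1 ± amplitude.
    """
    if amplitude == 0:
        return np.ones(shape)
    field_ = np.ones(shape)
    for ax, n in enumerate(shape):
        t = np.cos(np.pi * np.arange(n) / max(n - 1, 1))  # half period: +1 → −1
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        field_ = field_ * t[tuple(sl)]
    lo, hi = field_.min(), field_.max()
    unit = (field_ - lo) / (hi - lo)  # onto [0, 1]
    return 1.0 - amplitude + 2.0 * amplitude * unit


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Generate a phantom image and its exact ground-truth liver mask.

    The image is (phase-scaled piecewise means) × bias field + noise; the
    mask is the analytic ellipsoid interior. Identical specs produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    liver = _ellipsoid_mask(spec.shape, spec.liver_center, spec.liver_axes)
    img = np.full(spec.shape, spec.background_intensity, dtype=float)
    img[liver] = spec.liver_intensity * PHASE_MULTIPLIERS[spec.phase]
    if spec.distractor_intensity is not None:
        center = spec.distractor_center or tuple(s / 5.0 for s in spec.shape)
        radius = (spec.distractor_radius,) * len(spec.shape)
        distractor = _ellipsoid_mask(spec.shape, center, radius) & ~liver
        img[distractor] = spec.distractor_intensity
    img = img * _bias_field(spec.shape, spec.bias_amplitude)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return (
        ImageVolume(img, spec.spacing),
        BinaryMask(liver, spec.spacing),
    )


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices of the two-sided boundary band: inner boundary plus the
    background voxels face-adjacent to the mask."""
    inner = mask & ~ndimage.binary_erosion(mask, border_value=0)
    outer = ndimage.binary_dilation(mask) & ~mask
    return np.argwhere(inner | outer)


def make_marker(truth: BinaryMask, spec: MarkerSpec) -> BinaryMask:
    """Derive a marker mask from ground truth per the marker spec.

    ``noisy`` flips exactly ``round(error_rate * n_boundary)`` voxels of
    the boundary band, chosen with the spec's seed.
    """
    if spec.mode == "oracle":
        return truth
    data = truth.data
    if not data.any():
        raise ValueError("truth mask is empty; only oracle mode is defined")
    if spec.mode == "eroded":
        out = ndimage.binary_erosion(data, iterations=spec.iterations, border_value=0)
    elif spec.mode == "dilated":
        out = ndimage.binary_dilation(data, iterations=spec.iterations)
    else:  # noisy
        out = data.copy()
        boundary = _boundary_voxels(data)
        n_flip = int(round(spec.error_rate * len(boundary)))
        if n_flip > 0:
            rng = np.random.default_rng(spec.seed)
            picks = rng.choice(len(boundary), size=n_flip, replace=False)
            idx = tuple(boundary[picks].T)
            out[idx] = ~out[idx]
    return truth.with_data(out)


def save_case(
    spec: PhantomSpec,
    marker_spec: MarkerSpec,
    out_dir: str | Path,
    stem: str = "case",
) -> dict[str, str]:
    """Write image/mask/marker NIfTI files plus a JSON sidecar of the spec."""
    from .imaging import write_mask, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img, truth = generate_phantom(spec)
    marker = make_marker(truth, marker_spec)
    paths = {
        "image": str(out_dir / f"{stem}_image.nii.gz"),
        "truth": str(out_dir / f"{stem}_truth.nii.gz"),
        "marker": str(out_dir / f"{stem}_marker.nii.gz"),
        "sidecar": str(out_dir / f"{stem}_spec.json"),
    }
    write_volume(img, paths["image"])
    write_mask(truth, paths["truth"])
    write_mask(marker, paths["marker"])
    sidecar = {"phantom": asdict(spec), "marker": asdict(marker_spec)}
    Path(paths["sidecar"]).write_text(json.dumps(sidecar, indent=2))
    return paths
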