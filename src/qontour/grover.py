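"""NAQSS image encoding and simulated Grover amplitude amplification.

An image with N = 2^n elements is encoded as a real amplitude vector
over the location basis states |i> (concatenated coordinate bits): each
intensity is quantized to one of M levels, mapped to a color angle
a_i = (pi/2)(level-1)/(M-1), and the angles are L2-normalized into
amplitudes theta_i. A marker mask supplies the per-state label bit
(chi_i = 1 marks candidate foreground).

Grover's search is simulated algebraically on that amplitude vector: the
oracle flips the sign of marked amplitudes and the diffusion operator
reflects all amplitudes about their mean. The optimal iteration count is

    t = round((1/omega) * (pi/2 - phi)),
    omega = arccos(1 - 2r/N),
    phi   = arctan((A0/L0) * sqrt(r/(N-r))),

with r marked states out of N, and A0/L0 the average amplitudes of the
marked/unmarked states. For a uniform start (A0 = L0) this reduces to
the textbook rotation with success probability sin^2((2k+1) alpha),
sin(alpha) = sqrt(r/N), and t ~ (pi/4) sqrt(N/r).

Everything runs on a classical real-amplitude vector (no gate
decomposition, no noise model); a small-n full statevector path exists
in the test suite as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .imaging import BinaryMask, DegenerateInputError, ImageVolume
from .metrics import postprocess_mask

__all__ = [
    "NaqssState",
    "GroverPlan",
    "NoMarkedStatesError",
    "naqss_encode",
    "grover_plan",
    "grover_iterate",
    "grover_success_probability",
    "grover_segment",
    "index_to_coords",
    "coords_to_index",
]


class NoMarkedStatesError(ValueError):
    """Raised when the marker marks no states (r = 0)."""


@dataclass(frozen=True)
class NaqssState:
    """Amplitude vector over 2^n location states with per-state labels.

    ``amplitudes`` is L2-normalized; padded states (beyond the original
    element count) carry amplitude 0 and label 0. ``shape`` remembers the
    original grid so recovered labels can be mapped back to voxels.
    """

    amplitudes: np.ndarray
    labels: np.ndarray
    M: int
    color_angles: np.ndarray
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.amplitudes)
        if n & (n - 1) != 0:
            raise ValueError("state length must be a power of two")
        norm = float(np.sum(self.amplitudes**2))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"amplitudes not normalized: sum sq = {norm}")

    @property
    def N(self) -> int:
        return len(self.amplitudes)

    @property
    def r(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class GroverPlan:
    """Closed-form iteration plan for one encoded state."""

    N: int
    r: int
    A0: float
    L0: float
    omega: float
    phi: float
    t: int

    def to_dict(self) -> dict:
        return asdict(self)


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def index_to_coords(i: int, shape: tuple[int, ...]) -> tuple[int, ...]:
    """Location basis index -> grid coordinates (row-major)."""
    return tuple(int(c) for c in np.unravel_index(i, shape))


def coords_to_index(coords: tuple[int, ...], shape: tuple[int, ...]) -> int:
    """Grid coordinates -> location basis index (row-major)."""
    return int(np.ravel_multi_index(coords, shape))


def quantize_levels(values: np.ndarray, M: int) -> np.ndarray:
    """Quantize intensities to levels 1..M by uniform min-max binning."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=int)
    levels = 1 + np.floor((values - lo) / (hi - lo) * M).astype(int)
    return np.clip(levels, 1, M)


def naqss_encode(
    values: ImageVolume | np.ndarray,
    marker: BinaryMask | np.ndarray,
    M: int = 256,
) -> NaqssState:
    """Encode an image (or superpixel mean array) into an NAQSS state.

    Quantizes each element to a level in {1..M}, maps levels to color
    angles a_i = (pi/2)(level-1)/(M-1), normalizes the angles into
    amplitudes, copies labels from the marker, and pads to the next power
    of two with zero-amplitude label-0 states.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    data = values.data if isinstance(values, ImageVolume) else np.asarray(values, float)
    labels_in = marker.data if isinstance(marker, BinaryMask) else np.asarray(marker)
    labels_in = labels_in.astype(bool)
    if labels_in.shape != data.shape:
        raise ValueError("marker shape must match image shape")
    levels = quantize_levels(data.ravel(), M)
    a = (np.pi / 2) * (levels - 1) / (M - 1)
    norm_sq = float(np.sum(a**2))
    if norm_sq == 0:
        raise DegenerateInputError(
            "all elements at the minimum intensity level: color angles are all "
            "zero and the state cannot be normalized"
        )
    n_states = _next_pow2(data.size)
    theta = np.zeros(n_states)
    theta[: data.size] = a / math.sqrt(norm_sq)
    labels = np.zeros(n_states, dtype=np.uint8)
    labels[: data.size] = labels_in.ravel().astype(np.uint8)
    angles = np.zeros(n_states)
    angles[: data.size] = a
    return NaqssState(theta, labels, M, angles, tuple(data.shape))


def grover_plan(state: NaqssState) -> GroverPlan:
    """Compute the optimal iteration count from the encoded state.

    phi uses the reading phi = arctan((A0/L0) sqrt(r/(N-r))); when the
    unmarked average amplitude L0 is 0 the initial state is already
    aligned with the marked subspace and t = 0.
    """
    N, r = state.N, state.r
    if r == 0:
        raise NoMarkedStatesError("no marked states: Grover has nothing to amplify")
    marked = state.labels.astype(bool)
    A0 = float(state.amplitudes[marked].mean())
    L0 = float(state.amplitudes[~marked].mean()) if r < N else 0.0
    omega = math.acos(max(-1.0, min(1.0, 1.0 - 2.0 * r / N)))
    if r == N:
        return GroverPlan(N, r, A0, L0, omega, math.pi / 2, 0)
    if L0 <= 0:
        phi = math.pi / 2
    else:
        phi = math.atan((A0 / L0) * math.sqrt(r / (N - r)))
    t_raw = (math.pi / 2 - phi) / omega
    t = max(0, math.floor(t_raw + 0.5))  # round half up
    return GroverPlan(N, r, A0, L0, omega, phi, t)


def grover_iterate(state: NaqssState, k: int) -> NaqssState:
    """Apply k rounds of oracle (sign flip on marked) + diffusion
    (reflection of all amplitudes about their mean)."""
    if k < 0:
        raise ValueError("iteration count must be >= 0")
    theta = state.amplitudes.copy()
    marked = state.labels.astype(bool)
    for _ in range(k):
        theta[marked] *= -1.0
        theta = 2.0 * theta.mean() - theta
    return NaqssState(theta, state.labels, state.M, state.color_angles, state.shape)


def grover_success_probability(state: NaqssState, k: int) -> float:
    """Summed squared amplitude over marked states after k iterations."""
    after = grover_iterate(state, k)
    return float(np.sum(after.amplitudes[after.labels.astype(bool)] ** 2))


def grover_segment(
    img: ImageVolume,
    marker: BinaryMask,
    superpixels: "SuperpixelGraph | None" = None,
    M: int = 256,
    postprocess: bool = True,
) -> tuple[BinaryMask, GroverPlan]:
    """Grover-based segmentation: amplify the marker-marked states.

    Optionally encodes at superpixel granularity (a superpixel is marked
    when most of its voxels are marked) and broadcasts recovered labels
    back to member voxels. Recovered set: states whose final squared
    amplitude exceeds the uniform level 1/N.
    """
    if not marker.data.any():
        raise NoMarkedStatesError("marker mask is empty")
    if superpixels is not None:
        sp_marked = superpixels.majority_labels(marker.data)
        state = naqss_encode(superpixels.means, sp_marked, M)
    else:
        state = naqss_encode(img, marker, M)
    plan = grover_plan(state)
    final = grover_iterate(state, plan.t)
    recovered = final.amplitudes**2 > 1.0 / final.N
    n_real = int(np.prod(state.shape))
    recovered = recovered[:n_real].reshape(state.shape)
    if superpixels is not None:
        voxel_mask = recovered[superpixels.memberships]
    else:
        voxel_mask = recovered
    mask = BinaryMask(voxel_mask, marker.spacing, affine=marker.affine)
    if postprocess:
        mask = postprocess_mask(mask)
    return mask, plan
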