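"""Quantum-resource accounting.

Counts the qubits needed to hold an image in the NAQSS superposition
encoding (n location qubits for 2^n pixels plus one intensity/label
qubit), the classical storage the same image needs, and the logical
annealer variables of the graph-cut formulation (one per superpixel).

Megabytes use the decimal convention (1 MB = 8x10^6 bits), matching the
usual "2.42 Gigabits ~ 300 Megabytes" arithmetic for a 32-bit
1024x1024x72 volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

__all__ = [
    "ResourceReport",
    "naqss_qubits",
    "classical_storage",
    "annealer_logical_qubits",
    "resource_report",
]


@dataclass(frozen=True)
class ResourceReport:
    n_pixels: int
    location_qubits: int
    total_qubits: int
    storage_bits: int
    storage_megabytes: float
    annealer_logical_qubits: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def naqss_qubits(dims: Sequence[int]) -> tuple[int, int]:
    """(location, total) qubit counts for a grid of the given dimensions.

    location = ceil(log2(prod(dims))); total adds the one intensity qubit.
    """
    dims = tuple(int(d) for d in dims)
    if not dims or any(d < 1 for d in dims):
        raise ValueError("dims must be non-empty positive integers")
    n_pixels = math.prod(dims)
    location = max(1, math.ceil(math.log2(n_pixels))) if n_pixels > 1 else 1
    return location, location + 1


def classical_storage(dims: Sequence[int], bit_depth: int) -> tuple[int, float]:
    """(bits, megabytes) of raw classical storage for the grid."""
    if bit_depth not in (8, 16, 32, 64):
        raise ValueError("bit_depth must be one of 8, 16, 32, 64")
    dims = tuple(int(d) for d in dims)
    if not dims or any(d < 1 for d in dims):
        raise ValueError("dims must be non-empty positive integers")
    bits = math.prod(dims) * bit_depth
    return bits, bits / 8e6


def annealer_logical_qubits(n_superpixels: int) -> int:
    """One binary annealing variable per superpixel graph node."""
    if n_superpixels < 1:
        raise ValueError("need at least one superpixel")
    return int(n_superpixels)


def resource_report(
    dims: Sequence[int], bit_depth: int = 32, n_superpixels: int | None = None
) -> ResourceReport:
    location, total = naqss_qubits(dims)
    bits, mb = classical_storage(dims, bit_depth)
    return ResourceReport(
        n_pixels=math.prod(int(d) for d in dims),
        location_qubits=location,
        total_qubits=total,
        storage_bits=bits,
        storage_megabytes=mb,
        annealer_logical_qubits=(
            annealer_logical_qubits(n_superpixels) if n_superpixels else None
        ),
    )
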