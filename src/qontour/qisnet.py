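"""Self-supervised quantum-inspired qutrit fuzzy segmentation network.

Each pixel neighborhood (a pixel and its eight nearest neighbors) is
mapped to a qutrit-like state whose population in [0, 1] is evolved by
two rotation layers — a counter-clockwise rotation R(theta) followed by
a clockwise rotation R(-theta) — and measured as |<z|z>|^2. The network
has no trained weights; structure emerges from the fuzzy interplay of
neighborhood features:

* B_t: the 3x3 intensity sum ("cardinality"), with amplitude A_t = 2 pi B_t;
* omega_t = 2 pi (2 pi - d_t), d_t the summed neighbor-minus-center
  intensity differences (the frequency);
* x_t = sum_j mu_j cos(omega_t - A_t), the aggregated input;
* alpha_{t,j} = pi/2 - (mu_t - mu_j), the fuzzy membership angle between
  a pixel and neighbor j (interconnection phi = [cos a, sin a]);
* gamma_t, the threshold angle of eta = [cos g, sin g];
* lambda_omega, a per-pixel gray-level index in (0, 1] read off a
  multi-class gray-level transition table;
* the activation sigma(x) = 1 / (lambda_omega + exp(-nu (x - beta))).

Printed formulations of this network are index-ambiguous in places; the
exact reading used here is isolated in :func:`neighborhood_features` and
:func:`qisnet_iterate` and documented in docs/methods.md. Notably the
threshold angle is taken as gamma_t = (pi/2) * mean of the 8 neighbor
intensities: a full 2 pi times the neighbor *sum* is degenerate modulo
2 pi at both intensity extremes (all-0 and all-1 neighborhoods collapse
onto the same angle), whereas a quarter-period span keeps the threshold
monotone in neighborhood brightness.

Border pixels are handled by edge-replication padding. Intensities are
min-max scaled to [0, 1] first, so the output is invariant to adding a
constant to the raw image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging import BinaryMask, ImageVolume, minmax_scale
from .metrics import EvalRecord, dice, hausdorff, multi_otsu_highest, postprocess_mask
from .imaging import DegenerateInputError

__all__ = [
    "TRANSITION_TABLE",
    "DEFAULT_NU_SWEEP",
    "QisnetParams",
    "QutritField",
    "quantum_sigmoid",
    "neighborhood_features",
    "qisnet_iterate",
    "qisnet_segment",
    "qisnet_sweep",
]

# Multi-class gray-level transition rows F_lambda-omega-L (fractions of
# pi/2). Rows 1-11 are the published candidate tables; row 12 is the
# variant reported as consistently best (differing from row 2 in its
# second level, 0.04 vs 0.14) and is the default.
TRANSITION_TABLE: tuple[tuple[float, ...], ...] = (
    (0.0, 0.15, 0.30, 0.46, 0.61, 0.76, 0.91, 1.0),
    (0.0, 0.14, 0.28, 0.42, 0.56, 0.70, 0.90, 1.0),
    (0.0, 0.13, 0.26, 0.39, 0.52, 0.75, 0.91, 1.0),
    (0.0, 0.18, 0.36, 0.54, 0.72, 0.90, 0.97, 1.0),
    (0.0, 0.17, 0.34, 0.51, 0.68, 0.85, 0.95, 1.0),
    (0.0, 0.15, 0.29, 0.43, 0.57, 0.71, 0.85, 1.0),
    (0.0, 0.15, 0.30, 0.46, 0.61, 0.76, 0.91, 1.0),
    (0.0, 0.62, 0.71, 0.80, 0.83, 0.93, 0.98, 1.0),
    (0.0, 0.60, 0.72, 0.82, 0.94, 0.96, 0.98, 1.0),
    (0.0, 0.63, 0.74, 0.79, 0.82, 0.88, 0.97, 1.0),
    (0.0, 0.70, 0.74, 0.79, 0.82, 0.88, 0.98, 1.0),
    (0.0, 0.04, 0.28, 0.42, 0.56, 0.70, 0.90, 1.0),
)

DEFAULT_NU_SWEEP: tuple[float, ...] = (0.02, 0.03, 0.04, 0.05)

_OFFSETS = [(p, c) for p in (-1, 0, 1) for c in (-1, 0, 1) if (p, c) != (0, 0)]


@dataclass(frozen=True)
class QisnetParams:
    """Hyperparameters of the network.

    nu: steepness of the activation; beta: activation midpoint (defaults
    to 0.5 on the [0, 1]-scaled input); transition_table_index: 1-based
    row of the gray-level transition table (12 = the best-reported
    variant); tol/max_iters: convergence controls on the mean absolute
    population change.
    """

    nu: float = 0.04
    beta: float = 0.5
    transition_table_index: int = 12
    max_iters: int = 50
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be > 0")
        if not 1 <= self.transition_table_index <= len(TRANSITION_TABLE):
            raise ValueError(
                f"transition_table_index must be in 1..{len(TRANSITION_TABLE)}"
            )
        if self.max_iters < 1 or self.tol <= 0:
            raise ValueError("max_iters >= 1 and tol > 0 required")

    @property
    def transition_row(self) -> np.ndarray:
        return np.asarray(TRANSITION_TABLE[self.transition_table_index - 1])


@dataclass
class QutritField:
    """Per-pixel state and the fixed neighborhood features driving it."""

    state: np.ndarray           # population |<z|z>|^2 in [0, 1], shape (H, W)
    mu: np.ndarray              # scaled intensities, shape (H, W)
    neighbors: np.ndarray       # mu of the 8 neighbors, shape (8, H, W)
    B: np.ndarray               # 3x3 intensity sum (cardinality)
    A: np.ndarray               # amplitude 2 pi B
    omega: np.ndarray           # frequency 2 pi (2 pi - d)
    x: np.ndarray               # aggregated input
    alpha: np.ndarray           # membership angles, shape (8, H, W)
    gamma: np.ndarray           # threshold angle
    lambda_omega: np.ndarray    # gray-level index in (0, 1]
    mean_change: float = float("inf")

    def copy_with_state(self, state: np.ndarray, mean_change: float) -> "QutritField":
        return replace(self, state=state, mean_change=mean_change)


def quantum_sigmoid(
    x: np.ndarray | float, params: QisnetParams, lambda_omega: np.ndarray | float
) -> np.ndarray | float:
    """sigma(x) = 1 / (lambda_omega + exp(-nu (x - beta)))."""
    if np.any(np.asarray(lambda_omega) <= 0):
        raise ValueError("lambda_omega must be > 0")
    expo = np.clip(-params.nu * (np.asarray(x, float) - params.beta), -700, 700)
    return 1.0 / (lambda_omega + np.exp(expo))


def _neighbor_stack(mu: np.ndarray) -> np.ndarray:
    """The 8 neighbor intensity maps via edge-replication padding."""
    padded = np.pad(mu, 1, mode="edge")
    h, w = mu.shape
    return np.stack(
        [padded[1 + p : 1 + p + h, 1 + c : 1 + c + w] for p, c in _OFFSETS]
    )


def _lambda_omega(neighbor_sum: np.ndarray, row: np.ndarray) -> np.ndarray:
    """Gray-level index: the transition-table interval width selected by
    the quantization bin of the 8-neighbor sum, scaled onto (0, 1]."""
    widths = np.diff(row)  # 7 interval widths
    u = np.clip(neighbor_sum / 8.0, 0.0, 1.0)
    bins = np.minimum((u * len(widths)).astype(int), len(widths) - 1)
    lam = widths[bins] / widths.max()
    return np.maximum(lam, 1e-6)


def neighborhood_features(img: ImageVolume | np.ndarray, params: QisnetParams | None = None) -> QutritField:
    """Compute the fixed qutrit features of a 2D slice.

    Input intensities are min-max scaled to [0, 1]; the state is
    initialized to the scaled intensity map.
    """
    params = params or QisnetParams()
    data = img.data if isinstance(img, ImageVolume) else np.asarray(img, float)
    if data.ndim != 2:
        raise ValueError(f"expected a 2D slice, got {data.ndim}D")
    mu = minmax_scale(data)
    nb = _neighbor_stack(mu)
    neighbor_sum = nb.sum(axis=0)             # S_N in [0, 8]
    B = neighbor_sum + mu                     # 3x3 cardinality
    A = 2.0 * np.pi * B
    d = (nb - mu).sum(axis=0)                 # summed neighbor differences
    omega = 2.0 * np.pi * (2.0 * np.pi - d)
    x = (nb * np.cos(omega - A)).sum(axis=0)
    alpha = np.pi / 2 - (mu - nb)             # shape (8, H, W)
    gamma = (np.pi / 2) * neighbor_sum / 8.0  # threshold angle (see module doc)
    lam = _lambda_omega(neighbor_sum, params.transition_row)
    return QutritField(
        state=mu.copy(),
        mu=mu,
        neighbors=nb,
        B=B,
        A=A,
        omega=omega,
        x=x,
        alpha=alpha,
        gamma=gamma,
        lambda_omega=lam,
    )


def _state_neighbors(state: np.ndarray) -> np.ndarray:
    return _neighbor_stack(state)


def _layer(field: QutritField, params: QisnetParams, state: np.ndarray, sign: float) -> np.ndarray:
    """One rotation layer: R(theta) for sign=+1, R(-theta) for sign=-1.

    Output neuron: z_t = sigma(x_t) * sum_j <phi_{t,j}|eta_t> e^{+/- i 2 pi s_j},
    measured as the clamped population |z_t|^2. The bra-ket product
    <phi|eta> = cos(alpha - gamma).
    """
    weights = np.cos(field.alpha - field.gamma)          # (8, H, W)
    phases = np.exp(sign * 2j * np.pi * _state_neighbors(state))
    z = quantum_sigmoid(field.x, params, field.lambda_omega) * (weights * phases).sum(axis=0)
    return np.clip(np.abs(z) ** 2, 0.0, 1.0)


def qisnet_iterate(field: QutritField, params: QisnetParams) -> QutritField:
    """One forward/backward rotation pass; returns the updated field with
    its mean absolute population change."""
    hidden = _layer(field, params, field.state, +1.0)
    new_state = _layer(field, params, hidden, -1.0)
    change = float(np.abs(new_state - field.state).mean())
    return field.copy_with_state(new_state, change)


def _segment_slice(
    data: np.ndarray, params: QisnetParams
) -> tuple[np.ndarray, bool, int]:
    """Run the network on one 2D slice; returns (binary map, warned, iters)."""
    field = neighborhood_features(data, params)
    iters = 0
    for iters in range(1, params.max_iters + 1):
        field = qisnet_iterate(field, params)
        assert 0.0 <= field.state.min() and field.state.max() <= 1.0
        if field.mean_change < params.tol:
            break
    pop = field.state
    try:
        thr = multi_otsu_highest(pop, levels=4)
    except DegenerateInputError:
        distinct = np.unique(pop)
        if len(distinct) < 2:
            return np.zeros_like(pop, dtype=bool), True, iters
        thr = float(distinct[:-1].max())  # binarize at the gap below the top value
    mask = pop > thr
    return mask, not mask.any(), iters


def qisnet_segment(
    img: ImageVolume, params: QisnetParams | None = None, postprocess: bool = True
) -> tuple[BinaryMask, dict]:
    """Segment a 2D slice or (slice-wise) a 3D volume.

    Iterates the network to convergence or ``max_iters``, binarizes the
    final population map at the highest 4-level Otsu threshold, then
    keeps the largest connected component and fills holes. Returns the
    mask and an info dict with a ``warning`` flag set when the
    thresholded map came out empty.
    """
    params = params or QisnetParams()
    data = img.data
    if data.ndim == 2:
        seg, warned, iters = _segment_slice(data, params)
        info = {"warning": warned, "iterations": iters}
    else:
        slices, warns, iters_all = [], [], []
        for k in range(data.shape[0]):
            seg_k, warn_k, it_k = _segment_slice(data[k], params)
            slices.append(seg_k)
            warns.append(warn_k)
            iters_all.append(it_k)
        seg = np.stack(slices)
        info = {"warning": all(warns), "iterations": max(iters_all)}
    mask = BinaryMask(seg, img.spacing, affine=img.affine)
    if postprocess and seg.any():
        mask = postprocess_mask(mask)
    return mask, info


def qisnet_sweep(
    img: ImageVolume,
    truth: BinaryMask,
    nus: tuple[float, ...] = DEFAULT_NU_SWEEP,
    params: QisnetParams | None = None,
    case_id: str = "",
) -> tuple[BinaryMask, EvalRecord]:
    """Run the network per steepness value and keep the best-Dice mask
    (the per-patient nu optimization protocol)."""
    if len(nus) == 0:
        raise ValueError("nu sweep list must be nonempty")
    if truth.shape != img.shape:
        raise ValueError("truth shape must match image shape")
    base = params or QisnetParams()
    best: tuple[float, BinaryMask, float] | None = None
    for nu in nus:
        mask, _ = qisnet_segment(img, replace(base, nu=nu))
        score = dice(mask, truth)
        if best is None or score > best[0]:
            best = (score, mask, nu)
    score, mask, nu = best
    record = EvalRecord(
        method="qisnet",
        dice=score,
        hausdorff=hausdorff(mask, truth) if mask.data.any() else float("inf"),
        params={"nu": nu, "table": base.transition_table_index},
        case_id=case_id,
    )
    return mask, record
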