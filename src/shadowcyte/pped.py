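"""Projected Principal-Edge Distribution (PPED) features.

PPED summarizes a 64×64 grayscale patch as a 64-dimensional vector that
is sensitive to the shape of its edges but robust to resolution loss —
the property that makes it usable on blurry lens-free shadow crops.
The chain is:

1. Correlate the patch with four zero-sum 5×5 kernels, one per
   principal edge orientation (horizontal, +45°, vertical, −45°), and
   take the magnitude of each response. Pixels whose 5×5 window leaves
   the patch get response 0.
2. At each pixel, if the strongest of the four responses clears a local
   threshold, set a binary edge flag for that single orientation
   (argmax assignment; ties resolve in the fixed order H, +45°, V, −45°).
3. Project each flag map along its own orientation: column sums for H,
   row sums for V, anti-diagonal sums (m = i + j) for +45° and diagonal
   sums (m = i − j + 63) for −45°.
4. The two 127-bin diagonal projections are smoothed down to 64 bins
   with a 1/2–1–1/2 stencil, then every projection is folded 4-to-1
   into 16 bins. Concatenating the four 16-bin blocks in the order
   H, +45°, V, −45° gives the descriptor.

Both reductions conserve mass, so the sum of the vector equals the
total number of edge flags — a useful integrity check.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

PATCH_SIZE = 64
KERNEL_RADIUS = 2  # 5x5 kernels
DIRECTIONS = ("H", "D45", "V", "DM45")  # fixed order everywhere

#: Column labels for a feature CSV, 16 per direction block.
FEATURE_NAMES = tuple(
    f"{prefix}{j:02d}"
    for prefix in ("H", "D45_", "V", "DM45_")
    for j in range(16)
)


def _horizontal_kernel() -> np.ndarray:
    k = np.zeros((5, 5), dtype=np.int64)
    k[:2, :] = 1
    k[3:, :] = -1
    return k


def _plus45_kernel() -> np.ndarray:
    # Zero on the anti-diagonal p + q = 0, +1 above it, -1 below.
    p, q = np.meshgrid(np.arange(-2, 3), np.arange(-2, 3), indexing="ij")
    return np.where(p + q < 0, 1, np.where(p + q > 0, -1, 0)).astype(np.int64)


@dataclass(frozen=True)
class KernelSet:
    """The four 5×5 directional edge kernels, in the order H, +45°, V, −45°.

    Each kernel is zero-sum (flat regions give zero response). The
    vertical kernel is the transpose of the horizontal one and the two
    diagonal kernels are mirror images, so transposing a patch swaps the
    roles of the H and V maps.
    """

    kernels: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.kernels) != 4:
            raise ValueError("need exactly four kernels")
        for k in self.kernels:
            if k.shape != (5, 5):
                raise ValueError(f"kernels must be 5x5, got {k.shape}")
            if int(k.sum()) != 0:
                raise ValueError("each kernel must sum to zero")

    @classmethod
    def default(cls) -> "KernelSet":
        h = _horizontal_kernel()
        d45 = _plus45_kernel()
        return cls((h, d45, h.T.copy(), np.fliplr(d45).copy()))

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {d: k.tolist() for d, k in zip(DIRECTIONS, self.kernels)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "KernelSet":
        with open(path) as fh:
            payload = json.load(fh)
        missing = [d for d in DIRECTIONS if d not in payload]
        if missing:
            raise ValueError(f"kernel JSON missing directions {missing}")
        return cls(tuple(np.asarray(payload[d], dtype=np.int64) for d in DIRECTIONS))


def _check_patch(patch: np.ndarray) -> np.ndarray:
    arr = np.asarray(patch, dtype=np.float64)
    if arr.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {arr.shape}")
    return arr


def edge_responses(patch: np.ndarray, kernels: KernelSet | None = None) -> np.ndarray:
    """Absolute directional filter responses, shape (4, 64, 64).

    Response at (x, y) is |Σ_pq K_d(p,q) · I(x+p, y+q)| over the 5×5
    window; the 2-pixel frame where the window exits the patch is 0.
    """
    arr = _check_patch(patch)
    kernels = kernels or KernelSet.default()
    out = np.zeros((4, PATCH_SIZE, PATCH_SIZE), dtype=np.float64)
    r = KERNEL_RADIUS
    for d, k in enumerate(kernels.kernels):
        resp = np.abs(ndimage.correlate(arr, k.astype(np.float64), mode="constant"))
        resp[:r, :] = resp[-r:, :] = 0.0
        resp[:, :r] = resp[:, -r:] = 0.0
        out[d] = resp
    return out


def _local_median_threshold(patch: np.ndarray, floor: float) -> np.ndarray:
    """Per-pixel threshold: median |difference| of the 40 horizontally and
    vertically adjacent pixel pairs inside the 5×5 window, floored.

    The frame (where no full window exists) gets +inf so no flag can be
    set there regardless of response values.
    """
    arr = _check_patch(patch)
    hdiff = np.abs(np.diff(arr, axis=1))  # (64, 63), pair (y, y+1)
    vdiff = np.abs(np.diff(arr, axis=0))  # (63, 64), pair (x, x+1)
    # Pairs fully inside the window of interior pixel (x, y), x,y in 2..61:
    # horizontal pairs span rows x-2..x+2 and start columns y-2..y+1 (5x4);
    # vertical pairs start rows x-2..x+1 and span columns y-2..y+2 (4x5).
    hwin = sliding_window_view(hdiff, (5, 4)).reshape(60, 60, 20)
    vwin = sliding_window_view(vdiff, (4, 5)).reshape(60, 60, 20)
    med = np.median(np.concatenate([hwin, vwin], axis=2), axis=2)
    th = np.full((PATCH_SIZE, PATCH_SIZE), np.inf)
    th[2:-2, 2:-2] = np.maximum(med, floor)
    return th


DEFAULT_THRESHOLD_POLICY = "global-fraction"


def threshold_map(patch: np.ndarray, policy: str = DEFAULT_THRESHOLD_POLICY,
                  floor: float = 1.0, fraction: float = 0.3,
                  responses: np.ndarray | None = None) -> np.ndarray:
    """Edge-detection threshold TH(x, y) under a named policy.

    ``global-fraction`` (the default) takes a flat ``fraction`` of the
    maximum response over the whole patch, so a flag marks an edge
    whose strength is commensurate with the strongest structure in the
    crop; it is contrast-invariant per patch. ``local-median`` adapts
    per pixel (see :func:`_local_median_threshold`) but on smoothly
    interpolated low-resolution crops its scale sits far below the
    response of a 5×5 zero-sum kernel, so it flags nearly every pixel
    and washes out the descriptor; it is kept as a named alternative.
    """
    if policy == "local-median":
        return _local_median_threshold(patch, floor)
    if policy == "global-fraction":
        if responses is None:
            responses = edge_responses(patch)
        return np.full((PATCH_SIZE, PATCH_SIZE), fraction * float(responses.max()))
    raise ValueError(f"unknown threshold policy {policy!r}")


def edge_flags(responses: np.ndarray, th: np.ndarray) -> np.ndarray:
    """Binary flag maps, shape (4, 64, 64), at most one flag per pixel.

    A pixel is flagged for the orientation of its maximal response iff
    that maximum is ≥ TH and strictly positive; argmax ties resolve to
    the earliest direction in the fixed order.
    """
    responses = np.asarray(responses, dtype=np.float64)
    if responses.shape[0] != 4 or responses.shape[1:] != np.asarray(th).shape:
        raise ValueError(f"bad response/threshold shapes {responses.shape} vs {np.shape(th)}")
    mx = responses.max(axis=0)
    winner = responses.argmax(axis=0)  # first max wins: H, +45, V, -45
    keep = (mx >= th) & (mx > 0)
    flags = np.zeros_like(responses, dtype=np.uint8)
    for d in range(4):
        flags[d] = keep & (winner == d)
    return flags


def project_flags(flags: np.ndarray) -> dict[str, np.ndarray]:
    """Orientation-specific projections of the four flag maps.

    Returns ``{"H": (64,), "D45": (127,), "V": (64,), "DM45": (127,)}``:
    column sums of the H map, row sums of the V map, and sums over the
    lines i + j = m (+45°) and i − j + 63 = m (−45°) for the diagonals.
    """
    flags = np.asarray(flags)
    if flags.shape != (4, PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"flags must have shape (4, 64, 64), got {flags.shape}")
    i, j = np.meshgrid(np.arange(PATCH_SIZE), np.arange(PATCH_SIZE), indexing="ij")
    n_diag = 2 * PATCH_SIZE - 1
    return {
        "H": flags[0].sum(axis=0).astype(np.float64),
        "D45": np.bincount((i + j).ravel(), weights=flags[1].ravel(), minlength=n_diag),
        "V": flags[2].sum(axis=1).astype(np.float64),
        "DM45": np.bincount((i - j + PATCH_SIZE - 1).ravel(),
                            weights=flags[3].ravel(), minlength=n_diag),
    }


def reduce_diagonal(p: np.ndarray) -> np.ndarray:
    """Fold a 127-bin diagonal projection to 64 bins.

    ``P'(m) = P(2m−1)/2 + P(2m) + P(2m+1)/2`` with the out-of-range
    bins P(−1) and P(127) taken as 0. Every input bin contributes total
    weight 1, so the sum is conserved exactly.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (127,):
        raise ValueError(f"expected 127 diagonal sums, got shape {p.shape}")
    padded = np.concatenate([[0.0], p, [0.0]])  # index m+1 == original m
    m = np.arange(PATCH_SIZE)
    return padded[2 * m] / 2.0 + padded[2 * m + 1] + padded[2 * m + 2] / 2.0


def reduce_to_16(p: np.ndarray) -> np.ndarray:
    """Merge each run of four neighboring bins of a 64-bin projection."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (PATCH_SIZE,):
        raise ValueError(f"expected 64 sums, got shape {p.shape}")
    return p.reshape(16, 4).sum(axis=1)


def pped_vector(patch: np.ndarray, kernels: KernelSet | None = None,
                threshold_policy: str = DEFAULT_THRESHOLD_POLICY,
                floor: float = 1.0, fraction: float = 0.3) -> np.ndarray:
    """The 64-component PPED descriptor of a 64×64 patch.

    Blocks of 16 in the order H, +45°, V, −45°. All components are
    non-negative multiples of 0.5 and their sum equals the number of
    edge flags set in the patch.
    """
    arr = _check_patch(patch)
    responses = edge_responses(arr, kernels)
    th = threshold_map(arr, threshold_policy, floor=floor, fraction=fraction,
                       responses=responses)
    flags = edge_flags(responses, th)
    proj = project_flags(flags)
    blocks = [
        reduce_to_16(proj["H"]),
        reduce_to_16(reduce_diagonal(proj["D45"])),
        reduce_to_16(proj["V"]),
        reduce_to_16(reduce_diagonal(proj["DM45"])),
    ]
    return np.concatenate(blocks)
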