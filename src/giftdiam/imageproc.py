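"""Deterministic image-processing stages.

These functions take one grayscale micrograph to a multiset of vertical
edge-to-edge pixel distances:

    to_gray8 -> crop_top -> sobel_magnitude -> percent_threshold
      -> make_rotation_stack -> line_opening (per copy)
      -> column_maxima -> gap_distances

Edges are pixels of high Sobel gradient magnitude (a boolean mask).
Rotated copies let fibers of any orientation present near-horizontal edge
segments, which the horizontal line opening isolates; the vertical distance
between consecutive surviving edges in a column recurs at the fiber
diameter, while fiber-to-fiber distances are randomly distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError


# ---------------------------------------------------------------------------
# conversion / cropping


def to_gray8(image: np.ndarray) -> np.ndarray:
    """Convert an arbitrary raster to single-channel 8-bit grayscale.

    Multi-channel images are converted with the Rec. 601 luminance weights;
    integer images deeper than 8 bits and float images are min-max rescaled
    to [0, 255] (a constant image maps to 0). 8-bit single-channel input is
    returned unchanged (as a copy-free view cast).
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        arr = rgb @ np.array([0.299, 0.587, 0.114])
        if np.issubdtype(np.asarray(image).dtype, np.integer) and np.asarray(
            image
        ).dtype.itemsize == 1:
            # 8-bit RGB: luminance already on the 0-255 scale
            return _check_shape(np.clip(np.rint(arr), 0, 255).astype(np.uint8))
    if arr.ndim != 2:
        raise InvalidParameterError(
            f"expected a 2-D image or an RGB(A) raster, got shape {np.shape(image)}"
        )
    if arr.dtype == np.uint8:
        return _check_shape(arr)
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:  # degenerate range maps to 0
        return _check_shape(np.zeros(arr.shape, dtype=np.uint8))
    out = (arr - lo) / (hi - lo) * 255.0
    return _check_shape(np.rint(out).astype(np.uint8))


def _check_shape(img: np.ndarray) -> np.ndarray:
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise InvalidParameterError(
            f"image must be at least 3x3 pixels, got shape {img.shape}"
        )
    return img


def crop_top(img: np.ndarray, keep_rows: int) -> np.ndarray:
    """Keep only the top ``keep_rows`` rows (row 0 = top of image)."""
    if keep_rows < 1:
        raise InvalidParameterError(f"keep_rows must be >= 1, got {keep_rows}")
    if keep_rows > img.shape[0]:
        raise InvalidParameterError(
            f"keep_rows={keep_rows} exceeds image height {img.shape[0]}"
        )
    return img[:keep_rows, :]


# ---------------------------------------------------------------------------
# edges


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) of the standard 3x3 Sobel kernels.

    Borders are handled by edge replication so the image frame itself does
    not produce an artificial gradient ring.
    """
    f = np.asarray(img, dtype=np.float64)
    if f.ndim != 2:
        raise InvalidParameterError("sobel_magnitude expects a 2-D image")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def quantize_gradient(grad: np.ndarray) -> np.ndarray:
    """Clip gradient magnitudes to the 8-bit range (saturating at 255).

    Edge images in 8-bit pipelines saturate: any magnitude >= 255 displays
    as 255. Quantizing before percent thresholding reproduces that tie
    structure — on a binary image every true edge pixel saturates into one
    tie class, so a small threshold percent still keeps all fiber edges
    instead of an arbitrary strongest sub-class.
    """
    mag = np.asarray(grad, dtype=np.float64)
    return np.clip(np.rint(mag), 0, 255).astype(np.uint8)


def percent_threshold(grad: np.ndarray, threshold_percent: float) -> np.ndarray:
    """Mark the strongest-gradient pixels as edges.

    The cutoff is the k-th largest magnitude with k = round(p% * N)
    (clamped to [1, N]); all pixels with magnitude >= cutoff are edges, so
    the whole tie class at the cutoff is included and the result is
    order-independent. Zero-magnitude pixels are never edges: a perfectly
    flat image yields an empty mask.
    """
    if not (0.0 < threshold_percent <= 100.0):
        raise InvalidParameterError(
            f"threshold_percent must be in (0, 100], got {threshold_percent}"
        )
    mag = np.asarray(grad, dtype=np.float64)
    n = mag.size
    k = int(round(threshold_percent / 100.0 * n))
    k = min(max(k, 1), n)
    # k-th largest via partition
    cutoff = np.partition(mag, n - k, axis=None)[n - k]
    return (mag >= cutoff) & (mag > 0)


def edge_fraction(mask: np.ndarray) -> float:
    """Fraction of pixels marked as edges."""
    m = np.asarray(mask)
    return float(np.count_nonzero(m)) / m.size


# ---------------------------------------------------------------------------
# rotation stack


@dataclass
class RotationStack:
    """Rotated copies of an edge mask plus per-copy validity masks.

    ``copies[k]`` is the edge mask rotated by ``angles_deg[k]`` about the
    image center on an expanded canvas (no source pixel lost);
    ``valid_regions[k]`` marks canvas pixels that originate from the source
    image rather than rotation padding. Copy 0 is the unrotated mask.
    """

    copies: list[np.ndarray] = field(default_factory=list)
    angles_deg: list[float] = field(default_factory=list)
    valid_regions: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.copies)


def make_rotation_stack(mask: np.ndarray, angle_step_deg: float) -> RotationStack:
    """Create floor(180/step) rotated copies of a binary edge mask.

    Rotation uses bilinear interpolation on the {0,1}-valued image,
    re-binarized at 0.5; the canvas is expanded to the rotated bounding box
    and padding is non-edge and invalid. Multiples of 90 deg map the pixel
    grid onto itself, so those copies are exact.
    """
    if angle_step_deg <= 0 or angle_step_deg > 90:
        raise InvalidParameterError(
            f"angle_step_deg must be in (0, 90], got {angle_step_deg}"
        )
    quotient = 180.0 / angle_step_deg
    if abs(quotient - round(quotient)) > 1e-9:
        raise InvalidParameterError(
            f"180 must be an integer multiple of angle_step_deg, got {angle_step_deg}"
        )
    n_copies = int(round(quotient))
    m = np.asarray(mask, dtype=bool)
    ones = np.ones(m.shape, dtype=np.float64)
    stack = RotationStack()
    for k in range(n_copies):
        angle = k * angle_step_deg
        if k == 0:
            copy, valid = m.copy(), np.ones(m.shape, dtype=bool)
        else:
            rot = ndimage.rotate(
                m.astype(np.float64), angle, reshape=True, order=1, mode="constant", cval=0.0
            )
            vrot = ndimage.rotate(
                ones, angle, reshape=True, order=1, mode="constant", cval=0.0
            )
            copy = rot >= 0.5
            valid = vrot >= 0.5
            copy &= valid
        stack.copies.append(copy)
        stack.angles_deg.append(float(angle))
        stack.valid_regions.append(valid)
    return stack


# ---------------------------------------------------------------------------
# morphological opening with a horizontal line


def line_opening(mask: np.ndarray, line_length_px: int) -> np.ndarray:
    """Morphological opening with a 1-row horizontal line of given length.

    Erosion followed by dilation: every surviving pixel lies inside a
    horizontal run of at least ``line_length_px`` edge pixels; shorter runs
    (and 1-px-wide vertical features) are removed entirely.
    """
    if line_length_px < 1:
        raise InvalidParameterError(
            f"line_length_px must be >= 1, got {line_length_px}"
        )
    m = np.asarray(mask, dtype=bool)
    if line_length_px == 1:
        return m.copy()
    # Opening with a 1-row line keeps exactly the horizontal runs of length
    # >= L (the union of every line placement contained in the mask), so it
    # can be computed exactly by run-length filtering, with no dependence on
    # structuring-element origin conventions.
    h, w = m.shape
    padded = np.zeros((h, w + 2), dtype=np.int8)
    padded[:, 1:-1] = m
    d = np.diff(padded, axis=1)
    rows_s, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)  # pairs with starts in order
    keep = (ends - starts) >= line_length_px
    out = np.zeros((h, w + 1), dtype=np.int32)
    np.add.at(out, (rows_s[keep], starts[keep]), 1)
    np.add.at(out, (rows_s[keep], ends[keep]), -1)
    return np.cumsum(out, axis=1)[:, :w] > 0


# ---------------------------------------------------------------------------
# column maxima and gap distances


def column_maxima(mask: np.ndarray, valid_region: np.ndarray | None = None):
    """Locate edge positions in every pixel column of a (rotated) edge mask.

    Each maximal contiguous vertical run of edge pixels contributes one
    position: the run's center row, rounding half down (toward the top).
    Runs vertically adjacent to invalid (rotation padding) pixels are
    discarded, since padding would truncate them arbitrarily.

    Returns
    -------
    cols, rows : 1-D integer arrays
        Parallel arrays of column index and center-row position, sorted by
        column then by row.
    """
    m = np.asarray(mask, dtype=bool)
    if valid_region is None:
        valid = np.ones(m.shape, dtype=bool)
    else:
        valid = np.asarray(valid_region, dtype=bool)
        if valid.shape != m.shape:
            raise InvalidParameterError("mask and valid_region must have equal shape")
    h, w = m.shape
    # column-contiguous layout: row i of `t` is column i of the image
    t = m.T
    padded = np.zeros((w, h + 2), dtype=np.int8)
    padded[:, 1:-1] = t
    d = np.diff(padded, axis=1)
    run_cols, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)  # exclusive end; pairs with starts in order
    if run_cols.size == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)

    keep = np.ones(run_cols.size, dtype=bool)
    above = starts - 1
    has_above = above >= 0
    keep[has_above] &= valid[above[has_above], run_cols[has_above]]
    below = ends  # first row after the run
    has_below = below < h
    keep[has_below] &= valid[below[has_below], run_cols[has_below]]

    cols = run_cols[keep]
    centers = (starts[keep] + ends[keep] - 1) // 2  # half rounds toward the top
    return cols.astype(np.intp), centers.astype(np.intp)


@dataclass
class DistanceSample:
    """Pooled multiset of vertical edge-to-edge gap distances.

    Distances are in output units (px divided by the px/um scale).
    ``per_copy_counts[k]`` is the number of distances contributed by rotated
    copy k.
    """

    distances: np.ndarray
    per_copy_counts: list[int]

    @property
    def n(self) -> int:
        return int(self.distances.size)


# Sobel edges are two pixels thick, so two distinct parallel edges closer
# than 3 px cannot be resolved; smaller gaps are re-binarization jitter of a
# single edge line, not fiber diameters.
MIN_RESOLVABLE_GAP_PX = 3

# A fiber diameter recurs along the fiber, so a genuine pair of parallel
# edge segments yields the same gap in many adjacent columns. Gaps between
# a pair of opened-mask components seen in fewer columns than this are
# fragments of oblique staircase edges that slipped through a short opening
# line, not recurring diameters.
MIN_PAIR_PERSISTENCE_COLS = 3


def gap_distances(
    cols: np.ndarray,
    rows: np.ndarray,
    scale_px_per_um: float = 1.0,
    min_gap_px: int = 0,
) -> np.ndarray:
    """Consecutive vertical gaps between edge positions, column by column.

    For each column holding k >= 2 positions the k-1 consecutive row
    differences are emitted (divided by the px/um scale); columns with fewer
    than two positions contribute nothing. Gaps below ``min_gap_px`` (in px,
    before scaling) are discarded.
    """
    if scale_px_per_um <= 0:
        raise InvalidParameterError(
            f"scale_px_per_um must be > 0, got {scale_px_per_um}"
        )
    cols = np.asarray(cols)
    rows = np.asarray(rows)
    if cols.size < 2:
        return np.empty(0, dtype=np.float64)
    same_col = cols[1:] == cols[:-1]
    gaps = (rows[1:] - rows[:-1])[same_col]
    if min_gap_px > 0:
        gaps = gaps[gaps >= min_gap_px]
    return gaps.astype(np.float64) / scale_px_per_um


def _persistent_gaps(
    opened: np.ndarray, valid: np.ndarray, scale_px_per_um: float
) -> np.ndarray:
    """Gap distances of one opened copy, filtered for recurrence.

    A gap is kept when the pair of opened-mask connected components it
    spans co-occurs in at least MIN_PAIR_PERSISTENCE_COLS columns and the
    gap itself is at least MIN_RESOLVABLE_GAP_PX pixels.
    """
    cols, rows = column_maxima(opened, valid)
    if cols.size < 2:
        return np.empty(0, dtype=np.float64)
    labels, _ = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    comp = labels[rows, cols]
    same_col = cols[1:] == cols[:-1]
    gaps = (rows[1:] - rows[:-1])[same_col]
    pairs = np.stack([comp[:-1][same_col], comp[1:][same_col]], axis=1)
    _, inverse, pair_counts = np.unique(
        pairs, axis=0, return_inverse=True, return_counts=True
    )
    keep = (pair_counts[inverse] >= MIN_PAIR_PERSISTENCE_COLS) & (
        gaps >= MIN_RESOLVABLE_GAP_PX
    )
    return gaps[keep].astype(np.float64) / scale_px_per_um


def measure_stack(stack: RotationStack, line_length_px: int, scale_px_per_um: float
                  ) -> DistanceSample:
    """Apply the line opening to every rotated copy and pool gap distances."""
    all_d: list[np.ndarray] = []
    counts: list[int] = []
    for copy, valid in zip(stack.copies, stack.valid_regions):
        opened = line_opening(copy, line_length_px)
        d = _persistent_gaps(opened, valid, scale_px_per_um)
        all_d.append(d)
        counts.append(int(d.size))
    pooled = np.concatenate(all_d) if all_d else np.empty(0)
    return DistanceSample(distances=pooled, per_copy_counts=counts)
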