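"""Grayscale conversion, ROI partitioning, and partition averaging.

The two thermal ROIs are rescaled to a common grayscale (white = hottest,
black = coldest, over the *joint* temperature range of the pair), each is
partitioned into ``N x M`` rectangular subregions, and each subregion is
reduced to its mean intensity.  The result is a pair of length
``L = N * M`` vectors — the inputs of the decision statistics.

Joint (rather than per-ROI) normalization is essential: scaling each ROI
by its own range would pin both means near 0.5 and erase the between-ROI
temperature difference the decision stage tests for.  A side effect is
that any constant temperature offset common to both ROIs (e.g. a camera
bias) cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PartitionError", "GrayRoi", "PartitionVector", "to_grayscale_joint",
           "partition", "partition_means", "partition_vector"]


class PartitionError(ValueError):
    """Invalid partition request (more slices than pixels, empty block)."""


@dataclass(frozen=True)
class GrayRoi:
    """An ROI rescaled to [0, 1] gray levels, with the degC bounds used."""

    values: np.ndarray
    source_min_c: float
    source_max_c: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("gray ROI must be a non-empty 2D array")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("gray values must lie in [0, 1]")
        if self.source_min_c > self.source_max_c:
            raise ValueError("normalization bounds out of order")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PartitionVector:
    """Row-major vector of the ``L = N * M`` subregion mean gray levels."""

    means: np.ndarray
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float).ravel()
        if len(m) != self.n_rows * self.n_cols:
            raise ValueError(
                f"vector length {len(m)} != n_rows*n_cols = "
                f"{self.n_rows * self.n_cols}"
            )
        object.__setattr__(self, "means", m)

    def __len__(self) -> int:
        return len(self.means)


def to_grayscale_joint(roi_a: np.ndarray, roi_b: np.ndarray) -> tuple[GrayRoi, GrayRoi]:
    """Min-max rescale two temperature grids over their joint range.

    ``g = (T - Tmin) / (Tmax - Tmin)`` with ``Tmin``/``Tmax`` taken over
    *both* grids, so the gray ordering of any two pixels — within or across
    ROIs — equals their temperature ordering.  A degenerate zero-range pair
    (both ROIs at one uniform temperature) maps to all-0.5, which keeps the
    downstream statistics defined and yields the correct *inadequate* call.
    """
    a = np.asarray(roi_a, dtype=float)
    b = np.asarray(roi_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ROI grids must be non-empty")
    tmin = float(min(a.min(), b.min()))
    tmax = float(max(a.max(), b.max()))
    if tmax == tmin:
        ga = np.full_like(a, 0.5)
        gb = np.full_like(b, 0.5)
    else:
        span = tmax - tmin
        ga = (a - tmin) / span
        gb = (b - tmin) / span
    return (GrayRoi(ga, tmin, tmax), GrayRoi(gb, tmin, tmax))


def _band_edges(size: int, n_bands: int) -> np.ndarray:
    # balanced remainder: the first (size mod n) bands get the extra pixel
    base, rem = divmod(size, n_bands)
    sizes = np.full(n_bands, base, dtype=int)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def partition(gray: GrayRoi, n_rows: int, n_cols: int) -> list[np.ndarray]:
    """Tile a gray ROI into ``n_rows x n_cols`` sub-grids, row-major.

    Band sizes are balanced: with ``h`` rows and ``N`` bands, the first
    ``h mod N`` bands get ``ceil(h/N)`` rows and the rest ``floor(h/N)``
    (analogously for columns).  Every pixel lands in exactly one block.
    """
    h, w = gray.values.shape
    if n_rows < 1 or n_cols < 1:
        raise PartitionError("partition counts must be >= 1")
    if n_rows > h or n_cols > w:
        raise PartitionError(
            f"cannot cut a {h}x{w} ROI into {n_rows}x{n_cols} subregions"
        )
    re = _band_edges(h, n_rows)
    ce = _band_edges(w, n_cols)
    return [
        gray.values[re[i]:re[i + 1], ce[j]:ce[j + 1]]
        for i in range(n_rows)
        for j in range(n_cols)
    ]


def partition_means(blocks: list[np.ndarray], n_rows: int, n_cols: int) -> PartitionVector:
    """Reduce each sub-grid to its arithmetic mean, preserving row-major order."""
    if not blocks:
        raise PartitionError("no blocks to average")
    means = np.empty(len(blocks))
    for k, blk in enumerate(blocks):
        if np.asarray(blk).size == 0:
            raise PartitionError(f"block {k} is empty")
        means[k] = float(np.mean(blk))
    return PartitionVector(means, n_rows, n_cols)


def partition_vector(gray: GrayRoi, n_rows: int, n_cols: int) -> PartitionVector:
    """Convenience composition of :func:`partition` and :func:`partition_means`."""
    return partition_means(partition(gray, n_rows, n_cols), n_rows, n_cols)
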