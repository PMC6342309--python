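"""HU thresholding and 2-D cubical topology of the low-attenuation set.

The binary convention follows the quantification procedure: 0 marks a lung
pixel with attenuation strictly below the threshold (emphysematous,
low-attenuation), 1 marks normal lung or anything outside the lung. The Betti
numbers of the 0 set are then

* ``b0`` — number of connected low-attenuation regions, and
* ``b1`` — number of normal-lung regions completely surrounded by
  low-attenuation regions (the holes of the 0 set).

Connectivity uses the standard dual pairing — foreground (0 set)
8-connected, background (1 set) 4-connected by default — which is exactly the
pairing under which ``b0 − b1`` equals the Euler characteristic of the union
of closed unit pixels. The pair is configurable should another convention be
required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .imaging_io import HUSlice, LungMask

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BinarySlice:
    """A thresholded slice: 0 = low-attenuation lung pixel, 1 = everything else."""

    values: np.ndarray
    threshold_hu: float
    n_lung_pixels: int
    n_low_pixels: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
            raise ValidationError("BinarySlice grid must be 2-D over {0,1}")
        object.__setattr__(self, "values", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BettiPair:
    """Betti numbers of the low-attenuation (0-pixel) set of one slice."""

    b0: int
    b1: int

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b1 < 0:
            raise ValidationError("Betti numbers are non-negative")
        if self.b0 == 0 and self.b1 != 0:
            raise ValidationError("an empty 0 set cannot enclose holes")

    def __add__(self, other: "BettiPair") -> "BettiPair":
        return BettiPair(self.b0 + other.b0, self.b1 + other.b1)


def binarize(hu: HUSlice, mask: LungMask, threshold_hu: float) -> BinarySlice:
    """Threshold a slice: pixel → 0 iff inside the mask and HU < threshold.

    The inequality is strict, so a pixel at exactly the threshold counts as
    normal lung. Raising the threshold can only grow the 0 set.
    """
    if hu.shape != mask.shape:
        raise ValidationError(f"slice shape {hu.shape} != mask shape {mask.shape}")
    if mask.n_inside == 0:
        raise DegenerateInputError("mask has no lung pixels")
    low = mask.values & (hu.values < threshold_hu)
    return BinarySlice(
        values=np.where(low, 0, 1),
        threshold_hu=float(threshold_hu),
        n_lung_pixels=mask.n_inside,
        n_low_pixels=int(low.sum()),
    )


def _structs(connectivity: tuple[int, int]):
    table = {4: _STRUCT_4, 8: _STRUCT_8}
    try:
        return table[connectivity[0]], table[connectivity[1]]
    except KeyError:
        raise ValidationError(f"connectivity pair must use 4 or 8, got {connectivity}")


def betti_numbers(b: BinarySlice, connectivity: tuple[int, int] = (8, 4)) -> BettiPair:
    """Betti numbers (b0, b1) of the 0-pixel set.

    ``connectivity`` is (foreground, background); the default (8, 4) is the
    dual pairing. b1 is the count of background components that do not touch
    the grid border — such a component is necessarily enclosed by 0 pixels.
    Outside-lung pixels are 1 and connect to the border, so they are never
    counted; the mask is not needed at topology time.
    """
    fg_struct, bg_struct = _structs(connectivity)
    zeros = b.values == 0
    if not zeros.any():
        return BettiPair(0, 0)
    _, n_fg = ndimage.label(zeros, structure=fg_struct)
    bg_labels, n_bg = ndimage.label(~zeros, structure=bg_struct)
    border = np.zeros_like(zeros)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(bg_labels[border & (bg_labels > 0)])
    n_holes = n_bg - len(touching)
    return BettiPair(int(n_fg), int(n_holes))


def euler_characteristic(b: BinarySlice, foreground_connectivity: int = 8) -> int:
    """Euler characteristic χ of the 0-pixel set.

    For the default 8-connected foreground, χ is computed by explicit cell
    counting on the union of closed unit squares: distinct lattice vertices −
    distinct lattice edges + pixel faces. This equals b0 − b1 under the (8, 4)
    connectivity pair. For a 4-connected foreground the Gray bit-quad formula
    is used instead (diagonal contacts then pinch components apart, which the
    closed-union count cannot represent).
    """
    zeros = b.values == 0
    if foreground_connectivity == 8:
        rows, cols = np.nonzero(zeros)
        if rows.size == 0:
            return 0
        faces = rows.size
        # each pixel (r, c) owns corners (r, c)..(r+1, c+1) on the lattice
        corners = set()
        edges = set()
        for r, c in zip(rows.tolist(), cols.tolist()):
            corners.update(((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)))
            edges.update((
                ("h", r, c), ("h", r + 1, c),     # horizontal edges at top/bottom
                ("v", r, c), ("v", r, c + 1),     # vertical edges at left/right
            ))
        return len(corners) - len(edges) + faces
    if foreground_connectivity == 4:
        return _euler_bit_quad(zeros)
    raise ValidationError("foreground connectivity must be 4 or 8")


def _euler_bit_quad(zeros: np.ndarray) -> int:
    """Gray's bit-quad Euler number for 4-connected foreground."""
    padded = np.pad(zeros.astype(np.int8), 1)
    q = (padded[:-1, :-1] + 2 * padded[:-1, 1:] + 4 * padded[1:, :-1]
         + 8 * padded[1:, 1:])
    counts = np.bincount(q.ravel(), minlength=16)
    n_q1 = counts[[1, 2, 4, 8]].sum()      # one foreground pixel in the quad
    n_q3 = counts[[7, 11, 13, 14]].sum()   # three foreground pixels
    n_qd = counts[[6, 9]].sum()            # diagonal pairs
    chi4 = (n_q1 - n_q3 + 2 * n_qd) / 4
    return int(round(chi4))


def write_binary_csv(b: BinarySlice, path) -> None:
    """Serialize the {0,1} grid as a CSV raster (deterministic, diffable)."""
    np.savetxt(path, b.values, delimiter=",", fmt="%d")
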