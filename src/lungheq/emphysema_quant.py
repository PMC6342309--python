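"""Per-patient emphysema quantification: slice selection, LAA%, Betti sums.

The procedure quantifies emphysema on three axial slices — upper, middle and
lower lung fields — rather than the whole volume. LAA% pools the three
slices:

    LAA% = 100 × (total low-attenuation lung pixels over the three slices)
                 / (total lung pixels over the three slices)

and, by parallel construction, the per-patient Betti numbers are the sums of
the per-slice values. Both are computed at each threshold in
:data:`~lungheq.imaging_io.THRESHOLDS` (−950, −910, −880 HU by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .binary_topology import BettiPair, BinarySlice, betti_numbers, binarize
from .errors import DegenerateInputError
from .imaging_io import THRESHOLDS, HUSlice, LungMask

logger = logging.getLogger(__name__)

#: Default fractional positions of the three analysis slices along the
#: cranio-caudal lung extent (upper, middle, lower lung fields).
DEFAULT_FRACTIONS = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class EmphysemaMetrics:
    """Quantification results for one patient.

    ``lung_area_mm2`` is ``None`` when the source images carried no pixel
    spacing; areas are then reported in pixels only.
    """

    lung_area_px: int
    lung_area_mm2: float | None
    laa_pct: dict[float, float]
    b0: dict[float, int]
    b1: dict[float, int]
    per_slice_betti: dict[float, tuple[BettiPair, ...]] = field(default_factory=dict)


def select_slices(
    volume: list[HUSlice],
    masks: list[LungMask],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
) -> list[tuple[HUSlice, LungMask]]:
    """Pick the three analysis slices at fractional positions of the lung extent.

    The extent runs from the first to the last slice containing any inside-mask
    pixel; each fraction maps to ``first + round(frac * (last - first))`` with
    half-up rounding. On very short extents the rounded indices can collide;
    they are then spread apart (earlier index down, later index up) so the
    three slices are always distinct.
    """
    if len(volume) != len(masks):
        raise DegenerateInputError("volume and mask slice counts differ")
    lung_bearing = [k for k, m in enumerate(masks) if m.n_inside > 0]
    if len(lung_bearing) < 3:
        raise DegenerateInputError(
            f"need ≥3 lung-bearing slices, found {len(lung_bearing)}"
        )
    first, last = lung_bearing[0], lung_bearing[-1]
    extent = last - first
    idx = [first + int(extent * f + 0.5) for f in fractions]
    # spread collisions outward within [first, last]
    changed = True
    while changed:
        changed = False
        for i in range(len(idx) - 1):
            if idx[i] >= idx[i + 1]:
                if idx[i] - 1 >= first and (i == 0 or idx[i] - 1 > idx[i - 1]):
                    idx[i] -= 1
                else:
                    idx[i + 1] += 1
                changed = True
    if idx[-1] > last or idx[0] < first:
        raise DegenerateInputError("cannot place three distinct slices in lung extent")
    return [(volume[k], masks[k]) for k in idx]


def laa_percent(binary_slices: list[BinarySlice]) -> float:
    """Pooled LAA% over the analysis slices at one threshold."""
    n_lung = sum(b.n_lung_pixels for b in binary_slices)
    if n_lung == 0:
        raise DegenerateInputError("no lung pixels across the analysis slices")
    n_low = sum(b.n_low_pixels for b in binary_slices)
    return 100.0 * n_low / n_lung


def quantify_patient(
    volume: list[HUSlice],
    masks: list[LungMask],
    thresholds: tuple[float, ...] = THRESHOLDS,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    connectivity: tuple[int, int] = (8, 4),
) -> EmphysemaMetrics:
    """Full quantification for one patient: LAA% and (b0, b1) per threshold.

    Betti numbers per patient are the sums over the three selected slices;
    per-slice pairs are retained for diagnostics.
    """
    pairs = select_slices(volume, masks, fractions)
    lung_px = sum(m.n_inside for _, m in pairs)
    spacing = next((s.pixel_spacing for s, _ in pairs if s.pixel_spacing), None)
    if spacing is None:
        logger.warning("no pixel spacing available; lung area reported in pixels only")
        area_mm2 = None
    else:
        area_mm2 = lung_px * spacing[0] * spacing[1]

    laa: dict[float, float] = {}
    b0: dict[float, int] = {}
    b1: dict[float, int] = {}
    per_slice: dict[float, tuple[BettiPair, ...]] = {}
    for t in thresholds:
        binaries = [binarize(s, m, t) for s, m in pairs]
        laa[t] = laa_percent(binaries)
        bettis = tuple(betti_numbers(b, connectivity) for b in binaries)
        total = sum(bettis[1:], bettis[0])
        b0[t], b1[t] = total.b0, total.b1
        per_slice[t] = bettis
    return EmphysemaMetrics(
        lung_area_px=lung_px,
        lung_area_mm2=area_mm2,
        laa_pct=laa,
        b0=b0,
        b1=b1,
        per_slice_betti=per_slice,
    )
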