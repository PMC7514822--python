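"""Region-of-interest extraction from the binary line-edge image.

The top boundary comes from the jump in the number of row peaks where the two
long bones end (searched in the central 50% of the rows); the lateral
boundaries come from the per-row four highest peaks, averaged position-wise
and expanded by 20% of the resulting bone span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xraypipe.entropy_seg import _merge_regions, _plateau_maxima
from xraypipe.errors import InvalidImageError, ValidationError

__all__ = ["ROIBox", "find_top_boundary", "find_width_box", "extract_roi"]


@dataclass(frozen=True)
class ROIBox:
    """Half-open crop box: rows [top_row, bottom_row), cols [left_col, right_col)."""

    top_row: int
    bottom_row: int
    left_col: int
    right_col: int

    def __post_init__(self):
        if not (0 <= self.top_row < self.bottom_row):
            raise ValidationError("ROI rows out of order")
        if not (0 <= self.left_col < self.right_col):
            raise ValidationError("ROI columns out of order")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bottom_row - self.top_row, self.right_col - self.left_col)


def find_top_boundary(
    peaks_per_row: np.ndarray,
    search_band: tuple[float, float] = (0.25, 0.75),
    retain_frac: float = 0.95,
) -> int:
    """Row index where the bones end, from the per-row peak-count sequence.

    Within the central band, local-maximum regions of the count sequence are
    collapsed to single representatives; of those at least ``retain_frac`` of
    the band maximum, the largest row index wins.
    """
    counts = np.asarray(peaks_per_row, dtype=np.float64)
    lo = int(np.floor(search_band[0] * counts.size))
    hi = int(np.floor(search_band[1] * counts.size))
    band = counts[lo:hi]
    if band.size == 0 or band.max() <= 0:
        raise InvalidImageError("invalid image: bones end outside central band")
    reps = _merge_regions(_plateau_maxima(band), merge_gap=2)
    if not reps:
        raise InvalidImageError("invalid image: bones end outside central band")
    vmax = max(v for _, v in reps)
    kept = [r for r, v in reps if v >= retain_frac * vmax]
    return lo + max(kept)


def find_width_box(
    peak_image: np.ndarray,
    entropy_map: np.ndarray,
    expand_frac: float = 0.2,
) -> tuple[int, int]:
    """Lateral bone boundaries as inclusive (left_col, right_col).

    Per row, the four white pixels with the highest entropy-map values are
    taken, sorted, and averaged position-wise over rows; the outermost means
    are expanded outwards by ``expand_frac`` of the bone span.  Rows with
    fewer than four peaks are skipped; more than half skipped is an error.
    """
    peak_image = np.asarray(peak_image)
    entropy_map = np.asarray(entropy_map, dtype=np.float64)
    if peak_image.shape != entropy_map.shape:
        raise ValidationError("peak image and entropy map shapes differ")
    h, w = peak_image.shape
    quads = []
    for r in range(h):
        cols = np.nonzero(peak_image[r])[0]
        if cols.size < 4:
            continue
        vals = entropy_map[r, cols]
        top4 = cols[np.argsort(vals, kind="stable")[-4:]]
        quads.append(np.sort(top4))
    if len(quads) < (h - len(quads)):
        raise InvalidImageError("insufficient bone evidence: too few 4-peak rows")
    means = np.mean(quads, axis=0)
    left, right = means[0], means[3]
    span = right - left
    left = int(round(left - expand_frac * span))
    right = int(round(right + expand_frac * span))
    return max(left, 0), min(right, w - 1)


def extract_roi(
    peak_image: np.ndarray,
    entropy_map: np.ndarray,
    search_band: tuple[float, float] = (0.25, 0.75),
    retain_frac: float = 0.95,
    expand_frac: float = 0.2,
) -> tuple[np.ndarray, ROIBox]:
    """Crop the line-edge image to the ulna/radius region.

    The bottom boundary is the image bottom, trimmed of trailing all-black
    rows (rotation and padding may leave an empty skirt below the exposed
    field).  Returns the cropped image and the box.
    """
    peak_image = np.asarray(peak_image)
    counts = (peak_image > 0).sum(axis=1)
    top = int(find_top_boundary(counts, search_band, retain_frac))
    nonzero_rows = np.nonzero(counts)[0]
    bottom = int(nonzero_rows[-1]) + 1
    if bottom <= top:
        raise InvalidImageError("invalid image: no content below the top boundary")
    sub_peaks = peak_image[top:bottom]
    sub_map = np.asarray(entropy_map)[top:bottom]
    left, right = find_width_box(sub_peaks, sub_map, expand_frac)
    box = ROIBox(top_row=top, bottom_row=bottom, left_col=left, right_col=right + 1)
    return peak_image[top:bottom, left : right + 1], box
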