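"""Sigma-weighted local entropy segmentation and entropy quality metrics.

The tissue-removal filter computes, per pixel, the Shannon entropy of the
empirical 8-bit intensity distribution inside a sliding n x n window,
multiplied by the window's population standard deviation.  Bone edges mix two
intensity plateaus inside the window and therefore stand out; homogeneous
tissue scores near zero.  A row-wise peak detector then reduces the map to a
binary line-edge image, and tile-based entropy scores quantify residual noise
after segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold

from xraypipe.errors import InvalidImageError, ValidationError

__all__ = [
    "EntropyWindow",
    "RowPeaks",
    "NoiseScore",
    "shannon_entropy",
    "local_entropy_map",
    "normalise_rows",
    "detect_row_peaks",
    "line_edge_image",
    "segmentation_entropy",
    "global_entropy_score",
    "baseline_edges",
]


@dataclass(frozen=True)
class EntropyWindow:
    """Sliding-window configuration: odd ``size`` (default 9), ``log_base`` 2."""

    size: int = 9
    log_base: float = 2.0

    def __post_init__(self):
        if self.size < 3 or self.size % 2 == 0:
            raise ValidationError("window size must be odd and >= 3")
        if self.log_base <= 1.0:
            raise ValidationError("log base must be > 1")


@dataclass(frozen=True)
class RowPeaks:
    """Surviving peak columns for one image row (strictly increasing)."""

    row_index: int
    peak_columns: tuple[int, ...]


@dataclass(frozen=True)
class NoiseScore:
    """Entropy-based segmentation quality: lower ``global_entropy`` is better."""

    image_entropy: float
    segmentation_entropy: float
    global_entropy: float
    n_windows: int
    window: int = 32


def shannon_entropy(values, log_base: float = 2.0) -> float:
    """Entropy of the empirical distribution of ``values`` (0*log0 := 0)."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValidationError("shannon_entropy of empty input is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / values.size
    return float(-np.sum(p * np.log(p)) / math.log(log_base))


def _window_sum(a: np.ndarray, n: int) -> np.ndarray:
    """Exact n x n window sums of an integer array via an integral image."""
    c = np.cumsum(np.cumsum(a, axis=0, dtype=np.int64), axis=1, dtype=np.int64)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[n:, n:] - c[:-n, n:] - c[n:, :-n] + c[:-n, :-n]


def local_entropy_map(img: np.ndarray, win: EntropyWindow | None = None) -> np.ndarray:
    """Per-pixel entropy x standard deviation, mirror-reflected at borders.

    Window histograms are accumulated with exact integer integral images, so
    the result matches a per-window brute-force recomputation to float
    round-off.  The standard deviation is the population form.
    """
    if win is None:
        win = EntropyWindow()
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError("expected a 2D image")
    if min(img.shape) < win.size:
        raise InvalidImageError("image smaller than the entropy window")
    n = win.size
    half = n // 2
    padded = np.pad(img.astype(np.int64), half, mode="reflect")
    area = n * n

    counts = np.arange(area + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        table = -(counts / area) * (np.log(counts / area) / math.log(win.log_base))
    table[0] = 0.0
    table[area] = 0.0

    entropy = np.zeros(img.shape, dtype=np.float64)
    for v in np.unique(padded):
        cnt = _window_sum(padded == v, n)
        entropy += table[cnt]

    # centred sums keep the variance formula well-conditioned and exact in int64
    x = padded - 128
    s1 = _window_sum(x, n).astype(np.float64)
    s2 = _window_sum(x * x, n).astype(np.float64)
    var = s2 / area - (s1 / area) ** 2
    np.maximum(var, 0.0, out=var)
    return entropy * np.sqrt(var)


def normalise_rows(emap: np.ndarray) -> np.ndarray:
    """Subtract the global mean of the map; negatives floor at zero."""
    emap = np.asarray(emap, dtype=np.float64)
    return np.maximum(emap - emap.mean(), 0.0)


def _plateau_maxima(row: np.ndarray) -> list[tuple[int, int, float]]:
    """Local-maximum plateaus of a 1D array as (start, end, value) triples.

    A plateau of equal values is a maximum when both neighbours (where they
    exist) are strictly smaller.  Zero-valued plateaus never qualify.
    """
    n = row.size
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and row[j + 1] == row[i]:
            j += 1
        v = row[i]
        if v > 0:
            left_ok = i == 0 or row[i - 1] < v
            right_ok = j == n - 1 or row[j + 1] < v
            if left_ok and right_ok:
                out.append((i, j, float(v)))
        i = j + 1
    return out


def _merge_regions(
    maxima: list[tuple[int, int, float]], merge_gap: int
) -> list[tuple[int, float]]:
    """Collapse maxima plateaus within ``merge_gap`` columns of each other.

    Each region keeps one representative at the round-half-to-even mean of its
    member pixel columns, valued at the region maximum.
    """
    reps: list[tuple[int, float]] = []
    group: list[tuple[int, int, float]] = []

    def flush():
        if not group:
            return
        cols = [c for s, e, _ in group for c in range(s, e + 1)]
        rep = int(round(float(np.mean(cols))))  # banker's rounding
        reps.append((rep, max(v for _, _, v in group)))

    for m in maxima:
        if group and m[0] - group[-1][1] > merge_gap:
            flush()
            group = []
        group.append(m)
    flush()
    return reps


def detect_row_peaks(
    row: np.ndarray,
    threshold_frac: float = 0.2,
    merge_gap: int = 2,
    row_index: int = 0,
) -> RowPeaks:
    """Find, merge and threshold intensity peaks along one row.

    Plateaus of local maxima are collapsed to a single representative column;
    representatives whose value is <= ``threshold_frac`` times the largest
    nonzero row value are discarded.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValidationError("threshold_frac must be in (0, 1)")
    row = np.asarray(row, dtype=np.float64)
    nonzero = row[row > 0]
    if nonzero.size == 0:
        return RowPeaks(row_index=row_index, peak_columns=())
    cut = threshold_frac * float(nonzero.max())
    reps = _merge_regions(_plateau_maxima(row), merge_gap)
    cols = tuple(sorted(c for c, v in reps if v > cut))
    return RowPeaks(row_index=row_index, peak_columns=cols)


def line_edge_image(
    emap: np.ndarray,
    threshold_frac: float = 0.2,
    merge_gap: int = 2,
    normalised: bool = False,
) -> np.ndarray:
    """Binary line-edge image: white where each row's surviving peaks sit.

    The map is mean-subtracted first unless ``normalised`` says it already was.
    """
    work = np.asarray(emap, dtype=np.float64)
    if not normalised:
        work = normalise_rows(work)
    out = np.zeros(work.shape, dtype=np.uint8)
    for r in range(work.shape[0]):
        peaks = detect_row_peaks(work[r], threshold_frac, merge_gap, row_index=r)
        if peaks.peak_columns:
            out[r, list(peaks.peak_columns)] = 255
    return out


def _tiles(img: np.ndarray, window: int):
    h, w = img.shape
    for r0 in range(0, h, window):
        for c0 in range(0, w, window):
            yield img[r0 : r0 + window, c0 : c0 + window]


def segmentation_entropy(img: np.ndarray, window: int = 32, log_base: float = 2.0) -> float:
    """Sum over non-overlapping tiles of (tile entropy - image entropy),
    divided by the image entropy.  Partial edge tiles are included."""
    img = np.asarray(img)
    eh = shannon_entropy(img, log_base)
    if eh <= 0.0:
        raise InvalidImageError("undefined segmentation entropy: constant image")
    total = 0.0
    for tile in _tiles(img, window):
        total += shannon_entropy(tile, log_base) - eh
    return total / eh


def global_entropy_score(img: np.ndarray, window: int = 32, log_base: float = 2.0) -> NoiseScore:
    """Combined noise score: image entropy plus the per-window-scaled
    segmentation term.  Lower means a cleaner segmentation."""
    img = np.asarray(img)
    eh = shannon_entropy(img, log_base)
    if eh <= 0.0:
        raise InvalidImageError("undefined segmentation entropy: constant image")
    tile_h = [shannon_entropy(t, log_base) for t in _tiles(img, window)]
    n_win = len(tile_h)
    seg = sum(th - eh for th in tile_h) / eh
    return NoiseScore(
        image_entropy=eh,
        segmentation_entropy=seg,
        global_entropy=eh + seg / n_win,
        n_windows=n_win,
        window=window,
    )


def _sobel_kernel_1d(size: int, derivative: bool) -> np.ndarray:
    """Extended Sobel component: binomial smoothing, optionally differenced."""
    k = np.array([1.0])
    reps = size - 2 if derivative else size - 1
    for _ in range(reps):
        k = np.convolve(k, [1.0, 1.0])
    if derivative:
        k = np.convolve(k, [1.0, -1.0])
    return k


def baseline_edges(img: np.ndarray, method: str) -> np.ndarray:
    """Reference edge detectors used only for the comparison harness.

    ``canny``   - 3x3 Sobel gradient magnitude with hysteresis thresholds at
                  (1 +/- 0.66) times the mean input intensity.
    ``laplacian`` - 3x3 Laplacian, binarised at its mean absolute response.
    ``sobel_v``/``sobel_h`` - 11x11 extended Sobel, binarised the same way.
    """
    img = np.asarray(img, dtype=np.float64)
    if method == "canny":
        mu = img.mean()
        gx = ndimage.sobel(img, axis=1)
        gy = ndimage.sobel(img, axis=0)
        mag = np.hypot(gx, gy)
        sigma = 0.66
        edges = apply_hysteresis_threshold(mag, (1 - sigma) * mu, (1 + sigma) * mu)
        return np.where(edges, 255, 0).astype(np.uint8)
    if method == "laplacian":
        resp = np.abs(ndimage.laplace(img))
    elif method in ("sobel_v", "sobel_h"):
        smooth = _sobel_kernel_1d(11, derivative=False)
        deriv = _sobel_kernel_1d(11, derivative=True)
        if method == "sobel_v":  # vertical edges: derivative across columns
            kernel = np.outer(smooth, deriv)
        else:
            kernel = np.outer(deriv, smooth)
        resp = np.abs(ndimage.convolve(img, kernel, mode="reflect"))
    else:
        raise ValidationError(f"unknown edge method: {method!r}")
    thr = resp.mean()
    return np.where(resp > thr, 255, 0).astype(np.uint8)
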