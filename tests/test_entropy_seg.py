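import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xraypipe.entropy_seg import (
    EntropyWindow,
    baseline_edges,
    detect_row_peaks,
    global_entropy_score,
    line_edge_image,
    local_entropy_map,
    normalise_rows,
    segmentation_entropy,
    shannon_entropy,
)
from xraypipe.errors import InvalidImageError, ValidationError


def brute_entropy_map(img, size=9, log_base=2.0):
    """Independent per-window recomputation of the sigma-weighted map."""
    half = size // 2
    padded = np.pad(np.asarray(img, dtype=float), half, mode="reflect")
    out = np.zeros(np.asarray(img).shape, dtype=float)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            window = padded[r : r + size, c : c + size].ravel()
            _, counts = np.unique(window, return_counts=True)
            p = counts / window.size
            h = -np.sum(p * np.log(p)) / math.log(log_base)
            out[r, c] = h * np.std(window)
    return out


class TestShannonEntropy:
    def test_constant_values_zero_bits(self):
        assert shannon_entropy([7] * 81) == 0.0

    def test_fair_coin_one_bit(self):
        assert shannon_entropy([0] * 40 + [255] * 40) == pytest.approx(1.0)

    def test_three_level_distribution(self):
        # {0 x4, 100 x2, 200 x2}: -(0.5 log 0.5 + 2 * 0.25 log 0.25) = 1.5 bits
        vals = [0, 0, 0, 0, 100, 100, 200, 200]
        assert shannon_entropy(vals) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy([])

    def test_other_log_base(self):
        vals = [0] * 5 + [9] * 5
        assert shannon_entropy(vals, log_base=math.e) == pytest.approx(math.log(2))

    @given(st.lists(st.integers(0, 255), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_permutation_invariance(self, vals):
        h = shannon_entropy(vals)
        assert h >= 0.0
        assert h <= math.log2(len(set(vals))) + 1e-12
        assert shannon_entropy(sorted(vals)) == pytest.approx(h)


class TestLocalEntropyMap:
    def test_constant_image_all_zero(self):
        assert not local_entropy_map(np.full((20, 20), 9, np.uint8)).any()

    def test_matches_brute_force_on_step_edge(self):
        img = np.zeros((20, 20), np.uint8)
        img[:, 10:] = 200
        emap = local_entropy_map(img)
        brute = brute_entropy_map(img)
        assert np.abs(emap - brute).max() < 1e-9
        # maximal along the edge, zero far from it
        assert emap[:, 9:11].min() > 0
        assert emap[:, 0].max() == 0.0
        assert np.argmax(emap[10]) in (9, 10)

    def test_matches_brute_force_random(self, rng):
        img = rng.integers(0, 256, (25, 25)).astype(np.uint8)
        assert np.abs(local_entropy_map(img) - brute_entropy_map(img)).max() < 1e-9

    def test_single_outlier_locality(self):
        img = np.full((21, 21), 50, np.uint8)
        img[10, 10] = 200
        emap = local_entropy_map(img)
        nz = np.argwhere(emap > 0)
        assert np.abs(nz - 10).max() <= 4  # within window reach

    def test_sigma_weighting_breaks_value_permutation(self):
        # entropy alone is invariant to relabelling intensities; the sigma
        # factor is not
        a = np.zeros((15, 15), np.uint8)
        a[:, 7:] = 10
        b = np.zeros((15, 15), np.uint8)
        b[:, 7:] = 250
        ea, eb = local_entropy_map(a), local_entropy_map(b)
        assert not np.allclose(ea, eb)
        ratio = eb[7, 7] / ea[7, 7]
        assert ratio == pytest.approx(25.0)  # sigma scales with the step size

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidImageError):
            local_entropy_map(np.zeros((5, 5), np.uint8))

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            EntropyWindow(size=8)


class TestNormaliseRows:
    def test_constant_map_to_zero(self):
        assert not normalise_rows(np.full((4, 4), 3.3)).any()

    def test_half_half(self):
        m = np.array([[0.0, 10.0], [0.0, 10.0]])
        assert np.array_equal(normalise_rows(m), [[0.0, 5.0], [0.0, 5.0]])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_mean_decreases(self, seed):
        m = np.random.default_rng(seed).uniform(0, 10, (8, 8))
        out = normalise_rows(m)
        assert out.min() >= 0.0
        if not np.allclose(m, m.flat[0]):
            assert out.mean() < m.mean()


def brute_peaks(row, threshold_frac=0.2, merge_gap=2):
    """Enumerative oracle: plateau maxima, merge, threshold."""
    row = np.asarray(row, dtype=float)
    n = row.size
    marked = []
    for i in range(n):
        v = row[i]
        if v <= 0:
            continue
        li = i
        while li > 0 and row[li - 1] == v:
            li -= 1
        ri = i
        while ri < n - 1 and row[ri + 1] == v:
            ri += 1
        if (li == 0 or row[li - 1] < v) and (ri == n - 1 or row[ri + 1] < v):
            marked.append(i)
    if not marked:
        return []
    regions = [[marked[0]]]
    for c in marked[1:]:
        if c - regions[-1][-1] <= merge_gap:
            regions[-1].append(c)
        else:
            regions.append([c])
    cut = threshold_frac * row[row > 0].max()
    out = []
    for reg in regions:
        if row[reg].max() > cut:
            out.append(round(float(np.mean(reg))))
    return sorted(out)


class TestDetectRowPeaks:
    def test_plateau_merged_to_mean(self):
        row = [0, 0, 5, 9, 9, 9, 5, 0, 0]
        peaks = detect_row_peaks(row, 0.2)
        assert list(peaks.peak_columns) == [4]
        assert list(peaks.peak_columns) == brute_peaks(row)

    def test_zero_row_no_peaks(self):
        assert detect_row_peaks(np.zeros(10), 0.2).peak_columns == ()

    def test_threshold_drops_small_peak(self):
        row = [0, 100, 0, 0, 0, 0, 15, 0]
        peaks = detect_row_peaks(row, 0.2)
        assert list(peaks.peak_columns) == [1]  # 15 <= 0.2 * 100

    def test_matches_brute_oracle_random(self, rng):
        for _ in range(50):
            row = rng.integers(0, 20, rng.integers(5, 40))
            got = list(detect_row_peaks(row, 0.2).peak_columns)
            assert got == brute_peaks(row)

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            detect_row_peaks([1, 2, 1], 0.0)


class TestLineEdgeImage:
    def test_all_zero_map(self):
        assert not line_edge_image(np.zeros((10, 10))).any()

    def test_single_bright_column(self):
        emap = np.zeros((10, 10))
        emap[:, 4] = 5.0
        out = line_edge_image(emap)
        expected = np.zeros((10, 10), np.uint8)
        expected[:, 4] = 255
        assert np.array_equal(out, expected)

    def test_binary_and_sparse(self, noisy_phantom):
        img, _ = noisy_phantom
        out = line_edge_image(local_entropy_map(img))
        assert set(np.unique(out)) <= {0, 255}
        assert ((out > 0).sum(axis=1) <= img.shape[1] / 2).all()

    def test_phantom_edges_near_ground_truth(self, clean_phantom):
        img, truth = clean_phantom
        out = line_edge_image(local_entropy_map(img))
        hit = 0
        rows = truth.edge_rows[:-1]  # last row mirrors into the border
        for i, r in enumerate(rows):
            cols = np.nonzero(out[r])[0]
            ok = all(
                np.abs(cols - truth.edge_cols[e][i]).min() <= 2.0 for e in range(4)
            )
            hit += ok
        assert hit / rows.size >= 0.90


def brute_noise_score(img, window):
    img = np.asarray(img)

    def ent(a):
        _, counts = np.unique(a, return_counts=True)
        p = counts / a.size
        return float(-(p * np.log2(p)).sum())

    eh = ent(img)
    tiles = []
    for r in range(0, img.shape[0], window):
        for c in range(0, img.shape[1], window):
            tiles.append(ent(img[r : r + window, c : c + window]))
    es = sum(t - eh for t in tiles) / eh
    return eh, es, eh + es / len(tiles), len(tiles)


class TestEntropyScores:
    def test_uniform_tiles_cancel(self):
        # every 2x2 tile is a half/half mix, matching the global distribution
        img = np.tile(np.array([[0, 255], [0, 255]], np.uint8), (4, 4))
        assert segmentation_entropy(img, window=2) == pytest.approx(0.0)
        score = global_entropy_score(img, window=2)
        assert score.global_entropy == pytest.approx(score.image_entropy)

    def test_two_tile_arithmetic(self):
        # left tile half/half (1 bit), right tile constant (0 bits)
        img = np.zeros((4, 8), np.uint8)
        img[:2, :4] = 255
        eh, es, n, nw = brute_noise_score(img, 4)
        assert segmentation_entropy(img, window=4) == pytest.approx(es)
        score = global_entropy_score(img, window=4)
        assert score.image_entropy == pytest.approx(eh)
        assert score.global_entropy == pytest.approx(n)
        assert score.n_windows == nw == 2

    def test_matches_brute_force_random(self, rng):
        img = (rng.random((40, 48)) < 0.1).astype(np.uint8) * 255
        eh, es, n, nw = brute_noise_score(img, 16)
        score = global_entropy_score(img, window=16)
        assert score.image_entropy == pytest.approx(eh)
        assert score.segmentation_entropy == pytest.approx(es)
        assert score.global_entropy == pytest.approx(n)

    def test_checkerboard_vs_half_ordering(self):
        checker = np.indices((32, 32)).sum(axis=0) % 2 * 255
        half = np.zeros((32, 32), np.uint8)
        half[:, 16:] = 255
        o_checker = global_entropy_score(checker.astype(np.uint8), 8).global_entropy
        o_half = global_entropy_score(half, 8).global_entropy
        b_checker = brute_noise_score(checker, 8)[2]
        b_half = brute_noise_score(half, 8)[2]
        assert (o_checker < o_half) == (b_checker < b_half)

    def test_constant_image_rejected(self):
        with pytest.raises(InvalidImageError):
            segmentation_entropy(np.zeros((8, 8), np.uint8))

    def test_proposed_beats_raw_on_phantom(self, noisy_phantom):
        img, _ = noisy_phantom
        edges = line_edge_image(local_entropy_map(img))
        assert (
            global_entropy_score(edges).global_entropy
            < global_entropy_score(img).global_entropy
        )


class TestBaselineEdges:
    @pytest.mark.parametrize("method", ["canny", "laplacian", "sobel_v", "sobel_h"])
    def test_constant_image_no_edges(self, method):
        img = np.full((30, 30), 90, np.uint8)
        assert not baseline_edges(img, method).any()

    def test_canny_finds_step_edge(self):
        img = np.zeros((30, 30), np.uint8)
        img[:, 15:] = 200
        out = baseline_edges(img, "canny")
        cols = np.nonzero(out[15])[0]
        assert cols.size and np.abs(cols - 14.5).min() <= 2

    def test_sobel_orientation_selectivity(self):
        img = np.zeros((40, 40), np.uint8)
        img[:, 20:] = 200  # vertical edge
        v = baseline_edges(img, "sobel_v")
        h = baseline_edges(img, "sobel_h")
        assert v.sum() > 0 and h.sum() == 0

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            baseline_edges(np.zeros((10, 10), np.uint8), "prewitt")

    def test_proposed_beats_canny_on_phantom(self, noisy_phantom):
        img, _ = noisy_phantom
        edges = line_edge_image(local_entropy_map(img))
        canny = baseline_edges(img, "canny")
        assert (
            global_entropy_score(edges).global_entropy
            < global_entropy_score(canny).global_entropy
        )
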