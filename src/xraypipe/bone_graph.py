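"""Graph-based bone contour tracing through the binary ROI image.

Every white pixel on the bottom row roots a tree.  Trees grow strictly upward
by repeatedly taking all nearest white pixels (Euclidean distance, ties kept)
inside a small search window.  Root-to-leaf paths spanning enough of the image
height are kept, and nearby duplicate contours caused by blur are merged into
single per-row bone lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from xraypipe.errors import NoContourError, ValidationError

__all__ = [
    "ContourGraph",
    "BoneLine",
    "select_roots",
    "next_pixels",
    "build_graph",
    "filter_paths",
    "merge_contours",
]

Pixel = tuple[int, int]  # (row, col)


@dataclass
class ContourGraph:
    """Forest of upward contour trees, one per root pixel."""

    roots: list[Pixel]
    parents: list[dict[Pixel, Pixel]] = field(default_factory=list)
    children: list[dict[Pixel, list[Pixel]]] = field(default_factory=list)

    def paths(self) -> list[list[Pixel]]:
        """All root-to-leaf pixel sequences, listed bottom-up."""
        out = []
        for root, parent, child in zip(self.roots, self.parents, self.children):
            nodes = [root] + list(parent)
            for node in nodes:
                if child.get(node):
                    continue
                path = [node]
                while path[-1] != root:
                    path.append(parent[path[-1]])
                path.reverse()
                out.append(path)
        return out


@dataclass(frozen=True)
class BoneLine:
    """One bone contour: contiguous rows (ascending) with one column each."""

    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=np.int64)
        cols = np.asarray(self.cols, dtype=np.float64)
        if rows.shape != cols.shape or rows.ndim != 1:
            raise ValidationError("rows and cols must be matching 1D arrays")
        if rows.size and np.any(np.diff(rows) != 1):
            raise ValidationError("bone line rows must be contiguous ascending")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)

    @property
    def extent(self) -> int:
        return int(self.rows[-1] - self.rows[0]) if self.rows.size else 0

    def col_at(self, row: int) -> float:
        idx = row - int(self.rows[0])
        if not 0 <= idx < self.rows.size:
            raise ValidationError(f"row {row} outside bone line extent")
        return float(self.cols[idx])

    def pixels(self) -> list[Pixel]:
        """(row, col) pairs bottom-up with columns rounded to ints."""
        return [
            (int(r), int(round(c))) for r, c in zip(self.rows[::-1], self.cols[::-1])
        ]


def select_roots(binary: np.ndarray) -> list[Pixel]:
    """All white pixels of the bottom row; ideally four, noise gives more."""
    binary = np.asarray(binary)
    last = binary.shape[0] - 1
    cols = np.nonzero(binary[last])[0]
    if cols.size == 0:
        raise NoContourError("no bone roots found: bottom row is empty")
    return [(last, int(c)) for c in cols]


def next_pixels(
    binary: np.ndarray, current: Pixel, up: int = 5, side: int = 5
) -> list[Pixel]:
    """All white pixels at minimum Euclidean distance inside the search box.

    The box spans ``up`` rows above the current pixel and ``side`` columns to
    either side.  Ties are all returned; an empty list marks a dead end.
    """
    binary = np.asarray(binary)
    r, c = current
    r0 = max(r - up, 0)
    c0 = max(c - side, 0)
    c1 = min(c + side, binary.shape[1] - 1)
    if r0 >= r:
        return []
    sub = binary[r0:r, c0 : c1 + 1]
    ys, xs = np.nonzero(sub)
    if ys.size == 0:
        return []
    rows = ys + r0
    cols = xs + c0
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    best = d2.min()
    picks = sorted(
        (int(rr), int(cc)) for rr, cc in zip(rows[d2 == best], cols[d2 == best])
    )
    return picks


def build_graph(
    binary: np.ndarray, roots: list[Pixel], up: int = 5, side: int = 5
) -> ContourGraph:
    """Breadth-first upward expansion of every root into its own tree.

    A pixel joins a given tree at most once, so each tree is cycle-free and
    every leaf induces exactly one root-to-leaf path.
    """
    if not roots:
        raise ValidationError("build_graph requires at least one root")
    binary = np.asarray(binary)
    graph = ContourGraph(roots=list(roots))
    for root in roots:
        parent: dict[Pixel, Pixel] = {}
        children: dict[Pixel, list[Pixel]] = {}
        visited = {root}
        queue = [root]
        while queue:
            node = queue.pop(0)
            kids = []
            for nxt in next_pixels(binary, node, up, side):
                if nxt in visited:
                    continue
                visited.add(nxt)
                parent[nxt] = node
                kids.append(nxt)
                queue.append(nxt)
            children[node] = kids
        graph.parents.append(parent)
        graph.children.append(children)
    return graph


def filter_paths(
    graph: ContourGraph, img_height: int, min_path_frac: float = 0.60
) -> list[list[Pixel]]:
    """Keep root-to-leaf paths whose vertical extent exceeds the height cut."""
    cut = min_path_frac * img_height
    kept = [p for p in graph.paths() if (p[0][0] - p[-1][0]) > cut]
    if not kept:
        raise NoContourError("no bone contour found: all paths below height cut")
    return kept


def _path_to_rowcols(path: list[Pixel]) -> tuple[np.ndarray, np.ndarray]:
    """Per-row columns of a bottom-up path, linearly interpolated over any
    skipped rows (steps may jump up to ``up`` rows)."""
    rows = np.array([p[0] for p in path], dtype=np.int64)[::-1]  # ascending
    cols = np.array([p[1] for p in path], dtype=np.float64)[::-1]
    full_rows = np.arange(rows[0], rows[-1] + 1)
    full_cols = np.interp(full_rows, rows, cols)
    return full_rows, full_cols


def merge_contours(
    paths: list[list[Pixel]],
    merge_window: int = 15,
    overlap_frac: float = 0.5,
    max_lines: int = 4,
) -> list[BoneLine]:
    """Group nearby duplicate contours and average them row-wise.

    Two paths join the same group when, over the rows they share, at least
    ``overlap_frac`` of the per-row column gaps are within ``merge_window``
    pixels.  Each group's line is the per-row mean column of its members.
    Returns at most ``max_lines`` lines (longest kept), sorted left to right.
    """
    if not paths:
        raise ValidationError("merge_contours requires at least one path")
    series = [_path_to_rowcols(p) for p in paths]
    n = len(series)
    group_id = list(range(n))

    def find(i):
        while group_id[i] != i:
            group_id[i] = group_id[group_id[i]]
            i = group_id[i]
        return i

    for i in range(n):
        ri, ci = series[i]
        for j in range(i + 1, n):
            rj, cj = series[j]
            lo = max(ri[0], rj[0])
            hi = min(ri[-1], rj[-1])
            if hi < lo:
                continue
            a = ci[lo - ri[0] : hi - ri[0] + 1]
            b = cj[lo - rj[0] : hi - rj[0] + 1]
            close = np.abs(a - b) <= merge_window
            if close.mean() >= overlap_frac:
                group_id[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    lines = []
    for members in groups.values():
        lo = min(series[i][0][0] for i in members)
        hi = max(series[i][0][-1] for i in members)
        rows = np.arange(lo, hi + 1)
        total = np.zeros(rows.size)
        count = np.zeros(rows.size)
        for i in members:
            ri, ci = series[i]
            sl = slice(ri[0] - lo, ri[-1] - lo + 1)
            total[sl] += ci
            count[sl] += 1
        present = count > 0
        # clip to the contiguous run containing the bottom row
        cols = np.where(present, total / np.maximum(count, 1), np.nan)
        start = rows.size - 1
        while start - 1 >= 0 and present[start - 1]:
            start -= 1
        lines.append(BoneLine(rows=rows[start:], cols=cols[start:]))

    if len(lines) > max_lines:
        warnings.warn(f"{len(lines)} contours found; keeping the {max_lines} longest")
        lines = sorted(lines, key=lambda l: l.extent, reverse=True)[:max_lines]
    elif len(lines) < max_lines:
        warnings.warn(f"only {len(lines)} bone contours recovered")
    return sorted(lines, key=lambda l: float(np.mean(l.cols)))
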