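"""Fracture classification and localisation from traced bone lines.

Each bone line is compared against its own "ideal healthy" contour — a
low-order polynomial least-squares fit — after the noisy curvature at the top
of the bone is cropped away.  Contiguous runs of rows whose residual exceeds a
pixel tolerance flag the image as fractured and are localised with a circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from xraypipe.bone_graph import BoneLine
from xraypipe.errors import ValidationError

__all__ = [
    "FitConfig",
    "ExcessRun",
    "DeviationScore",
    "Detection",
    "FractureReport",
    "crop_top_curvature",
    "fit_ideal_contour",
    "score_deviation",
    "detect_fracture",
]


@dataclass(frozen=True)
class FitConfig:
    ideal_degree: int = 3
    curvature_degree: int = 2
    top_frac: float = 0.20
    tolerance: float = 3.0
    min_run: int = 2
    #: excess runs on the same line closer than this many rows are one
    #: deviation area: a fracture's residual crosses zero at the fracture row,
    #: so the above-tolerance rows straddle it in two (or more) runs
    group_gap: int = 12
    #: deviation areas touching the last rows of a line are resampling /
    #: fit-boundary artifacts, mirroring why the top curvature is cropped
    bottom_margin: int = 5

    def __post_init__(self):
        if self.ideal_degree < 1:
            raise ValidationError("ideal_degree must be >= 1")
        if not 0.0 < self.top_frac < 1.0:
            raise ValidationError("top_frac must be in (0, 1)")
        if self.tolerance < 0:
            raise ValidationError("tolerance must be >= 0")


@dataclass(frozen=True)
class ExcessRun:
    """Maximal contiguous rows with |residual| above tolerance."""

    start_row: int
    end_row: int
    peak_row: int
    peak_dev: float

    @property
    def length(self) -> int:
        return self.end_row - self.start_row + 1


@dataclass(frozen=True)
class DeviationScore:
    mse: float
    excess_runs: tuple[ExcessRun, ...]
    rows: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class Detection:
    row: int
    col: float
    radius: float
    bone_line: int
    peak_dev: float


@dataclass(frozen=True)
class FractureReport:
    fractured: bool
    detections: tuple[Detection, ...]
    residual_traces: dict[int, DeviationScore] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fractured": self.fractured,
            "detections": [
                {
                    "row": d.row,
                    "col": d.col,
                    "radius": d.radius,
                    "bone_line": d.bone_line,
                    "peak_dev": d.peak_dev,
                }
                for d in self.detections
            ],
        }


def crop_top_curvature(line: BoneLine, cfg: FitConfig | None = None) -> BoneLine:
    """Remove the curved bone head above the quadratic-fit vertex.

    A degree-2 polynomial is fitted over the top ``top_frac`` of the rows.  If
    its vertex falls inside that band the line is cropped at the vertex;
    otherwise (no hook: the band is essentially straight) the whole band is
    removed, since the bone head is noisy regardless of whether it curves.
    """
    cfg = cfg or FitConfig()
    if line.rows.size < 20:
        raise ValidationError("bone line too short to crop its top curvature")
    k = max(int(np.ceil(cfg.top_frac * line.rows.size)), cfg.curvature_degree + 1)
    band_rows = line.rows[:k].astype(float)
    band_cols = line.cols[:k]
    poly = Polynomial.fit(band_rows, band_cols, cfg.curvature_degree).convert()
    coefs = poly.coef
    crop_row = int(band_rows[-1])
    if len(coefs) >= 3 and abs(coefs[2]) > 1e-9:
        vertex = -coefs[1] / (2.0 * coefs[2])
        if band_rows[0] <= vertex <= band_rows[-1]:
            crop_row = int(np.floor(vertex))
    keep = line.rows > crop_row
    return BoneLine(rows=line.rows[keep], cols=line.cols[keep])


def fit_ideal_contour(line: BoneLine, degree: int = 3) -> Polynomial:
    """Least-squares polynomial col ~ p(row): the fracture-free reference."""
    if line.rows.size <= degree:
        raise ValidationError("bone line underdetermined for the requested degree")
    return Polynomial.fit(line.rows.astype(float), line.cols, degree)


def score_deviation(
    line: BoneLine, fit: Polynomial, tolerance: float = 3.0
) -> DeviationScore:
    """Residual trace of the line against its ideal contour.

    Residual per row is (observed column - fitted column).  Runs require the
    strict inequality |residual| > tolerance.
    """
    rows = line.rows
    residuals = line.cols - fit(rows.astype(float))
    mse = float(np.mean(residuals**2))
    over = np.abs(residuals) > tolerance
    runs = []
    i = 0
    while i < over.size:
        if not over[i]:
            i += 1
            continue
        j = i
        while j + 1 < over.size and over[j + 1]:
            j += 1
        seg = np.abs(residuals[i : j + 1])
        peak = i + int(np.argmax(seg))
        runs.append(
            ExcessRun(
                start_row=int(rows[i]),
                end_row=int(rows[j]),
                peak_row=int(rows[peak]),
                peak_dev=float(seg.max()),
            )
        )
        i = j + 1
    return DeviationScore(mse=mse, excess_runs=tuple(runs), rows=rows, residuals=residuals)


def detect_fracture(lines: list[BoneLine], cfg: FitConfig | None = None) -> FractureReport:
    """Classify and localise fractures over 1-4 bone lines.

    Per line: crop the top curvature, fit the ideal contour, track residual
    runs.  Runs closer than ``cfg.group_gap`` rows form one deviation area; an
    area qualifies when at least one of its runs spans ``cfg.min_run`` rows
    (isolated single-row spikes are segmentation noise).  Each qualifying area
    yields a circle centred at its peak row with radius
    max(area extent / 2, tolerance).
    """
    cfg = cfg or FitConfig()
    if not lines:
        raise ValidationError("detect_fracture requires at least one bone line")
    detections = []
    traces = {}
    for idx, line in enumerate(lines):
        cropped = crop_top_curvature(line, cfg)
        fit = fit_ideal_contour(cropped, cfg.ideal_degree)
        score = score_deviation(cropped, fit, cfg.tolerance)
        traces[idx] = score
        groups: list[list[ExcessRun]] = []
        for run in score.excess_runs:
            if groups and run.start_row - groups[-1][-1].end_row <= cfg.group_gap:
                groups[-1].append(run)
            else:
                groups.append([run])
        edge_row = int(cropped.rows[-1]) - cfg.bottom_margin
        for group in groups:
            if max(r.length for r in group) < cfg.min_run:
                continue
            if group[-1].end_row >= edge_row:
                continue
            peak = max(group, key=lambda r: r.peak_dev)
            extent = group[-1].end_row - group[0].start_row + 1
            radius = max(extent / 2.0, cfg.tolerance)
            detections.append(
                Detection(
                    row=peak.peak_row,
                    col=cropped.col_at(peak.peak_row),
                    radius=radius,
                    bone_line=idx,
                    peak_dev=peak.peak_dev,
                )
            )
    return FractureReport(
        fractured=bool(detections),
        detections=tuple(detections),
        residual_traces=traces,
    )
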