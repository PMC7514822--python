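"""Synthetic forearm-radiograph phantoms with known ground truth.

A phantom is a bright collimation box on a black frame containing two
near-vertical long bones (high intensity plateaus) inside a soft-tissue halo
(intermediate intensity).  A textured "carpal" comb just above the bone ends
reproduces the jump in row-peak counts that the ROI stage keys on.  Optional
fracture perturbations (lateral step, gap, or bump) displace one bone's
contour below a chosen row.

Bone centrelines are cubic polynomials of the row coordinate, so a healthy
phantom's edges are exactly representable by the ideal-contour fit and the
fracture detector's null case is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from xraypipe.errors import ValidationError

__all__ = ["FractureGroundTruth", "PhantomSpec", "GroundTruth", "generate_phantom"]

_FRACTURE_KINDS = ("step", "gap", "bump")


@dataclass(frozen=True)
class FractureGroundTruth:
    """Where and how a bone contour is perturbed."""

    bone_index: int
    row: int
    kind: str = "step"
    magnitude: float = 8.0

    def __post_init__(self):
        if self.bone_index not in (0, 1):
            raise ValidationError("bone_index must be 0 or 1")
        if self.kind not in _FRACTURE_KINDS:
            raise ValidationError(f"fracture kind must be one of {_FRACTURE_KINDS}")
        if self.magnitude <= 0:
            raise ValidationError("fracture magnitude must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs render identically."""

    image_height: int = 320
    image_width: int = 260
    box_angle: float = 0.0  # display-CCW tilt of the collimation box, degrees
    box_top: int = 12
    box_margin: int = 25  # black frame width left/right of the box
    bone_centers: tuple[float, float] = (104.0, 156.0)
    # centreline curvature: column offset = a1*t + a3*t^3 with t in [-1, 1]
    bone_curves: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 1.5),
        (-1.5, 1.0),
    )
    bone_half_width: int = 9
    tissue_extra: int = 18
    bone_intensity: int = 230
    tissue_intensity: int = 110
    box_intensity: int = 45
    bone_top_frac: float = 0.38
    comb_period: int = 6
    comb_max_depth: int = 12
    noise_sigma: float = 2.0
    blur_sigma: float = 0.7
    fracture: FractureGroundTruth | None = None
    rng_seed: int = 0

    @property
    def bone_top(self) -> int:
        return int(self.bone_top_frac * self.image_height)

    def validate(self):
        if not (0 < self.box_intensity < self.tissue_intensity < self.bone_intensity <= 255):
            raise ValidationError("need bone > tissue > box intensity > 0")
        lo = self.box_margin
        hi = self.image_width - self.box_margin
        halo = self.bone_half_width + self.tissue_extra
        for base, (a1, a3) in zip(self.bone_centers, self.bone_curves):
            wiggle = abs(a1) + abs(a3)
            mag = self.fracture.magnitude if self.fracture else 0.0
            if base - wiggle - halo - mag < lo or base + wiggle + halo + mag > hi:
                raise ValidationError("bone centreline (plus halo) leaves the box")
        if self.fracture is not None:
            top = self.bone_top
            bot = self.image_height - 1
            cut = top + 0.2 * (bot - top)
            if not (cut <= self.fracture.row <= bot):
                raise ValidationError(
                    "fracture row must lie below the top 20% of the bone line"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Known answers for one phantom, in the unrotated frame."""

    box_angle: float
    bone_end_row: int
    edge_rows: np.ndarray  # rows covered by the bones, ascending
    edge_cols: np.ndarray  # shape (4, n_rows): per-edge columns, left to right
    line_to_bone: tuple[int, ...]  # which bone each edge belongs to
    fracture: FractureGroundTruth | None


def _centreline(spec: PhantomSpec, bone: int, rows: np.ndarray) -> np.ndarray:
    base = spec.bone_centers[bone]
    a1, a3 = spec.bone_curves[bone]
    top, bot = spec.bone_top, spec.image_height - 1
    t = (2.0 * (rows - top) / (bot - top)) - 1.0
    cols = base + a1 * t + a3 * t**3
    frac = spec.fracture
    if frac is not None and frac.bone_index == bone:
        if frac.kind == "step":
            # 3-row transition keeps the per-row lateral jump within the
            # tracer's search window while still reading as a step to the fit
            ramp = np.clip((rows - frac.row + 1) / 3.0, 0.0, 1.0)
            cols = cols + frac.magnitude * ramp
        elif frac.kind == "bump":
            cols = cols + frac.magnitude * np.exp(-(((rows - frac.row) / 5.0) ** 2))
    return cols


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the phantom and its ground truth.

    Pixels outside the collimation box are exactly 0; inside they are at least
    1 even after blur and noise, so the binarisation step sees the whole box.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    lo, hi = spec.box_margin, w - spec.box_margin
    top = spec.bone_top
    rows = np.arange(top, h)

    scene = np.zeros((h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.float64)
    mask[spec.box_top :, lo:hi] = 1.0
    scene[spec.box_top :, lo:hi] = spec.box_intensity

    halo = spec.bone_half_width + spec.tissue_extra
    centres = [_centreline(spec, b, rows) for b in (0, 1)]
    tissue_left = int(np.floor(min(c.min() for c in centres) - halo))
    tissue_right = int(np.ceil(max(c.max() for c in centres) + halo))
    scene[top - spec.comb_max_depth - 2 :, tissue_left : tissue_right + 1] = (
        spec.tissue_intensity
    )

    # carpal comb: stripe depth grows with column so row peak counts ramp up
    # toward the bone-end row, making it the retained far-bottom count peak
    stripes = np.arange(tissue_left + 2, tissue_right - 1, spec.comb_period)
    for k, col in enumerate(stripes):
        depth = 2 + int(round((spec.comb_max_depth - 2) * k / max(len(stripes) - 1, 1)))
        scene[top - depth : top, col : col + 2] = spec.bone_intensity

    cols_grid = np.arange(w)[None, :]
    for b in (0, 1):
        centre = centres[b][:, None]
        bone_mask = np.abs(cols_grid - centre) <= spec.bone_half_width
        frac = spec.fracture
        if frac is not None and frac.bone_index == b and frac.kind == "gap":
            gap_rows = (rows >= frac.row) & (rows < frac.row + frac.magnitude)
            bone_mask[gap_rows] = False
        region = scene[top:, :]
        region[bone_mask] = spec.bone_intensity

    if spec.blur_sigma > 0:
        scene = ndimage.gaussian_filter(scene, spec.blur_sigma)

    if spec.box_angle != 0.0:
        scene = ndimage.rotate(scene, spec.box_angle, reshape=True, order=1)
        mask = ndimage.rotate(mask, spec.box_angle, reshape=True, order=1)
    inside = mask > 0.5
    scene = np.where(inside, np.maximum(scene, 1.0), 0.0)

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sigma > 0:
        scene[inside] += rng.normal(0.0, spec.noise_sigma, int(inside.sum()))
        scene[inside] = np.maximum(scene[inside], 1.0)

    img = np.clip(np.rint(scene), 0, 255).astype(np.uint8)
    img[~inside] = 0

    hw = spec.bone_half_width + 0.5
    edge_cols = np.stack(
        [
            centres[0] - hw,
            centres[0] + hw,
            centres[1] - hw,
            centres[1] + hw,
        ]
    )
    truth = GroundTruth(
        box_angle=spec.box_angle,
        bone_end_row=top,
        edge_rows=rows,
        edge_cols=edge_cols,
        line_to_bone=(0, 0, 1, 1),
        fracture=spec.fracture,
    )
    return img, truth


def random_spec(
    rng: np.random.Generator,
    fracture: bool = False,
    kind: str = "step",
    magnitude_range: tuple[float, float] = (7.0, 12.0),
    noise_sigma: float = 2.0,
    blur_sigma: float = 0.7,
) -> PhantomSpec:
    """Draw a randomised phantom spec (centreline curvature, seed, fracture).

    Step magnitudes default to >= 7 px so the residual of the cubic ideal-bone
    fit clears the 3-px tolerance with margin.
    """
    curves = tuple(
        (float(rng.uniform(-3, 3)), float(rng.uniform(-2, 2))) for _ in range(2)
    )
    spec = PhantomSpec(
        bone_curves=curves,
        noise_sigma=noise_sigma,
        blur_sigma=blur_sigma,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    if fracture:
        top, bot = spec.bone_top, spec.image_height - 1
        row = int(rng.integers(top + int(0.3 * (bot - top)), top + int(0.7 * (bot - top))))
        frac = FractureGroundTruth(
            bone_index=int(rng.integers(0, 2)),
            row=row,
            kind=kind,
            magnitude=float(rng.uniform(*magnitude_range)),
        )
        spec = replace(spec, fracture=frac)
    return spec
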