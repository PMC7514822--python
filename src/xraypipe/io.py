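"""8-bit grayscale image I/O and simple overlay rendering."""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from xraypipe.errors import ValidationError

__all__ = ["read_gray", "write_gray", "overlay_report", "overlay_lines"]


def read_gray(path) -> np.ndarray:
    """Load a PNG/TIFF as an 8-bit grayscale array (converted if needed)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_gray(path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValidationError("image values outside [0, 255]")
        img = img.astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def overlay_lines(img: np.ndarray, lines, path) -> None:
    """Save the image with traced bone lines drawn in green."""
    rgb = Image.fromarray(np.asarray(img), mode="L").convert("RGB")
    draw = ImageDraw.Draw(rgb)
    for line in lines:
        pts = [(float(c), float(r)) for r, c in zip(line.rows, line.cols)]
        if len(pts) > 1:
            draw.line(pts, fill=(0, 200, 0), width=1)
    rgb.save(path)


def overlay_report(img: np.ndarray, report, path) -> None:
    """Save the image with a red circle around each detected fracture area."""
    rgb = Image.fromarray(np.asarray(img), mode="L").convert("RGB")
    draw = ImageDraw.Draw(rgb)
    for det in report.detections:
        r = det.radius
        bbox = (det.col - r, det.row - r, det.col + r, det.row + r)
        draw.ellipse(bbox, outline=(255, 0, 0), width=2)
    rgb.save(path)
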