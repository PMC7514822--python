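"""Pipeline hyperparameters with their published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from xraypipe.errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    pad: int = 10
    closing_kernel: int = 10
    entropy_window: int = 9
    log_base: float = 2.0
    peak_threshold: float = 0.20
    roi_band: tuple[float, float] = (0.25, 0.75)
    peak_retention: float = 0.95
    width_expansion: float = 0.20
    search_up: int = 5
    search_side: int = 5
    min_path_frac: float = 0.60
    merge_window: int = 15
    ideal_degree: int = 3
    curvature_top_frac: float = 0.20
    tolerance: float = 3.0
    metric_window: int = 32
    min_run: int = 2

    def __post_init__(self):
        if self.pad < 0 or self.closing_kernel < 1:
            raise ValidationError("pad must be >= 0 and closing_kernel >= 1")
        if self.entropy_window < 3 or self.entropy_window % 2 == 0:
            raise ValidationError("entropy_window must be odd and >= 3")
        if not 0 < self.peak_threshold < 1:
            raise ValidationError("peak_threshold must be in (0, 1)")
        lo, hi = self.roi_band
        if not 0 <= lo < hi <= 1:
            raise ValidationError("roi_band must satisfy 0 <= lo < hi <= 1")
        if not 0 < self.min_path_frac < 1:
            raise ValidationError("min_path_frac must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_band"] = list(d["roi_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "roi_band" in d:
            d = dict(d)
            d["roi_band"] = tuple(d["roi_band"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
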