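"""Pipeline configuration.

Every tunable threshold of the preprocessing, landmark-detection and
index-extraction stages lives here so that a run is fully described by
(recording, config, seed).  Configs serialize to YAML and carry a stable
hash that is recorded in all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    #: side length of the square median-filter window (cells, odd)
    median_window: int = 3
    #: Gaussian smoothing sigma (cells)
    gaussian_sigma: float = 1.0
    #: support threshold as a fraction of the frame maximum
    support_frac: float = 0.05
    #: minimum connected-component area accepted as a torso (cells)
    min_torso_area: int = 800


@dataclass
class LandmarkConfig:
    #: moving-average window applied to pbar(j) before peak/inflection search
    pbar_smooth_rows: int = 5
    #: peak prominence required, as a fraction of the smoothed-curve maximum
    peak_prominence_frac: float = 0.10
    #: minimum row distance between prominent peaks
    peak_min_distance: int = 5
    #: consecutive supported rows required to declare the torso start
    sustained_support_rows: int = 3
    #: Canny smoothing sigma for the pelvic sub-image
    canny_sigma: float = 1.0
    #: Canny hysteresis thresholds as gradient-magnitude quantiles
    canny_low_quantile: float = 0.50
    canny_high_quantile: float = 0.80
    #: waist segmentation threshold as a fraction of the mean masked pressure
    waist_threshold_frac: float = 0.5
    #: columns belong to the sacral imprint when the sacral row exceeds this
    #: fraction of its maximum
    sacral_column_frac: float = 0.5


@dataclass
class IndexConfig:
    #: moving-average window applied to COP(j) before differentiation
    cop_smooth_rows: int = 7
    #: prominence (columns) for a COP extremum to count as a curvature apex
    cop_peak_prominence: float = 0.2
    #: minimum row span between the flanking inflections of an apex; sharper
    #: kinks are local pressure artifacts, not spinal curvature
    min_apex_span_rows: int = 10
    #: moving-average window applied to the second difference before the
    #: inflection (sign-change) search
    d2_smooth_rows: int = 9
    #: COP rows whose total pressure falls below this fraction of the
    #: heaviest row are dropped (taper rows, quantization-dominated)
    min_row_weight_frac: float = 0.1


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    indices: IndexConfig = field(default_factory=IndexConfig)
    version: str = "1"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            landmarks=LandmarkConfig(**raw.get("landmarks", {})),
            indices=IndexConfig(**raw.get("indices", {})),
            version=str(raw.get("version", "1")),
            seed=int(raw.get("seed", 0)),
        )
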