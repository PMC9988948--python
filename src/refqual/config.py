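"""Cohort-level configuration.

Everything a scoring run can vary lives here: the ten indicator weights
(default all 1 — every indicator counts equally), the sample→species
aggregation mode, the percentile convention for adjusted-N50 scaling, PCA
options for transcript diversity, the reference species for relative
diversity, and the missing-data policy for the final index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .errors import ValidationError

#: The ten indicators, in canonical order.
INDICATOR_COLUMNS = [
    "AdjN50Contig",
    "AdjN50Scaffold",
    "UngapRate",
    "UnimapRate",
    "MapRate",
    "MultiMapRate",
    "TranscriptDiversity",
    "QuantRate",
    "QuantRateAbs",
    "QuantRateAmb",
]

MISSING_DATA_POLICIES = ("complete", "renormalize")


@dataclass
class CohortConfig:
    weights: list[float] = field(default_factory=lambda: [1.0] * 10)
    aggregation: str = "mean"  # or "pooled"
    percentile_convention: str = "rank_minmax"  # or "ecdf"
    pca_mode: str = "covariance"  # or "correlation"
    reference_species: Optional[str] = None
    missing_data_policy: str = "complete"  # or "renormalize"
    shannon_global_s: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (10,):
            raise ValidationError("weights must be a vector of 10 values")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValidationError("weights must be finite and >= 0")
        if w.sum() == 0:
            raise ValidationError("weights must not all be zero")
        if self.missing_data_policy not in MISSING_DATA_POLICIES:
            raise ValidationError(
                f"missing_data_policy must be one of {MISSING_DATA_POLICIES}"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
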