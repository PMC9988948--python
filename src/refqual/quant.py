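"""Quantification-stage indicators and the quantification quality index (QQI).

A read counter (featureCounts-style) labels every mapped read unit with a
status category.  Writing ``T`` for the mapped-read denominator — the sum
of all categories except ``unassigned_unmapped``, which is a mapping
failure, not a quantification one — each sample contributes:

* ``QuantRate``    = assigned / T
* ``QuantRateAbs`` = 1 − no_features / T   (failure by absence of annotation)
* ``QuantRateAmb`` = 1 − ambiguity / T     (failure by overlapping annotation)

``QuantRate <= QuantRateAbs + QuantRateAmb − 1`` always holds, with
equality exactly when no other failure category carries counts.  Species
aggregation mirrors the mapping module (unweighted per-sample mean by
default, pooled counts optional); ``QQI`` is the mean of the three
species-level rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .records import (
    ASSIGNED,
    QuantSummary,
    UNASSIGNED_AMBIGUITY,
    UNASSIGNED_NO_FEATURES,
)
from .mapping import AGGREGATION_MODES


@dataclass(frozen=True)
class QuantIndicatorBlock:
    species_id: str
    n_samples: int
    QuantRate: float
    QuantRateAbs: float
    QuantRateAmb: float
    QQI: float
    per_sample: list[tuple] = field(default_factory=list)


def sample_quant_rates(summary: QuantSummary) -> tuple[float, float, float]:
    """(QuantRate, QuantRateAbs, QuantRateAmb) for one sample."""
    t = summary.mapped_total()
    if t <= 0:
        raise DomainError(
            f"{summary.sample_id}: no mapped reads in quantification summary"
        )
    c = summary.category_counts
    assigned = c.get(ASSIGNED, 0)
    ambiguity = c.get(UNASSIGNED_AMBIGUITY, 0)
    no_features = c.get(UNASSIGNED_NO_FEATURES, 0)
    return (assigned / t, 1.0 - no_features / t, 1.0 - ambiguity / t)


def qqi(rates: Sequence[float]) -> float:
    """Arithmetic mean of (QuantRate, QuantRateAbs, QuantRateAmb)."""
    if len(rates) != 3:
        raise DomainError("QQI takes exactly three rates")
    for r in rates:
        if r is None or not np.isfinite(r) or not 0.0 <= r <= 1.0:
            raise DomainError(f"rate {r!r} outside [0, 1]")
    return float(sum(rates)) / 3.0


def aggregate_species(
    species_id: str,
    samples: Iterable[QuantSummary],
    mode: str = "mean",
) -> QuantIndicatorBlock:
    """Aggregate per-sample quantification rates to one species block."""
    samples = list(samples)
    if not samples:
        raise DomainError(f"{species_id}: no quantification samples")
    if mode not in AGGREGATION_MODES:
        raise DomainError(f"unknown aggregation mode {mode!r}")

    triples = [sample_quant_rates(s) for s in samples]
    if mode == "mean":
        arr = np.asarray(triples, dtype=float)
        q, qabs, qamb = (float(x) for x in arr.mean(axis=0))
    else:
        pooled: dict[str, int] = {}
        for s in samples:
            for k, v in s.category_counts.items():
                pooled[k] = pooled.get(k, 0) + v
        merged = QuantSummary(
            sample_id=f"{species_id}:pooled", species_id=species_id,
            category_counts=pooled,
        )
        q, qabs, qamb = sample_quant_rates(merged)

    return QuantIndicatorBlock(
        species_id=species_id,
        n_samples=len(samples),
        QuantRate=q,
        QuantRateAbs=qabs,
        QuantRateAmb=qamb,
        QQI=qqi((q, qabs, qamb)),
        per_sample=[(s.sample_id, *t) for s, t in zip(samples, triples)],
    )
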