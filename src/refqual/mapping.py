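"""Mapping-stage indicators and the mapping quality index (MQI).

Each RNA-seq sample contributes three rates computed from its read-unit
partition (unique + multi + unmapped = total):

* ``UnimapRate``   = unique / total
* ``MapRate``      = 1 − unmapped / total
* ``MultiMapRate`` = 1 − multi / total

All three point "up" (closer to 1 is better).  The partition forces the
identity ``UnimapRate = MapRate + MultiMapRate − 1`` for every sample.
Species-level rates are the unweighted mean over that species' samples
(samples are assumed comparably sized; a pooled-count mode is available),
and ``MQI`` is the arithmetic mean of the three species-level rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DomainError
from .records import MappingSummary

AGGREGATION_MODES = ("mean", "pooled")


@dataclass(frozen=True)
class MappingIndicatorBlock:
    """Species-level mapping indicators plus the per-sample triples behind them."""

    species_id: str
    n_samples: int
    UnimapRate: float
    MapRate: float
    MultiMapRate: float
    MQI: float
    per_sample: list[tuple] = field(default_factory=list)


def sample_mapping_rates(
    summary: MappingSummary,
) -> tuple[Optional[float], float, Optional[float]]:
    """(UnimapRate, MapRate, MultiMapRate) for one sample.

    Components that the summary dialect does not report (no multi-mapped
    count) come back as ``None`` rather than an approximation.
    """
    t = summary.total_units
    if t <= 0:
        raise DomainError(f"{summary.sample_id}: total_units must be > 0")
    map_rate = 1.0 - summary.unmapped_units / t
    uni = summary.unique_units / t if summary.unique_units is not None else None
    multi = (
        1.0 - summary.multi_units / t if summary.multi_units is not None else None
    )
    return (uni, map_rate, multi)


def mqi(rates: Sequence[float]) -> float:
    """Arithmetic mean of (UnimapRate, MapRate, MultiMapRate)."""
    if len(rates) != 3:
        raise DomainError("MQI takes exactly three rates")
    for r in rates:
        if r is None or not np.isfinite(r) or not 0.0 <= r <= 1.0:
            raise DomainError(f"rate {r!r} outside [0, 1]")
    return float(sum(rates)) / 3.0


def aggregate_species(
    species_id: str,
    samples: Iterable[MappingSummary],
    mode: str = "mean",
) -> MappingIndicatorBlock:
    """Aggregate per-sample rates to one species block.

    ``mode="mean"`` (default) averages each rate over samples, skipping
    missing components per sample; ``mode="pooled"`` sums the raw counts
    first and computes rates on the pooled partition.  A component missing
    in every sample stays NaN, and MQI is NaN whenever any of its three
    components is.
    """
    samples = list(samples)
    if not samples:
        raise DomainError(f"{species_id}: no mapping samples")
    if mode not in AGGREGATION_MODES:
        raise DomainError(f"unknown aggregation mode {mode!r}")

    triples = [sample_mapping_rates(s) for s in samples]
    if mode == "mean":
        cols = []
        for j in range(3):
            vals = [t[j] for t in triples if t[j] is not None]
            cols.append(float(np.mean(vals)) if vals else float("nan"))
        uni, map_rate, multi = cols
    else:
        total = sum(s.total_units for s in samples)
        unmapped = sum(s.unmapped_units for s in samples)
        uniques = [s.unique_units for s in samples]
        multis = [s.multi_units for s in samples]
        uni = sum(u for u in uniques) / total if all(u is not None for u in uniques) else float("nan")
        multi = (
            1.0 - sum(m for m in multis) / total
            if all(m is not None for m in multis)
            else float("nan")
        )
        map_rate = 1.0 - unmapped / total

    rates = (uni, map_rate, multi)
    score = mqi(rates) if all(np.isfinite(r) for r in rates) else float("nan")
    return MappingIndicatorBlock(
        species_id=species_id,
        n_samples=len(samples),
        UnimapRate=uni,
        MapRate=map_rate,
        MultiMapRate=multi,
        MQI=score,
        per_sample=[(s.sample_id, *t) for s, t in zip(samples, triples)],
    )
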