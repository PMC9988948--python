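"""Assembly-derived quality indicators.

Three of the ten indicators come straight from assembly statistics:

* ``AdjN50Contig``  — cohort percentile of contig N50 / genome size
* ``AdjN50Scaffold`` — cohort percentile of scaffold N50 / genome size
* ``UngapRate``      — 1 − spanned_gaps / max(spanned_gaps) over the cohort

Dividing N50 by genome size makes contiguity comparable across genomes of
very different sizes; the percentile then places each species within the
cohort on a 0–1 scale.  All three are cohort-relative: adding or removing
a species changes the scaling (but not raw ratios).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DomainError
from .records import AssemblyStats

logger = logging.getLogger(__name__)

PERCENTILE_CONVENTIONS = ("rank_minmax", "ecdf")


def adjusted_n50(n50: float, genome_size: float) -> float:
    """N50 divided by genome size, in (0, 1].

    Raises :class:`DomainError` unless ``0 < n50 <= genome_size``.
    """
    if genome_size <= 0 or n50 <= 0:
        raise DomainError("n50 and genome_size must be positive")
    if n50 > genome_size:
        raise DomainError(f"n50 ({n50}) exceeds genome_size ({genome_size})")
    return n50 / genome_size


def percentile_scale(
    values: Sequence[float], convention: str = "rank_minmax"
) -> np.ndarray:
    """Map cohort values onto [0, 1] by rank.

    The default convention is ``(rank − 1) / (n − 1)`` with ascending
    average ranks for ties, so the minimum maps exactly to 0 and the
    maximum to 1.  ``"ecdf"`` uses ``rank / n`` instead.  A single-species
    cohort has no meaningful percentile; it returns 1.0 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError("percentile_scale needs a non-empty 1-d vector")
    if not np.all(np.isfinite(arr)):
        raise DomainError("percentile_scale requires finite values")
    if convention not in PERCENTILE_CONVENTIONS:
        raise DomainError(
            f"unknown percentile convention {convention!r}; "
            f"choose from {PERCENTILE_CONVENTIONS}"
        )
    n = arr.size
    if n == 1:
        logger.warning("percentile of a single-species cohort is undefined; returning 1.0")
        return np.ones(1)
    ranks = rankdata(arr, method="average")
    if convention == "rank_minmax":
        return (ranks - 1.0) / (n - 1.0)
    return ranks / n


def ungap_rate(spanned_gaps: Sequence[float]) -> np.ndarray:
    """``1 − gaps_i / max_j(gaps_j)`` per species.

    The species with the cohort's largest gap count scores exactly 0; a
    gapless species scores 1.  An all-zero cohort is the limit of equal
    quality and scores 1.0 everywhere.
    """
    arr = np.asarray(spanned_gaps, dtype=float)
    if arr.size == 0:
        raise DomainError("ungap_rate needs a non-empty cohort")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DomainError("spanned-gap counts must be finite and >= 0")
    top = arr.max()
    if top == 0:
        return np.ones_like(arr)
    return 1.0 - arr / top


def genome_indicator_block(
    cohort: Iterable[AssemblyStats], percentile_convention: str = "rank_minmax"
) -> pd.DataFrame:
    """Compute the three assembly indicators for a cohort.

    Returns a species-indexed frame with the raw adjusted-N50 ratios and
    the scaled ``AdjN50Contig``, ``AdjN50Scaffold`` and ``UngapRate``
    columns.  Percentiles are computed over exactly the species given, so
    the caller controls the complete-case subset.
    """
    stats = list(cohort)
    if not stats:
        raise DomainError("empty cohort")
    idx = [s.species_id for s in stats]
    contig = [adjusted_n50(s.contig_n50, s.genome_size) for s in stats]
    scaffold = [adjusted_n50(s.scaffold_n50, s.genome_size) for s in stats]
    gaps = [s.spanned_gaps for s in stats]
    return pd.DataFrame(
        {
            "adj_n50_contig_raw": contig,
            "adj_n50_scaffold_raw": scaffold,
            "spanned_gaps": gaps,
            "AdjN50Contig": percentile_scale(contig, percentile_convention),
            "AdjN50Scaffold": percentile_scale(scaffold, percentile_convention),
            "UngapRate": ungap_rate(gaps),
        },
        index=pd.Index(idx, name="species_id"),
    )
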