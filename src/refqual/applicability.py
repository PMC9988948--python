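"""The integrated NGS applicability index.

The ten indicators — three assembly statistics, three mapping rates,
transcript diversity, and three quantification rates — are joined into a
species × 10 matrix and combined as a weighted arithmetic mean:

    index_i = Σ_k w_k · indicator_{i,k} / Σ_k w_k

with all weights 1 by default, i.e. the plain mean of the ten.  Because
three of the ten are the MQI components and three are the QQI components,
the equal-weight index equals
``(3·MQI + 3·QQI + AdjN50Contig + AdjN50Scaffold + UngapRate +
TranscriptDiversity) / 10``.

Cohort-relative indicators (the two adjusted-N50 percentiles, UngapRate
and TranscriptDiversity) are computed over the subset of species that have
the corresponding input, so one species' missing annotation does not
invalidate everyone's assembly percentile.  Species missing any indicator
are excluded from the ranking under the default complete-case policy, or
scored over their available indicators with renormalized weights under
``missing_data_policy="renormalize"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .config import INDICATOR_COLUMNS, CohortConfig
from .diversity import DiversityResult, diversity_result
from .errors import DomainError
from .genome import genome_indicator_block
from .mapping import MappingIndicatorBlock
from .quant import QuantIndicatorBlock
from .records import AssemblyStats, BiotypeProfile


@dataclass
class IndicatorMatrix:
    """Species × 10 indicator values plus derived indices.

    ``values`` holds NaN where an indicator is unavailable; ``mask`` is the
    availability matrix; ``index`` is NaN for species excluded under the
    complete-case policy.
    """

    values: pd.DataFrame  # species × INDICATOR_COLUMNS
    weights: np.ndarray
    MQI: pd.Series
    QQI: pd.Series
    index: pd.Series
    mask: pd.DataFrame = None
    diversity: Optional[DiversityResult] = None
    optional_columns: Optional[pd.DataFrame] = None

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def to_table(self) -> pd.DataFrame:
        """Flat per-species table: 10 indicators, MQI, QQI, index, rank."""
        out = self.values.copy()
        out["MQI"] = self.MQI
        out["QQI"] = self.QQI
        out["index"] = self.index
        order = out["index"].rank(ascending=False, method="min")
        out["rank"] = order.where(out["index"].notna())
        if self.optional_columns is not None and not self.optional_columns.empty:
            out = out.join(self.optional_columns)
        return out


def assemble_indicator_matrix(
    assembly: Iterable[AssemblyStats],
    mapping: Iterable[MappingIndicatorBlock],
    quant: Iterable[QuantIndicatorBlock],
    profiles: Iterable[BiotypeProfile],
    config: Optional[CohortConfig] = None,
    species_order: Optional[Sequence[str]] = None,
    optional_columns: Optional[pd.DataFrame] = None,
) -> IndicatorMatrix:
    """Join per-module blocks into the species × 10 indicator matrix.

    The species set is the union over blocks (or ``species_order`` if
    given); missing blocks leave NaN cells recorded in the mask.
    Cohort-relative columns are computed on the per-indicator complete
    subset.  The join is independent of input order.
    """
    config = config or CohortConfig()
    assembly = list(assembly)
    mapping = list(mapping)
    quant = list(quant)
    profiles = list(profiles)

    if species_order is None:
        seen: dict[str, None] = {}
        for sid in itertools.chain(
            (a.species_id for a in assembly),
            (m.species_id for m in mapping),
            (q.species_id for q in quant),
            (p.species_id for p in profiles),
        ):
            seen.setdefault(sid)
        species_order = sorted(seen)
    if not species_order:
        raise DomainError("empty cohort: no species in any block")

    idx = pd.Index(species_order, name="species_id")
    values = pd.DataFrame(np.nan, index=idx, columns=INDICATOR_COLUMNS)
    mqi = pd.Series(np.nan, index=idx, name="MQI")
    qqi = pd.Series(np.nan, index=idx, name="QQI")

    if assembly:
        gb = genome_indicator_block(
            assembly, percentile_convention=config.percentile_convention
        )
        for col in ("AdjN50Contig", "AdjN50Scaffold", "UngapRate"):
            values.loc[gb.index.intersection(idx), col] = gb[col]

    for m in mapping:
        if m.species_id not in idx:
            continue
        values.loc[m.species_id, "UnimapRate"] = m.UnimapRate
        values.loc[m.species_id, "MapRate"] = m.MapRate
        values.loc[m.species_id, "MultiMapRate"] = m.MultiMapRate
        mqi.loc[m.species_id] = m.MQI

    for q in quant:
        if q.species_id not in idx:
            continue
        values.loc[q.species_id, "QuantRate"] = q.QuantRate
        values.loc[q.species_id, "QuantRateAbs"] = q.QuantRateAbs
        values.loc[q.species_id, "QuantRateAmb"] = q.QuantRateAmb
        qqi.loc[q.species_id] = q.QQI

    div = None
    usable_profiles = [p for p in profiles if p.n_genes > 0]
    if len(usable_profiles) >= 2:
        _, div = diversity_result(
            usable_profiles,
            mode=config.pca_mode,
            reference_species=(
                config.reference_species
                if config.reference_species
                in {p.species_id for p in usable_profiles}
                else None
            ),
            shannon_global_s=config.shannon_global_s,
        )
        common = div.transcript_diversity.index.intersection(idx)
        values.loc[common, "TranscriptDiversity"] = div.transcript_diversity[common]

    mask = values.notna()
    weights = np.asarray(config.weights, dtype=float)
    index = ngs_applicability(values, weights, policy=config.missing_data_policy)

    return IndicatorMatrix(
        values=values,
        weights=weights,
        MQI=mqi,
        QQI=qqi,
        index=index,
        mask=mask,
        diversity=div,
        optional_columns=optional_columns,
    )


def ngs_applicability(
    values: pd.DataFrame,
    weights: Sequence[float],
    policy: str = "complete",
) -> pd.Series:
    """Weighted arithmetic mean of the ten indicators per species.

    ``policy="complete"`` scores only species with all ten indicators
    present (others get NaN); ``"renormalize"`` averages over the available
    indicators with weights renormalized accordingly.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(INDICATOR_COLUMNS),):
        raise DomainError("weights must match the 10 indicators")
    if np.any(w < 0) or w.sum() == 0 or not np.all(np.isfinite(w)):
        raise DomainError("weights must be non-negative, finite, not all zero")
    X = values[INDICATOR_COLUMNS].to_numpy(dtype=float)
    present = np.isfinite(X)
    out = np.full(len(values), np.nan)
    for i in range(len(values)):
        p = present[i]
        if policy == "complete":
            if p.all():
                out[i] = float(X[i] @ w / w.sum())
        elif policy == "renormalize":
            wp = w[p]
            if wp.sum() > 0:
                out[i] = float(X[i, p] @ wp / wp.sum())
        else:
            raise DomainError(f"unknown missing-data policy {policy!r}")
    return pd.Series(out, index=values.index, name="index")


def rank_report(matrix: IndicatorMatrix) -> pd.DataFrame:
    """Per-species report sorted by descending index, ties broken by species_id.

    Unscored species (incomplete under the complete-case policy) are
    omitted; the report carries all 10 indicators plus MQI and QQI.
    """
    table = matrix.to_table()
    # stable sort on a lexicographically pre-sorted frame → deterministic ties
    scored = (
        table[table["index"].notna()]
        .sort_index()
        .sort_values("index", ascending=False, kind="mergesort")
    )
    scored["rank"] = np.arange(1, len(scored) + 1)
    return scored


def correlate_indicators(
    table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlation of numeric columns with pairwise-complete filtering.

    Pairs with fewer than 3 complete observations, and constant columns,
    yield NaN.  The result is symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        out.loc[a, a] = 1.0
        for b in cols[i + 1 :]:
            pair = num[[a, b]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = (
                pearsonr(x, y).statistic
                if method == "pearson"
                else spearmanr(x, y).statistic
            )
            out.loc[a, b] = out.loc[b, a] = float(r)
    return out


def compare_builds(builds: dict[str, IndicatorMatrix]) -> pd.DataFrame:
    """Long-format comparison of several builds of the same species set.

    One row per (species, build) with the ten indicators, the index, and
    any optional passthrough columns (e.g. BUSCO completeness).  A species
    absent from a build contributes an all-NaN row flagged ``missing``.
    """
    if len(builds) < 2:
        raise DomainError("need at least two builds to compare")
    all_species = sorted({s for m in builds.values() for s in m.species})
    rows = []
    for build_name, m in builds.items():
        table = m.to_table()
        for sid in all_species:
            if sid in table.index:
                row = table.loc[sid].to_dict()
                row.update(species_id=sid, build=build_name, missing=False)
            else:
                row = {c: np.nan for c in table.columns}
                row.update(species_id=sid, build=build_name, missing=True)
            rows.append(row)
    out = pd.DataFrame(rows)
    front = ["species_id", "build", "missing"]
    return out[front + [c for c in out.columns if c not in front]]
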