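"""Validated domain records.

Each record corresponds to one external artifact consumed by the scorer:
assembly statistics, a per-sample alignment summary, a per-sample
quantification summary, or a per-species annotation profile.  Records
validate their invariants at construction time and raise
:class:`~refqual.errors.ValidationError` on violation, so everything
downstream can assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ValidationError

#: Canonical quantification status categories (featureCounts-style, normalised).
ASSIGNED = "assigned"
UNASSIGNED_AMBIGUITY = "unassigned_ambiguity"
UNASSIGNED_NO_FEATURES = "unassigned_no_features"
UNASSIGNED_UNMAPPED = "unassigned_unmapped"


@dataclass(frozen=True)
class AssemblyStats:
    """Contiguity and gap statistics of one species' reference assembly."""

    species_id: str
    genome_size: int
    contig_n50: int
    scaffold_n50: int
    spanned_gaps: int

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValidationError(f"{self.species_id}: genome_size must be positive")
        for name in ("contig_n50", "scaffold_n50"):
            v = getattr(self, name)
            if not 0 < v <= self.genome_size:
                raise ValidationError(
                    f"{self.species_id}: {name}={v} outside (0, genome_size={self.genome_size}]"
                )
        if self.spanned_gaps < 0:
            raise ValidationError(f"{self.species_id}: spanned_gaps must be >= 0")


@dataclass(frozen=True)
class MappingSummary:
    """One sample's read-unit partition after alignment.

    ``unique_units`` and ``multi_units`` may be ``None`` for summary dialects
    that only report mapped/unmapped totals (e.g. samtools stats); the
    partition invariant ``unique + multi + unmapped == total`` is enforced
    whenever all parts are present.  ``unit`` records whether counts are
    reads or fragments (read pairs); indicators are ratios within one
    summary, so the convention never mixes across samples.
    """

    sample_id: str
    species_id: str
    total_units: int
    unmapped_units: int
    unique_units: Optional[int] = None
    multi_units: Optional[int] = None
    unit: str = "read"

    def __post_init__(self) -> None:
        if self.total_units <= 0:
            raise ValidationError(f"{self.sample_id}: total_units must be > 0")
        parts = [self.unmapped_units, self.unique_units, self.multi_units]
        for v in parts:
            if v is not None and v < 0:
                raise ValidationError(f"{self.sample_id}: negative count")
        if self.unique_units is not None and self.multi_units is not None:
            s = self.unique_units + self.multi_units + self.unmapped_units
            if s != self.total_units:
                raise ValidationError(
                    f"{self.sample_id}: unique+multi+unmapped = {s} != total "
                    f"{self.total_units} (residual {self.total_units - s})"
                )

    @property
    def is_complete(self) -> bool:
        return self.unique_units is not None and self.multi_units is not None


@dataclass(frozen=True)
class QuantSummary:
    """One sample's quantification status-category counts."""

    sample_id: str
    species_id: str
    category_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.category_counts:
            raise ValidationError(f"{self.sample_id}: empty category table")
        for k, v in self.category_counts.items():
            if v < 0:
                raise ValidationError(f"{self.sample_id}: negative count for {k!r}")
        if sum(self.category_counts.values()) <= 0:
            raise ValidationError(f"{self.sample_id}: all categories zero")

    def mapped_total(self) -> int:
        """Denominator for quantification rates: every category except
        ``unassigned_unmapped``, which is a mapping (not quantification)
        failure and is excluded."""
        return sum(
            v for k, v in self.category_counts.items() if k != UNASSIGNED_UNMAPPED
        )


@dataclass(frozen=True)
class BiotypeProfile:
    """Gene-biotype composition and genic-structure statistics of one annotation."""

    species_id: str
    biotype_counts: dict[str, int]
    n_genes: int
    mean_gene_length: float
    genic_fraction: float
    exonic_fraction: float

    def __post_init__(self) -> None:
        for k, v in self.biotype_counts.items():
            if v < 0:
                raise ValidationError(f"{self.species_id}: negative count for biotype {k!r}")
        if self.n_genes != sum(self.biotype_counts.values()):
            raise ValidationError(
                f"{self.species_id}: n_genes != sum of biotype counts"
            )
        if not 0.0 <= self.exonic_fraction <= self.genic_fraction <= 1.0:
            raise ValidationError(
                f"{self.species_id}: require 0 <= exonic ({self.exonic_fraction}) "
                f"<= genic ({self.genic_fraction}) <= 1"
            )
        if self.n_genes > 0 and self.mean_gene_length <= 0:
            raise ValidationError(f"{self.species_id}: mean_gene_length must be > 0")

    def proportions(self) -> dict[str, float]:
        if self.n_genes == 0:
            raise ValidationError(f"{self.species_id}: no genes; proportions undefined")
        return {k: v / self.n_genes for k, v in self.biotype_counts.items()}


@dataclass
class ManifestEntry:
    """One species row of a cohort manifest.

    Paths are stored as given; ``missing_inputs`` lists which artifact kinds
    were absent or unresolvable at load time ("assembly", "gtf", "mapping",
    "quant"), so downstream stages can mask indicators instead of failing.
    """

    species_id: str
    display_name: str = ""
    assembly_stats_path: Optional[Path] = None
    gtf_path: Optional[Path] = None
    mapping_summary_paths: list[Path] = field(default_factory=list)
    quant_summary_paths: list[Path] = field(default_factory=list)
    optional_columns: dict[str, float] = field(default_factory=dict)
    missing_inputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, v in self.optional_columns.items():
            if not math.isfinite(v):
                raise ValidationError(
                    f"{self.species_id}: optional column {k!r} is not finite"
                )


@dataclass
class CohortManifest:
    """The full cohort: an ordered list of species entries with unique ids."""

    entries: list[ManifestEntry]
    path: Optional[Path] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.species_id in seen:
                raise ValidationError(f"duplicate species_id {e.species_id!r}")
            seen.add(e.species_id)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def species_ids(self) -> list[str]:
        return [e.species_id for e in self.entries]

    def get(self, species_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.species_id == species_id:
                return e
        raise KeyError(species_id)
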