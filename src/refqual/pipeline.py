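"""End-to-end scoring: manifest in, ranked indicator table out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import io, mapping, quant
from .applicability import (
    IndicatorMatrix,
    assemble_indicator_matrix,
    correlate_indicators,
    rank_report,
)
from .config import CohortConfig
from .errors import RefqualError
from .records import AssemblyStats, BiotypeProfile, CohortManifest

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """Everything a scoring run produces."""

    matrix: IndicatorMatrix
    ranked: pd.DataFrame
    manifest: CohortManifest
    config: CohortConfig
    per_sample_mapping: pd.DataFrame
    per_sample_quant: pd.DataFrame
    issues: list[str] = field(default_factory=list)

    @property
    def n_scored(self) -> int:
        return int(self.matrix.index.notna().sum())


def score_cohort(
    manifest: Union[str, Path, CohortManifest],
    config: Optional[CohortConfig] = None,
) -> CohortResult:
    """Load every artifact a manifest references and score the cohort.

    Species with unreadable or missing artifacts lose the affected
    indicators (recorded in ``issues`` and the completeness mask) instead
    of aborting the run — mirroring real cohorts, where a few species
    always lack some input and drop out of the final ranking.
    """
    config = config or CohortConfig()
    if not isinstance(manifest, CohortManifest):
        manifest = io.read_manifest(manifest)

    issues: list[str] = []
    assembly: list[AssemblyStats] = []
    mapping_blocks = []
    quant_blocks = []
    profiles: list[BiotypeProfile] = []
    map_rows = []
    quant_rows = []

    for entry in manifest:
        sid = entry.species_id
        if entry.assembly_stats_path is not None:
            try:
                stats = io.parse_assembly_stats(entry.assembly_stats_path, species_id=sid)
                if stats is None:
                    issues.append(f"{sid}: assembly stats incomplete (NA fields)")
                elif isinstance(stats, AssemblyStats):
                    assembly.append(stats)
                else:  # multi-species table: keep the matching row
                    assembly.extend(s for s in stats if s.species_id == sid)
            except RefqualError as exc:
                issues.append(f"{sid}: assembly stats unreadable: {exc}")
        else:
            issues.append(f"{sid}: assembly stats missing")

        summaries = []
        for p in entry.mapping_summary_paths:
            try:
                summaries.append(
                    io.parse_alignment_summary(p, sample_id=p.stem, species_id=sid)
                )
            except RefqualError as exc:
                issues.append(f"{sid}: alignment summary {p.name}: {exc}")
        if summaries:
            block = mapping.aggregate_species(sid, summaries, mode=config.aggregation)
            mapping_blocks.append(block)
            for sample_id, uni, mr, multi in block.per_sample:
                map_rows.append(
                    dict(species_id=sid, sample_id=sample_id,
                         UnimapRate=uni, MapRate=mr, MultiMapRate=multi)
                )
        else:
            issues.append(f"{sid}: mapping summaries missing")

        qsummaries = []
        for p in entry.quant_summary_paths:
            try:
                qsummaries.append(
                    io.parse_quant_summary(p, sample_id=p.stem, species_id=sid)
                )
            except RefqualError as exc:
                issues.append(f"{sid}: quant summary {p.name}: {exc}")
        if qsummaries:
            block = quant.aggregate_species(sid, qsummaries, mode=config.aggregation)
            quant_blocks.append(block)
            for sample_id, q, qabs, qamb in block.per_sample:
                quant_rows.append(
                    dict(species_id=sid, sample_id=sample_id,
                         QuantRate=q, QuantRateAbs=qabs, QuantRateAmb=qamb)
                )
        else:
            issues.append(f"{sid}: quantification summaries missing")

        if entry.gtf_path is not None:
            genome_size = None
            for a in assembly:
                if a.species_id == sid:
                    genome_size = a.genome_size
            if genome_size is None:
                issues.append(f"{sid}: GTF present but genome size unknown; skipped")
            else:
                try:
                    profiles.append(io.profile_gtf(entry.gtf_path, genome_size, sid))
                except RefqualError as exc:
                    issues.append(f"{sid}: GTF unreadable: {exc}")
        else:
            issues.append(f"{sid}: annotation missing")

    opt = pd.DataFrame(
        {e.species_id: e.optional_columns for e in manifest}
    ).T.rename_axis("species_id")

    matrix = assemble_indicator_matrix(
        assembly, mapping_blocks, quant_blocks, profiles,
        config=config,
        species_order=manifest.species_ids,
        optional_columns=opt if not opt.empty else None,
    )
    ranked = rank_report(matrix)
    for msg in issues:
        logger.info("issue: %s", msg)
    return CohortResult(
        matrix=matrix,
        ranked=ranked,
        manifest=manifest,
        config=config,
        per_sample_mapping=pd.DataFrame(map_rows),
        per_sample_quant=pd.DataFrame(quant_rows),
        issues=issues,
    )


def write_outputs(result: CohortResult, outdir: Union[str, Path]) -> dict[str, Path]:
    """Write indicators.tsv, index_ranked.tsv, correlations.tsv and report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["indicators"] = io.write_indicator_table(
        result.matrix.to_table(), outdir / "indicators.tsv"
    )
    paths["ranked"] = io.write_indicator_table(
        result.ranked, outdir / "index_ranked.tsv"
    )
    corr = correlate_indicators(result.matrix.to_table().drop(columns=["rank"]))
    corr.index.name = "indicator"
    corr.reset_index().to_csv(outdir / "correlations.tsv", sep="\t", index=False,
                              float_format="%.6f")
    paths["correlations"] = outdir / "correlations.tsv"
    report = {
        "n_species": len(result.manifest),
        "n_scored": result.n_scored,
        "pc1_variance_explained": (
            result.matrix.diversity.variance_explained_pc1
            if result.matrix.diversity is not None
            else None
        ),
        "issues": result.issues,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    paths["report"] = outdir / "report.json"
    return paths
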