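"""Readers and writers for every external artifact the scorer touches.

Supported input dialects
------------------------
* **Manifest** — TSV with header ``species_id, display_name, assembly_stats,
  gtf, mapping_summaries, quant_summaries`` (the two summary columns are
  semicolon-separated path lists) plus arbitrary extra numeric columns
  (e.g. ``busco_completeness``, ``repeat_fraction``).
* **Assembly statistics** — TSV with header ``genome_size, contig_n50,
  scaffold_n50, spanned_gaps`` (one row per species; an optional
  ``species_id`` column allows multi-species tables), or an ENA-style
  assembly XML with ``<ASSEMBLY_ATTRIBUTE><TAG>/<VALUE>`` pairs.
* **Alignment summaries** — HISAT2/bowtie2-style paired-end summary text,
  or samtools-stats ``SN`` key/value text (which lacks a multi-mapped
  count; that component is recorded as missing, never guessed).
* **Quantification summaries** — featureCounts-style two-column ``.summary``
  status tables.
* **Annotation** — GTF (GFF2 attribute syntax); biotypes are taken from the
  ``gene_biotype`` attribute with ``gene_type`` as fallback.

Every parser either returns a validated record or raises a typed error;
none of them silently substitutes defaults for malformed input.
"""

from __future__ import annotations

import logging
import math
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ParseError, ValidationError
from .records import (
    AssemblyStats,
    BiotypeProfile,
    CohortManifest,
    ManifestEntry,
    MappingSummary,
    QuantSummary,
)

logger = logging.getLogger(__name__)

MANIFEST_CORE_COLUMNS = [
    "species_id",
    "display_name",
    "assembly_stats",
    "gtf",
    "mapping_summaries",
    "quant_summaries",
]

ASSEMBLY_FIELDS = ["genome_size", "contig_n50", "scaffold_n50", "spanned_gaps"]

#: ENA assembly-attribute tags mapped onto our field names.
_ENA_TAGS = {
    "total-length": "genome_size",
    "contig-n50": "contig_n50",
    "scaffold-n50": "scaffold_n50",
    "spanned-gaps": "spanned_gaps",
}

ALIGNMENT_DIALECTS = ("hisat2", "samtools_stats")

#: featureCounts status names whose normalisation is not just lower-casing.
_QUANT_ALIASES = {
    "unassigned_nofeatures": "unassigned_no_features",
    "unassigned_multimapping": "unassigned_multi_mapping",
}


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() in ("", "NA", "na", ".")
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path: Union[str, Path]) -> CohortManifest:
    """Read a cohort manifest TSV into a validated :class:`CohortManifest`.

    Referenced paths are resolved relative to the manifest's directory.
    Missing artifacts are flagged per species (``missing_inputs``) rather
    than failing the whole cohort; a duplicated ``species_id`` is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot read manifest: {exc}") from exc
    missing_cols = [c for c in ("species_id",) if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: manifest header lacks column(s) {missing_cols}")

    extra_cols = [c for c in df.columns if c not in MANIFEST_CORE_COLUMNS]
    base = path.parent
    entries: list[ManifestEntry] = []
    for i, row in df.iterrows():
        sid = row["species_id"]
        if _is_blank(sid):
            raise ParseError(f"{path}: row {i + 2}: empty species_id")
        entry = ManifestEntry(species_id=str(sid).strip())
        if "display_name" in df.columns and not _is_blank(row.get("display_name")):
            entry.display_name = str(row["display_name"]).strip()

        def _resolve(cell, kind: str) -> Optional[Path]:
            if _is_blank(cell):
                entry.missing_inputs.append(kind)
                return None
            p = base / str(cell).strip()
            if not p.exists():
                entry.missing_inputs.append(kind)
                logger.warning("%s: %s file %s not found", entry.species_id, kind, p)
                return None
            return p

        entry.assembly_stats_path = _resolve(row.get("assembly_stats"), "assembly")
        entry.gtf_path = _resolve(row.get("gtf"), "gtf")
        for col, attr, kind in (
            ("mapping_summaries", "mapping_summary_paths", "mapping"),
            ("quant_summaries", "quant_summary_paths", "quant"),
        ):
            cell = row.get(col)
            if _is_blank(cell):
                entry.missing_inputs.append(kind)
                continue
            paths = []
            for piece in str(cell).split(";"):
                piece = piece.strip()
                if not piece:
                    continue
                p = base / piece
                if not p.exists():
                    logger.warning("%s: %s file %s not found", entry.species_id, kind, p)
                    continue
                paths.append(p)
            if not paths:
                entry.missing_inputs.append(kind)
            setattr(entry, attr, paths)

        for col in extra_cols:
            cell = row.get(col)
            if _is_blank(cell):
                continue  # absent, not zero
            try:
                entry.optional_columns[col] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {i + 2}: optional column {col!r} "
                    f"has non-numeric value {cell!r}"
                ) from exc
        entries.append(entry)
    return CohortManifest(entries=entries, path=path)


def write_manifest(manifest: CohortManifest, path: Union[str, Path]) -> Path:
    """Write a manifest back to TSV (paths relative to the output directory)."""
    path = Path(path)
    base = path.parent
    rows = []
    opt_cols: list[str] = []
    for e in manifest:
        for k in e.optional_columns:
            if k not in opt_cols:
                opt_cols.append(k)

    def _rel(p: Optional[Path]) -> str:
        if p is None:
            return ""
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    for e in manifest:
        row = {
            "species_id": e.species_id,
            "display_name": e.display_name,
            "assembly_stats": _rel(e.assembly_stats_path),
            "gtf": _rel(e.gtf_path),
            "mapping_summaries": ";".join(_rel(p) for p in e.mapping_summary_paths),
            "quant_summaries": ";".join(_rel(p) for p in e.quant_summary_paths),
        }
        for k in opt_cols:
            row[k] = e.optional_columns.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

def parse_assembly_stats(
    source: Union[str, Path],
    species_id: Optional[str] = None,
) -> Union[AssemblyStats, None, list[AssemblyStats]]:
    """Parse assembly statistics from TSV (authoritative) or ENA-style XML.

    A single-row TSV (or XML) needs ``species_id`` supplied by the caller
    (normally from the manifest).  A multi-row TSV with its own
    ``species_id`` column returns a list.  A row whose ``spanned_gaps`` (or
    any required field) is ``NA`` yields ``None`` — the species is
    assembly-stats-missing, not silently zero-filled.
    """
    source = Path(source)
    text = source.read_text()
    if text.lstrip().startswith("<"):
        return _parse_assembly_xml(text, species_id, source)

    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"{source}: cannot read assembly stats: {exc}") from exc
    missing = [c for c in ASSEMBLY_FIELDS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: assembly stats lack field(s) {missing}")

    def _row_to_stats(row, sid: str) -> Optional[AssemblyStats]:
        values = {}
        for f in ASSEMBLY_FIELDS:
            cell = row[f]
            if _is_blank(cell):
                logger.warning("%s: assembly field %s is NA; species marked missing", sid, f)
                return None
            try:
                values[f] = int(float(str(cell).replace(",", "")))
            except ValueError as exc:
                raise ParseError(f"{source}: non-numeric {f}={cell!r}") from exc
        return AssemblyStats(species_id=sid, **values)

    if "species_id" in df.columns and len(df) > 1:
        out = []
        for _, row in df.iterrows():
            stats = _row_to_stats(row, str(row["species_id"]))
            if stats is not None:
                out.append(stats)
        return out
    if len(df) != 1:
        raise ParseError(f"{source}: expected exactly one data row, got {len(df)}")
    row = df.iloc[0]
    sid = species_id or (str(row["species_id"]) if "species_id" in df.columns else None)
    if sid is None:
        raise ParseError(f"{source}: no species_id column and none supplied")
    return _row_to_stats(row, sid)


def _parse_assembly_xml(text: str, species_id: Optional[str], source: Path):
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"{source}: malformed XML: {exc}") from exc
    values: dict[str, int] = {}
    for attr in root.iter("ASSEMBLY_ATTRIBUTE"):
        tag = attr.findtext("TAG", "").strip().lower()
        if tag in _ENA_TAGS:
            raw = attr.findtext("VALUE", "").strip()
            try:
                values[_ENA_TAGS[tag]] = int(float(raw.replace(",", "")))
            except ValueError as exc:
                raise ParseError(f"{source}: non-numeric value {raw!r} for {tag}") from exc
    missing = [f for f in ASSEMBLY_FIELDS if f not in values]
    if missing:
        raise ParseError(f"{source}: XML lacks attribute(s) for {missing}")
    if species_id is None:
        alias = root.find(".//ASSEMBLY")
        species_id = alias.get("alias") if alias is not None else None
    if species_id is None:
        raise ParseError(f"{source}: no species identifier available")
    return AssemblyStats(species_id=species_id, **values)


def write_assembly_stats(stats: AssemblyStats, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(["species_id"] + ASSEMBLY_FIELDS) + "\n")
        fh.write(
            "\t".join(
                [stats.species_id]
                + [str(getattr(stats, f)) for f in ASSEMBLY_FIELDS]
            )
            + "\n"
        )
    return path


# ---------------------------------------------------------------------------
# Alignment summaries
# ---------------------------------------------------------------------------

_HISAT_TOTAL = re.compile(r"^\s*(\d+)\s+reads; of these:")
_HISAT_PAIRED = re.compile(r"^\s*(\d+)\s+\([\d.]+%\)\s+were paired")
_HISAT_ZERO = re.compile(r"^\s*(\d+)\s+\([\d.]+%\)\s+aligned concordantly 0 times")
_HISAT_ONE = re.compile(r"^\s*(\d+)\s+\([\d.]+%\)\s+aligned concordantly exactly 1 time")
_HISAT_MULTI = re.compile(r"^\s*(\d+)\s+\([\d.]+%\)\s+aligned concordantly >1 times")
_SN_LINE = re.compile(r"^SN\t([^:]+):\t(\d+)")


def parse_alignment_summary(
    text_or_path: Union[str, Path],
    sample_id: str,
    species_id: str,
    dialect: str = "auto",
) -> MappingSummary:
    """Parse an aligner summary into a :class:`MappingSummary`.

    ``dialect`` is ``"hisat2"`` (paired-end summary text, fragment units),
    ``"samtools_stats"`` (``SN`` key/value lines, read units, no
    multi-mapped count) or ``"auto"`` to sniff.  Counts violating the
    partition invariant raise :class:`ValidationError` with the residual;
    a truncated file raises :class:`ParseError`, never silent zeros.
    """
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str) and "\n" not in text_or_path and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)

    if dialect == "auto":
        if re.search(r"^SN\t", text, flags=re.M):
            dialect = "samtools_stats"
        elif "reads; of these:" in text:
            dialect = "hisat2"
        else:
            raise ParseError(
                f"{sample_id}: unrecognized alignment-summary dialect; "
                f"supported: {', '.join(ALIGNMENT_DIALECTS)}"
            )
    if dialect == "hisat2":
        return _parse_hisat2(text, sample_id, species_id)
    if dialect == "samtools_stats":
        return _parse_samtools_stats(text, sample_id, species_id)
    raise ParseError(
        f"unknown dialect {dialect!r}; supported: {', '.join(ALIGNMENT_DIALECTS)}"
    )


def _parse_hisat2(text: str, sample_id: str, species_id: str) -> MappingSummary:
    found: dict[str, int] = {}
    for line in text.splitlines():
        for key, rx in (
            ("total", _HISAT_TOTAL),
            ("paired", _HISAT_PAIRED),
            ("zero", _HISAT_ZERO),
            ("one", _HISAT_ONE),
            ("multi", _HISAT_MULTI),
        ):
            m = rx.match(line)
            if m and key not in found:
                found[key] = int(m.group(1))
    required = ("total", "zero", "one", "multi")
    missing = [k for k in required if k not in found]
    if missing:
        raise ParseError(
            f"{sample_id}: truncated or non-conforming paired-end summary "
            f"(missing {missing})"
        )
    total = found.get("paired", found["total"])
    return MappingSummary(
        sample_id=sample_id,
        species_id=species_id,
        total_units=total,
        unique_units=found["one"],
        multi_units=found["multi"],
        unmapped_units=found["zero"],
        unit="fragment",
    )


def _parse_samtools_stats(text: str, sample_id: str, species_id: str) -> MappingSummary:
    sn: dict[str, int] = {}
    for line in text.splitlines():
        m = _SN_LINE.match(line)
        if m:
            sn[m.group(1).strip()] = int(m.group(2))
    try:
        total = sn["raw total sequences"]
        unmapped = sn["reads unmapped"]
    except KeyError as exc:
        raise ParseError(
            f"{sample_id}: samtools-stats summary lacks SN field {exc}"
        ) from exc
    # This dialect reports no multi-mapped count; the component stays
    # missing rather than being inferred from MAPQ.
    return MappingSummary(
        sample_id=sample_id,
        species_id=species_id,
        total_units=total,
        unmapped_units=unmapped,
        unique_units=None,
        multi_units=None,
        unit="read",
    )


def write_hisat2_summary(summary: MappingSummary, path: Union[str, Path]) -> Path:
    """Emit a paired-end summary in the dialect :func:`parse_alignment_summary` reads."""
    if not summary.is_complete:
        raise ValidationError(f"{summary.sample_id}: cannot emit incomplete summary")
    t = summary.total_units

    def pct(x: int) -> str:
        return f"{100.0 * x / t:.2f}"

    aligned = t - summary.unmapped_units
    lines = [
        f"{t} reads; of these:",
        f"  {t} (100.00%) were paired; of these:",
        f"    {summary.unmapped_units} ({pct(summary.unmapped_units)}%) aligned concordantly 0 times",
        f"    {summary.unique_units} ({pct(summary.unique_units)}%) aligned concordantly exactly 1 time",
        f"    {summary.multi_units} ({pct(summary.multi_units)}%) aligned concordantly >1 times",
        f"{100.0 * aligned / t:.2f}% overall alignment rate",
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Quantification summaries
# ---------------------------------------------------------------------------

def normalize_quant_category(name: str) -> str:
    """Canonical lower-case key for a quantification status category."""
    key = name.strip().lower()
    return _QUANT_ALIASES.get(key, key)


def parse_quant_summary(
    path: Union[str, Path], sample_id: str, species_id: str
) -> QuantSummary:
    """Parse a featureCounts-style two-column ``.summary`` status table.

    Category names are normalised to canonical lower-case keys; unknown
    categories are preserved under their normalised name (they still count
    in the mapped-read denominator).
    """
    path = Path(path)
    counts: dict[str, int] = {}
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty quantification summary")
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {ln}: expected two tab-separated columns")
        name = parts[0].strip()
        if ln == 1 and name.lower() == "status":
            continue  # header
        try:
            value = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: non-integer count {parts[1]!r}") from exc
        counts[normalize_quant_category(name)] = counts.get(
            normalize_quant_category(name), 0
        ) + value
    if not counts:
        raise ParseError(f"{path}: no status rows found")
    return QuantSummary(sample_id=sample_id, species_id=species_id, category_counts=counts)


def write_quant_summary(summary: QuantSummary, path: Union[str, Path]) -> Path:
    """Emit a featureCounts-style ``.summary`` table (title-cased status names)."""
    display = {
        "assigned": "Assigned",
        "unassigned_ambiguity": "Unassigned_Ambiguity",
        "unassigned_no_features": "Unassigned_NoFeatures",
        "unassigned_unmapped": "Unassigned_Unmapped",
    }
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"Status\t{summary.sample_id}\n")
        for k, v in summary.category_counts.items():
            fh.write(f"{display.get(k, k.title())}\t{v}\n")
    return path


# ---------------------------------------------------------------------------
# GTF profiling
# ---------------------------------------------------------------------------

def _merged_length(df: pd.DataFrame) -> int:
    """Total genome length covered by intervals, strand-ignored.

    ``df`` uses pyranges convention (0-based half-open Start/End)."""
    if df.empty:
        return 0
    gr = pr.PyRanges(df[["Chromosome", "Start", "End"]].copy())
    merged = gr.merge(strand=False).df
    return int((merged.End - merged.Start).sum())


def profile_gtf(
    gtf_path: Union[str, Path], genome_size: int, species_id: str
) -> BiotypeProfile:
    """Profile a GTF into per-biotype gene counts and genic-structure statistics.

    Genes are the distinct ``gene_id`` values: explicit ``gene`` feature
    lines are used when present, otherwise each gene's span is the hull of
    its transcript/exon lines, so both encodings of the same annotation
    yield identical profiles.  Biotype comes from ``gene_biotype`` (fallback
    ``gene_type``); a gene with no biotype attribute is counted under
    ``"unannotated_biotype"``, and conflicting biotypes across lines resolve
    first-seen-wins with a logged warning.  Fractions are merged-interval
    coverage (strand-ignored, per sequence) divided by ``genome_size``;
    GTF coordinates are 1-based inclusive, so a span's length is
    ``end - start + 1``.
    """
    if genome_size <= 0:
        raise ValidationError(f"{species_id}: genome_size must be positive")
    gtf_path = Path(gtf_path)
    try:
        df = pr.read_gtf(str(gtf_path)).df
    except Exception as exc:
        raise ParseError(f"{gtf_path}: cannot parse GTF: {exc}") from exc
    if df.empty:
        raise ParseError(f"{gtf_path}: no features")
    if "gene_id" not in df.columns:
        raise ParseError(f"{gtf_path}: no gene_id attribute in any feature line")

    biotype_col = None
    for cand in ("gene_biotype", "gene_type"):
        if cand in df.columns:
            biotype_col = cand
            break

    # Per-gene biotype: first non-null in file order; warn on conflicts.
    biotypes: dict[str, str] = {}
    if biotype_col is not None:
        sub = df[["gene_id", biotype_col]].dropna()
        for gid, bt in sub.itertuples(index=False):
            if gid in biotypes:
                if biotypes[gid] != bt:
                    logger.warning(
                        "%s: gene %s has conflicting biotypes (%s, %s); keeping first",
                        species_id, gid, biotypes[gid], bt,
                    )
            else:
                biotypes[gid] = bt

    gene_rows = df[df.Feature == "gene"]
    span_source = gene_rows if not gene_rows.empty else df
    spans = (
        span_source.groupby("gene_id", sort=False)
        .agg(Chromosome=("Chromosome", "first"), Start=("Start", "min"), End=("End", "max"))
        .reset_index()
    )

    biotype_counts: dict[str, int] = {}
    for gid in spans.gene_id:
        bt = biotypes.get(gid, "unannotated_biotype")
        biotype_counts[bt] = biotype_counts.get(bt, 0) + 1

    gene_lengths = (spans.End - spans.Start).to_numpy()
    genic_len = _merged_length(spans)
    exon_rows = df[df.Feature == "exon"]
    exonic_len = _merged_length(exon_rows) if not exon_rows.empty else 0
    genic_fraction = min(genic_len / genome_size, 1.0)
    exonic_fraction = min(exonic_len / genome_size, genic_fraction)

    return BiotypeProfile(
        species_id=species_id,
        biotype_counts=biotype_counts,
        n_genes=len(spans),
        mean_gene_length=float(np.mean(gene_lengths)) if len(spans) else 0.0,
        genic_fraction=genic_fraction,
        exonic_fraction=exonic_fraction,
    )


# ---------------------------------------------------------------------------
# Indicator tables
# ---------------------------------------------------------------------------

def write_indicator_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a species × indicator table to TSV.

    Floats are written at 6 decimal places (lossless re-read at 1e-6);
    missing values stay empty cells, never zeros.  Column order is
    preserved; ``species_id`` is the first column.
    """
    path = Path(path)
    out = table.reset_index() if table.index.name == "species_id" else table.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="")
    return path


def read_indicator_table(path: Union[str, Path]) -> pd.DataFrame:
    """Re-read a table written by :func:`write_indicator_table` (species-indexed)."""
    df = pd.read_csv(path, sep="\t")
    if "species_id" in df.columns:
        df = df.set_index("species_id")
    return df
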