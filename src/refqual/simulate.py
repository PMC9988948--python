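"""Synthetic cohorts with controllable latent quality and diversity.

Real inputs to the scorer are assembly statistics, aligner summaries,
counter summaries and GTFs for dozens of species — artifacts that demand
large downloads.  This module fabricates a complete, parseable input tree
from two latent gradients so every stage of the framework is exercisable
and its directional claims testable:

* ``q`` — scalar *quality* latent in [0, 1] per species.  Higher q means
  larger adjusted N50, fewer spanned gaps, a larger uniquely-mapped share,
  and a larger assigned share at quantification.
* ``d`` — *diversity* latent controlling annotation biotype richness and
  the Dirichlet concentration of biotype proportions.  By default d = q
  (one scalar latent drives everything, the configuration under which the
  integrated index should recover the latent ranking); it can be drawn
  independently.
* ``g`` — *genic-fraction* latent, a noisy companion of q.  A denser
  annotation raises quantification failure by ambiguity and lowers
  failure by absence, so the no-features share decreases and the
  ambiguity share increases in g.

Compositional draws use a Dirichlet-multinomial scheme: category shares
are drawn from a Dirichlet around latent-dependent means, then counts
from a multinomial, which guarantees the read-unit partition invariant by
construction.  Emitted file dialects exactly match the parsers in
:mod:`refqual.io`, so the generated fixtures double as format
documentation.  All randomness flows from a single seed; the same seed
reproduces a byte-identical file tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .diversity import ENSEMBL_BIOTYPES
from .errors import ValidationError
from .io import write_hisat2_summary, write_quant_summary
from .records import MappingSummary, QuantSummary

__all__ = [
    "SimulationParams",
    "SimulatedCohort",
    "simulate_cohort",
    "worked_micro_cohort",
    "MICRO_EXPECTED",
    "MICRO_RANKING",
]


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort.

    Defaults describe a mid-sized benchmarking cohort: 50 species, 10
    RNA-seq samples each, genomes log-uniform between 50 Mb and 3 Gb, a
    30-name biotype vocabulary, and moderate compositional noise
    (Dirichlet concentrations of a few hundred, i.e. per-sample shares
    wobble by a percent or two around the species mean).
    """

    n_species: int = 50
    n_samples_per_species: int = 10
    seed: int = 0
    genome_size_log10_range: tuple[float, float] = (7.7, 9.5)
    mapping_concentration: float = 400.0
    quant_concentration: float = 600.0
    biotype_vocab_size: int = 30
    diversity_latent: str = "coupled"  # "coupled" (d = q) or "independent"
    mean_total_units_log10: tuple[float, float] = (5.0, 5.5)

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_samples_per_species < 1:
            raise ValidationError("need at least one species and one sample")
        lo, hi = self.genome_size_log10_range
        if not lo < hi:
            raise ValidationError("genome_size_log10_range must be increasing")
        if self.mapping_concentration <= 0 or self.quant_concentration <= 0:
            raise ValidationError("Dirichlet concentrations must be positive")
        if not 2 <= self.biotype_vocab_size <= len(ENSEMBL_BIOTYPES):
            raise ValidationError(
                f"biotype_vocab_size must be in [2, {len(ENSEMBL_BIOTYPES)}]"
            )
        if self.diversity_latent not in ("coupled", "independent"):
            raise ValidationError("diversity_latent must be 'coupled' or 'independent'")


@dataclass
class SimulatedCohort:
    """Paths of the generated tree plus the true latents behind it."""

    manifest_path: Path
    latents: pd.DataFrame  # species_id, q, d, g, genome_size, ...
    params: SimulationParams


def _species_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"sp{str(i).zfill(width)}" for i in range(n)]


def simulate_cohort(
    params: SimulationParams, outdir: Union[str, Path]
) -> SimulatedCohort:
    """Generate a full on-disk input set under ``outdir``.

    Layout: ``manifest.tsv`` at the top; per species, an assembly-stats
    TSV, a GTF, and per-sample alignment/quantification summaries under
    ``<species_id>/``.  Returns the manifest path and the latent table.
    """
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = params.n_species
    ids = _species_ids(n)

    q = rng.uniform(0.0, 1.0, size=n)
    d = q.copy() if params.diversity_latent == "coupled" else rng.uniform(size=n)
    g = np.clip(0.6 * q + 0.4 * rng.uniform(size=n), 0.0, 1.0)

    lo, hi = params.genome_size_log10_range
    genome_size = np.round(10 ** rng.uniform(lo, hi, size=n)).astype(np.int64)

    rows = []
    manifest_rows = []
    vocab = ENSEMBL_BIOTYPES[: params.biotype_vocab_size]

    for i, sid in enumerate(ids):
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)

        # --- assembly statistics -------------------------------------------
        log_contig = -4.6 + 3.3 * q[i] + rng.normal(0.0, 0.25)
        contig_ratio = float(np.clip(10 ** log_contig, 1e-7, 0.8))
        scaf_ratio = float(
            np.clip(contig_ratio * 10 ** abs(rng.normal(0.9, 0.2)), contig_ratio, 1.0)
        )
        contig_n50 = max(1, int(round(contig_ratio * genome_size[i])))
        scaffold_n50 = max(contig_n50, int(round(scaf_ratio * genome_size[i])))
        scaffold_n50 = min(scaffold_n50, int(genome_size[i]))
        gaps = int(round(10 ** (5.2 - 4.7 * q[i] + rng.normal(0.0, 0.3))))
        stats_path = sdir / "assembly_stats.tsv"
        stats_path.write_text(
            "species_id\tgenome_size\tcontig_n50\tscaffold_n50\tspanned_gaps\n"
            f"{sid}\t{genome_size[i]}\t{contig_n50}\t{scaffold_n50}\t{gaps}\n"
        )

        # --- mapping summaries ---------------------------------------------
        u_share = 0.50 + 0.42 * q[i]
        m_share = 0.18 - 0.10 * q[i]
        shares = np.array([u_share, m_share, 1.0 - u_share - m_share])
        map_paths = []
        for j in range(params.n_samples_per_species):
            total = int(round(10 ** rng.uniform(*params.mean_total_units_log10)))
            p = rng.dirichlet(params.mapping_concentration * shares)
            counts = rng.multinomial(total, p)
            summary = MappingSummary(
                sample_id=f"{sid}_s{j:02d}",
                species_id=sid,
                total_units=total,
                unique_units=int(counts[0]),
                multi_units=int(counts[1]),
                unmapped_units=int(counts[2]),
                unit="fragment",
            )
            path = sdir / f"{summary.sample_id}.hisat2.txt"
            write_hisat2_summary(summary, path)
            map_paths.append(path)

        # --- quantification summaries --------------------------------------
        base = np.array(
            [
                0.30 + 0.45 * q[i],            # assigned
                0.02 + 0.33 * (1.0 - g[i]),    # no_features: sparser annotation, more misses
                0.05 + 0.30 * g[i],            # ambiguity: denser annotation, more overlap
                0.03,                          # other counter-internal categories
            ]
        )
        base = base / base.sum()
        quant_paths = []
        for j in range(params.n_samples_per_species):
            total = int(round(10 ** rng.uniform(*params.mean_total_units_log10)))
            p = rng.dirichlet(params.quant_concentration * base)
            counts = rng.multinomial(total, p)
            unmapped = int(round(total * 0.08))
            summary = QuantSummary(
                sample_id=f"{sid}_s{j:02d}",
                species_id=sid,
                category_counts={
                    "assigned": int(counts[0]),
                    "unassigned_no_features": int(counts[1]),
                    "unassigned_ambiguity": int(counts[2]),
                    "unassigned_secondary": int(counts[3]),
                    "unassigned_unmapped": unmapped,
                },
            )
            path = sdir / f"{summary.sample_id}.summary"
            write_quant_summary(summary, path)
            quant_paths.append(path)

        # --- annotation -----------------------------------------------------
        # Mature annotations carry many non-coding classes, so their
        # protein-coding share drops (human ≈ 0.33) while young annotations
        # are nearly all protein-coding; d moves the cohort along that axis,
        # with richness and Dirichlet concentration rising alongside it.
        richness = 2 + int(round(d[i] * (len(vocab) - 2)))
        pc_share = 0.95 - 0.55 * d[i]
        tail = 1.0 / (1.0 + np.arange(richness - 1))
        prevalence = np.concatenate(([pc_share], (1.0 - pc_share) * tail / tail.sum()))
        conc = 30.0 + 120.0 * d[i]
        props = rng.dirichlet(conc * prevalence)
        n_genes = 80 + int(round(140.0 * d[i]))
        counts = rng.multinomial(n_genes - richness, props) + 1  # every drawn biotype present
        genic_target = 0.03 + 0.6 * g[i]
        mean_len = max(200.0, genic_target * genome_size[i] / n_genes)
        gtf_path = sdir / f"{sid}.gtf"
        _write_toy_gtf(gtf_path, sid, vocab[:richness], counts, genome_size[i], mean_len, rng)

        manifest_rows.append(
            {
                "species_id": sid,
                "display_name": f"Synthetic species {sid}",
                "assembly_stats": f"{sid}/assembly_stats.tsv",
                "gtf": f"{sid}/{sid}.gtf",
                "mapping_summaries": ";".join(f"{sid}/{p.name}" for p in map_paths),
                "quant_summaries": ";".join(f"{sid}/{p.name}" for p in quant_paths),
                "busco_completeness": round(
                    float(np.clip(0.92 + 0.07 * q[i] + rng.normal(0, 0.01), 0, 1)), 4
                ),
            }
        )
        rows.append(
            {
                "species_id": sid,
                "q": q[i],
                "d": d[i],
                "g": g[i],
                "genome_size": int(genome_size[i]),
                "spanned_gaps": gaps,
                "contig_ratio": contig_ratio,
                "genic_target": genic_target,
            }
        )

    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    latents = pd.DataFrame(rows).set_index("species_id")
    latents.to_csv(outdir / "latents.tsv", sep="\t", float_format="%.8f")
    return SimulatedCohort(manifest_path=manifest_path, latents=latents, params=params)


def _write_toy_gtf(
    path: Path,
    species_id: str,
    biotypes: list[str],
    counts: np.ndarray,
    genome_size: int,
    mean_len: float,
    rng: np.random.Generator,
) -> None:
    lines = []
    gene_no = 0
    for bt, cnt in zip(biotypes, counts):
        for _ in range(int(cnt)):
            gene_no += 1
            gid = f"{species_id}_G{gene_no:05d}"
            length = max(60, int(round(mean_len * 10 ** rng.normal(0.0, 0.25))))
            length = min(length, genome_size - 1)
            start = int(rng.integers(1, max(2, genome_size - length)))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            attrs = f'gene_id "{gid}"; gene_biotype "{bt}";'
            lines.append(
                f"1\trefqual_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
            exon_end = start + max(30, int(0.6 * length)) - 1
            lines.append(
                f"1\trefqual_sim\texon\t{start}\t{exon_end}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{gid}.1"; gene_biotype "{bt}";'
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Worked micro-cohort (golden fixture)
# ---------------------------------------------------------------------------

#: Hand-computed expectations for the 3-species micro cohort below.  Every
#: number traces to explicit arithmetic on the fixture's counts:
#: adjusted-N50 ratios (0.01, 0.1, 0.5 contig / 0.1, 0.5, 0.9 scaffold)
#: rank-scale to (0, 0.5, 1); gap counts (1000, 100, 0) give UngapRate
#: (0, 0.9, 1); per-sample mapping/quant rates are simple count ratios and
#: species values their two-sample means; the three biotype-proportion
#: rows lie on a straight line in composition space, so PC1 carries all
#: the variance and min-max scaled diversity is exactly (0, 0.5, 1).
MICRO_EXPECTED: dict[str, dict[str, float]] = {
    "alpha": {
        "AdjN50Contig": 0.0, "AdjN50Scaffold": 0.0, "UngapRate": 0.0,
        "UnimapRate": 0.725, "MapRate": 0.8, "MultiMapRate": 0.925,
        "TranscriptDiversity": 0.0,
        "QuantRate": 0.525, "QuantRateAbs": 0.6, "QuantRateAmb": 0.925,
        "MQI": 2.45 / 3.0, "QQI": 2.05 / 3.0, "index": 0.45,
        "shannon_equitability": 0.0,
    },
    "beta": {
        "AdjN50Contig": 0.5, "AdjN50Scaffold": 0.5, "UngapRate": 0.9,
        "UnimapRate": 0.875, "MapRate": 0.95, "MultiMapRate": 0.925,
        "TranscriptDiversity": 0.5,
        "QuantRate": 0.725, "QuantRateAbs": 0.875, "QuantRateAmb": 0.85,
        "MQI": 2.75 / 3.0, "QQI": 2.45 / 3.0, "index": 0.76,
        "shannon_equitability": 0.659517637169433,
    },
    "gamma": {
        "AdjN50Contig": 1.0, "AdjN50Scaffold": 1.0, "UngapRate": 1.0,
        "UnimapRate": 0.94, "MapRate": 0.97, "MultiMapRate": 0.97,
        "TranscriptDiversity": 1.0,
        "QuantRate": 0.82, "QuantRateAbs": 0.91, "QuantRateAmb": 0.91,
        "MQI": 2.88 / 3.0, "QQI": 2.64 / 3.0, "index": 0.952,
        "shannon_equitability": 0.9232196723355077,
    },
}

#: Expected descending-index order of the micro cohort.
MICRO_RANKING = ["gamma", "beta", "alpha"]

_MICRO_ASSEMBLY = {
    # species: (genome_size, contig_n50, scaffold_n50, spanned_gaps)
    "alpha": (1_000_000, 10_000, 100_000, 1000),
    "beta": (2_000_000, 200_000, 1_000_000, 100),
    "gamma": (500_000, 250_000, 450_000, 0),
}

_MICRO_MAPPING = {
    # species: [(total, unique, multi, unmapped), ...]
    "alpha": [(100_000, 70_000, 10_000, 20_000), (100_000, 75_000, 5_000, 20_000)],
    "beta": [(200_000, 170_000, 20_000, 10_000), (200_000, 180_000, 10_000, 10_000)],
    "gamma": [(50_000, 48_000, 1_000, 1_000), (50_000, 46_000, 2_000, 2_000)],
}

_MICRO_QUANT = {
    # species: [{category: count}, ...]; the unmapped category in alpha's
    # first sample exercises its exclusion from the denominator.
    "alpha": [
        {"assigned": 50_000, "unassigned_ambiguity": 10_000,
         "unassigned_no_features": 40_000, "unassigned_unmapped": 20_000},
        {"assigned": 55_000, "unassigned_ambiguity": 5_000,
         "unassigned_no_features": 40_000},
    ],
    "beta": [
        {"assigned": 140_000, "unassigned_ambiguity": 30_000,
         "unassigned_no_features": 30_000},
        {"assigned": 150_000, "unassigned_ambiguity": 30_000,
         "unassigned_no_features": 20_000},
    ],
    "gamma": [
        {"assigned": 40_000, "unassigned_ambiguity": 5_000,
         "unassigned_no_features": 5_000},
        {"assigned": 42_000, "unassigned_ambiguity": 4_000,
         "unassigned_no_features": 4_000},
    ],
}

_MICRO_BIOTYPES = {
    # species: [(biotype, gene count)] — beta and gamma sit on the line
    # through alpha in composition space (see MICRO_EXPECTED note).
    "alpha": [("protein_coding", 20)],
    "beta": [("protein_coding", 14), ("lncRNA", 3), ("miRNA", 2), ("pseudogene", 1)],
    "gamma": [("protein_coding", 8), ("lncRNA", 6), ("miRNA", 4), ("pseudogene", 2)],
}

_MICRO_GENE_GEOMETRY = {
    # species: (spacing, gene length, exon length)
    "alpha": (10_000, 2_000, 1_000),
    "beta": (20_000, 3_000, 1_500),
    "gamma": (15_000, 2_500, 1_000),
}


def worked_micro_cohort(outdir: Union[str, Path]) -> SimulatedCohort:
    """Write the deterministic 3-species golden cohort under ``outdir``.

    ``alpha`` is a deliberately poor species (fragmented assembly, gappy,
    protein-coding-only annotation), ``gamma`` a polished one, ``beta``
    in between.  The expected pipeline output is :data:`MICRO_EXPECTED`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    latent_rows = []
    busco = {"alpha": 0.95, "beta": 0.97, "gamma": 0.99}
    for rank, sid in enumerate(sorted(_MICRO_ASSEMBLY)):
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        gsize, cn50, sn50, gaps = _MICRO_ASSEMBLY[sid]
        (sdir / "assembly_stats.tsv").write_text(
            "species_id\tgenome_size\tcontig_n50\tscaffold_n50\tspanned_gaps\n"
            f"{sid}\t{gsize}\t{cn50}\t{sn50}\t{gaps}\n"
        )
        map_paths = []
        for j, (total, uni, multi, unmap) in enumerate(_MICRO_MAPPING[sid]):
            s = MappingSummary(
                sample_id=f"{sid}_s{j}", species_id=sid, total_units=total,
                unique_units=uni, multi_units=multi, unmapped_units=unmap,
                unit="fragment",
            )
            map_paths.append(write_hisat2_summary(s, sdir / f"{s.sample_id}.hisat2.txt"))
        quant_paths = []
        for j, counts in enumerate(_MICRO_QUANT[sid]):
            s = QuantSummary(
                sample_id=f"{sid}_s{j}", species_id=sid, category_counts=dict(counts)
            )
            quant_paths.append(write_quant_summary(s, sdir / f"{s.sample_id}.summary"))
        gtf_path = sdir / f"{sid}.gtf"
        _write_micro_gtf(gtf_path, sid)
        manifest_rows.append(
            {
                "species_id": sid,
                "display_name": sid.title(),
                "assembly_stats": f"{sid}/assembly_stats.tsv",
                "gtf": f"{sid}/{sid}.gtf",
                "mapping_summaries": ";".join(f"{sid}/{p.name}" for p in map_paths),
                "quant_summaries": ";".join(f"{sid}/{p.name}" for p in quant_paths),
                "busco_completeness": busco[sid],
            }
        )
        latent_rows.append({"species_id": sid, "q": rank / 2.0, "d": rank / 2.0, "g": rank / 2.0})
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    latents = pd.DataFrame(latent_rows).set_index("species_id")
    params = SimulationParams(n_species=3, n_samples_per_species=2, seed=0)
    return SimulatedCohort(manifest_path=manifest_path, latents=latents, params=params)


def _write_micro_gtf(path: Path, species_id: str) -> None:
    spacing, glen, elen = _MICRO_GENE_GEOMETRY[species_id]
    lines = []
    gene_no = 0
    for bt, cnt in _MICRO_BIOTYPES[species_id]:
        for _ in range(cnt):
            start = 1 + gene_no * spacing
            end = start + glen - 1
            gid = f"{species_id}_G{gene_no:03d}"
            lines.append(
                f"1\trefqual_micro\tgene\t{start}\t{end}\t.\t+\t.\t"
                f'gene_id "{gid}"; gene_biotype "{bt}";'
            )
            lines.append(
                f"1\trefqual_micro\texon\t{start}\t{start + elen - 1}\t.\t+\t.\t"
                f'gene_id "{gid}"; transcript_id "{gid}.1"; gene_biotype "{bt}";'
            )
            gene_no += 1
    path.write_text("\n".join(lines) + "\n")
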