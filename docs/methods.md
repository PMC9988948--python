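# Methods

## Scope and model

`refqual` scores the *relative* quality of reference genomes and gene
annotations across a cohort of species. It consumes summary artifacts only —
assembly statistics, aligner summary text, read-counter status tables, and
GTFs — never reads, BAMs or sequences. Ten indicators per species, each in
[0, 1] with 1 = better, are combined as a weighted arithmetic mean (the "NGS
applicability index"). Three indicator groups are empirical (they require
RNA-seq mapping/quantification summaries); the assembly and annotation
groups come from the reference data alone.

### Assembly indicators (1–3)

N50 is not comparable across genomes of different sizes, so contig and
scaffold N50 are divided by genome size and the resulting ratios converted
to cohort percentiles. The percentile convention is `(rank − 1)/(n − 1)`
with ascending average ranks for ties: the cohort minimum maps exactly to 0
and the maximum to 1, matching the indicators' stated 0–1 range. An
empirical-CDF convention (`rank/n`) is available via
`CohortConfig.percentile_convention="ecdf"`. A single-species cohort has no
meaningful percentile; the function returns 1.0 with a logged warning rather
than crashing single-species runs.

`UngapRate = 1 − gaps_i / max_j(gaps_j)` compares each species' spanned-gap
count with the gappiest assembly in the cohort; that species scores exactly
0. An all-zero cohort is defined as all-1.0 — the limit of the formula along
cohorts of equal (perfect) quality. Adjusted N75/N90 are deliberately not
part of the ten-indicator index.

### Mapping indicators (4–6) and MQI

Each sample's aligner summary yields a partition
`unique + multi + unmapped = total` of read units. The three rates
(`unique/total`, `1 − unmapped/total`, `1 − multi/total`) satisfy
`UnimapRate = MapRate + MultiMapRate − 1` identically; this is asserted
property-style in the tests. The read unit (read vs fragment) is whatever
the summary reports — every indicator is a ratio within one summary, so
units never mix. Two dialects are parsed: HISAT2/bowtie2-style paired-end
summary text (fragment units) and samtools-stats `SN` text. The latter
carries no multi-mapped count; that component is recorded missing rather
than inferred from MAPQ, and a species whose every sample lacks it gets a
missing MultiMapRate and MQI.

Species-level rates are the unweighted mean of per-sample rates (cohorts
are normally built with equal sample counts per species); pooled-count
aggregation is available via `CohortConfig.aggregation="pooled"`. MQI is the
mean of the three species-level rates.

### Transcript diversity (7)

Rationale: annotations mature by growing non-coding classes (lncRNA, small
RNAs, pseudogenes), so the biotype *composition* of an annotation is a
proxy for its curation depth. The species × biotype proportion matrix is
built over the union of observed biotypes (zero-filled; rows sum to 1),
columns mean-centered without variance scaling — all columns are
commensurate proportions — and PC1 of the covariance extracted.
Correlation-mode PCA is available (`CohortConfig.pca_mode`). Scores are
min-max scaled to [0, 1]. PC1's sign is arbitrary; it is oriented so scores
correlate non-negatively with per-species biotype richness (ties broken
toward a non-negative loading on the first column), so "more biotype
classes" scores higher. Log-transforms of proportions before PCA were
considered and rejected: zeros are ubiquitous in biotype tables and any
pseudocount choice would dominate the embedding.

Shannon's equitability (`H/ln S`, S = observed positive biotypes, 0 by
convention for S = 1) is computed alongside as an independent evenness
summary; on simulated gradients it is strongly rank-correlated with the PC1
score, which is the intended sanity check on the embedding. `S` can be fixed
globally (`shannon_global_s`) to compare evenness against a fixed vocabulary
size instead of observed richness. Relative diversity (species / reference
ratio of the min-max-scaled scores) is reported when a reference species is
configured; the ratio convention is this package's choice.

Biotypes are read directly from the GTF (`gene_biotype`, fallback
`gene_type`) rather than from a database query — the GTF is the
self-contained artifact and needs no network. The vocabulary ships with the
30 standard Ensembl biotype names; novel biotypes are kept verbatim, never
collapsed. GTF coordinates are treated as 1-based inclusive
(span = end − start + 1); genic/exonic fractions use strand-ignored,
per-sequence interval merging (via pyranges). Genes are distinct `gene_id`
values; explicit `gene` lines are used when present, otherwise gene spans
are the hulls of transcript/exon lines, and both encodings of the same
annotation produce identical profiles. A gene with conflicting biotypes
across lines resolves first-seen-wins with a warning; a gene with no biotype
attribute counts under `unannotated_biotype`.

### Quantification indicators (8–10) and QQI

The counter's status table is reduced to a denominator
`T = Σ categories − unassigned_unmapped`: unmapped reads are a mapping
failure, not a quantification one, so adding unmapped counts changes no
quantification output (tested). `unassigned_no_features` maps to failure by
absence of annotation, `unassigned_ambiguity` to failure by overlapping
annotation; every other category counts only in `T`. Consequently
`QuantRate ≤ QuantRateAbs + QuantRateAmb − 1`, with equality exactly when no
other failure category carries counts. The counter's own configuration
(fragment vs read counting, multi-overlap handling) is deliberately not
interpreted — the parser is agnostic to it. Aggregation mirrors the mapping
module; QQI is the mean of the three species-level rates.

### The index

`index_i = Σ w_k x_{ik} / Σ w_k`, default `w = 1` (all indicators equal).
With equal weights the index decomposes as
`(3·MQI + 3·QQI + 4 remaining indicators)/10`, an identity asserted at
1e-12. Cohort-relative indicators are computed over the per-indicator
complete-case subset, so one species' missing GTF does not perturb others'
assembly percentiles. Under the default complete-case policy, species
missing any indicator are excluded from the ranking (reported, not
silently dropped); `missing_data_policy="renormalize"` instead averages
over available indicators with renormalized weights. Ranking ties break
lexicographically on species id. BUSCO completeness and other optional
manifest columns pass through as diagnostics and are never folded into the
index — across published reference assemblies BUSCO varies too little to
discriminate.

## The synthetic cohort generator

The generator emulates the *inputs* of a benchmarking cohort, not the
biology: no reads or sequences, only directionally realistic summary files.
One scalar quality latent `q ∈ [0, 1]` per species drives adjusted-N50
(log-linear, ~3 decades across the gradient with 0.25 dex of noise),
spanned-gap counts (log-linear decreasing, ~10⁵ down to a handful), the
uniquely-mapped share (0.50 → 0.92) and the assigned share (≈0.30 → 0.75).
A genic-density latent `g` (a noisy companion of q) raises the ambiguity
share and lowers the no-features share, reproducing the opposing failure
modes of dense vs sparse annotations. The diversity latent `d` defaults to
`q` (one scalar latent drives everything — the configuration under which
the integrated index should recover the latent ranking) and moves the
protein-coding share from ≈0.95 down to 0.40 while biotype richness grows
from 2 to the vocabulary size, mirroring how curated annotations
accumulate non-coding classes.

Per-sample compositions are Dirichlet-multinomial: shares drawn from a
Dirichlet around the species mean (concentrations of a few hundred, i.e.
percent-level sample wobble), counts multinomial — which makes the read-unit
partition invariant hold by construction. Defaults are 50 species × 10
samples with ~10⁵–3×10⁵ read units per sample and 80–220 genes per toy GTF:
large enough for stable rank statistics, small enough that the full
pipeline on a simulated cohort runs in seconds. All randomness flows from
one seed; a repeated seed yields a byte-identical file tree.

What passing synthetic tests shows — and does not. They verify the formulas,
the scaling conventions, the plumbing, and that the index recovers a known
quality ordering under the generator's directional assumptions. They cannot
certify behaviour on real cohorts, where indicator noise is not Dirichlet,
samples differ in depth and tissue, and the latent "quality" is not scalar.

The 3-species worked cohort is fully deterministic with hand-computed
expectations (`MICRO_EXPECTED`): its three biotype rows are placed exactly
on one line in composition space so PC1 provably carries all variance and
the scaled diversities are exactly (0, 0.5, 1).

## Numerical choices and degenerate inputs

- PCA via dense symmetric eigendecomposition of the covariance;
  variance-explained uses the positively clipped spectrum. Zero total
  variance (identical species) raises a degenerate-cohort error, as does a
  constant PC1 vector at min-max scaling — no fabricated 0.5s.
- Correlations use pairwise-complete observations; pairs with n < 3 or a
  constant column report missing, never 0.
- Parsers are total: validated record or typed error (`ParseError`,
  `ValidationError`, `DomainError`), never silent defaults; the mapping
  partition residual is included in the error message.
- Indicator tables are written at 6 decimal places and round-trip at 1e-6;
  missing values stay empty cells, never zeros.

## Known limitations

- MQI mixes whatever summary dialects the cohort provides; rates from read-
  vs fragment-unit summaries are averaged together if a cohort mixes them.
- The samtools-stats dialect cannot contribute MultiMapRate.
- Cohort-relative indicators make every score contingent on cohort
  membership by design; indices from different cohorts are not comparable.
- The equal-weight combination is a transparent default, not an optimally
  calibrated one.
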