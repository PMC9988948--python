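# refqual

Relative quality scoring of reference genomes and gene annotations across
species.

## The problem

Every short-read sequencing application — variant calling, RNA-seq, single
cell — leans on two pieces of reference data: the genome assembly and its
gene annotation. Their quality varies enormously between species, and there
is no single tool-reported number that says "this species' reference data is
ready for RNA-seq work". Assembly assessors (N50, gap counts, BUSCO) ignore
the annotation; annotation assessments usually require a well-annotated
sister species. `refqual` scores both at once, for an arbitrary cohort of
species, using only cheap summary artifacts: assembly statistic tables,
aligner summary reports, read-counter summary tables and the GTF itself.

## The model

Ten indicators per species *i*, each scaled to [0, 1] with 1 = better:

| # | Indicator | Definition |
|---|-----------|------------|
| 1 | AdjN50Contig | cohort percentile of contig N50 / genome size |
| 2 | AdjN50Scaffold | cohort percentile of scaffold N50 / genome size |
| 3 | UngapRate | 1 − spanned_gaps / max<sub>cohort</sub>(spanned_gaps) |
| 4 | UnimapRate | uniquely mapped read units / total |
| 5 | MapRate | 1 − unmapped / total |
| 6 | MultiMapRate | 1 − multi-mapped / total |
| 7 | TranscriptDiversity | min-max-scaled PC1 of the species × biotype proportion matrix |
| 8 | QuantRate | assigned reads / mapped reads |
| 9 | QuantRateAbs | 1 − (unassigned, no feature) / mapped |
| 10 | QuantRateAmb | 1 − (unassigned, ambiguous) / mapped |

Two stage summaries and the integrated index:

    MQI_i = (UnimapRate_i + MapRate_i + MultiMapRate_i) / 3
    QQI_i = (QuantRate_i + QuantRateAbs_i + QuantRateAmb_i) / 3

    index_i = Σ_k w_k · indicator_{i,k} / Σ_k w_k        (w_k = 1 by default)

Indicators 1, 2, 3 and 7 are **cohort-relative**: they compare each species
against the others in the run, so the index is a relative readiness score,
not an absolute one.

## Worked example

The shipped 3-species worked cohort (`refqual.worked_micro_cohort`) is small
enough that every number can be re-derived by hand from its counts.
`python examples/02_worked_micro_cohort.py` prints:

```
            AdjN50Contig  AdjN50Scaffold  UngapRate  UnimapRate  MapRate  MultiMapRate  TranscriptDiversity  QuantRate  QuantRateAbs  QuantRateAmb       MQI       QQI  index  rank
species_id
alpha                0.0             0.0        0.0       0.725     0.80         0.925                  0.0      0.525         0.600         0.925  0.816667  0.683333  0.450   3.0
beta                 0.5             0.5        0.9       0.875     0.95         0.925                  0.5      0.725         0.875         0.850  0.916667  0.816667  0.760   2.0
gamma                1.0             1.0        1.0       0.940     0.97         0.970                  1.0      0.820         0.910         0.910  0.960000  0.880000  0.952   1.0
```

`alpha` has the most fragmented, gappiest assembly in the cohort (all three
cohort-relative assembly indicators are 0), the weakest mapping and
quantification rates, and a protein-coding-only annotation (diversity 0), so
its index is lowest at 0.450. `gamma` leads every column and scores 0.952.
The equal-weight index is exactly `(3·MQI + 3·QQI + AdjN50Contig +
AdjN50Scaffold + UngapRate + TranscriptDiversity) / 10`.

Other entry points:

```python
from refqual import SimulationParams, simulate_cohort, score_cohort

cohort = simulate_cohort(SimulationParams(n_species=50, seed=7), "cohort/")
result = score_cohort(cohort.manifest_path)
print(result.ranked[["index", "MQI", "QQI", "rank"]])
```

or from the shell:

```
refqual simulate --n-species 50 --n-samples 10 --seed 7 --out cohort/
refqual index --manifest cohort/manifest.tsv --out results/
```

`examples/` holds one short narrative script per capability (cohort
scoring, the worked micro cohort, transcript diversity, build comparison).

## Inputs

A tab-separated manifest lists, per species: an assembly-stats TSV (genome
size, contig/scaffold N50, spanned gaps; an ENA-style assembly XML is also
accepted), a GTF, any number of HISAT2/bowtie2-style paired-end alignment
summaries (or samtools-stats `SN` text), any number of featureCounts-style
`.summary` tables, and optional numeric columns (e.g. BUSCO completeness,
carried through as a diagnostic but never folded into the index). Species
with missing artifacts lose the affected indicators and drop out of the
ranking under the default complete-case policy.

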