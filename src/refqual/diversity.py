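"""Transcript diversity of gene annotations.

The richer and more even an annotation's mix of gene biotypes
(protein_coding, lncRNA, miRNA, pseudogene, ...), the more mature the
annotation tends to be: heavily curated annotations such as human and
mouse carry many non-coding and pseudogene classes that young annotations
lack.  This module turns the species × biotype proportion matrix into a
single 0–1 "transcript diversity" score per species:

1. build the proportion matrix over the union of observed biotypes
   (rows sum to 1, absent biotypes zero-filled);
2. mean-center the columns and take PC1 of the covariance — a data-driven
   linear combination of biotype proportions that captures the dominant
   axis of compositional variation across the cohort;
3. min-max scale the PC1 scores to [0, 1].

PC1's sign is mathematically arbitrary; it is oriented so that scores
correlate non-negatively with per-species biotype richness, making "more
biotype classes annotated" score higher.  Shannon's equitability
(entropy / ln S) is provided as an independent summary of the same
compositional evenness for cross-checking PC1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, DomainError, ValidationError
from .records import BiotypeProfile

PCA_MODES = ("covariance", "correlation")

#: Ensembl gene-biotype vocabulary used to seed simulations and column
#: ordering; observed biotypes outside this list are kept verbatim.
ENSEMBL_BIOTYPES = [
    "protein_coding", "lncRNA", "miRNA", "snRNA", "snoRNA", "scaRNA",
    "rRNA", "tRNA", "misc_RNA", "Mt_rRNA", "Mt_tRNA", "ribozyme", "sRNA",
    "vault_RNA", "pseudogene", "processed_pseudogene",
    "unprocessed_pseudogene", "transcribed_processed_pseudogene",
    "transcribed_unprocessed_pseudogene", "translated_processed_pseudogene",
    "unitary_pseudogene", "polymorphic_pseudogene", "IG_C_gene", "IG_D_gene",
    "IG_J_gene", "IG_V_gene", "TR_C_gene", "TR_J_gene", "TR_V_gene", "TEC",
]


@dataclass
class BiotypeMatrix:
    """Species × biotype proportion matrix; rows sum to 1."""

    proportions: pd.DataFrame  # index species_id, columns biotypes

    def __post_init__(self) -> None:
        p = self.proportions
        if ((p < -1e-12) | (p > 1 + 1e-12)).any().any():
            raise ValidationError("proportions must lie in [0, 1]")
        sums = p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
            raise ValidationError(f"rows do not sum to 1: {bad}")

    @property
    def species(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def biotypes(self) -> list[str]:
        return list(self.proportions.columns)

    def richness(self) -> pd.Series:
        """Number of biotypes with positive proportion, per species."""
        return (self.proportions > 0).sum(axis=1)


@dataclass
class DiversityResult:
    pc1_scores: pd.Series
    variance_explained_pc1: float
    transcript_diversity: pd.Series
    shannon_equitability: pd.Series
    loadings: pd.Series
    relative_to_reference: Optional[pd.Series] = None


def biotype_proportion_matrix(profiles: Iterable[BiotypeProfile]) -> BiotypeMatrix:
    """Build the cohort proportion matrix from per-species biotype counts.

    Columns are the union of observed biotypes, ordered by the Ensembl
    vocabulary first and then lexicographically for novel names; absent
    biotypes fill with 0.  Species with zero genes are excluded (flagged
    by the caller via the completeness mask).
    """
    profiles = [p for p in profiles]
    usable = [p for p in profiles if p.n_genes > 0]
    if not usable:
        raise DomainError("no species with a non-empty annotation")
    observed: set[str] = set()
    for p in usable:
        observed.update(p.biotype_counts)
    known = [b for b in ENSEMBL_BIOTYPES if b in observed]
    novel = sorted(observed - set(ENSEMBL_BIOTYPES))
    columns = known + novel
    rows = []
    for p in usable:
        props = p.proportions()
        rows.append([props.get(b, 0.0) for b in columns])
    df = pd.DataFrame(
        rows, index=pd.Index([p.species_id for p in usable], name="species_id"),
        columns=columns,
    )
    return BiotypeMatrix(proportions=df)


def pca_pc1(
    matrix: BiotypeMatrix, mode: str = "covariance"
) -> tuple[pd.Series, float, pd.Series]:
    """PC1 scores, variance-explained fraction and loadings of the cohort.

    Columns are mean-centered (``mode="correlation"`` additionally divides
    by the column standard deviation; constant columns are left at zero).
    Scores are the projection onto the leading eigenvector of the sample
    covariance of the centered matrix.  Sign is fixed by non-negative
    correlation with biotype richness, ties broken toward a non-negative
    loading on the first column.
    """
    if mode not in PCA_MODES:
        raise DomainError(f"unknown PCA mode {mode!r}; choose from {PCA_MODES}")
    X = matrix.proportions.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise DomainError("PCA needs at least 2 species and 2 biotypes")
    Xc = X - X.mean(axis=0)
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        nz = sd > 0
        Xc[:, nz] = Xc[:, nz] / sd[nz]
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = eigvals[::-1]
    eigvecs = eigvecs[:, ::-1]
    total = float(np.clip(eigvals, 0.0, None).sum())
    if total <= 0.0:
        raise DegenerateCohortError("zero total variance: all species identical")
    v1 = eigvecs[:, 0]
    scores = Xc @ v1

    richness = matrix.richness().to_numpy(dtype=float)
    sign = 0.0
    if np.std(richness) > 0 and np.std(scores) > 0:
        sign = float(np.corrcoef(scores, richness)[0, 1])
    if sign == 0.0 or not np.isfinite(sign):
        sign = 1.0 if v1[0] >= 0 else -1.0
    if sign < 0:
        v1 = -v1
        scores = -scores

    var_explained = float(max(eigvals[0], 0.0) / total)
    idx = matrix.proportions.index
    return (
        pd.Series(scores, index=idx, name="pc1"),
        var_explained,
        pd.Series(v1, index=matrix.proportions.columns, name="loading"),
    )


def transcript_diversity(pc1_scores: Sequence[float]) -> np.ndarray:
    """Min-max scale PC1 scores to [0, 1]: ``(X − min X) / (max X − min X)``."""
    x = np.asarray(pc1_scores, dtype=float)
    if x.size < 2:
        raise DomainError("need at least 2 species to scale diversity")
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite PC1 scores")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateCohortError(
            "all PC1 scores identical; transcript diversity undefined"
        )
    return (x - lo) / (hi - lo)


def shannon_equitability(
    proportions: Sequence[float], global_s: Optional[int] = None
) -> float:
    """Shannon entropy of a proportion vector divided by ln(S).

    ``S`` defaults to the number of positive-proportion categories
    (``global_s`` fixes it, e.g. to a vocabulary size).  A single-category
    profile has zero evenness by convention.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise DomainError("negative proportion")
    total = p.sum()
    if total <= 0:
        raise DomainError("proportions must have a positive sum")
    p = p / total
    pos = p[p > 0]
    s = int(global_s) if global_s is not None else pos.size
    if s <= 1:
        return 0.0
    h = float(-(pos * np.log(pos)).sum())
    return h / np.log(s)


def biotype_diversity_correlation(
    matrix: BiotypeMatrix, diversity: Sequence[float]
) -> pd.Series:
    """Pearson correlation of each biotype's proportion column with diversity.

    Constant columns yield NaN (undefined, reported missing rather than 0).
    """
    d = np.asarray(diversity, dtype=float)
    X = matrix.proportions
    if len(X) != d.size:
        raise DomainError("diversity vector length mismatch")
    if len(X) < 3:
        raise DomainError("need at least 3 species for correlations")
    out = {}
    dc = d - d.mean()
    sd_d = np.sqrt((dc ** 2).sum())
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        xc = x - x.mean()
        sd_x = np.sqrt((xc ** 2).sum())
        if sd_x == 0 or sd_d == 0:
            out[col] = float("nan")
        else:
            out[col] = float((xc * dc).sum() / (sd_x * sd_d))
    return pd.Series(out, name="correlation_with_diversity")


def relative_diversity(
    diversity: pd.Series, reference_species: str
) -> pd.Series:
    """Each species' min-max-scaled diversity as a fraction of a reference's.

    Expressed on the reference's scale (reference = 1.0); undefined when
    the reference scores 0.
    """
    if reference_species not in diversity.index:
        raise DomainError(f"reference species {reference_species!r} not in cohort")
    ref = diversity.loc[reference_species]
    if ref == 0:
        raise DegenerateCohortError(
            f"reference {reference_species!r} has zero diversity"
        )
    return diversity / ref


def diversity_result(
    profiles: Iterable[BiotypeProfile],
    mode: str = "covariance",
    reference_species: Optional[str] = None,
    shannon_global_s: Optional[int] = None,
) -> tuple[BiotypeMatrix, DiversityResult]:
    """One-call pipeline: proportion matrix → PC1 → scaled diversity + evenness."""
    matrix = biotype_proportion_matrix(profiles)
    scores, var1, loadings = pca_pc1(matrix, mode=mode)
    scaled = pd.Series(
        transcript_diversity(scores.to_numpy()), index=scores.index,
        name="TranscriptDiversity",
    )
    evenness = pd.Series(
        {
            sid: shannon_equitability(
                matrix.proportions.loc[sid].to_numpy(), global_s=shannon_global_s
            )
            for sid in matrix.species
        },
        name="shannon_equitability",
    )
    rel = None
    if reference_species is not None:
        rel = relative_diversity(scaled, reference_species)
    return matrix, DiversityResult(
        pc1_scores=scores,
        variance_explained_pc1=var1,
        transcript_diversity=scaled,
        shannon_equitability=evenness,
        loadings=loadings,
        relative_to_reference=rel,
    )
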