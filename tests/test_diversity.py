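"""Biotype proportion matrix, PC1 transcript diversity, Shannon evenness."""

import math

import numpy as np
import pandas as pd
import pytest

from refqual.diversity import (
    BiotypeMatrix,
    biotype_diversity_correlation,
    biotype_proportion_matrix,
    pca_pc1,
    relative_diversity,
    shannon_equitability,
    transcript_diversity,
)
from refqual.errors import DegenerateCohortError, DomainError
from refqual.records import BiotypeProfile


def _profile(sid, counts):
    n = sum(counts.values())
    return BiotypeProfile(species_id=sid, biotype_counts=counts, n_genes=n,
                          mean_gene_length=1000.0, genic_fraction=0.1,
                          exonic_fraction=0.05)


def _random_matrix(rng, n, p):
    rows = rng.dirichlet(np.ones(p), size=n)
    cols = [f"bt{j}" for j in range(p)]
    return BiotypeMatrix(pd.DataFrame(rows, columns=cols,
                                      index=[f"s{i}" for i in range(n)]))


class TestProportionMatrix:
    def test_union_with_zero_fill(self):
        a = _profile("A", {"protein_coding": 2, "lncRNA": 1})
        b = _profile("B", {"protein_coding": 1})
        m = biotype_proportion_matrix([a, b])
        assert m.biotypes == ["protein_coding", "lncRNA"]
        np.testing.assert_allclose(m.proportions.to_numpy(),
                                   [[2 / 3, 1 / 3], [1.0, 0.0]])

    def test_identical_profiles_identical_rows(self):
        a = _profile("A", {"protein_coding": 4, "miRNA": 1})
        b = _profile("B", {"protein_coding": 4, "miRNA": 1})
        m = biotype_proportion_matrix([a, b])
        np.testing.assert_allclose(m.proportions.loc["A"], m.proportions.loc["B"])

    def test_random_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        profiles = []
        for i in range(20):
            counts = {f"bt{j}": int(c) for j, c in
                      enumerate(rng.integers(0, 50, size=6)) if c > 0}
            if counts:
                profiles.append(_profile(f"s{i}", counts))
        m = biotype_proportion_matrix(profiles)
        np.testing.assert_allclose(m.proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_gene_species_excluded(self):
        a = _profile("A", {"protein_coding": 2})
        empty = BiotypeProfile(species_id="E", biotype_counts={}, n_genes=0,
                               mean_gene_length=1.0, genic_fraction=0.0,
                               exonic_fraction=0.0)
        b = _profile("B", {"protein_coding": 1})
        m = biotype_proportion_matrix([a, empty, b])
        assert m.species == ["A", "B"]


class TestPCA:
    def test_two_distinct_species_pc1_explains_all(self):
        m = BiotypeMatrix(pd.DataFrame([[0.8, 0.2], [0.4, 0.6]],
                                       columns=["x", "y"], index=["a", "b"]))
        _, var1, _ = pca_pc1(m)
        assert var1 == pytest.approx(1.0, abs=1e-12)

    def test_single_varying_column_concentrates_loading(self):
        base = np.array([0.5, 0.2, 0.3])
        rows = [base.copy() for _ in range(4)]
        shift = [-0.2, -0.05, 0.05, 0.2]
        for r, s in zip(rows, shift):
            r[0] += s
            r[1] -= s
        # variance lives entirely in the (x, -y) direction
        m = BiotypeMatrix(pd.DataFrame(rows, columns=["x", "y", "z"],
                                       index=list("abcd")))
        scores, var1, loadings = pca_pc1(m)
        assert var1 == pytest.approx(1.0, abs=1e-12)
        assert abs(loadings["z"]) < 1e-12

    def test_matches_sklearn_oracle_up_to_sign(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(6)
        m = _random_matrix(rng, 6, 4)
        scores, var1, _ = pca_pc1(m)
        p = PCA(n_components=4).fit(m.proportions.to_numpy())
        ref = p.transform(m.proportions.to_numpy())[:, 0]
        sign = np.sign(np.dot(ref, scores.to_numpy()))
        np.testing.assert_allclose(scores.to_numpy(), sign * ref, atol=1e-8)
        assert var1 == pytest.approx(p.explained_variance_ratio_[0], abs=1e-10)

    def test_orientation_follows_richness(self):
        # richer species (more nonzero biotypes) must not score lowest
        rich = _profile("rich", {"protein_coding": 5, "lncRNA": 3, "miRNA": 2})
        poor = _profile("poor", {"protein_coding": 10})
        mid = _profile("mid", {"protein_coding": 7, "lncRNA": 3})
        m = biotype_proportion_matrix([rich, poor, mid])
        scores, _, _ = pca_pc1(m)
        assert scores["rich"] > scores["poor"]

    def test_degenerate_cohort_rejected(self):
        m = BiotypeMatrix(pd.DataFrame([[0.5, 0.5]] * 3, columns=["x", "y"],
                                       index=list("abc")))
        with pytest.raises(DegenerateCohortError):
            pca_pc1(m)

    def test_species_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        m = _random_matrix(rng, 8, 5)
        perm = rng.permutation(8)
        m2 = BiotypeMatrix(m.proportions.iloc[perm])
        s1, v1, _ = pca_pc1(m)
        s2, v2, _ = pca_pc1(m2)
        assert v1 == pytest.approx(v2, abs=1e-12)
        np.testing.assert_allclose(s2.to_numpy(), s1.to_numpy()[perm], atol=1e-10)

    def test_zero_column_leaves_diversity_unchanged(self):
        rng = np.random.default_rng(12)
        m = _random_matrix(rng, 7, 4)
        padded = m.proportions.copy()
        padded["ghost"] = 0.0
        m2 = BiotypeMatrix(padded)
        d1 = transcript_diversity(pca_pc1(m)[0].to_numpy())
        d2 = transcript_diversity(pca_pc1(m2)[0].to_numpy())
        np.testing.assert_allclose(d1, d2, atol=1e-10)


class TestTranscriptDiversity:
    def test_affine_map(self):
        np.testing.assert_allclose(transcript_diversity([-1.0, 0.0, 3.0]),
                                   [0.0, 0.25, 1.0])

    def test_extremes(self):
        out = transcript_diversity([2.0, 5.0, 3.0])
        assert out.max() == 1.0 and out.min() == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=12)
        for a, b in [(2.0, 3.0), (0.1, -5.0), (100.0, 0.0)]:
            np.testing.assert_allclose(transcript_diversity(a * x + b),
                                       transcript_diversity(x), atol=1e-10)

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateCohortError):
            transcript_diversity([1.0, 1.0, 1.0])


class TestShannonEquitability:
    def test_uniform_is_one(self):
        assert shannon_equitability([0.25] * 4) == pytest.approx(1.0, abs=1e-12)

    def test_single_type_is_zero(self):
        assert shannon_equitability([1.0, 0.0, 0.0]) == 0.0

    def test_worked_value(self):
        # H = -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.039721, ln 3 = 1.098612
        assert shannon_equitability([0.5, 0.25, 0.25]) == pytest.approx(
            0.946395, abs=1e-6
        )

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            h = -sum(v * math.log(v) for v in p if v > 0)
            assert shannon_equitability(p) == pytest.approx(h / math.log(5), abs=1e-12)

    def test_global_s_option(self):
        # evenness against a fixed vocabulary size instead of observed richness
        val = shannon_equitability([0.5, 0.5], global_s=4)
        assert val == pytest.approx(math.log(2) / math.log(4), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            shannon_equitability([-0.1, 1.1])


class TestBiotypeDiversityCorrelation:
    def test_identical_column_is_one(self):
        div = np.array([0.1, 0.5, 0.9])
        rest = (1 - div)
        m = BiotypeMatrix(pd.DataFrame({"a": div, "b": rest}, index=list("xyz")))
        corr = biotype_diversity_correlation(m, div)
        assert corr["a"] == pytest.approx(1.0, abs=1e-12)
        assert corr["b"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_column_is_missing(self):
        m = BiotypeMatrix(pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.2, 0.3, 0.4],
                                        "c": [0.3, 0.2, 0.1]}, index=list("xyz")))
        corr = biotype_diversity_correlation(m, [0.0, 0.5, 1.0])
        assert math.isnan(corr["a"])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(15)
        m = _random_matrix(rng, 10, 4)
        div = rng.uniform(size=10)
        corr = biotype_diversity_correlation(m, div)
        for col in m.biotypes:
            x = m.proportions[col].to_numpy()
            expected = (np.cov(x, div, ddof=1)[0, 1]
                        / (np.std(x, ddof=1) * np.std(div, ddof=1)))
            assert corr[col] == pytest.approx(expected, abs=1e-10)

    def test_too_few_species_rejected(self):
        m = BiotypeMatrix(pd.DataFrame({"a": [0.5, 0.6], "b": [0.5, 0.4]},
                                       index=list("xy")))
        with pytest.raises(DomainError):
            biotype_diversity_correlation(m, [0.1, 0.9])


class TestRelativeDiversity:
    def test_reference_scale(self):
        d = pd.Series({"human": 1.0, "mouse": 0.88, "duck": 0.12})
        rel = relative_diversity(d, "human")
        assert rel["mouse"] == pytest.approx(0.88)
        assert rel["human"] == 1.0

    def test_zero_reference_rejected(self):
        d = pd.Series({"a": 0.0, "b": 1.0})
        with pytest.raises(DegenerateCohortError):
            relative_diversity(d, "a")

    def test_unknown_reference_rejected(self):
        with pytest.raises(DomainError):
            relative_diversity(pd.Series({"a": 1.0}), "zz")
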