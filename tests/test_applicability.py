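"""Indicator matrix assembly, the weighted index, ranking and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refqual.applicability import (
    IndicatorMatrix,
    assemble_indicator_matrix,
    compare_builds,
    correlate_indicators,
    ngs_applicability,
    rank_report,
)
from refqual.config import INDICATOR_COLUMNS, CohortConfig
from refqual.errors import DomainError
from refqual.mapping import MappingIndicatorBlock
from refqual.quant import QuantIndicatorBlock
from refqual.records import AssemblyStats, BiotypeProfile


def _assembly():
    return [
        AssemblyStats("a", 1_000_000, 10_000, 100_000, 1000),
        AssemblyStats("b", 2_000_000, 200_000, 1_000_000, 100),
        AssemblyStats("c", 500_000, 250_000, 450_000, 0),
    ]


def _mapping(sids=("a", "b", "c")):
    vals = {"a": (0.7, 0.8, 0.9), "b": (0.85, 0.95, 0.9), "c": (0.95, 0.99, 0.96)}
    return [
        MappingIndicatorBlock(s, 2, *vals[s], MQI=sum(vals[s]) / 3)
        for s in sids
    ]


def _quant(sids=("a", "b", "c")):
    vals = {"a": (0.5, 0.6, 0.9), "b": (0.7, 0.85, 0.85), "c": (0.8, 0.9, 0.9)}
    return [
        QuantIndicatorBlock(s, 2, *vals[s], QQI=sum(vals[s]) / 3)
        for s in sids
    ]


def _profiles(sids=("a", "b", "c")):
    counts = {
        "a": {"protein_coding": 20},
        "b": {"protein_coding": 14, "lncRNA": 3, "miRNA": 2, "pseudogene": 1},
        "c": {"protein_coding": 8, "lncRNA": 6, "miRNA": 4, "pseudogene": 2},
    }
    return [
        BiotypeProfile(s, counts[s], sum(counts[s].values()), 1000.0, 0.1, 0.05)
        for s in sids
    ]


def _matrix_from_values(values: pd.DataFrame, weights=None) -> IndicatorMatrix:
    w = np.asarray(weights if weights is not None else [1.0] * 10)
    mqi = values[["UnimapRate", "MapRate", "MultiMapRate"]].mean(axis=1)
    qqi = values[["QuantRate", "QuantRateAbs", "QuantRateAmb"]].mean(axis=1)
    return IndicatorMatrix(values=values, weights=w, MQI=mqi, QQI=qqi,
                           index=ngs_applicability(values, w),
                           mask=values.notna())


class TestAssemble:
    def test_three_complete_species(self):
        m = assemble_indicator_matrix(_assembly(), _mapping(), _quant(), _profiles())
        assert m.values.shape == (3, 10)
        assert m.mask.all().all()
        assert m.index.notna().all()

    def test_missing_annotation_masks_diversity_only(self):
        m = assemble_indicator_matrix(_assembly(), _mapping(), _quant(),
                                      _profiles(("b", "c")))
        assert not m.mask.loc["a", "TranscriptDiversity"]
        assert m.mask.loc["a"].drop("TranscriptDiversity").all()
        assert math.isnan(m.index.loc["a"])  # complete-case policy
        assert m.index.loc[["b", "c"]].notna().all()

    def test_join_order_independent(self):
        m1 = assemble_indicator_matrix(_assembly(), _mapping(), _quant(), _profiles())
        m2 = assemble_indicator_matrix(list(reversed(_assembly())),
                                       list(reversed(_mapping())),
                                       list(reversed(_quant())),
                                       list(reversed(_profiles())))
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_renormalize_policy_scores_incomplete_species(self):
        cfg = CohortConfig(missing_data_policy="renormalize")
        m = assemble_indicator_matrix(_assembly(), _mapping(), _quant(),
                                      _profiles(("b", "c")), config=cfg)
        expected = m.values.loc["a"].dropna().mean()
        assert m.index.loc["a"] == pytest.approx(expected, abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            assemble_indicator_matrix([], [], [], [])


class TestNgsApplicability:
    def _values(self, rows, sids=None):
        sids = sids or [f"s{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=pd.Index(sids, name="species_id"),
                            columns=INDICATOR_COLUMNS)

    def test_all_ones(self):
        v = self._values([[1.0] * 10])
        assert ngs_applicability(v, [1.0] * 10).iloc[0] == 1.0

    def test_half_and_half(self):
        v = self._values([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]])
        assert ngs_applicability(v, [1.0] * 10).iloc[0] == pytest.approx(0.5)

    def test_random_weighted_mean_oracle(self):
        rng = np.random.default_rng(11)
        v = self._values(rng.uniform(size=(8, 10)))
        w = rng.uniform(0.1, 2.0, size=10)
        out = ngs_applicability(v, w)
        for i in range(8):
            expected = sum(w[k] * v.iloc[i, k] for k in range(10)) / sum(w)
            assert out.iloc[i] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_weight_scale_invariance(self, c):
        rng = np.random.default_rng(13)
        v = self._values(rng.uniform(size=(5, 10)))
        w = rng.uniform(0.1, 1.0, size=10)
        np.testing.assert_allclose(ngs_applicability(v, w),
                                   ngs_applicability(v, c * w), atol=1e-12)

    def test_improving_one_indicator_never_lowers_index(self):
        rng = np.random.default_rng(14)
        v = self._values(rng.uniform(0, 0.9, size=(4, 10)))
        w = rng.uniform(0.0, 1.0, size=10)
        base = ngs_applicability(v, w)
        for k in range(10):
            bumped = v.copy()
            bumped.iloc[2, k] += 0.1
            out = ngs_applicability(bumped, w)
            assert out.iloc[2] >= base.iloc[2] - 1e-12

    def test_equal_weight_identity_with_mqi_qqi(self):
        m = assemble_indicator_matrix(_assembly(), _mapping(), _quant(), _profiles())
        v = m.values
        lhs = m.index
        rhs = (
            3 * m.MQI + 3 * m.QQI + v["AdjN50Contig"] + v["AdjN50Scaffold"]
            + v["UngapRate"] + v["TranscriptDiversity"]
        ) / 10
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_bad_weights_rejected(self):
        v = self._values([[0.5] * 10])
        for w in ([0.0] * 10, [-1.0] + [1.0] * 9, [1.0] * 9):
            with pytest.raises(DomainError):
                ngs_applicability(v, w)


class TestRankReport:
    def test_descending_order(self):
        rng = np.random.default_rng(19)
        v = pd.DataFrame(rng.uniform(size=(3, 10)), columns=INDICATOR_COLUMNS,
                         index=pd.Index(["x", "y", "z"], name="species_id"))
        v.iloc[0] = 0.9
        v.iloc[1] = 0.5
        v.iloc[2] = 0.7
        report = rank_report(_matrix_from_values(v))
        assert list(report.index) == ["x", "z", "y"]
        assert report["rank"].tolist() == [1, 2, 3]

    def test_ties_broken_lexicographically(self):
        v = pd.DataFrame(0.5, columns=INDICATOR_COLUMNS,
                         index=pd.Index(["zeta", "alpha", "mid"], name="species_id"))
        report = rank_report(_matrix_from_values(v))
        assert list(report.index) == ["alpha", "mid", "zeta"]

    def test_row_count_excludes_unscored(self):
        m = assemble_indicator_matrix(_assembly(), _mapping(), _quant(),
                                      _profiles(("b", "c")))
        report = rank_report(m)
        assert len(report) == 2  # 'a' unscored under complete-case policy
        assert set(report.index) == {"b", "c"}


class TestCorrelateIndicators:
    def test_self_correlation_unit_diagonal(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 1.0, 4.0, 3.0]})
        corr = correlate_indicators(df)
        assert corr.loc["x", "x"] == 1.0
        assert corr.equals(corr.T)

    def test_antimonotone_spearman(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [10.0, 7.0, 3.0, 1.0]})
        corr = correlate_indicators(df, method="spearman")
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        corr = correlate_indicators(df)
        ref = np.corrcoef(df.to_numpy().T)
        np.testing.assert_allclose(corr.to_numpy(), ref, atol=1e-10)

    def test_short_pairs_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan],
                           "y": [1.0, np.nan, 2.0, 3.0]})
        corr = correlate_indicators(df)
        assert math.isnan(corr.loc["x", "y"])

    def test_constant_column_missing(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        corr = correlate_indicators(df)
        assert math.isnan(corr.loc["x", "y"])


class TestCompareBuilds:
    def _build(self, level: float) -> IndicatorMatrix:
        v = pd.DataFrame(
            np.clip(level + np.linspace(0, 0.05, 10), 0, 1).reshape(1, -1).repeat(2, 0),
            columns=INDICATOR_COLUMNS,
            index=pd.Index(["sp1", "sp2"], name="species_id"),
        )
        return _matrix_from_values(v)

    def test_identical_builds_identical_indices(self):
        table = compare_builds({"v1": self._build(0.5), "v2": self._build(0.5)})
        by_build = table.groupby("build")["index"].mean()
        assert by_build["v1"] == pytest.approx(by_build["v2"], abs=1e-12)

    def test_dominating_build_scores_higher(self):
        table = compare_builds({"old": self._build(0.3), "new": self._build(0.6)})
        wide = table.pivot(index="species_id", columns="build", values="index")
        assert (wide["new"] >= wide["old"]).all()

    def test_three_build_gradient_strictly_increasing(self):
        builds = {f"b{i}": self._build(0.2 + 0.25 * i) for i in range(3)}
        table = compare_builds(builds)
        means = table.groupby("build")["index"].mean()
        assert means["b0"] < means["b1"] < means["b2"]

    def test_absent_species_flagged(self):
        full = self._build(0.5)
        partial = IndicatorMatrix(
            values=full.values.iloc[:1], weights=full.weights,
            MQI=full.MQI.iloc[:1], QQI=full.QQI.iloc[:1],
            index=full.index.iloc[:1], mask=full.mask.iloc[:1],
        )
        table = compare_builds({"full": full, "partial": partial})
        flagged = table[(table.build == "partial") & (table.species_id == "sp2")]
        assert flagged["missing"].all()

    def test_single_build_rejected(self):
        with pytest.raises(DomainError):
            compare_builds({"only": self._build(0.5)})
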