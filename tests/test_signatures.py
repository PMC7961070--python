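"""Normalisation chain, signature scoring, DEG flags and heatmap layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from tilmark.signatures import (
    CountMatrix,
    SignatureCoverageError,
    SignatureDefinition,
    background_floor,
    differential_expression,
    heatmap_prepare,
    hk_normalize,
    load_signatures,
    normalize,
    positive_control_normalize,
    score_signature,
    select_stable_hk,
)


def toy_matrix(counts: dict, classes: dict, groups: dict | None = None):
    df = pd.DataFrame(counts)
    return CountMatrix.from_frames(
        counts=df,
        gene_class=pd.Series(classes),
        groups=pd.Series(groups) if groups else None,
    )


class TestPositiveControlNormalize:
    def test_identical_samples_scale_one(self):
        m = toy_matrix(
            {"s1": [100, 10, 50], "s2": [100, 10, 50]},
            classes={0: "positive", 1: "negative", 2: "endogenous"},
        )
        out = positive_control_normalize(m)
        assert np.allclose(out.values, m.counts)

    def test_doubled_controls_halved(self):
        # s2's positive controls doubled: factor 0.5 up to cohort renormalisation
        m = toy_matrix(
            {"s1": [100, 50], "s2": [200, 50]},
            classes={0: "positive", 1: "endogenous"},
        )
        out = positive_control_normalize(m)
        # geomeans 100 and 200, cohort mean 150 -> factors 1.5 and 0.75 (ratio 2)
        assert out.values.loc[1, "s1"] == pytest.approx(75.0)
        assert out.values.loc[1, "s2"] == pytest.approx(37.5)

    def test_single_sample_is_identity(self):
        m = toy_matrix({"s1": [100, 50]}, classes={0: "positive", 1: "endogenous"})
        out = positive_control_normalize(m)
        assert np.allclose(out.values, m.counts)

    def test_zero_control_names_sample(self):
        m = toy_matrix({"s1": [0, 50]}, classes={0: "positive", 1: "endogenous"})
        with pytest.raises(ValueError, match="s1"):
            positive_control_normalize(m)


class TestBackgroundFloor:
    def test_all_negatives_zero_floor_is_one(self):
        m = toy_matrix(
            {"s1": [0, 0, 0.5]},
            classes={0: "negative", 1: "negative", 2: "endogenous"},
        )
        out = background_floor(m)
        assert out.values.loc[2, "s1"] == 1.0

    def test_constant_negatives(self):
        m = toy_matrix(
            {"s1": [10, 10, 10, 10, 5]},
            classes={i: "negative" for i in range(4)} | {4: "endogenous"},
        )
        out = background_floor(m)
        assert out.values.loc[4, "s1"] == 10.0

    def test_mean_plus_two_sd(self):
        # negatives {5, 10, 15}: sample SD 5 -> floor 20; endogenous 8 raised
        m = toy_matrix(
            {"s1": [5, 10, 15, 8, 100]},
            classes={0: "negative", 1: "negative", 2: "negative",
                     3: "endogenous", 4: "endogenous"},
        )
        out = background_floor(m)
        assert out.values.loc[3, "s1"] == pytest.approx(20.0)
        assert out.values.loc[4, "s1"] == pytest.approx(100.0)
        # controls themselves are not floored
        assert out.values.loc[0, "s1"] == 5.0


class TestStableHk:
    def test_constant_gene_ranked_first(self):
        m = toy_matrix(
            {"s1": [100, 50, 10], "s2": [100, 500, 10], "s3": [100, 5, 10]},
            classes={0: "housekeeping", 1: "housekeeping", 2: "negative"},
        )
        m = CountMatrix.from_frames(
            m.counts.rename(index={0: "HKA", 1: "HKB", 2: "NEG"}),
            pd.Series({"HKA": "housekeeping", "HKB": "housekeeping",
                       "NEG": "negative"}),
        )
        assert select_stable_hk(m, 1) == ["HKA"]
        assert set(select_stable_hk(m, 2)) == {"HKA", "HKB"}

    def test_k_too_large(self):
        m = toy_matrix({"s1": [10]}, classes={0: "housekeeping"})
        with pytest.raises(ValueError):
            select_stable_hk(m, 2)


class TestHkNormalize:
    def test_two_sample_geomeans(self):
        # HK geomeans 10 and 40 -> cohort mean 25 -> factors 2.5 and 0.625
        m = toy_matrix(
            {"s1": [10, 100], "s2": [40, 100]},
            classes={0: "housekeeping", 1: "endogenous"},
        )
        out = hk_normalize(m, [0])
        assert out.values.loc[1, "s1"] == pytest.approx(250.0)
        assert out.values.loc[1, "s2"] == pytest.approx(62.5)

    def test_column_scaling_is_undone(self):
        m = toy_matrix(
            {"s1": [10, 20, 100], "s2": [30, 60, 300]},
            classes={0: "housekeeping", 1: "housekeeping", 2: "endogenous"},
        )
        out = hk_normalize(m, [0, 1])
        assert out.values.loc[2, "s1"] == pytest.approx(out.values.loc[2, "s2"])

    def test_nonpositive_hk_rejected(self):
        m = toy_matrix(
            {"s1": [0, 100]}, classes={0: "housekeeping", 1: "endogenous"}
        )
        with pytest.raises(ValueError):
            hk_normalize(m, [0])


class TestScoreSignature:
    def test_single_gene_signature(self):
        m = toy_matrix({"s1": [100.0]}, classes={0: "endogenous"})
        m = CountMatrix.from_frames(
            m.counts.rename(index={0: "GENE1"}),
            pd.Series({"GENE1": "endogenous"}),
        )
        from tilmark.signatures import _as_norm

        sig = SignatureDefinition("custom", frozenset({"GENE1"}))
        out = score_signature(_as_norm(m), sig)
        assert out.loc[0, "score"] == pytest.approx(2.0)

    def test_mean_of_log10(self):
        m = CountMatrix.from_frames(
            pd.DataFrame({"s1": [10.0, 1000.0]}, index=["G1", "G2"]),
            pd.Series({"G1": "endogenous", "G2": "endogenous"}),
        )
        from tilmark.signatures import _as_norm

        sig = SignatureDefinition("custom", frozenset({"G1", "G2"}))
        out = score_signature(_as_norm(m), sig)
        assert out.loc[0, "score"] == pytest.approx(2.0)

    def test_low_coverage_names_missing_genes(self):
        m = CountMatrix.from_frames(
            pd.DataFrame({"s1": [10.0]}, index=["G1"]),
            pd.Series({"G1": "endogenous"}),
        )
        from tilmark.signatures import _as_norm

        sig = SignatureDefinition("custom", frozenset({"G1", "G2", "G3"}))
        with pytest.raises(SignatureCoverageError, match="G2"):
            score_signature(_as_norm(m), sig)

    def test_packaged_signatures_load(self):
        sigs = load_signatures()
        assert {"IFN-gamma", "ExpandedImmune", "TcellInflamed"} <= set(sigs)
        assert "IFNG" in sigs["IFN-gamma"].gene_symbols


def _cohort_matrix(rng, n_samples=6, scale=None):
    """Small full-featured matrix: 4 endo + 3 HK + 2 pos + 3 neg."""
    genes = ["G1", "G2", "G3", "G4", "HK1", "HK2", "HK3", "POS1", "POS2",
             "NEG1", "NEG2", "NEG3"]
    classes = pd.Series(
        ["endogenous"] * 4 + ["housekeeping"] * 3 + ["positive"] * 2
        + ["negative"] * 3,
        index=genes,
    )
    base = np.array([200, 500, 50, 1000, 400, 600, 800, 5000, 1000, 2, 3, 1])
    counts = rng.poisson(base[:, None] * np.ones(n_samples)[None, :]).astype(float)
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    if scale is not None:
        df = df.mul(pd.Series(scale, index=samples), axis=1)
    groups = pd.Series(
        ["TR"] * (n_samples // 2) + ["NTR"] * (n_samples - n_samples // 2),
        index=samples,
    )
    return CountMatrix.from_frames(df, classes, groups)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    factors=hst.lists(
        hst.floats(0.5, 2.0, allow_nan=False), min_size=6, max_size=6
    )
)
def test_scores_invariant_to_per_sample_scaling(factors):
    """Multiplying a sample's raw counts by any factor leaves scores unchanged."""
    rng = np.random.default_rng(0)
    base = _cohort_matrix(rng)
    scaled = CountMatrix.from_frames(
        base.counts.mul(pd.Series(factors, index=base.samples), axis=1),
        base.gene_class,
        base.groups,
    )
    sig = SignatureDefinition("custom", frozenset({"G1", "G2", "G3", "G4"}))
    s0 = score_signature(normalize(base, hk_k=3), sig)["score"].to_numpy()
    s1 = score_signature(normalize(scaled, hk_k=3), sig)["score"].to_numpy()
    assert np.allclose(s0, s1, atol=1e-10)


def test_score_monotone_in_signature_gene():
    rng = np.random.default_rng(1)
    base = _cohort_matrix(rng)
    bumped = base.counts.copy()
    bumped.loc["G1", "s0"] *= 3.0
    bumped = CountMatrix.from_frames(bumped, base.gene_class, base.groups)
    sig = SignatureDefinition("custom", frozenset({"G1", "G2"}))
    s0 = score_signature(normalize(base, hk_k=3), sig).set_index("sample_id")
    s1 = score_signature(normalize(bumped, hk_k=3), sig).set_index("sample_id")
    # HK normalisation is untouched by an endogenous bump, so s0's score rises
    assert s1.loc["s0", "score"] >= s0.loc["s0", "score"]


class TestDifferentialExpression:
    def test_identical_groups_ns(self):
        rng = np.random.default_rng(2)
        m = _cohort_matrix(rng)
        sym = m.counts.copy()
        sym.iloc[:, 3:] = sym.iloc[:, :3].to_numpy()  # NTR mirrors TR exactly
        m = CountMatrix.from_frames(sym, m.gene_class, m.groups)
        deg = differential_expression(normalize(m, hk_k=3))
        assert (deg["flag"] == "ns").all()
        assert np.allclose(deg["fold_change"], 1.0)

    def test_fourfold_shift_flags_up(self):
        rng = np.random.default_rng(3)
        m = _cohort_matrix(rng, n_samples=8)
        up = m.counts.copy()
        up.loc["G1", m.groups[m.groups == "TR"].index] *= 4.0
        m = CountMatrix.from_frames(up, m.gene_class, m.groups)
        deg = differential_expression(normalize(m, hk_k=3)).set_index("gene")
        assert deg.loc["G1", "fold_change"] > 2.0
        assert deg.loc["G1", "flag"] == "up"

    def test_fold_change_gate_overrides_small_p(self):
        """FC 1.8 stays ns regardless of p: both gates are required."""
        from tilmark.signatures import _flag

        assert _flag(1.8, 0.001) == "ns"
        assert _flag(4.0, 0.001) == "up"
        assert _flag(0.2, 0.001) == "down"
        assert _flag(4.0, 0.2) == "ns"

    def test_flag_soundness_exhaustive(self):
        rng = np.random.default_rng(4)
        m = _cohort_matrix(rng, n_samples=8)
        deg = differential_expression(normalize(m, hk_k=3))
        for _, row in deg.iterrows():
            if row.flag == "up":
                assert row.fold_change > 2 and row.p_value < 0.05
            elif row.flag == "down":
                assert row.fold_change < 0.5 and row.p_value < 0.05


class TestHeatmapPrepare:
    @staticmethod
    def _norm(rng, n_samples=4):
        return normalize(_cohort_matrix(rng, n_samples=n_samples), hk_k=3)

    def test_rows_centred(self):
        norm = self._norm(np.random.default_rng(5))
        layout = heatmap_prepare(norm, ["G1", "G2", "G3"])
        assert np.allclose(layout.standardized.mean(axis=1), 0.0, atol=1e-12)

    def test_identical_samples_adjacent(self):
        norm = self._norm(np.random.default_rng(6))
        vals = norm.values.copy()
        vals["s3"] = vals["s0"]  # duplicate column
        from dataclasses import replace

        norm = replace(norm, values=vals)
        layout = heatmap_prepare(norm, ["G1", "G2", "G3", "G4"])
        order = list(layout.col_order)
        assert abs(order.index("s0") - order.index("s3")) == 1

    def test_three_by_three_matches_manual_agglomeration(self):
        # rows A,B close together, C far: expected leaf order keeps A,B adjacent
        vals = pd.DataFrame(
            {"s1": [1.0, 1.1, 10.0], "s2": [1.2, 1.3, 10.5], "s3": [0.9, 1.0, 9.5]},
            index=["A", "B", "C"],
        )
        vals = 10.0 ** vals  # heatmap_prepare takes linear values, logs internally
        from tilmark.signatures import NormalizedMatrix

        norm = NormalizedMatrix(
            values=vals,
            gene_class=pd.Series({"A": "endogenous", "B": "endogenous",
                                  "C": "endogenous"}),
        )
        layout = heatmap_prepare(norm, ["A", "B", "C"], zscore=False)
        order = list(layout.row_order)
        assert abs(order.index("A") - order.index("B")) == 1
        assert order.index("C") in (0, 2)

    def test_single_sample_warns(self):
        norm = self._norm(np.random.default_rng(7), n_samples=2)
        from dataclasses import replace

        norm = replace(norm, values=norm.values[["s0"]])
        with pytest.warns(UserWarning, match="single sample"):
            layout = heatmap_prepare(norm, ["G1", "G2"])
        assert layout.col_order == ("s0",)

    def test_empty_gene_list_rejected(self):
        norm = self._norm(np.random.default_rng(8))
        with pytest.raises(ValueError):
            heatmap_prepare(norm, [])
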