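from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortaxis.axis import PEAK_THRESHOLDS
from cortaxis.grn import (
    classify_enhancers,
    export_network,
    mann_whitney_u,
    summarize_tfs,
    target_correlation_by_class,
    tf_activity_correlation,
    tf_target_expression_correlation,
)
from cortaxis.io import ERegulonTable, ValidationError


def _eregulons(rows):
    return ERegulonTable(pd.DataFrame(
        rows, columns=["tf", "peak", "target_gene", "strength"]
    ))


def _screen(features, rs, qs=None, classes=None):
    n = len(features)
    return pd.DataFrame({
        "feature": features,
        "r": rs,
        "p": [0.001] * n,
        "q": qs if qs is not None else [0.001] * n,
        "sign_class": classes if classes is not None else ["null"] * n,
    })


ER = _eregulons([
    ["TF1", "chr1:0-100", "g1", 1.0],
    ["TF1", "chr1:0-100", "g2", 0.5],
    ["TF1", "chr1:200-300", "g1", 2.0],
    ["TF2", "chr1:400-500", "g3", 1.0],
])


class TestClassifyEnhancers:
    def test_published_peak_thresholds(self):
        screen = _screen(["chr1:0-100", "chr1:200-300", "chr1:400-500"],
                         [0.6, 0.1, -0.55], qs=[0.01, 0.5, 0.01],
                         classes=["positive", "null", "negative"])
        classes, missing = classify_enhancers(ER, screen, PEAK_THRESHOLDS)
        by_peak = classes.set_index("peak")["sign_class"]
        assert by_peak["chr1:0-100"] == "positive"
        assert by_peak["chr1:200-300"] == "null"
        assert by_peak["chr1:400-500"] == "negative"
        assert missing == []

    def test_missing_peak_reported_not_dropped(self):
        screen = _screen(["chr1:0-100"], [0.6], classes=["positive"])
        classes, missing = classify_enhancers(ER, screen)
        assert set(missing) == {"chr1:200-300", "chr1:400-500"}
        assert len(classes) == 1

    def test_empty_table_rejected(self):
        empty = ERegulonTable(pd.DataFrame(
            columns=["tf", "peak", "target_gene", "strength"]
        ))
        with pytest.raises(ValidationError):
            classify_enhancers(empty, _screen(["x"], [0.1]))


class TestTargetCorrelationByClass:
    def test_per_link_distributions_and_means(self):
        er = _eregulons([
            ["TF1", "p_pos1", "gA", 1.0],
            ["TF1", "p_pos2", "gB", 1.0],
            ["TF2", "p_neg1", "gC", 1.0],
            ["TF2", "p_neg2", "gD", 1.0],
        ])
        classes = pd.DataFrame({
            "peak": ["p_pos1", "p_pos2", "p_neg1", "p_neg2"],
            "sign_class": ["positive", "positive", "negative", "negative"],
            "r": [0.8, 0.9, -0.8, -0.9],
        })
        genes = _screen(["gA", "gB", "gC", "gD"], [0.8, 0.9, -0.7, -0.8])
        report = target_correlation_by_class(classes, er, genes)
        assert report["summary"]["positive"]["mean"] == pytest.approx(0.85)
        assert report["summary"]["negative"]["mean"] == pytest.approx(-0.75)

    def test_gene_counted_once_per_linking_enhancer(self):
        er = _eregulons([
            ["TF1", "p1", "gA", 1.0],
            ["TF1", "p2", "gA", 1.0],
        ])
        classes = pd.DataFrame({"peak": ["p1", "p2"],
                                "sign_class": ["positive", "positive"],
                                "r": [0.8, 0.9]})
        genes = _screen(["gA"], [0.5])
        report = target_correlation_by_class(classes, er, genes)
        assert report["distributions"]["positive"] == [0.5, 0.5]

    def test_exact_mwu_small_example(self):
        er = _eregulons([
            ["TF1", "p1", "gA", 1.0], ["TF1", "p2", "gB", 1.0],
            ["TF2", "p3", "gC", 1.0], ["TF2", "p4", "gD", 1.0],
        ])
        classes = pd.DataFrame({
            "peak": ["p1", "p2", "p3", "p4"],
            "sign_class": ["positive", "positive", "negative", "negative"],
            "r": [0.8, 0.9, -0.8, -0.9],
        })
        genes = _screen(["gA", "gB", "gC", "gD"], [1.0, 2.0, 3.0, 4.0])
        report = target_correlation_by_class(classes, er, genes)
        # positive {1,2} vs negative {3,4}: exact two-sided p = 1/3
        assert report["mwu"]["p"] == pytest.approx(1 / 3)

    def test_empty_class_skips_test_but_emits_distributions(self):
        er = _eregulons([["TF1", "p1", "gA", 1.0]])
        classes = pd.DataFrame({"peak": ["p1"], "sign_class": ["positive"],
                                "r": [0.8]})
        genes = _screen(["gA"], [0.5])
        report = target_correlation_by_class(classes, er, genes)
        assert "skipped" in report["mwu"]
        assert report["distributions"]["positive"] == [0.5]


def brute_force_mwu(x, y, alternative="two-sided"):
    """Enumerate all rank assignments (tie-free) for the exact p-value."""
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    all_u = []
    for subset in combinations(range(1, n + m + 1), n):
        all_u.append(sum(subset) - n * (n + 1) / 2)
    all_u = np.array(all_u)
    p_le = np.mean(all_u <= u_obs)
    p_ge = np.mean(all_u >= u_obs)
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitneyU:
    def test_complete_separation_u_zero(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_interleaved_exact_example(self):
        u, p = mann_whitney_u([1, 3], [2, 4])
        assert u == 1.0
        assert p == pytest.approx(2 / 3)

    def test_identical_tied_samples_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_u_complementarity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            ux, _ = mann_whitney_u(x, y)
            uy, _ = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_matches_brute_force_sample(self):
        rng = np.random.default_rng(1)
        for nx, ny in [(2, 2), (3, 4), (5, 3), (6, 6)]:
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            for alt in ("two-sided", "greater", "less"):
                _, p = mann_whitney_u(x, y, alternative=alt)
                assert p == pytest.approx(brute_force_mwu(x, y, alt), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1, size=25)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_sample_matches_scipy(self):
        x = [1, 2, 2, 3, 5, 5, 6, 8]
        y = [2, 2, 4, 5, 5, 7, 9, 9]
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestTFSummaries:
    def test_activity_is_mean_over_distinct_peaks(self):
        screen = _screen(["chr1:0-100", "chr1:200-300", "chr1:400-500"],
                         [0.5, 0.7, -0.4])
        activity = tf_activity_correlation(ER, screen)
        # TF1 peaks {chr1:0-100, chr1:200-300}: duplicate link counted once
        assert activity["TF1"] == pytest.approx(0.6)
        assert activity["TF2"] == pytest.approx(-0.4)

    def test_targets_counted_once_per_gene(self):
        genes = _screen(["g1", "g2", "g3"], [0.2, 0.4, 0.6])
        targets = tf_target_expression_correlation(ER, genes)
        # TF1 targets {g1, g2} despite g1 appearing via two enhancers
        assert targets["TF1"] == pytest.approx(0.3)
        assert targets["TF2"] == pytest.approx(0.6)

    def test_tf_without_results_omitted_with_warning(self):
        screen = _screen(["chr1:0-100"], [0.5])
        with pytest.warns(UserWarning, match="TF2"):
            activity = tf_activity_correlation(ER, screen)
        assert "TF2" not in activity

    def test_summaries_include_counts(self):
        peaks = _screen(["chr1:0-100", "chr1:200-300", "chr1:400-500"],
                        [0.5, 0.7, -0.4])
        genes = _screen(["g1", "g2", "g3", "TF1"], [0.2, 0.4, 0.6, 0.9])
        summaries = {s.tf: s for s in summarize_tfs(ER, peaks, genes)}
        assert summaries["TF1"].n_sites == 2
        assert summaries["TF1"].n_targets == 2
        assert summaries["TF1"].tf_expr_r == pytest.approx(0.9)
        assert np.isnan(summaries["TF2"].tf_expr_r)


class TestExportNetwork:
    def _inputs(self):
        peaks = _screen(["chr1:0-100", "chr1:200-300", "chr1:400-500"],
                        [0.5, 0.7, -0.4],
                        classes=["positive", "positive", "null"])
        genes = _screen(["g1", "g2", "g3"], [0.2, 0.4, 0.6])
        classes, _ = classify_enhancers(ER, peaks)
        summaries = summarize_tfs(ER, peaks, genes)
        return classes, genes, summaries

    def test_full_export_keeps_all_edges(self):
        classes, genes, summaries = self._inputs()
        net = export_network(ER, classes, genes, summaries)
        assert len(net) == 4
        assert set(net.columns) >= {"tf", "peak", "target_gene", "strength",
                                    "peak_sign_class", "gene_axis_r",
                                    "tf_activity_r"}

    def test_gene_subset_restricts_edges(self):
        classes, genes, summaries = self._inputs()
        net = export_network(ER, classes, genes, summaries, gene_subset=["g1"])
        assert len(net) == 2 and set(net["target_gene"]) == {"g1"}

    def test_empty_subset_warns_and_returns_header(self):
        classes, genes, summaries = self._inputs()
        with pytest.warns(UserWarning):
            net = export_network(ER, classes, genes, summaries,
                                 gene_subset=["nope"])
        assert len(net) == 0 and "tf" in net.columns
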