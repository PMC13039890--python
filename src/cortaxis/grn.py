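"""eRegulon concordance: do enhancer accessibility trends predict target
gene expression trends?

Enhancer peaks are classified positive / negative / null by their axis
correlation (peak thresholds |r| > 0.5, q < 0.05). The target genes of
positive- vs negative-class enhancers are then compared on their own
expression axis correlations — one value per enhancer-gene link — with a
two-sided Mann-Whitney U test. Per-TF summaries average the axis
correlation of a TF's distinct binding-site peaks (activity), of its
distinct target genes (target expression), and record the TF's own
expression correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from cortaxis.axis import AxisThresholds, PEAK_THRESHOLDS
from cortaxis.io import ERegulonTable, ValidationError


@dataclass
class TFSummary:
    tf: str
    activity_r: float
    target_expr_r: float
    tf_expr_r: float
    n_sites: int
    n_targets: int


def classify_enhancers(
    eregulons: ERegulonTable,
    peak_results: pd.DataFrame,
    thresholds: AxisThresholds = PEAK_THRESHOLDS,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify each distinct eRegulon peak by its accessibility trend.

    ``peak_results`` is a classified axis screen (feature, r, q,
    sign_class). Returns a (peak, sign_class, r) table over the peaks
    that have results, plus the list of peaks with no axis result.
    """
    if len(eregulons) == 0:
        raise ValidationError("empty eRegulon table")
    res = peak_results.set_index("feature")
    rows, missing = [], []
    for peak in eregulons.peaks:
        if peak in res.index:
            row = res.loc[peak]
            rows.append({"peak": peak, "sign_class": row["sign_class"],
                         "r": float(row["r"])})
        else:
            missing.append(peak)
    return pd.DataFrame(rows, columns=["peak", "sign_class", "r"]), missing


def target_correlation_by_class(
    classes: pd.DataFrame,
    eregulons: ERegulonTable,
    gene_results: pd.DataFrame,
) -> dict:
    """Distributions of target-gene axis correlations per enhancer class.

    One value per enhancer-gene link (a gene targeted by two enhancers of
    a class contributes twice). The report carries per-class summary
    statistics and the two-sided Mann-Whitney U p-value comparing the
    positive- vs negative-class distributions; if either class is empty
    the test is skipped with an explanation but distributions are still
    emitted.
    """
    class_of = dict(zip(classes["peak"], classes["sign_class"]))
    gene_r = dict(zip(gene_results["feature"], gene_results["r"]))
    dists: dict[str, list[float]] = {"positive": [], "negative": [], "null": []}
    for row in eregulons.df.itertuples(index=False):
        cls = class_of.get(row.peak)
        if cls is None or row.target_gene not in gene_r:
            continue
        dists[cls].append(float(gene_r[row.target_gene]))
    report: dict = {"distributions": dists, "summary": {}}
    for cls, values in dists.items():
        if values:
            arr = np.asarray(values)
            report["summary"][cls] = {
                "n": len(values),
                "min": float(arr.min()),
                "max": float(arr.max()),
                "mean": float(arr.mean()),
                "q25": float(np.percentile(arr, 25)),
                "median": float(np.percentile(arr, 50)),
                "q75": float(np.percentile(arr, 75)),
            }
    if dists["positive"] and dists["negative"]:
        u, p = mann_whitney_u(dists["positive"], dists["negative"])
        report["mwu"] = {
            "U": u,
            "p": p,
            "alternative": "two-sided",
            "direction": "positive>negative"
            if np.mean(dists["positive"]) > np.mean(dists["negative"])
            else "negative>=positive",
        }
    else:
        empty = [c for c in ("positive", "negative") if not dists[c]]
        report["mwu"] = {"skipped": f"empty class(es): {', '.join(empty)}"}
    return report


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_count_table(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value for sample sizes
    (n, m) without ties; classic recursion c(n,m,u) = c(n-1,m,u-m) +
    c(n,m-1,u)."""
    if n == 0 or m == 0:
        return (1,)
    a = _u_count_table(n - 1, m)
    b = _u_count_table(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u in range(size):
        if u - m >= 0 and u - m < len(a):
            out[u] += a[u - m]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U statistic for x vs y and its p-value.

    The p-value is exact (by enumeration of the null U distribution) when
    n_x + n_y <= ``exact_max_n`` and there are no ties; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _rankdata_average(combined)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0

    has_ties = len(np.unique(combined)) < combined.size
    if not has_ties and n + m <= exact_max_n:
        counts = _u_count_table(n, m)
        total = math.comb(n + m, n)
        u_int = int(round(u_x))
        cdf_le = sum(counts[: u_int + 1]) / total
        sf_ge = sum(counts[u_int:]) / total
        if alternative == "less":
            p = cdf_le
        elif alternative == "greater":
            p = sf_ge
        else:
            p = min(1.0, 2.0 * min(cdf_le, sf_ge))
        return float(u_x), float(p)

    # normal approximation with tie correction and continuity correction
    mu = n * m / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n + m) * (n + m - 1))
    sigma2 = n * m / 12.0 * ((n + m + 1) - tie_term)
    if sigma2 <= 0:
        return float(u_x), 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u_x - mu) - 0.5) / sigma
        p = 2.0 * _norm_sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_x - mu - 0.5) / sigma
        p = _norm_sf(z)
    else:
        z = (u_x - mu + 0.5) / sigma
        p = 1.0 - _norm_sf(z)
    return float(u_x), float(min(p, 1.0))


def _rankdata_average(a: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.size, dtype=float)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# per-TF summaries


def tf_activity_correlation(
    eregulons: ERegulonTable, peak_results: pd.DataFrame
) -> dict[str, float]:
    """Mean axis correlation of each TF's distinct binding-site peaks."""
    r_of = dict(zip(peak_results["feature"], peak_results["r"]))
    out: dict[str, float] = {}
    for tf, group in eregulons.df.groupby("tf"):
        rs = [r_of[p] for p in group["peak"].unique() if p in r_of]
        if not rs:
            warnings.warn(f"TF {tf!r} has no peaks with axis results; omitted")
            continue
        out[tf] = float(np.mean(rs))
    return out


def tf_target_expression_correlation(
    eregulons: ERegulonTable, gene_results: pd.DataFrame
) -> dict[str, float]:
    """Mean expression axis correlation of each TF's distinct target genes."""
    r_of = dict(zip(gene_results["feature"], gene_results["r"]))
    out: dict[str, float] = {}
    for tf, group in eregulons.df.groupby("tf"):
        rs = [r_of[g] for g in group["target_gene"].unique() if g in r_of]
        if not rs:
            warnings.warn(f"TF {tf!r} has no targets with axis results; omitted")
            continue
        out[tf] = float(np.mean(rs))
    return out


def summarize_tfs(
    eregulons: ERegulonTable,
    peak_results: pd.DataFrame,
    gene_results: pd.DataFrame,
) -> list[TFSummary]:
    """Per-TF activity, target-expression and own-expression correlations."""
    activity = tf_activity_correlation(eregulons, peak_results)
    targets = tf_target_expression_correlation(eregulons, gene_results)
    tf_expr = dict(zip(gene_results["feature"], gene_results["r"]))
    out = []
    for tf, group in eregulons.df.groupby("tf"):
        if tf not in activity or tf not in targets:
            continue
        out.append(
            TFSummary(
                tf=tf,
                activity_r=activity[tf],
                target_expr_r=targets[tf],
                tf_expr_r=float(tf_expr.get(tf, np.nan)),
                n_sites=group["peak"].nunique(),
                n_targets=group["target_gene"].nunique(),
            )
        )
    return out


def export_network(
    eregulons: ERegulonTable,
    classes: pd.DataFrame,
    gene_results: pd.DataFrame,
    tf_summaries: list[TFSummary],
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Annotated TF -> peak -> gene edge list, optionally gene-subsetted."""
    class_of = dict(zip(classes["peak"], classes["sign_class"]))
    gene_r = dict(zip(gene_results["feature"], gene_results["r"]))
    activity = {s.tf: s.activity_r for s in tf_summaries}
    df = eregulons.df.copy()
    if gene_subset is not None:
        df = df[df["target_gene"].isin(set(gene_subset))]
        if df.empty:
            warnings.warn("gene subset leaves no edges")
    df["peak_sign_class"] = df["peak"].map(class_of)
    df["gene_axis_r"] = df["target_gene"].map(gene_r)
    df["tf_activity_r"] = df["tf"].map(activity)
    cols = ["tf", "peak", "target_gene", "strength", "peak_sign_class",
            "gene_axis_r", "tf_activity_r"]
    return df[cols].reset_index(drop=True)
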