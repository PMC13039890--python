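"""Axis-correlation screening with FDR control and sign classification.

Each feature's abundance (log2 CPM by default, computed upstream) is
correlated against the integer order indices of its samples' regions
along an ordered cortical axis. Raw two-sided p-values are adjusted with
Benjamini-Hochberg over the post-filtering background, and features are
classified positive / negative / null against published thresholds:
genes |r| > 0.7 with q < 0.01, peaks |r| > 0.5 with q < 0.05.

Both Pearson and Spearman coefficients are supported; Pearson is the
default, matching the thresholds as stated alongside it, and the method
used is stamped into every result row. ``sample_mode`` chooses whether
each (region, donor) sample is one observation (``per_sample``, default)
or values are first averaged within region (``region_mean``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cortaxis.io import AxisSpec, ValidationError
from cortaxis.pseudobulk import (
    FilterParams,
    PseudobulkMatrix,
    cpm_transform,
    filter_by_expression,
)

#: published screen thresholds
GENE_THRESHOLDS: "AxisThresholds"
PEAK_THRESHOLDS: "AxisThresholds"


@dataclass(frozen=True)
class AxisThresholds:
    """Significance cutoffs for calling a feature axis-correlated."""

    min_abs_r: float
    max_q: float

    def __post_init__(self) -> None:
        if not 0 < self.min_abs_r < 1:
            raise ValidationError("min_abs_r must be in (0, 1)")
        if not 0 < self.max_q < 1:
            raise ValidationError("max_q must be in (0, 1)")


GENE_THRESHOLDS = AxisThresholds(min_abs_r=0.7, max_q=0.01)
PEAK_THRESHOLDS = AxisThresholds(min_abs_r=0.5, max_q=0.05)


def correlate_axis(
    abundance: pd.DataFrame,
    sample_regions: Sequence[str],
    axis: AxisSpec,
    method: str = "pearson",
    sample_mode: str = "per_sample",
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate each feature against region order indices.

    Parameters
    ----------
    abundance
        features x samples matrix (rows indexed by feature id).
    sample_regions
        Region label of each column; every region must be on the axis.
    method
        "pearson" or "spearman".
    sample_mode
        "per_sample": each column is one observation. "region_mean":
        columns are first averaged within region, so n = #regions.

    Returns
    -------
    (results, excluded)
        ``results`` has columns feature, r, p; ``excluded`` lists features
        dropped because their abundance had zero variance (correlation
        undefined).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    if sample_mode not in ("per_sample", "region_mean"):
        raise ValidationError(f"unknown sample_mode {sample_mode!r}")
    order = axis.order_indices(sample_regions)

    values = abundance.to_numpy(dtype=float)
    if sample_mode == "region_mean":
        uniq = np.unique(order)
        values = np.column_stack([values[:, order == o].mean(axis=1) for o in uniq])
        x = uniq.astype(float)
    else:
        x = order.astype(float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need >= 3 distinct order indices on the axis")

    if method == "spearman":
        # rank-transform, then Pearson on ranks (= Spearman with p from
        # the t approximation, matching scipy.stats.spearmanr)
        values = stats.rankdata(values, axis=1)
        x = stats.rankdata(x)

    keep = values.std(axis=1) > 0
    excluded = [f for f, k in zip(abundance.index, keep) if not k]
    values = values[keep]
    feats = [f for f, k in zip(abundance.index, keep) if k]

    n = len(x)
    xc = x - x.mean()
    vc = values - values.mean(axis=1, keepdims=True)
    r = (vc @ xc) / (np.linalg.norm(vc, axis=1) * np.linalg.norm(xc))
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from the t distribution with n-2 df
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r * r, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.minimum(p, 1.0)
    return pd.DataFrame({"feature": feats, "r": r, "p": p}), excluded


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q for the i-th smallest p is min over j >= i of m * p_(j) / j,
    clipped at 1, returned in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_features(
    results: pd.DataFrame,
    thresholds: AxisThresholds,
    axis_name: str = "",
    subclass: str = "",
    method: str = "pearson",
    sample_mode: str = "per_sample",
) -> pd.DataFrame:
    """Attach BH q-values and positive/negative/null sign classes.

    ``results`` must carry feature, r, p (q is computed here if absent)
    over the full post-filtering background, so the BH adjustment spans
    exactly one (subclass, axis, modality) screen.
    """
    out = results.copy()
    if "q" not in out.columns:
        out["q"] = adjust_bh(out["p"])
    sign = np.where(
        (out["r"] > thresholds.min_abs_r) & (out["q"] < thresholds.max_q), "positive",
        np.where(
            (out["r"] < -thresholds.min_abs_r) & (out["q"] < thresholds.max_q),
            "negative", "null",
        ),
    )
    out["sign_class"] = sign
    out["axis"] = axis_name
    out["subclass"] = subclass
    out["method"] = method
    out["sample_mode"] = sample_mode
    return out


def screen_axis(
    pb: PseudobulkMatrix,
    axis: AxisSpec,
    thresholds: AxisThresholds = GENE_THRESHOLDS,
    filter_params: FilterParams | None = FilterParams(),
    method: str = "pearson",
    sample_mode: str = "per_sample",
    log: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full screen: filter -> log2 CPM -> correlate -> BH -> classify.

    Pass ``filter_params=None`` to skip expression filtering. Returns one
    row per retained, non-constant feature with columns feature, r, p, q,
    sign_class, axis, subclass, method, sample_mode.
    """
    if filter_params is not None:
        kept = filter_by_expression(pb, filter_params)
        pb = pb.subset_features(kept)
    abundance = cpm_transform(pb, log=log, pseudocount=pseudocount)
    results, _ = correlate_axis(abundance, pb.sample_regions, axis,
                                method=method, sample_mode=sample_mode)
    return classify_features(results, thresholds, axis_name=axis.name,
                             subclass=pb.subclass, method=method,
                             sample_mode=sample_mode)


def summarize_unique(per_subclass: Mapping[str, set[str]]) -> pd.DataFrame:
    """Total and subclass-unique correlated-feature counts.

    A feature is unique to a subclass if it appears in exactly one
    subclass's correlated set.
    """
    counts: dict[str, int] = {}
    for features in per_subclass.values():
        for f in features:
            counts[f] = counts.get(f, 0) + 1
    rows = [
        {
            "subclass": sc,
            "total": len(features),
            "unique": sum(1 for f in features if counts[f] == 1),
        }
        for sc, features in per_subclass.items()
    ]
    return pd.DataFrame(rows, columns=["subclass", "total", "unique"])
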