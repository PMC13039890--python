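"""Pseudobulk aggregation, down-sampling, expression filtering and CPM.

Within one cell subclass, single-cell counts are summed into one sample
per (region, donor) pair; each donor is a biological replicate of its
region. Lowly expressed features are removed with a CPM rule derived from
``min_count`` and the median library size, evaluated against the smallest
region group, plus a total-count floor — the behavior of the standard
``filterByExpr``-style filter with default gene parameters min_count=10 /
min_total_count=15 and peak parameters 5 / 15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from cortaxis.io import CellTable, CountMatrix, ValidationError

#: published filter defaults for gene expression and peak coverage
GENE_FILTER_DEFAULTS = {"min_count": 10, "min_total_count": 15}
PEAK_FILTER_DEFAULTS = {"min_count": 5, "min_total_count": 15}


@dataclass(frozen=True)
class FilterParams:
    min_count: int = 10
    min_total_count: int = 15

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_total_count < 0:
            raise ValidationError("filter parameters must be >= 0")


@dataclass
class PseudobulkMatrix:
    """Feature x sample count matrix; a sample is one (region, donor) pair."""

    features: list[str]
    samples: list[tuple[str, str]]  # (region, donor)
    counts: np.ndarray
    subclass: str

    def __post_init__(self) -> None:
        self.features = list(self.features)
        self.samples = [tuple(s) for s in self.samples]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValidationError("pseudobulk shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate (region, donor) sample")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative pseudobulk count")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def sample_regions(self) -> list[str]:
        return [r for r, _ in self.samples]

    def subset_features(self, feature_ids: list[str]) -> "PseudobulkMatrix":
        idx = {f: i for i, f in enumerate(self.features)}
        rows = [idx[f] for f in feature_ids]
        return PseudobulkMatrix(feature_ids, self.samples, self.counts[rows], self.subclass)

    def to_tsv(self, path, samples_path) -> None:
        cols = [f"{r}|{d}" for r, d in self.samples]
        pd.DataFrame(self.counts, index=pd.Index(self.features, name="feature"),
                     columns=cols).to_csv(path, sep="\t")
        pd.DataFrame(self.samples, columns=["region", "donor"]).to_csv(
            samples_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, samples_path, subclass: str) -> "PseudobulkMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(samples_path, sep="\t", dtype=str)
        samples = [tuple(row) for row in meta[["region", "donor"]].itertuples(index=False)]
        return cls(list(df.index), samples, df.to_numpy(), subclass)


def aggregate_pseudobulk(counts: CountMatrix, cells: CellTable,
                         subclass: str) -> PseudobulkMatrix:
    """Sum counts over the subclass's cells per (region, donor).

    (region, donor) pairs with no cells of the subclass produce no column.
    """
    meta = cells.df
    mask = meta["subclass"] == subclass
    if not mask.any():
        raise ValidationError(f"subclass {subclass!r} absent from cell table")
    sub = meta[mask]
    col_of = {c: j for j, c in enumerate(counts.cells)}
    missing = [c for c in sub.index if c not in col_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells of subclass {subclass!r} not in count matrix "
            f"(first: {missing[0]!r})"
        )
    groups = sub.groupby(["region", "donor"], observed=True, sort=True).groups
    samples: list[tuple[str, str]] = []
    cols = []
    mat = counts.counts.tocsc() if sp.issparse(counts.counts) else np.asarray(counts.counts)
    for (region, donor), cell_ids in groups.items():
        j = [col_of[c] for c in cell_ids]
        block = mat[:, j]
        col = np.asarray(block.sum(axis=1)).ravel()
        samples.append((str(region), str(donor)))
        cols.append(col)
    return PseudobulkMatrix(counts.features, samples,
                            np.column_stack(cols).astype(np.int64), subclass)


def downsample_cells(cells: CellTable, subclass: str, n_per_region: int,
                     seed: int) -> tuple[CellTable, dict[str, int]]:
    """Keep at most ``n_per_region`` cells of the subclass per region.

    Sampling is uniform without replacement and deterministic given seed.
    Regions with fewer cells keep all of them; the returned dict reports
    the shortfall per region (0 where the quota was met).
    """
    if n_per_region < 1:
        raise ValidationError("n_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    meta = cells.df
    mask = meta["subclass"] == subclass
    keep_ids: list[str] = []
    shortfall: dict[str, int] = {}
    for region in sorted(meta.loc[mask, "region"].unique()):
        ids = meta.index[mask & (meta["region"] == region)].to_numpy()
        if len(ids) > n_per_region:
            ids = rng.choice(ids, size=n_per_region, replace=False)
            shortfall[region] = 0
        else:
            shortfall[region] = n_per_region - len(ids)
        keep_ids.extend(ids)
    out = CellTable(meta.loc[sorted(keep_ids)].copy())
    return out, shortfall


def filter_by_expression(pb: PseudobulkMatrix, params: FilterParams,
                         group_labels: list[str] | None = None) -> list[str]:
    """Feature ids passing the CPM + total-count expression filter.

    A feature is kept iff its CPM exceeds ``min_count / median(library
    sizes) * 1e6`` in at least n_min samples — n_min being the size of the
    smallest region group — and its total count is >= ``min_total_count``.
    Order follows the input feature order.
    """
    if pb.counts.shape[1] < 2:
        raise ValidationError("need at least 2 pseudobulk samples to filter")
    lib = pb.library_sizes.astype(float)
    if np.all(lib == 0):
        raise ValidationError("all library sizes are zero")
    if group_labels is None:
        group_labels = pb.sample_regions
    n_min = pd.Series(group_labels).value_counts().min()
    cpm_cutoff = params.min_count / np.median(lib) * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = np.where(lib > 0, pb.counts / lib * 1e6, 0.0)
    keep = ((cpm > cpm_cutoff).sum(axis=1) >= n_min) & (
        pb.counts.sum(axis=1) >= params.min_total_count
    )
    return [f for f, k in zip(pb.features, keep) if k]


def cpm_transform(pb: PseudobulkMatrix, log: bool = True,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Counts-per-million abundance, optionally log2(CPM + pseudocount).

    Returns a features x samples DataFrame (columns are ``region|donor``).
    """
    lib = pb.library_sizes.astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        r, d = pb.samples[zero[0]]
        raise ValidationError(f"sample ({r}, {d}) has zero library size")
    cpm = pb.counts / lib * 1e6
    if log:
        cpm = np.log2(cpm + pseudocount)
    return pd.DataFrame(cpm, index=pd.Index(pb.features, name="feature"),
                        columns=[f"{r}|{d}" for r, d in pb.samples])


def normalize_feature_counts(counts_per_region: dict[str, int],
                             background_size: int) -> dict[str, float]:
    """Fraction of the filtered background that is differential, per region."""
    if background_size <= 0:
        raise ValidationError("background_size must be > 0")
    return {r: c / background_size for r, c in counts_per_region.items()}
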