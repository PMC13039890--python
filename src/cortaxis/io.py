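"""File formats and shared domain types.

Single-cell count matrices arrive as MatrixMarket (MTX) files with
one-column sidecars of feature and cell ids, or as dense TSV with feature
ids in the first column. Cell metadata is CSV; eRegulon tables (TF ->
enhancer peak -> target gene) are TSV with BED-style 0-based half-open
peak coordinates. Peak ids are canonicalized as ``chrom:start-end``.

Region and subclass labels are opaque strings throughout; any biological
ordering of regions lives in :class:`AxisSpec`, never in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

RESULT_SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AxisSpec:
    """An ordered list of region labels defining an axis.

    The order index of a region is its 0-based position in
    ``ordered_regions``; correlation screens regress abundance against
    these indices.
    """

    name: str
    ordered_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        regions = tuple(self.ordered_regions)
        object.__setattr__(self, "ordered_regions", regions)
        if len(regions) < 3:
            raise ValidationError(f"axis {self.name!r} needs >= 3 regions, got {len(regions)}")
        if len(set(regions)) != len(regions):
            raise ValidationError(f"axis {self.name!r} has duplicate regions")

    def order_index(self, region: str) -> int:
        try:
            return self.ordered_regions.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not on axis {self.name!r}") from None

    def order_indices(self, regions: Sequence[str]) -> np.ndarray:
        """Order indices for a sequence of region labels."""
        lookup = {r: i for i, r in enumerate(self.ordered_regions)}
        try:
            return np.array([lookup[r] for r in regions], dtype=int)
        except KeyError as exc:
            raise ValidationError(
                f"region {exc.args[0]!r} is not on axis {self.name!r}"
            ) from None


@dataclass(frozen=True)
class PeakInterval:
    """A genomic interval in BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not self.start < self.end:
            raise ValidationError(
                f"peak start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, peak_id: str) -> "PeakInterval":
        chrom, _, span = peak_id.rpartition(":")
        start_s, _, end_s = span.partition("-")
        if not chrom or not start_s or not end_s:
            raise FormatError(f"malformed peak id {peak_id!r}")
        return cls(chrom, int(start_s), int(end_s))


@dataclass
class CellTable:
    """Per-cell metadata: subclass, region, donor, optional x/y in um.

    Wraps a DataFrame indexed by unique ``cell_id``. The x/y columns are
    either both present or both absent.
    """

    df: pd.DataFrame

    REQUIRED = ("subclass", "region", "donor")

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "cell_id":
            if "cell_id" in df.columns:
                df = df.set_index("cell_id")
            else:
                raise FormatError("cell table needs a cell_id column or index")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"cell table missing mandatory column(s): {missing}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate cell_id {dup!r}")
        has_x, has_y = "x" in df.columns, "y" in df.columns
        if has_x != has_y:
            raise FormatError("x and y must both be present or both absent")
        self.df = df

    @property
    def cell_ids(self) -> pd.Index:
        return self.df.index

    @property
    def has_coordinates(self) -> bool:
        return "x" in self.df.columns

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, cell_ids: Sequence[str]) -> "CellTable":
        return CellTable(self.df.loc[list(cell_ids)].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path)


@dataclass
class CountMatrix:
    """Feature x cell matrix of non-negative integer counts.

    ``counts`` may be dense or scipy sparse; feature ids are unique gene
    symbols or canonical peak ids.
    """

    features: list[str]
    cells: list[str]
    counts: "sp.spmatrix | np.ndarray"

    def __post_init__(self) -> None:
        self.features = list(self.features)
        self.cells = list(self.cells)
        shape = self.counts.shape
        if shape != (len(self.features), len(self.cells)):
            raise FormatError(
                f"count matrix shape {shape} does not match "
                f"{len(self.features)} features x {len(self.cells)} cells"
            )
        if len(set(self.features)) != len(self.features):
            raise ValidationError("duplicate feature ids")
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and np.min(data) < 0:
            raise ValidationError("negative count entry")
        if data.size and not np.all(np.equal(np.mod(data, 1), 0)):
            raise ValidationError("counts must be integers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def to_files(self, matrix_path: str | Path, features_path: str | Path,
                 cells_path: str | Path) -> None:
        """Write MTX + one-id-per-line sidecars."""
        mat = self.counts if sp.issparse(self.counts) else sp.coo_matrix(self.counts)
        scipy.io.mmwrite(str(matrix_path), mat)
        Path(features_path).write_text("\n".join(self.features) + "\n")
        Path(cells_path).write_text("\n".join(self.cells) + "\n")


@dataclass
class ERegulonTable:
    """TF -> enhancer peak -> target gene triplets with a regulatory strength.

    Stored as a DataFrame with columns tf, peak (canonical id), target_gene,
    strength. Triplets are unique.
    """

    df: pd.DataFrame

    COLUMNS = ("tf", "peak", "target_gene", "strength")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"eRegulon table missing column(s): {missing}")
        dup = self.df.duplicated(subset=["tf", "peak", "target_gene"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise ValidationError(
                f"duplicate eRegulon triplet ({row.tf}, {row.peak}, {row.target_gene})"
            )
        if not np.isfinite(self.df["strength"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite strength value")
        self.df = self.df.reset_index(drop=True)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.df["tf"].unique())

    @property
    def peaks(self) -> list[str]:
        return sorted(self.df["peak"].unique())

    @property
    def target_genes(self) -> list[str]:
        return sorted(self.df["target_gene"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        peaks = out["peak"].map(PeakInterval.from_id)
        out["chrom"] = [p.chrom for p in peaks]
        out["start"] = [p.start for p in peaks]
        out["end"] = [p.end for p in peaks]
        out[["tf", "chrom", "start", "end", "target_gene", "strength"]].to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# loaders


def load_counts(matrix_path: str | Path, features_path: str | Path,
                cells_path: str | Path) -> CountMatrix:
    """Load a count matrix from MTX (+ id sidecars) or dense TSV.

    For dense TSV, ``matrix_path`` holds feature ids in column 1 and cell
    ids in the header; the sidecar paths are still read and checked.
    """
    matrix_path = Path(matrix_path)
    features = _read_ids(features_path)
    cells = _read_ids(cells_path)
    if matrix_path.suffix == ".mtx" or matrix_path.name.endswith(".mtx.gz"):
        try:
            mat = scipy.io.mmread(str(matrix_path)).tocsr()
        except Exception as exc:
            raise FormatError(f"cannot parse MTX file {matrix_path}: {exc}") from exc
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if list(df.columns) != cells:
            raise FormatError(
                f"cell ids in {matrix_path} header do not match sidecar {cells_path}"
            )
        if list(df.index) != features:
            raise FormatError(
                f"feature ids in {matrix_path} do not match sidecar {features_path}"
            )
        mat = df.to_numpy()
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{matrix_path} declares {mat.shape[0]} rows but sidecar "
            f"{features_path} lists {len(features)} features"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"{matrix_path} declares {mat.shape[1]} columns but sidecar "
            f"{cells_path} lists {len(cells)} cells"
        )
    return CountMatrix(features, cells, mat)


def _read_ids(path: str | Path) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not ids:
        raise FormatError(f"empty id sidecar {path}")
    return ids


def load_cell_table(path: str | Path, regions: Sequence[str]) -> tuple[CellTable, int]:
    """Load a cell CSV, dropping rows whose region is not configured.

    Returns the table and the number of rejected rows.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise FormatError(f"{path} has no cell_id column")
    table = CellTable(df)  # validates columns/coords/duplicates first
    keep = table.df["region"].isin(set(regions))
    n_rejected = int((~keep).sum())
    return CellTable(table.df[keep].copy()), n_rejected


def load_eregulons(path: str | Path) -> ERegulonTable:
    """Load a TSV of (tf, chrom, start, end, target_gene, strength) rows."""
    df = pd.read_csv(path, sep="\t")
    required = ["tf", "chrom", "start", "end", "target_gene", "strength"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing column(s): {missing}")
    peak_ids = []
    for i, row in df.iterrows():
        try:
            peak_ids.append(PeakInterval(str(row.chrom), int(row.start), int(row.end)).peak_id)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    out = pd.DataFrame(
        {
            "tf": df["tf"].astype(str),
            "peak": peak_ids,
            "target_gene": df["target_gene"].astype(str),
            "strength": df["strength"].astype(float),
        }
    )
    return ERegulonTable(out)


# ---------------------------------------------------------------------------
# result writers


def write_result_tsv(df: pd.DataFrame, path: str | Path, **metadata: str) -> None:
    """Write a results table as UTF-8 TSV with '#key=value' header lines."""
    path = Path(path)
    header = [f"#schema_version={RESULT_SCHEMA_VERSION}"]
    header += [f"#{k}={v}" for k, v in sorted(metadata.items())]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_result_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a result TSV written by :func:`write_result_tsv`."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                meta[key] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return df, meta


def write_result_json(obj: dict, path: str | Path) -> None:
    payload = {"schema_version": RESULT_SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def write_bed(peaks: Sequence[str], path: str | Path) -> None:
    """Export canonical peak ids as a 3-column BED file."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in peaks:
            p = PeakInterval.from_id(pid)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
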