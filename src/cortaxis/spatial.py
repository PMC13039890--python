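"""Laminar depth profiles and cell-neighborhood composition.

Cortical depth is normalized per cell as d_pial / (d_pial + d_wm), the
Euclidean distances to the nearest points of the pial and white-matter
landmark polylines, giving 0 at the pia and 1 at the white matter.
Subclass density along depth is a Gaussian KDE evaluated on 1000 equally
spaced units and renormalized on the bounded grid. Neighborhoods are
closed 200-um balls around up to 100 query cells per subclass and region
(all cells when fewer are available), with the query cell excluded;
compositions can be normalized against the region's overall subclass
proportions to give enrichment ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import cKDTree

from cortaxis.io import CellTable, ValidationError

DEPTH_GRID_SIZE = 1000
NEIGHBOR_RADIUS_UM = 200.0
N_QUERY_CELLS = 100


@dataclass
class DepthProfile:
    """KDE of a subclass's normalized laminar depth in one region."""

    subclass: str
    region: str
    grid: np.ndarray
    density: np.ndarray
    n_cells: int
    undefined: bool = False

    def argmax_depth(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class NeighborhoodProfile:
    """Average subclass composition around a query subclass in one region."""

    query_subclass: str
    region: str
    raw_proportions: dict[str, float]
    normalized_proportions: dict[str, float]
    n_query_cells: int


def normalize_depth(cells: CellTable, pial_boundary: np.ndarray,
                    wm_boundary: np.ndarray) -> pd.Series:
    """Per-cell normalized depth d_pial / (d_pial + d_wm), clipped to [0, 1]."""
    if not cells.has_coordinates:
        raise ValidationError("cell table has no coordinates")
    pial = np.asarray(pial_boundary, dtype=float)
    wm = np.asarray(wm_boundary, dtype=float)
    if len(pial) == 0 or len(wm) == 0:
        raise ValidationError("empty boundary polyline")
    pts = shapely.points(cells.df[["x", "y"]].to_numpy(dtype=float))
    d_p = shapely.distance(pts, _as_line(pial))
    d_w = shapely.distance(pts, _as_line(wm))
    total = d_p + d_w
    if np.any(total == 0):
        raise ValidationError(
            "cell lies on both boundaries (pial and white-matter landmarks intersect)"
        )
    depth = np.clip(d_p / total, 0.0, 1.0)
    return pd.Series(depth, index=cells.cell_ids, name="depth")


def _as_line(poly: np.ndarray):
    if len(poly) == 1:
        return shapely.points(poly[0])
    return shapely.linestrings(poly)


def depth_density(depths, grid_size: int = DEPTH_GRID_SIZE,
                  bandwidth: float | str = "scott",
                  subclass: str = "", region: str = "") -> DepthProfile:
    """Gaussian KDE of depths on a bounded [0, 1] grid, renormalized to
    integrate to 1.

    Fewer than two distinct depth values leave the KDE undefined; the
    profile is returned flagged so correlation stages can exclude it.
    """
    depths = np.asarray(list(depths), dtype=float)
    grid = np.linspace(0.0, 1.0, grid_size)
    if depths.size < 2 or np.ptp(depths) == 0:
        return DepthProfile(subclass, region, grid, np.zeros(grid_size),
                            n_cells=depths.size, undefined=True)
    kde = stats.gaussian_kde(depths, bw_method=bandwidth)
    density = kde(grid)
    delta = grid[1] - grid[0]
    density = density / (density.sum() * delta)
    return DepthProfile(subclass, region, grid, density, n_cells=depths.size)


def cross_region_profile_correlation(
    profiles: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Region x region Pearson correlation matrix of profile vectors.

    Constant vectors give NaN rows/columns (correlation undefined);
    diagonal entries are exactly 1.
    """
    regions = list(profiles)
    if len(regions) < 2:
        raise ValidationError("need >= 2 regions")
    lengths = {len(np.asarray(v)) for v in profiles.values()}
    if len(lengths) != 1:
        raise ValidationError(f"profile length mismatch: {sorted(lengths)}")
    mat = np.full((len(regions), len(regions)), np.nan)
    arrays = [np.asarray(profiles[r], dtype=float) for r in regions]
    constant = [np.ptp(a) == 0 for a in arrays]
    for i in range(len(regions)):
        for j in range(i, len(regions)):
            if i == j:
                mat[i, j] = 1.0
            elif not constant[i] and not constant[j]:
                mat[i, j] = mat[j, i] = float(np.corrcoef(arrays[i], arrays[j])[0, 1])
    return pd.DataFrame(mat, index=regions, columns=regions)


def neighborhood_composition(
    cells: CellTable,
    query_subclass: str,
    radius_um: float = NEIGHBOR_RADIUS_UM,
    n_query: int = N_QUERY_CELLS,
    seed: int = 0,
) -> dict[str, NeighborhoodProfile]:
    """Per-region average subclass composition within a closed ball.

    Up to ``n_query`` query cells of the query subclass are sampled
    without replacement per region (all of them when fewer exist). For
    each query, neighbors are all other cells within ``radius_um``
    (boundary included); the region profile averages per-query proportion
    vectors over queries with at least one neighbor. Regions without the
    query subclass are omitted with a warning.
    """
    if not cells.has_coordinates:
        raise ValidationError("cell table has no coordinates")
    if radius_um <= 0:
        raise ValidationError("radius must be > 0")
    rng = np.random.default_rng(seed)
    meta = cells.df
    subclasses = sorted(meta["subclass"].unique())
    out: dict[str, NeighborhoodProfile] = {}
    for region in sorted(meta["region"].unique()):
        in_region = meta[meta["region"] == region]
        query_ids = in_region.index[in_region["subclass"] == query_subclass].to_numpy()
        if len(query_ids) == 0:
            warnings.warn(
                f"query subclass {query_subclass!r} absent in region {region!r}; omitted"
            )
            continue
        if len(query_ids) > n_query:
            query_ids = rng.choice(query_ids, size=n_query, replace=False)
        xy = in_region[["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        pos_of = {cid: i for i, cid in enumerate(in_region.index)}
        labels = in_region["subclass"].to_numpy()
        vectors = []
        for qid in query_ids:
            qi = pos_of[qid]
            idx = tree.query_ball_point(xy[qi], r=radius_um)
            idx = [i for i in idx if i != qi]  # closed ball, self excluded
            if not idx:
                continue
            counts = pd.Series(labels[idx]).value_counts()
            vec = counts.reindex(subclasses, fill_value=0).to_numpy(dtype=float)
            vectors.append(vec / vec.sum())
        if not vectors:
            warnings.warn(
                f"all queries in region {region!r} had zero neighbors; omitted"
            )
            continue
        mean_vec = np.mean(vectors, axis=0)
        out[region] = NeighborhoodProfile(
            query_subclass=query_subclass,
            region=region,
            raw_proportions=dict(zip(subclasses, mean_vec.tolist())),
            normalized_proportions={},
            n_query_cells=len(query_ids),
        )
    return out


def regional_composition(cells: CellTable, region: str) -> dict[str, float]:
    """Fraction of all called cells per subclass in one region."""
    sub = cells.df[cells.df["region"] == region]["subclass"]
    if sub.empty:
        raise ValidationError(f"no cells in region {region!r}")
    frac = sub.value_counts(normalize=True)
    return frac.to_dict()


def normalize_neighborhood(
    profile: NeighborhoodProfile, region_composition: dict[str, float]
) -> NeighborhoodProfile:
    """Divide raw proportions by the region's overall subclass fractions.

    The result is an enrichment ratio: 1 means the neighborhood matches
    the regional composition.
    """
    total = sum(region_composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"region composition sums to {total}, not 1")
    normalized: dict[str, float] = {}
    for sc, raw in profile.raw_proportions.items():
        comp = region_composition.get(sc, 0.0)
        if raw > 0 and comp == 0:
            raise ValidationError(
                f"subclass {sc!r} observed among neighbors but has zero "
                "regional composition"
            )
        normalized[sc] = raw / comp if comp > 0 else 0.0
    return NeighborhoodProfile(
        query_subclass=profile.query_subclass,
        region=profile.region,
        raw_proportions=profile.raw_proportions,
        normalized_proportions=normalized,
        n_query_cells=profile.n_query_cells,
    )
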