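"""Synthetic single-cell, spatial and eRegulon data with known structure.

The generator emulates the design of a nine-region, multi-donor cortical
survey: per-cell gene (or peak) counts are negative-binomial with
mean = library_scale * 2^(baseline + sign * slope * order_index + donor
effect) and variance mu + dispersion * mu^2, where order_index is the
region's position on an ordered axis. A configurable fraction of features
carries a monotone trend (sign split evenly, ties to positive); donor
effects are additive on the log2 scale and shared across features within
a donor, so they mimic replicate structure without gene-specific
confounding. Spatial maps place cells by a Poisson point process with
laminar (truncated-normal) depth profiles between pial and white-matter
landmark polylines. eRegulon simulations propagate each TF's activity
sign to its enhancers' accessibility and its target genes' expression, so
concordance holds by construction.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cortaxis.io import AxisSpec, CellTable, CountMatrix, ERegulonTable, PeakInterval

DEFAULT_REGIONS = ("ACC", "DFC", "FI", "M1C", "S1C", "MTG", "A1C", "AnG", "V1C")


class ParameterError(ValueError):
    """A simulation parameter is out of its valid range."""


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters for the synthetic generators.

    Defaults emulate the survey design: 9 cortical regions, 6 donors,
    negative-binomial counts with moderate overdispersion. ``trend_slope``
    is the log2-scale change per region step; ``donor_sd`` the log2 SD of
    the shared per-donor offset. ``baseline_log2_mean/sd`` parameterize
    the log-normal per-cell baseline expression (median ~0.5 counts per
    gene per cell, a typical snRNA-seq depth at ~2,000 genes).
    """

    n_regions: int = 9
    n_donors: int = 6
    subclasses: tuple[str, ...] = ("L2/3 IT",)
    genes_per_subclass: int = 2000
    cells_per_group: int = 300
    frac_trend: float = 0.05
    trend_slope: float = 0.3
    nb_dispersion: float = 0.1
    donor_sd: float = 0.2
    seed: int = 0
    library_scale: float = 1.0
    baseline_log2_mean: float = -1.0
    baseline_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_trend <= 1:
            raise ParameterError("frac_trend must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.n_regions < 3:
            raise ParameterError("n_regions must be >= 3")
        if self.n_donors < 2:
            raise ParameterError("n_donors must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth record emitted alongside every simulation."""

    #: rows of (feature, subclass, sign in {+1,-1}, slope)
    trend_features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature", "subclass", "sign", "slope"]
        )
    )
    #: TF -> +1 / -1 activity sign
    tf_signs: dict[str, int] = field(default_factory=dict)
    #: subclass -> region -> (depth mean, depth SD)
    layer_assignments: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def trend_set(self, subclass: str | None = None) -> set[str]:
        df = self.trend_features
        if subclass is not None:
            df = df[df["subclass"] == subclass]
        return set(df["feature"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trend_features": self.trend_features.to_dict(orient="records"),
            "tf_signs": self.tf_signs,
            "layer_assignments": {
                sc: {r: list(ms) for r, ms in regions.items()}
                for sc, regions in self.layer_assignments.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# counts


def _assign_trend_signs(rng: np.random.Generator, n_features: int,
                        frac_trend: float) -> np.ndarray:
    """Per-feature trend signs: k = round(frac * n) trending, split evenly
    between +1 and -1 with the odd one going to +."""
    k = int(round(frac_trend * n_features))
    if 0 < k < 2:
        raise ParameterError(
            f"frac_trend * n_features = {k} < 2: cannot assign both signs"
        )
    signs = np.zeros(n_features, dtype=int)
    if k:
        chosen = rng.choice(n_features, size=k, replace=False)
        n_pos = k - k // 2  # ties to +
        signs[chosen[:n_pos]] = 1
        signs[chosen[n_pos:]] = -1
    return signs


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
             n_cells: int) -> np.ndarray:
    """NB counts with variance mu + dispersion * mu^2, one column per cell."""
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p[:, None],
                                 size=(mu.size, n_cells)).astype(np.int32)


def simulate_counts(
    params: SimulationParams, axis: AxisSpec
) -> tuple[CountMatrix, CellTable, SyntheticTruth]:
    """Simulate a genes x cells count matrix with injected axis trends.

    One block of ``cells_per_group`` cells is drawn per (subclass, region,
    donor). Trend genes are assigned independently per subclass; trends
    are centered on the middle of the axis so a trending gene's average
    abundance matches its baseline.
    """
    regions = axis.ordered_regions[: params.n_regions]
    if len(regions) < params.n_regions:
        raise ParameterError(
            f"axis {axis.name!r} covers {len(regions)} regions, "
            f"params request {params.n_regions}"
        )
    rng = np.random.default_rng(params.seed)
    n_genes = params.genes_per_subclass
    genes = [f"G{i:05d}" for i in range(n_genes)]
    donors = [f"D{j + 1}" for j in range(params.n_donors)]
    donor_effects = rng.normal(0.0, params.donor_sd, size=params.n_donors)
    baselines = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd,
                           size=n_genes)
    center = (params.n_regions - 1) / 2.0

    truth_rows = []
    blocks: list[np.ndarray] = []
    cell_rows: list[dict] = []
    for subclass in params.subclasses:
        signs = _assign_trend_signs(rng, n_genes, params.frac_trend)
        for g in np.flatnonzero(signs):
            truth_rows.append(
                {"feature": genes[g], "subclass": subclass,
                 "sign": int(signs[g]), "slope": params.trend_slope}
            )
        for o, region in enumerate(regions):
            log2_mu = baselines + signs * params.trend_slope * (o - center)
            for j, donor in enumerate(donors):
                mu = params.library_scale * np.exp2(log2_mu + donor_effects[j])
                blocks.append(_nb_draw(rng, mu, params.nb_dispersion,
                                       params.cells_per_group))
                for i in range(params.cells_per_group):
                    cell_rows.append(
                        {"cell_id": f"{subclass}.{region}.{donor}.{i}",
                         "subclass": subclass, "region": region, "donor": donor}
                    )
    counts = np.concatenate(blocks, axis=1)
    cells = CellTable(pd.DataFrame(cell_rows))
    truth = SyntheticTruth(
        trend_features=pd.DataFrame(
            truth_rows, columns=["feature", "subclass", "sign", "slope"]
        )
    )
    return CountMatrix(genes, list(cells.cell_ids), counts), cells, truth


# ---------------------------------------------------------------------------
# spatial


@dataclass
class SpatialSimulation:
    """Cells with coordinates plus the landmark polylines used to place them."""

    cells: CellTable
    #: region -> (pial polyline, white-matter polyline), each an (n, 2) array
    boundaries: dict[str, tuple[np.ndarray, np.ndarray]]
    truth: SyntheticTruth


def default_layer_assignments(
    subclasses: tuple[str, ...], regions: tuple[str, ...], depth_sd: float = 0.06
) -> dict[str, dict[str, tuple[float, float]]]:
    """Evenly spaced laminar depth means in (0, 1), identical across regions."""
    n = len(subclasses)
    means = (np.arange(n) + 1) / (n + 1)
    return {
        sc: {r: (float(means[i]), depth_sd) for r in regions}
        for i, sc in enumerate(subclasses)
    }


def simulate_spatial(
    params: SimulationParams,
    seed: int | None = None,
    layer_assignments: dict[str, dict[str, tuple[float, float]]] | None = None,
    section_width_um: float = 2000.0,
    section_depth_um: float = 2000.0,
) -> SpatialSimulation:
    """Place cells in laminar point patterns between pial and WM landmarks.

    Per (subclass, region), the cell count is Poisson(``cells_per_group``),
    x is uniform over the section width, and normalized depth is a
    truncated normal on [0, 1] with the subclass's (mean, SD) for that
    region; y maps depth between the pial (y = 0) and white-matter
    (y = section_depth_um) boundary polylines.
    """
    if seed is None:
        seed = params.seed
    regions = DEFAULT_REGIONS[: params.n_regions]
    if layer_assignments is None:
        layer_assignments = default_layer_assignments(params.subclasses, regions)
    for sc, per_region in layer_assignments.items():
        for r, (_, sd) in per_region.items():
            if sd <= 0:
                raise ParameterError(f"depth SD must be > 0 ({sc!r} in {r!r})")
    rng = np.random.default_rng(seed)
    xs = np.linspace(0.0, section_width_um, 5)
    boundaries = {
        r: (np.column_stack([xs, np.zeros_like(xs)]),
            np.column_stack([xs, np.full_like(xs, section_depth_um)]))
        for r in regions
    }
    rows: list[dict] = []
    for region in regions:
        for subclass in params.subclasses:
            if subclass not in layer_assignments or region not in layer_assignments[subclass]:
                continue
            mean, sd = layer_assignments[subclass][region]
            n = rng.poisson(params.cells_per_group)
            if n == 0:
                continue
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            depth = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                        random_state=rng)
            x = rng.uniform(0.0, section_width_um, size=n)
            y = depth * section_depth_um
            for i in range(n):
                rows.append(
                    {"cell_id": f"{subclass}.{region}.sp{i}", "subclass": subclass,
                     "region": region, "donor": "D1",
                     "x": float(x[i]), "y": float(y[i])}
                )
    cells = CellTable(pd.DataFrame(rows))
    truth = SyntheticTruth(layer_assignments=layer_assignments)
    return SpatialSimulation(cells=cells, boundaries=boundaries, truth=truth)


# ---------------------------------------------------------------------------
# eRegulons


@dataclass
class ERegulonSimulation:
    """eRegulon table with matched accessibility and expression matrices."""

    eregulons: ERegulonTable
    peak_counts: CountMatrix
    gene_counts: CountMatrix
    cells: CellTable
    truth: SyntheticTruth


def simulate_eregulons(
    params: SimulationParams,
    n_tfs: int = 4,
    enhancers_per_tf: int = 3,
    genes_per_enhancer: int = 2,
    seed: int | None = None,
    n_background: int = 200,
) -> ERegulonSimulation:
    """Simulate TF -> enhancer -> gene triplets with concordant axis trends.

    Half the TFs get + activity, half -, and the sign propagates to their
    enhancers' accessibility and target genes' expression. ``n_background``
    untrended peaks and genes are added so downstream FDR adjustment runs
    over a realistic background. Peak counts use a 5x smaller library
    scale than gene counts (accessibility matrices are sparser).
    """
    if n_tfs % 2 != 0:
        raise ParameterError("n_tfs must be even (half +, half -)")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    axis = AxisSpec("sim", DEFAULT_REGIONS[: params.n_regions])
    subclass = params.subclasses[0]

    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    tf_signs = {tf: (1 if i < n_tfs // 2 else -1) for i, tf in enumerate(tfs)}

    rows = []
    peak_ids: list[str] = []
    gene_ids: list[str] = []
    peak_signs: list[int] = []
    gene_signs: list[int] = []
    k = 0
    for tf in tfs:
        sign = tf_signs[tf]
        for e in range(enhancers_per_tf):
            start = 1000 * (k + 1)
            peak = PeakInterval("chr1", start, start + 500).peak_id
            k += 1
            peak_ids.append(peak)
            peak_signs.append(sign)
            for g in range(genes_per_enhancer):
                gene = f"{tf}_E{e + 1}_G{g + 1}"
                gene_ids.append(gene)
                gene_signs.append(sign)
                rows.append(
                    {"tf": tf, "peak": peak, "target_gene": gene,
                     "strength": float(rng.uniform(0.5, 2.0))}
                )
    for i in range(n_background):
        start = 1000 * (k + 1)
        peak_ids.append(PeakInterval("chr1", start, start + 500).peak_id)
        peak_signs.append(0)
        k += 1
        gene_ids.append(f"BG{i + 1:04d}")
        gene_signs.append(0)

    table = ERegulonTable(pd.DataFrame(rows))
    truth = SyntheticTruth(tf_signs=tf_signs)
    truth.trend_features = pd.DataFrame(
        [
            {"feature": f, "subclass": subclass, "sign": s, "slope": params.trend_slope}
            for f, s in list(zip(peak_ids, peak_signs)) + list(zip(gene_ids, gene_signs))
            if s != 0
        ],
        columns=["feature", "subclass", "sign", "slope"],
    )

    gene_counts, cells = _counts_for_features(
        rng, gene_ids, np.array(gene_signs), params, axis, params.library_scale,
        subclass,
    )
    peak_counts, _ = _counts_for_features(
        rng, peak_ids, np.array(peak_signs), params, axis,
        params.library_scale * 0.2, subclass, cells=cells,
    )
    return ERegulonSimulation(eregulons=table, peak_counts=peak_counts,
                              gene_counts=gene_counts, cells=cells, truth=truth)


def _counts_for_features(
    rng: np.random.Generator,
    features: list[str],
    signs: np.ndarray,
    params: SimulationParams,
    axis: AxisSpec,
    library_scale: float,
    subclass: str,
    cells: CellTable | None = None,
) -> tuple[CountMatrix, CellTable]:
    """NB counts for an explicit feature list with given trend signs."""
    regions = axis.ordered_regions[: params.n_regions]
    donors = [f"D{j + 1}" for j in range(params.n_donors)]
    donor_effects = rng.normal(0.0, params.donor_sd, size=params.n_donors)
    baselines = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd,
                           size=len(features))
    center = (params.n_regions - 1) / 2.0
    blocks = []
    cell_rows = []
    for o, region in enumerate(regions):
        log2_mu = baselines + signs * params.trend_slope * (o - center)
        for j, donor in enumerate(donors):
            mu = library_scale * np.exp2(log2_mu + donor_effects[j])
            blocks.append(_nb_draw(rng, mu, params.nb_dispersion,
                                   params.cells_per_group))
            cell_rows.extend(
                {"cell_id": f"{subclass}.{region}.{donor}.{i}",
                 "subclass": subclass, "region": region, "donor": donor}
                for i in range(params.cells_per_group)
            )
    counts = np.concatenate(blocks, axis=1)
    if cells is None:
        cells = CellTable(pd.DataFrame(cell_rows))
    return CountMatrix(features, list(cells.cell_ids), counts), cells
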