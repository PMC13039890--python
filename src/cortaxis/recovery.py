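"""Parameter-recovery benchmarks: run each stage on simulations with
known injected structure and measure how well it recovers the truth.

These are the package's own verification experiments — the screen's
sensitivity and false-positive rate on injected axis trends, its
empirical FDR on null simulations, laminar-depth recovery, and
eRegulon-concordance recovery — at the study-scale conditions (9 regions,
multi-donor pseudobulk, published filter and threshold values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cortaxis.axis import GENE_THRESHOLDS, AxisThresholds, screen_axis
from cortaxis.grn import (
    classify_enhancers,
    summarize_tfs,
    target_correlation_by_class,
)
from cortaxis.io import AxisSpec
from cortaxis.pseudobulk import (
    FilterParams,
    GENE_FILTER_DEFAULTS,
    PEAK_FILTER_DEFAULTS,
    aggregate_pseudobulk,
)
from cortaxis.simulate import (
    DEFAULT_REGIONS,
    SimulationParams,
    default_layer_assignments,
    simulate_counts,
    simulate_eregulons,
    simulate_spatial,
)
from cortaxis.spatial import (
    cross_region_profile_correlation,
    depth_density,
    normalize_depth,
)
from cortaxis.axis import PEAK_THRESHOLDS


def _default_axis(n_regions: int) -> AxisSpec:
    return AxisSpec("RC", DEFAULT_REGIONS[:n_regions])


#: conditions of the axis-screen recovery experiment: 9 regions x 5
#: donors, 2,000 genes with 100 trending (|slope| 0.3 log2/step, NB
#: dispersion 0.1), 300 cells per region x donor group
AXIS_RECOVERY_PARAMS = dict(
    n_regions=9,
    n_donors=5,
    genes_per_subclass=2000,
    cells_per_group=300,
    frac_trend=0.05,
    trend_slope=0.3,
    nb_dispersion=0.1,
)


@dataclass
class ScreenRecovery:
    sensitivity: float
    false_positive_rate: float
    n_injected: int
    n_null: int


def axis_screen_recovery(
    seed: int,
    thresholds: AxisThresholds = GENE_THRESHOLDS,
    **overrides,
) -> ScreenRecovery:
    """Sensitivity and null false-positive rate of the gene axis screen.

    Simulates counts with injected trends, runs the full screen
    (published gene filter 10/15, Pearson, per-sample mode, thresholds
    |r| > 0.7 / q < 0.01), and scores calls against the simulation truth.
    Injected genes lost to the expression filter count against
    sensitivity; the false-positive rate is over null genes that survived
    filtering.
    """
    params = SimulationParams(**{**AXIS_RECOVERY_PARAMS, **overrides, "seed": seed})
    axis = _default_axis(params.n_regions)
    counts, cells, truth = simulate_counts(params, axis)
    subclass = params.subclasses[0]
    pb = aggregate_pseudobulk(counts, cells, subclass)
    screen = screen_axis(pb, axis, thresholds=thresholds,
                         filter_params=FilterParams(**GENE_FILTER_DEFAULTS))
    injected = truth.trend_set(subclass)
    called = set(screen.loc[screen["sign_class"] != "null", "feature"])
    nulls_screened = set(screen["feature"]) - injected
    tp = len(called & injected)
    fp = len(called - injected)
    return ScreenRecovery(
        sensitivity=tp / len(injected),
        false_positive_rate=fp / len(nulls_screened) if nulls_screened else 0.0,
        n_injected=len(injected),
        n_null=len(nulls_screened),
    )


#: conditions of the null-FDR experiment (size chosen for desk-scale
#: runtime; the slope is exactly zero so every feature is null)
NULL_FDR_PARAMS = dict(
    n_regions=9,
    n_donors=4,
    genes_per_subclass=1000,
    cells_per_group=100,
    frac_trend=0.0,
    trend_slope=0.0,
    nb_dispersion=0.1,
)


def null_q_fraction(seed: int, q_threshold: float = 0.05, **overrides) -> float:
    """Fraction of features with BH q below threshold on a null simulation."""
    params = SimulationParams(**{**NULL_FDR_PARAMS, **overrides, "seed": seed})
    axis = _default_axis(params.n_regions)
    counts, cells, _ = simulate_counts(params, axis)
    pb = aggregate_pseudobulk(counts, cells, params.subclasses[0])
    screen = screen_axis(pb, axis, filter_params=FilterParams(**GENE_FILTER_DEFAULTS))
    if screen.empty:
        return 0.0
    return float((screen["q"] < q_threshold).mean())


@dataclass
class SpatialRecovery:
    max_argmax_error: float
    identical_layer_correlation: float
    disjoint_layer_correlation: float


def spatial_recovery(seed: int, cells_per_group: int = 600) -> SpatialRecovery:
    """Laminar-profile recovery on three subclasses at depths 0.2/0.5/0.8.

    Measures the worst |argmax(KDE) - true depth mean| over subclasses and
    regions, the cross-region density correlation between two regions
    simulated with identical layer assignments, and between two regions
    with disjoint (reversed) assignments.
    """
    subclasses = ("SCa", "SCb", "SCc")
    depth_means = (0.2, 0.5, 0.8)
    params = SimulationParams(subclasses=subclasses, n_regions=3,
                              cells_per_group=cells_per_group, seed=seed)
    regions = DEFAULT_REGIONS[:3]
    assignments = {
        sc: {r: (m, 0.05) for r in regions}
        for sc, m in zip(subclasses, depth_means)
    }
    # third region gets reversed depths -> disjoint laminar structure
    for sc, m in zip(subclasses, depth_means):
        assignments[sc][regions[2]] = (1.0 - m + 0.0, 0.05) if m != 0.5 else (0.95, 0.05)
    sim = simulate_spatial(params, seed=seed, layer_assignments=assignments)

    pial, wm = sim.boundaries[regions[0]]
    depth_of = normalize_depth(sim.cells, pial, wm)
    errors = []
    profiles_first: dict[str, np.ndarray] = {}
    for region in regions:
        densities = []
        for sc in subclasses:
            mask = (sim.cells.df["region"] == region) & (sim.cells.df["subclass"] == sc)
            profile = depth_density(depth_of[mask], subclass=sc, region=region)
            densities.append(profile.density)
            true_mean = assignments[sc][region][0]
            errors.append(abs(profile.argmax_depth() - true_mean))
        profiles_first[region] = np.concatenate(densities)
    corr = cross_region_profile_correlation(profiles_first)
    return SpatialRecovery(
        max_argmax_error=float(max(errors)),
        identical_layer_correlation=float(corr.loc[regions[0], regions[1]]),
        disjoint_layer_correlation=float(corr.loc[regions[0], regions[2]]),
    )


#: conditions of the eRegulon-concordance experiment: 2 + 2 TFs, 3
#: enhancers per TF, 2 genes per enhancer, slope 0.3, 5 donors
GRN_RECOVERY_PARAMS = dict(n_regions=9, n_donors=5, cells_per_group=300,
                           trend_slope=0.3, nb_dispersion=0.1)


@dataclass
class GRNRecovery:
    tf_sign_agreement: float
    mwu_p: float
    n_positive_links: int
    n_negative_links: int


def grn_concordance_recovery(seed: int, **overrides) -> GRNRecovery:
    """End-to-end eRegulon concordance on a 2+2-TF simulation.

    Screens simulated peak accessibility and target-gene expression along
    the axis, classifies enhancers with the published peak thresholds,
    compares positive- vs negative-class target correlations by MWU, and
    checks each recovered TF activity sign against the simulated one.
    """
    params = SimulationParams(**{**GRN_RECOVERY_PARAMS, **overrides, "seed": seed})
    sim = simulate_eregulons(params, n_tfs=4, enhancers_per_tf=3,
                             genes_per_enhancer=2, seed=seed)
    axis = _default_axis(params.n_regions)
    subclass = params.subclasses[0]
    pb_peaks = aggregate_pseudobulk(sim.peak_counts, sim.cells, subclass)
    pb_genes = aggregate_pseudobulk(sim.gene_counts, sim.cells, subclass)
    peak_screen = screen_axis(pb_peaks, axis, thresholds=PEAK_THRESHOLDS,
                              filter_params=FilterParams(**PEAK_FILTER_DEFAULTS))
    gene_screen = screen_axis(pb_genes, axis,
                              filter_params=FilterParams(**GENE_FILTER_DEFAULTS))
    classes, _missing = classify_enhancers(sim.eregulons, peak_screen)
    report = target_correlation_by_class(classes, sim.eregulons, gene_screen)
    summaries = summarize_tfs(sim.eregulons, peak_screen, gene_screen)
    agree = [
        (s.activity_r > 0) == (sim.truth.tf_signs[s.tf] > 0) for s in summaries
    ]
    mwu_p = report["mwu"].get("p", 1.0)
    return GRNRecovery(
        tf_sign_agreement=sum(agree) / len(sim.truth.tf_signs),
        mwu_p=float(mwu_p),
        n_positive_links=len(report["distributions"]["positive"]),
        n_negative_links=len(report["distributions"]["negative"]),
    )
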