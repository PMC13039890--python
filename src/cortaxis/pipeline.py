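"""End-to-end orchestration: simulate -> pseudobulk -> axis -> spatial ->
grn -> report, driven by one YAML config with a single root seed.

Every stage writes deterministic text outputs under the configured
output directory, and the run manifest records the config hash, derived
per-stage seeds, and a SHA-256 checksum of every output file, so two runs
with the same config and seed are byte-identical and every reported
number is traceable to a listed file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cortaxis import grn as grn_mod
from cortaxis import signatures as sig_mod
from cortaxis import spatial as spatial_mod
from cortaxis.axis import AxisThresholds, screen_axis
from cortaxis.io import (
    AxisSpec,
    CellTable,
    ValidationError,
    load_cell_table,
    load_counts,
    load_eregulons,
    write_result_json,
    write_result_tsv,
)
from cortaxis.pseudobulk import FilterParams, aggregate_pseudobulk, cpm_transform
from cortaxis.simulate import (
    SimulationParams,
    simulate_counts,
    simulate_eregulons,
    simulate_spatial,
)

#: default axis orderings; editable via config, never hard-coded downstream.
#: R-C follows the rostral-to-caudal presentation order of the nine
#: regions; T-S separates transmodal/association from sensorimotor areas.
#: Both are configurable assumptions.
DEFAULT_AXES = {
    "RC": ["ACC", "DFC", "FI", "M1C", "S1C", "MTG", "A1C", "AnG", "V1C"],
    "TS": ["ACC", "FI", "DFC", "AnG", "MTG", "M1C", "S1C", "A1C", "V1C"],
}

STAGES = ("simulate", "pseudobulk", "axis", "spatial", "grn", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict[str, Any]
    seed: int
    output_dir: Path
    axes: dict[str, AxisSpec]
    axis_name: str
    subclass: str
    method: str
    sample_mode: str
    gene_filter: FilterParams
    peak_filter: FilterParams
    gene_thresholds: AxisThresholds
    peak_thresholds: AxisThresholds
    spatial_params: dict[str, Any]
    simulate: dict[str, Any] | None
    inputs: dict[str, Any]
    stages: dict[str, bool]
    receptor_families: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path | None = None) -> "RunConfig":
        base = Path(base_dir) if base_dir else Path.cwd()
        axes_raw = raw.get("axes", DEFAULT_AXES)
        axes = {name: AxisSpec(name, tuple(order)) for name, order in axes_raw.items()}
        axis_name = raw.get("axis", next(iter(axes)))
        if axis_name not in axes:
            raise ValidationError(f"axis {axis_name!r} not defined in config")
        stages = {s: True for s in STAGES[1:]}
        stages.update(raw.get("stages", {}))
        simulate = raw.get("simulate")
        inputs = dict(raw.get("inputs", {}))
        if simulate is None:
            needed = ["counts_matrix", "counts_features", "counts_cells", "cell_table"]
            if stages.get("grn", True):
                needed.append("eregulons")
            for key in needed:
                if key not in inputs:
                    raise ValidationError(f"config inputs missing {key!r}")
                path = base / inputs[key]
                if not path.exists():
                    raise ValidationError(f"input file not found: {path}")
                inputs[key] = path
        gf = raw.get("gene_filter", {"min_count": 10, "min_total_count": 15})
        pf = raw.get("peak_filter", {"min_count": 5, "min_total_count": 15})
        gt = raw.get("gene_thresholds", {"min_abs_r": 0.7, "max_q": 0.01})
        pt = raw.get("peak_thresholds", {"min_abs_r": 0.5, "max_q": 0.05})
        sp = {"radius_um": 200.0, "n_query": 100, "grid_size": 1000}
        sp.update(raw.get("spatial_params", {}))
        return cls(
            raw=raw,
            seed=int(raw.get("seed", 0)),
            output_dir=base / raw.get("output_dir", "cortaxis_out"),
            axes=axes,
            axis_name=axis_name,
            subclass=raw.get("subclass", "L2/3 IT"),
            method=raw.get("method", "pearson"),
            sample_mode=raw.get("sample_mode", "per_sample"),
            gene_filter=FilterParams(**gf),
            peak_filter=FilterParams(**pf),
            gene_thresholds=AxisThresholds(**gt),
            peak_thresholds=AxisThresholds(**pt),
            spatial_params=sp,
            simulate=simulate,
            inputs=inputs,
            stages=stages,
            receptor_families=raw.get("receptor_families", {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base_dir=path.parent)

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1009 + STAGES.index(stage) * 9973) % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict[str, Any] = {}
    axis = config.axes[config.axis_name]

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "seed": config.stage_seed(stage),
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
        }

    plan = [
        ("simulate", _stage_simulate),
        ("pseudobulk", _stage_pseudobulk),
        ("axis", _stage_axis),
        ("spatial", _stage_spatial),
        ("grn", _stage_grn),
        ("report", _stage_report),
    ]
    for stage, fn in plan:
        enabled = (config.simulate is not None) if stage == "simulate" \
            else config.stages.get(stage, True)
        if not enabled:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        try:
            files = fn(config, axis, state, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            )
            raise StageError(stage, exc) from exc
        record(stage, files)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, axis: AxisSpec, state: dict,
                    out: Path) -> list[Path]:
    sim_dir = out / "inputs"
    sim_dir.mkdir(exist_ok=True)
    opts = dict(config.simulate or {})
    ereg_opts = opts.pop("eregulons", {})
    spatial_opts = opts.pop("spatial", {})
    params = SimulationParams(**opts, seed=config.stage_seed("simulate"))
    counts, cells, truth = simulate_counts(params, axis)
    state["counts"], state["cells"], state["truth"] = counts, cells, truth
    files = [sim_dir / "counts.mtx", sim_dir / "features.txt",
             sim_dir / "cells.txt", sim_dir / "cell_table.csv",
             sim_dir / "truth.json"]
    counts.to_files(files[0], files[1], files[2])
    cells.to_csv(files[3])
    truth.to_json(files[4])

    spatial_sim = simulate_spatial(params, seed=config.stage_seed("simulate") + 1,
                                   **spatial_opts)
    state["spatial"] = spatial_sim
    spatial_file = sim_dir / "spatial_cells.csv"
    spatial_sim.cells.to_csv(spatial_file)
    files.append(spatial_file)

    ereg_sim = simulate_eregulons(params, seed=config.stage_seed("simulate") + 2,
                                  **ereg_opts)
    state["ereg_sim"] = ereg_sim
    ereg_file = sim_dir / "eregulons.tsv"
    ereg_sim.eregulons.to_tsv(ereg_file)
    files.append(ereg_file)
    return files


def _stage_pseudobulk(config: RunConfig, axis: AxisSpec, state: dict,
                      out: Path) -> list[Path]:
    if "counts" not in state:
        counts = load_counts(config.inputs["counts_matrix"],
                             config.inputs["counts_features"],
                             config.inputs["counts_cells"])
        cells, _ = load_cell_table(config.inputs["cell_table"],
                                   axis.ordered_regions)
        state["counts"], state["cells"] = counts, cells
    pb = aggregate_pseudobulk(state["counts"], state["cells"], config.subclass)
    state["pb"] = pb
    files = [out / "pseudobulk.tsv", out / "pseudobulk_samples.tsv"]
    pb.to_tsv(files[0], files[1])
    return files


def _stage_axis(config: RunConfig, axis: AxisSpec, state: dict,
                out: Path) -> list[Path]:
    screen = screen_axis(state["pb"], axis, thresholds=config.gene_thresholds,
                         filter_params=config.gene_filter, method=config.method,
                         sample_mode=config.sample_mode)
    state["gene_screen"] = screen
    path = out / "axis_genes.tsv"
    write_result_tsv(screen, path, axis=axis.name, modality="expression",
                     abundance="log2(CPM+1)")
    files = [path]
    if "ereg_sim" in state:
        sim = state["ereg_sim"]
        pb_peaks = aggregate_pseudobulk(sim.peak_counts, sim.cells, config.subclass)
        pb_genes = aggregate_pseudobulk(sim.gene_counts, sim.cells, config.subclass)
        peak_screen = screen_axis(pb_peaks, axis, thresholds=config.peak_thresholds,
                                  filter_params=config.peak_filter,
                                  method=config.method,
                                  sample_mode=config.sample_mode)
        target_screen = screen_axis(pb_genes, axis,
                                    thresholds=config.gene_thresholds,
                                    filter_params=config.gene_filter,
                                    method=config.method,
                                    sample_mode=config.sample_mode)
        state["peak_screen"], state["target_screen"] = peak_screen, target_screen
        ppath = out / "axis_peaks.tsv"
        write_result_tsv(peak_screen, ppath, axis=axis.name,
                         modality="accessibility", abundance="log2(CPM+1)")
        tpath = out / "axis_target_genes.tsv"
        write_result_tsv(target_screen, tpath, axis=axis.name,
                         modality="expression", abundance="log2(CPM+1)")
        files += [ppath, tpath]
    return files


def _stage_spatial(config: RunConfig, axis: AxisSpec, state: dict,
                   out: Path) -> list[Path]:
    if "spatial" in state:
        cells = state["spatial"].cells
        boundaries = state["spatial"].boundaries
    else:
        path = config.inputs.get("spatial_cells")
        if path is None:
            raise ValidationError("spatial stage enabled but no spatial_cells input")
        cells, _ = load_cell_table(path, axis.ordered_regions)
        boundaries = None
    sp = config.spatial_params
    regions = sorted(cells.df["region"].unique())
    # depth: from landmarks when available, else a precomputed depth column
    if boundaries is not None:
        pial, wm = boundaries[regions[0]]
        depth = spatial_mod.normalize_depth(cells, pial, wm)
    elif "depth" in cells.df.columns:
        depth = cells.df["depth"]
    else:
        raise ValidationError("no landmarks or depth column for spatial stage")
    profile_rows = []
    density_vectors: dict[str, np.ndarray] = {}
    for region in regions:
        vecs = []
        for sc in sorted(cells.df["subclass"].unique()):
            mask = (cells.df["region"] == region) & (cells.df["subclass"] == sc)
            prof = spatial_mod.depth_density(depth[mask],
                                             grid_size=sp["grid_size"],
                                             subclass=sc, region=region)
            if not prof.undefined:
                vecs.append(prof.density)
                profile_rows.append(
                    {"subclass": sc, "region": region, "n_cells": prof.n_cells,
                     "argmax_depth": prof.argmax_depth()}
                )
        if vecs:
            density_vectors[region] = np.concatenate(vecs)
    files = []
    prof_path = out / "depth_profiles.tsv"
    write_result_tsv(pd.DataFrame(profile_rows), prof_path,
                     grid_size=str(sp["grid_size"]))
    files.append(prof_path)
    if len(density_vectors) >= 2:
        corr = spatial_mod.cross_region_profile_correlation(density_vectors)
        state["density_corr"] = corr
        cpath = out / "density_region_correlation.tsv"
        corr.to_csv(cpath, sep="\t", float_format="%.17g")
        files.append(cpath)

    # neighborhood composition for the configured subclass
    profiles = spatial_mod.neighborhood_composition(
        cells, config.subclass, radius_um=sp["radius_um"],
        n_query=sp["n_query"], seed=config.stage_seed("spatial"),
    )
    rows = []
    norm_vectors: dict[str, np.ndarray] = {}
    subclasses = sorted(cells.df["subclass"].unique())
    for region, prof in profiles.items():
        comp = spatial_mod.regional_composition(cells, region)
        norm = spatial_mod.normalize_neighborhood(prof, comp)
        for sc in subclasses:
            rows.append(
                {"region": region, "query_subclass": config.subclass,
                 "neighbor_subclass": sc,
                 "raw_proportion": prof.raw_proportions.get(sc, 0.0),
                 "normalized": norm.normalized_proportions.get(sc, 0.0),
                 "n_query_cells": prof.n_query_cells}
            )
        norm_vectors[region] = np.array(
            [norm.normalized_proportions.get(sc, 0.0) for sc in subclasses]
        )
    npath = out / "neighborhoods.tsv"
    write_result_tsv(pd.DataFrame(rows), npath,
                     radius_um=str(sp["radius_um"]), n_query=str(sp["n_query"]))
    files.append(npath)
    if len(norm_vectors) >= 2:
        ncorr = spatial_mod.cross_region_profile_correlation(norm_vectors)
        state["neighbor_corr"] = ncorr
        ncpath = out / "neighborhood_region_correlation.tsv"
        ncorr.to_csv(ncpath, sep="\t", float_format="%.17g")
        files.append(ncpath)
    return files


def _stage_grn(config: RunConfig, axis: AxisSpec, state: dict,
               out: Path) -> list[Path]:
    if "ereg_sim" in state:
        eregulons = state["ereg_sim"].eregulons
        peak_screen = state["peak_screen"]
        gene_screen = state["target_screen"]
    else:
        eregulons = load_eregulons(config.inputs["eregulons"])
        peak_screen = state.get("peak_screen")
        gene_screen = state.get("gene_screen")
        if peak_screen is None:
            raise ValidationError("grn stage needs a peak axis screen")
    classes, missing = grn_mod.classify_enhancers(eregulons, peak_screen,
                                                  config.peak_thresholds)
    report = grn_mod.target_correlation_by_class(classes, eregulons, gene_screen)
    report["missing_peaks"] = missing
    summaries = grn_mod.summarize_tfs(eregulons, peak_screen, gene_screen)
    network = grn_mod.export_network(eregulons, classes, gene_screen, summaries)
    files = [out / "enhancer_classes.tsv", out / "grn_concordance.json",
             out / "tf_summaries.tsv", out / "network_edges.tsv"]
    write_result_tsv(classes, files[0], thresholds=str(config.peak_thresholds))
    write_result_json(report, files[1])
    write_result_tsv(pd.DataFrame([vars(s) for s in summaries]), files[2])
    write_result_tsv(network, files[3])
    state["tf_summaries"] = summaries
    return files


def _stage_report(config: RunConfig, axis: AxisSpec, state: dict,
                  out: Path) -> list[Path]:
    files = []
    pb = state.get("pb")
    if pb is not None:
        abundance = cpm_transform(pb)
        regions = sorted(set(pb.sample_regions))
        labels = np.asarray(pb.sample_regions)
        region_means = pd.DataFrame(
            {r: abundance.to_numpy()[:, labels == r].mean(axis=1) for r in regions},
            index=abundance.index,
        )
        z = sig_mod.regional_zscore(region_means, subclass=config.subclass)
        zpath = out / "zscores.tsv"
        write_result_tsv(z.values.reset_index(), zpath, subclass=config.subclass,
                         sd_convention=z.sd_convention)
        files.append(zpath)
        state["expr_corr"] = sig_mod.molecular_region_correlation(
            abundance, pb.sample_regions
        )
    if config.receptor_families and "gene_screen" in state:
        switching = sig_mod.detect_subunit_switching(
            config.receptor_families, state["gene_screen"]
        )
        spath = out / "subunit_switching.json"
        write_result_json(
            {"families": json.loads(switching.to_json(orient="records"))}, spath
        )
        files.append(spath)
    have = [k in state for k in ("density_corr", "neighbor_corr", "expr_corr")]
    if all(have):
        atac = state.get("atac_corr", state["expr_corr"])
        if "ereg_sim" in state:
            sim = state["ereg_sim"]
            pb_peaks = aggregate_pseudobulk(sim.peak_counts, sim.cells,
                                            config.subclass)
            atac = sig_mod.molecular_region_correlation(
                cpm_transform(pb_peaks), pb_peaks.sample_regions
            )
        common = sorted(
            set(state["density_corr"].index)
            & set(state["neighbor_corr"].index)
            & set(state["expr_corr"].index)
            & set(atac.index)
        )
        if len(common) >= 2:
            concordance = sig_mod.assemble_modality_concordance(
                state["density_corr"].loc[common, common],
                state["neighbor_corr"].loc[common, common],
                state["expr_corr"].loc[common, common],
                atac.loc[common, common],
                subclass=config.subclass,
            )
            cpath = out / "modality_concordance.json"
            write_result_json(concordance, cpath)
            files.append(cpath)
    if not files:
        placeholder = out / "report_empty.json"
        write_result_json({"note": "no report inputs available"}, placeholder)
        files.append(placeholder)
    return files
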