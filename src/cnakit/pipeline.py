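"""Pipeline orchestration: simulate -> segment -> gistic -> amplicons ->
integrate -> subtype -> survive, with a run manifest of output checksums.

A run is driven by a single config mapping (YAML on disk) that names every
stage parameter and an explicit seed; re-running an identical config
reproduces identical output checksums. Stage outputs are flat files in the
standard formats (SEG / TSV) so any stage can be run standalone on external
data through the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import amplicons as amp_mod
from . import gistic as gistic_mod
from . import integration as integ_mod
from . import io as io_mod
from . import segmentation as seg_mod
from . import simulate as sim_mod
from . import subtyping as sub_mod
from . import survival as surv_mod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "gistic", "amplicons", "integrate", "subtype", "survive")


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in config:
        raise ConfigError("config missing required key 'seed'")
    if not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    for key in config:
        if key not in ("seed",) + STAGES + ("inputs",):
            raise ConfigError(f"unknown config key {key!r}")
    for stage in STAGES:
        if stage in config and not isinstance(config[stage], dict):
            raise ConfigError(f"config section {stage!r} must be a mapping")
    return config


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages in dependency order; return the run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    seed = config["seed"]
    manifest: dict = {"seed": seed, "stages": []}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {f.name: _sha256(f) for f in files},
            }
        )

    # --- simulate (or load external inputs) ---
    sim_params = dict(config.get("simulate", {}))
    inputs = config.get("inputs")
    if inputs:
        probe_map = io_mod.read_probe_map(inputs["probe_map"])
        cn = io_mod.read_matrix(inputs["matrix"], probe_map)
        expr = io_mod.read_expression(inputs["expression"]) if "expression" in inputs else None
        clinical = io_mod.read_clinical(inputs["clinical"]) if "clinical" in inputs else None
        truth = None
        record("simulate", {"loaded_from": dict(inputs)}, [])
    else:
        gen_config = sim_mod.GeneratorConfig(**sim_params)
        probe_map, cn, expr, clinical, truth = sim_mod.generate_cohort(gen_config, seed=seed)
        files = []
        io_mod.write_probe_map(probe_map, outdir / "probes.bed")
        io_mod.write_matrix(cn, outdir / "log2_ratios.tsv")
        io_mod.write_expression(expr, outdir / "expression.tsv")
        io_mod.write_clinical(clinical, outdir / "clinical.tsv")
        truth.subtypes.to_csv(outdir / "truth_subtypes.tsv", sep="\t")
        truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
        files = [
            outdir / f
            for f in (
                "probes.bed", "log2_ratios.tsv", "expression.tsv",
                "clinical.tsv", "truth_subtypes.tsv", "truth_events.tsv",
            )
        ]
        record("simulate", sim_params, files)

    # --- segment + call ---
    seg_params = dict(config.get("segment", {}))
    seg = seg_mod.segment_cohort(
        cn,
        alpha=seg_params.get("alpha", 0.01),
        n_perm=seg_params.get("n_perm", 1000),
        seed=seed,
    )
    calls = seg_mod.call_cohort(
        cn,
        seg,
        window_bp=seg_params.get("window_bp", 250_000),
        k=seg_params.get("k", 2.5),
        tau_min=seg_params.get("tau_min", 0.1),
        amp_cut=seg_params.get("amp_cut", 1.0),
        min_probes=seg_params.get("min_probes", 4),
    )
    io_mod.write_seg(seg.records, outdir / "segments.seg")
    seg_mod.write_calls(calls, outdir / "calls.tsv")
    fga_table = seg_mod.fga_cohort(calls)
    fga_table.to_csv(outdir / "fga.tsv", sep="\t")
    record(
        "segment", seg_params,
        [outdir / "segments.seg", outdir / "calls.tsv", outdir / "fga.tsv"],
    )

    # --- gistic ---
    g_params = dict(config.get("gistic", {}))
    regions = gistic_mod.run_gistic(
        seg,
        calls,
        n_perm=g_params.get("n_perm", 1000),
        seed=seed,
        q_threshold=g_params.get("q_threshold", 0.25),
        cap=g_params.get("cap", 2.0),
        plateau_fraction=g_params.get("plateau_fraction", 0.95),
        merge_gap=g_params.get("merge_gap", 5),
    )
    gistic_mod.write_regions(regions, outdir / "gistic_regions.tsv")
    record("gistic", g_params, [outdir / "gistic_regions.tsv"])

    # --- amplicons ---
    a_params = dict(config.get("amplicons", {}))
    catalog = amp_mod.detect_amplicons(
        calls, recurrence=a_params.get("recurrence", 0.01), regions=regions
    )
    catalog.to_frame().to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
    files = [outdir / "amplicons.tsv"]
    if len(catalog):
        coamp = amp_mod.coamplification(
            catalog,
            min_carriers=a_params.get("min_carriers", 3),
            display_cut=a_params.get("display_cut", 0.2),
        )
        coamp.raw.to_csv(outdir / "coamplification.tsv", sep="\t")
        coamp.masked.to_csv(outdir / "coamplification_masked.tsv", sep="\t", na_rep="NA")
        files += [outdir / "coamplification.tsv", outdir / "coamplification_masked.tsv"]
    record("amplicons", a_params, files)

    # --- integrate ---
    i_params = dict(config.get("integrate", {}))
    files = []
    if expr is not None and len(regions):
        assignment = integ_mod.map_genes_to_regions(expr.genes, regions)
        rv = sub_mod.region_means(regions, seg)
        result = integ_mod.dosage_correlation(
            expr,
            rv,
            assignment,
            n_perm=i_params.get("n_perm", 100),
            alpha=i_params.get("alpha", 0.05),
            seed=seed,
            two_sided=i_params.get("two_sided", False),
        )
        out = result.table.copy()
        out["r_star"] = result.r_star
        out.to_csv(outdir / "dosage_correlation.tsv", sep="\t", index=False)
        files = [outdir / "dosage_correlation.tsv"]
    else:
        logger.info("integrate stage skipped: no expression data or no regions")
    record("integrate", i_params, files)

    # --- subtype ---
    s_params = dict(config.get("subtype", {}))
    files = []
    subtype_labels = None
    if len(regions):
        matrix = sub_mod.build_region_matrix(regions, seg)
        k = min(s_params.get("k", 6), cn.n_samples)
        assign = sub_mod.cluster_subtypes(matrix, k=k)
        if not inputs:
            templates = sim_mod.archetype_templates(
                probe_map, sim_mod.GeneratorConfig(**sim_params).archetypes
            )
            assign = sub_mod.name_clusters_by_template(assign, seg, templates)
        assign.labels.to_csv(outdir / "subtypes.tsv", sep="\t")
        files = [outdir / "subtypes.tsv"]
        subtype_labels = assign.labels
        if expr is not None:
            centroids = sub_mod.build_centroids(expr, assign, list(expr.values.index))
            centroids.to_csv(outdir / "centroids.tsv", sep="\t")
            files.append(outdir / "centroids.tsv")
    record("subtype", s_params, files)

    # --- survive ---
    v_params = dict(config.get("survive", {}))
    files = []
    if clinical is not None and subtype_labels is not None:
        endpoint = v_params.get("endpoint", "os")
        t_col, e_col = f"{endpoint}_time", f"{endpoint}_event"
        tab = clinical.table.set_index("sample_id")
        shared = [s for s in subtype_labels.index if s in tab.index]
        times = tab.loc[shared, t_col]
        events = tab.loc[shared, e_col]
        groups = subtype_labels.loc[shared]
        rows = []
        if groups.nunique() >= 2 and events.sum() > 0:
            chi2, df, p = surv_mod.logrank_test(times, events, groups)
            rows.append(("logrank", chi2, df, p))
        pd.DataFrame(rows, columns=["test", "statistic", "df", "p"]).to_csv(
            outdir / "survival_tests.tsv", sep="\t", index=False
        )
        km = surv_mod.km_by_group(
            pd.DataFrame({"t": times, "e": events, "g": groups}), "t", "e", "g"
        )
        km_rows = [
            (label, t, s)
            for label, est in sorted(km.items())
            for t, s in zip(est.times, est.survival)
        ]
        pd.DataFrame(km_rows, columns=["group", "time", "survival"]).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False
        )
        files = [outdir / "survival_tests.tsv", outdir / "km_curves.tsv"]
    record("survive", v_params, files)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
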