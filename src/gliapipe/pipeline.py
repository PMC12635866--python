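"""End-to-end orchestration with a reproducibility manifest.

Stages run in protocol order: simulate -> qc -> dpa -> de -> score ->
morph. Any stage subset can be requested; each stage reads only the
artifact directory, so externally supplied inputs can stand in for a
skipped stage. All randomness flows from one master seed, and a JSON
manifest (config hash, seed, per-stage timings, row counts, output
digests) is written atomically at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, dpa, io, morpho, qc, scoring, simulate

log = logging.getLogger("gliapipe")

ALL_STAGES = ("simulate", "qc", "dpa", "de", "score", "morph")

_SIM_FIELDS = {f.name for f in dataclasses.fields(simulate.SimConfig)}


def _validate(config: dict) -> None:
    known = {"sim", "qc", "dpa", "de", "score", "morph", "seed"}
    for key in config:
        if key not in known:
            raise ValueError(f"unknown config section: {key}")
    for key in config.get("sim", {}):
        if key not in _SIM_FIELDS:
            raise ValueError(f"unknown field: sim.{key}")


def make_sim_config(config: dict, seed: int | None = None) -> simulate.SimConfig:
    sim_kwargs = dict(config.get("sim", {}))
    for tup_field in ("genotypes", "clusters", "base_props", "histo_corr"):
        if tup_field in sim_kwargs and isinstance(sim_kwargs[tup_field], list):
            sim_kwargs[tup_field] = tuple(
                tuple(x) if isinstance(x, list) else x for x in sim_kwargs[tup_field]
            )
    if seed is not None:
        sim_kwargs["seed"] = int(seed)
    return simulate.SimConfig(**sim_kwargs)


def make_fixture(size: str = "small", seed: int = 0) -> dict:
    """Curated demo configs: 'small' (4 genotypes x 2 mice x ~1,000
    cells, 500 genes) for fast runs, 'medium' for a fuller cohort."""
    if size == "small":
        sim = {
            "mice_per_genotype": 2,
            "cells_per_mouse": 1000.0,
            "n_genes": 500,
            "markers_per_cluster": 8,
            "mean_umi_per_cell": 2500.0,
        }
        dpa_cfg = {"B": 200}
        # the 500-gene demo transcriptome needs proportionally lower
        # detected-gene/UMI floors than a full transcriptome
        qc_cfg = {"min_genes": 100, "min_umi": 250}
        return {"seed": seed, "sim": sim, "dpa": dpa_cfg, "qc": qc_cfg}
    elif size == "medium":
        sim = {
            "mice_per_genotype": 2,
            "cells_per_mouse": 5000.0,
            "n_genes": 2000,
            "markers_per_cluster": 10,
        }
        dpa_cfg = {"B": 200}
    else:
        raise ValueError("size must be 'small' or 'medium'")
    return {"seed": seed, "sim": sim, "dpa": dpa_cfg}


def run_pipeline(
    config: dict,
    outdir,
    seed: int | None = None,
    stages=ALL_STAGES,
) -> dict:
    """Execute the requested stages; returns the run manifest."""
    _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    stages = list(stages)
    manifest: dict = {
        "config_hash": io.config_digest(config),
        "seed": seed,
        "stages": {},
    }
    sim_cfg = make_sim_config(config, seed=seed)

    def _stage(name):
        t0 = time.time()
        log.info("[%s] start", name)
        return t0

    def _done(name, t0, **info):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log.info("[%s] done in %.2fs %s", name, time.time() - t0, info)

    if "simulate" in stages:
        t0 = _stage("simulate")
        comp = simulate.gen_composition(sim_cfg)
        ds = simulate.gen_counts(comp.table, sim_cfg)
        histology, _ = simulate.gen_histology(sim_cfg)
        shapes = simulate.gen_shapes(sim_cfg)
        io.write_counts(ds.counts, ds.gene_names, ds.cells["cell_id"], outdir / "counts")
        io.write_table(ds.cells, outdir / "cells.tsv")
        io.write_table(comp.table, outdir / "composition_truth.tsv")
        truth_props = comp.expected_props.reset_index(names="genotype")
        io.write_table(truth_props, outdir / "expected_props_truth.tsv")
        io.write_table(histology, outdir / "histology.tsv")
        io.write_shapes(shapes, outdir / "shapes.csv")
        markers_truth = pd.DataFrame(
            [(c, g) for c, gs in ds.truth["markers"].items() for g in gs],
            columns=["cluster", "gene"],
        )
        io.write_table(markers_truth, outdir / "markers_truth.tsv")
        _done("simulate", t0, n_cells=len(ds.cells), n_genes=sim_cfg.n_genes)

    if "qc" in stages:
        t0 = _stage("qc")
        cells = io.read_table(outdir / "cells.tsv")
        th_kwargs = config.get("qc", {})
        cells_qc, report = qc.apply_qc(cells, qc.QCThresholds(**th_kwargs))
        io.write_table(cells_qc, outdir / "cells_qc.tsv")
        io.write_table(report, outdir / "qc_report.tsv")
        _done("qc", t0, retained=int(cells_qc["passed_qc"].sum()), removed=int((~cells_qc["passed_qc"]).sum()))

    if "dpa" in stages:
        t0 = _stage("dpa")
        cells = io.read_table(outdir / "cells_qc.tsv")
        cells = cells[cells["passed_qc"]]
        dcfg = config.get("dpa", {})
        result = dpa.run_dpa(
            cells=cells,
            clusters=list(sim_cfg.clusters),
            genotypes=list(sim_cfg.genotypes),
            B=int(dcfg.get("B", 200)),
            seed=seed,
            normalize=dcfg.get("normalize", "per_replicate"),
            observation_unit=dcfg.get("observation_unit", "sample"),
        )
        io.write_table(result.contrasts, outdir / "dpa_contrasts.tsv")
        io.write_table(result.wald, outdir / "dpa_wald.tsv")
        io.write_table(result.proportions, outdir / "dpa_proportions.tsv")
        with open(outdir / "dpa_manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2)
        _done("dpa", t0, **{k: result.manifest[k] for k in ("B", "dropped")})

    if "de" in stages or "score" in stages:
        X, genes, _ = io.read_counts(outdir / "counts")
        cells = io.read_table(outdir / "cells_qc.tsv")
        keep = cells["passed_qc"].to_numpy()
        X = X[:, keep]
        cells = cells[keep].reset_index(drop=True)
        expr = de.log_normalize(X)

    if "de" in stages:
        t0 = _stage("de")
        decfg = config.get("de", {})
        markers = de.find_all_markers(
            expr, genes, cells["cluster"],
            lfc_min=float(decfg.get("marker_lfc", 0.25)),
            fdr_max=float(decfg.get("fdr", 0.01)),
        )
        io.write_table(markers, outdir / "markers.tsv")
        io.write_table(de.top_markers(markers, n=5), outdir / "markers_top5.tsv")
        ref = sim_cfg.genotypes[0]
        up_lists, down_lists = {}, {}
        for g in sim_cfg.genotypes[1:]:
            res = de.pseudobulk_de(
                expr, genes, cells["genotype"], g, ref,
                lfc_min=float(decfg.get("pseudobulk_lfc", 0.10)),
                fdr_max=float(decfg.get("fdr", 0.01)),
            )
            io.write_table(res, outdir / f"pseudobulk_{g}_vs_{ref}.tsv")
            sig = res[res["significant"]]
            up_lists[g] = sig.loc[sig["lfc"] > 0, "gene"].tolist()
            down_lists[g] = sig.loc[sig["lfc"] < 0, "gene"].tolist()
        io.write_table(de.overlap_sets(up_lists), outdir / "overlap_up.tsv")
        io.write_table(de.overlap_sets(down_lists), outdir / "overlap_down.tsv")
        _done("de", t0, n_marker_rows=len(markers))

    if "score" in stages:
        t0 = _stage("score")
        scfg = config.get("score", {})
        module_file = scfg.get("module_file")
        if module_file:
            module = [l.strip() for l in open(module_file) if l.strip()]
        else:
            # default module: top upregulated genes of the combined-pathology
            # genotype versus reference, from the pseudobulk stage
            path = outdir / f"pseudobulk_{sim_cfg.genotypes[-1]}_vs_{sim_cfg.genotypes[0]}.tsv"
            degs = io.read_table(path)
            n_top = int(scfg.get("n_top", 30))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                module = de.top_n_upregulated(degs, n=n_top)
            if not module and len(degs):
                log.warning(
                    "[score] no genes pass the FDR gate; falling back to the "
                    "strongest upregulated genes by raw p"
                )
                module = (
                    degs[degs["lfc"] > 0]
                    .sort_values(["p_raw", "lfc"], ascending=[True, False], kind="stable")
                    ["gene"].head(n_top).tolist()
                )
        result = scoring.score_module(
            expr, genes, module,
            n_bins=int(scfg.get("n_bins", 24)),
            n_ctrl=int(scfg.get("n_ctrl", 100)),
            seed=seed,
        )
        table = cells[["cell_id", "sample_id", "genotype", "cluster"]].copy()
        table["score"] = result.scores
        table["quartile_bin"] = scoring.bin_quartiles(result.scores)
        io.write_table(table, outdir / "module_scores.tsv")
        cmp = scoring.compare_scores(result.scores, cells["genotype"])
        io.write_table(cmp["tukey"], outdir / "module_score_tukey.tsv")
        with open(outdir / "module_score_anova.json", "w") as fh:
            json.dump({"F": cmp["F"], "p": cmp["p"], "group_means": cmp["group_means"]}, fh, indent=2)
        _done("score", t0, n_module_genes=len(result.module_genes))

    if "morph" in stages:
        t0 = _stage("morph")
        mcfg = config.get("morph", {})
        shapes = io.read_shapes(outdir / "shapes.csv")
        measured = morpho.measure_shapes(shapes, cutoff=float(mcfg.get("cutoff", 50.0)))
        io.write_table(measured, outdir / "shape_metrics.tsv")
        io.write_table(morpho.count_rods(measured), outdir / "rod_counts.tsv")
        histology = io.read_table(outdir / "histology.tsv")
        r, p, sig = morpho.correlation_matrix(
            histology.drop(columns=["mouse_id", "genotype"]), alpha=float(mcfg.get("alpha", 0.05))
        )
        r.to_csv(outdir / "histology_corr_r.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
        p.to_csv(outdir / "histology_corr_p.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
        _done("morph", t0, n_shapes=len(measured), n_rods=int(measured["is_rod"].sum()))

    digests = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            digests[str(f.relative_to(outdir))] = io.file_digest(f)
    manifest["outputs"] = digests
    tmp = outdir / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    os.replace(tmp, outdir / "manifest.json")
    return manifest
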