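"""Config-driven orchestration of the full integration + network workflow.

Stage order: synthesize (or load) → probe collapse → merge → batch
correction → PVCA audit → exploration → IQR filter → co-expression
network → template match → peak enrichment. All randomness flows from the
single config seed; artifacts are written as hash-stable TSV/JSON so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .batch import combat, pvca
from .explore import cluster_samples, pca
from .merge import (MergedStudy, ProbeMatrix, collapse_probes, exclude_samples,
                    intersect_and_merge, iqr_filter, renormalize)
from .network import (ModuleAssignment, NetworkModel, adjacency,
                      detect_modules, export_module_edges,
                      intramodular_connectivity, merge_close_modules,
                      module_eigengenes, module_overlap, tom_similarity)
from .peaks import annotate_peaks_to_genes, module_peak_enrichment
from .synthetic import (SyntheticDesign, default_design, generate_gene_loci,
                        generate_peak_table, generate_two_platform_study)
from .template import pavlidis_template_match

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_networks",
           "PAPER_DEFAULTS"]

log = logging.getLogger("coexmerge")

#: stage parameters with their conventional defaults
PAPER_DEFAULTS = {
    "iqr_threshold": 0.5,
    "merge_distance": 0.25,
    "beta_presets": (9, 20),
    "r_threshold": 0.8,
    "edge_weight_threshold": 0.41,
    "edge_weight_threshold_alt": 0.54,
    "peak_max_distance": 1000,
    "peak_max_distance_alt": 2000,
    "min_peak_score": 50.0,
}


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Defaults follow the conventional values for each stage (IQR filter
    0.5, eigengene merge distance 0.25, soft power 9 with 20 as the
    scale-free alternative, template threshold R > 0.8, edge weight 0.41,
    peak/TSS distance 1 kbp with a 2 kbp variant, peak score 50).
    """

    design: SyntheticDesign = field(default_factory=default_design)
    input_dir: str | None = None          # load probe matrices instead
    seed: int = 0
    out_dir: str | None = None
    exclude: tuple[str, ...] = ()
    renormalize_method: str = "none"
    run_combat: bool = True
    run_pvca: bool = True
    pvca_factors: tuple[str, ...] = ("platform", "state")
    pvca_variance_threshold: float = 0.6
    iqr_threshold: float = 0.5
    beta: float = 9.0
    min_module_size: int = 30
    cut_height: float = 0.998
    merge_distance: float = 0.25
    r_threshold: float = 0.8
    edge_weight_threshold: float = 0.41
    peak_max_distance: int = 1000
    min_peak_score: float = 50.0
    peak_enrich_fraction_in: float = 0.5
    peak_enrich_fraction_out: float = 0.05

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles to every stage product plus the run report."""

    config: RunConfig
    merged: MergedStudy
    corrected: MergedStudy
    filtered: MergedStudy
    network: NetworkModel
    assignment: ModuleAssignment
    connectivity: pd.DataFrame
    pvca_before: pd.Series | None
    pvca_after: pd.Series | None
    template_result: object
    enrichment: object
    truth: object
    report: dict


def _load_inputs(config: RunConfig):
    d = Path(config.input_dir)
    pm = {}
    for tag in ("a", "b"):
        values = cio.read_matrix_tsv(d / f"probes_{tag}.tsv")
        ann = pd.read_csv(d / f"annotation_{tag}.tsv", sep="\t",
                          index_col=0)["symbol"]
        pm[tag] = ProbeMatrix(values, ann, platform_id=tag)
    meta = pd.read_csv(d / "metadata.tsv", sep="\t", index_col=0)
    return pm["a"], pm["b"], meta, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all enabled stages in order and emit a run report.

    With ``config.out_dir`` set, every stage product is written beneath it
    and the report records a combined artifact hash.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        if out:
            path = out / name
            writer(path)
            written.append(path)

    report: dict = {"version": __version__, "config_hash": config.config_hash(),
                    "stages": {}, "warnings": []}

    def stage(name):
        log.info("[%s] running", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        # ---- inputs -----------------------------------------------------
        if config.input_dir:
            rec = stage("load")
            pm_a, pm_b, meta, truth = _load_inputs(config)
        else:
            rec = stage("simulate")
            from dataclasses import replace
            design = replace(config.design, seed=config.seed)
            pm_a, pm_b, meta, truth = generate_two_platform_study(design)
            emit("probes_a.tsv", lambda p: cio.write_matrix_tsv(pm_a.values, p))
            emit("probes_b.tsv", lambda p: cio.write_matrix_tsv(pm_b.values, p))
            emit("annotation_a.tsv",
                 lambda p: cio.write_tsv(pm_a.annotation.to_frame(), p))
            emit("annotation_b.tsv",
                 lambda p: cio.write_tsv(pm_b.annotation.to_frame(), p))
            emit("metadata.tsv", lambda p: cio.write_tsv(meta, p))
            emit("truth.json", lambda p: cio.write_json({
                "hub_gene": truth.hub_gene,
                "template_gene": truth.template_gene,
                "peak_enriched_module": truth.peak_enriched_module,
                "module_membership": truth.module_membership,
                "follower_genes": truth.follower_genes,
            }, p))
        rec.update(probes_a=int(pm_a.n_probes), probes_b=int(pm_b.n_probes),
                   samples=int(len(meta)))

        # ---- collapse + merge -------------------------------------------
        rec = stage("collapse")
        gm_a, gm_b = collapse_probes(pm_a), collapse_probes(pm_b)
        rec.update(genes_a=int(len(gm_a.gene_symbols)),
                   genes_b=int(len(gm_b.gene_symbols)))

        rec = stage("merge")
        ms = intersect_and_merge(gm_a, gm_b, meta)
        if config.exclude:
            ms = exclude_samples(ms, list(config.exclude))
        if config.renormalize_method != "none":
            ms = renormalize(ms, config.renormalize_method)
        rec.update(intersected_genes=int(ms.values.shape[0]),
                   samples=int(ms.values.shape[1]))
        emit("merged.tsv", lambda p: cio.write_matrix_tsv(ms.values, p))

        # ---- PVCA before / combat / PVCA after --------------------------
        pvca_before = pvca_after = None
        if config.run_pvca:
            rec = stage("pvca_before")
            pvca_before = pvca(ms, list(config.pvca_factors),
                               config.pvca_variance_threshold).proportions
            rec.update(top_factor=str(pvca_before.idxmax()))
            emit("pvca_before.tsv", lambda p: cio.write_tsv(
                pvca_before.rename("proportion").to_frame(), p))
        corrected = ms
        if config.run_combat:
            rec = stage("combat")
            corrected = combat(ms, batch_factor="platform")
            rec.update(batches=corrected.report["combat"]["batches"])
            emit("corrected.tsv",
                 lambda p: cio.write_matrix_tsv(corrected.values, p))
            if config.run_pvca:
                rec = stage("pvca_after")
                pvca_after = pvca(corrected, list(config.pvca_factors),
                                  config.pvca_variance_threshold).proportions
                rec.update(top_factor=str(pvca_after.idxmax()))
                emit("pvca_after.tsv", lambda p: cio.write_tsv(
                    pvca_after.rename("proportion").to_frame(), p))

        # ---- exploration ------------------------------------------------
        rec = stage("explore")
        pc = pca(corrected, n_components=3)
        tree = cluster_samples(corrected)
        rec.update(variance_pc1_3=float(pc.variance_fraction[:3].sum()))
        emit("pca_scores.tsv", lambda p: cio.write_tsv(
            pc.scores.join(corrected.metadata), p))
        emit("pca_variance.tsv", lambda p: cio.write_tsv(pd.DataFrame({
            "component": np.arange(1, len(pc.variance_fraction) + 1),
            "variance_fraction": pc.variance_fraction}), p, index=False))
        emit("samples.nwk", lambda p: Path(p).write_text(tree.to_newick() + "\n"))

        # ---- variance filter + network ----------------------------------
        rec = stage("iqr_filter")
        filtered = iqr_filter(corrected, config.iqr_threshold)
        rec.update(filtered.report["iqr_filter"])

        rec = stage("network")
        nm = tom_similarity(adjacency(filtered, beta=config.beta))
        assignment = detect_modules(nm, min_module_size=config.min_module_size,
                                    cut_height=config.cut_height)
        if assignment.n_modules >= 2:
            assignment = merge_close_modules(filtered, assignment,
                                             merge_distance=config.merge_distance)
        conn = intramodular_connectivity(nm, assignment)
        rec.update(n_modules=int(assignment.n_modules),
                   module_sizes=assignment.sizes().to_dict(),
                   hubs={int(m): str(_first_hub(conn, m))
                         for m in assignment.sizes().index})
        emit("modules.tsv", lambda p: cio.write_tsv(pd.DataFrame({
            "module": assignment.labels, "color": assignment.colors}), p))
        emit("connectivity.tsv", lambda p: cio.write_tsv(conn, p))
        if assignment.n_modules:
            eig = module_eigengenes(filtered, assignment)
            emit("eigengenes.tsv",
                 lambda p: cio.write_tsv(eig.eigengenes, p))
            reg_module = _regulator_module(assignment, truth)
            if reg_module is not None:
                edges, degree = export_module_edges(
                    nm, assignment, reg_module, config.edge_weight_threshold)
                rec["regulator_module"] = int(reg_module)
                rec["exported_edges"] = int(len(edges))
                emit("module_edges.tsv",
                     lambda p: cio.write_tsv(edges, p, index=False))

        # ---- template match ---------------------------------------------
        template_result = None
        template = truth.template_gene if truth is not None else None
        if template and template in corrected.genes:
            rec = stage("template_match")
            template_result = pavlidis_template_match(
                corrected, template, r_threshold=config.r_threshold)
            rec.update(template=template,
                       n_matched=int(template_result.n_matched))
            emit("template_match.tsv", lambda p: cio.write_tsv(
                pd.DataFrame({"R": template_result.correlations,
                              "matched": template_result.correlations.index
                              .isin(template_result.matched)}), p))

        # ---- peak enrichment --------------------------------------------
        enrichment = None
        if truth is not None and assignment.n_modules >= 2:
            rec = stage("peak_enrichment")
            loci = generate_gene_loci(list(truth.module_membership.index))
            peaks = generate_peak_table(
                truth, loci,
                enrich_fraction_in=config.peak_enrich_fraction_in,
                enrich_fraction_out=config.peak_enrich_fraction_out,
                seed=config.seed)
            flags = annotate_peaks_to_genes(
                peaks, loci, max_distance=config.peak_max_distance,
                min_score=0.0)["has_peak"]
            module_genes = set(truth.module_genes(truth.peak_enriched_module))
            comparison = set(truth.module_membership.index) - module_genes
            enrichment = module_peak_enrichment(flags, module_genes, comparison)
            rec.update(p_value=float(enrichment.p_value),
                       odds_ratio=float(enrichment.odds_ratio),
                       **enrichment.counts())
            emit("peaks.bed", lambda p: peaks.to_csv(
                p, sep="\t", header=False, index=False,
                float_format=cio.FLOAT_FORMAT))
            emit("enrichment.json", lambda p: cio.write_json(
                {"p_value": enrichment.p_value,
                 "odds_ratio": enrichment.odds_ratio,
                 **enrichment.counts()}, p))

    except Exception as exc:
        if out:
            (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    if out:
        report["artifact_hash"] = cio.tree_sha256(written)
    report["report_hash"] = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=str).encode()).hexdigest()
    if out:
        cio.write_json(report, out / "report.json")
    return PipelineResult(
        config=config, merged=ms, corrected=corrected, filtered=filtered,
        network=nm, assignment=assignment, connectivity=conn,
        pvca_before=pvca_before, pvca_after=pvca_after,
        template_result=template_result, enrichment=enrichment,
        truth=truth, report=report)


def _first_hub(conn: pd.DataFrame, module: int) -> str:
    sub = conn[(conn["module"] == module) & conn["is_hub"]]
    return sub.index[0] if len(sub) else ""


def _regulator_module(assignment: ModuleAssignment, truth) -> int | None:
    if truth is None or truth.hub_gene not in assignment.labels.index:
        return None
    lab = int(assignment.labels[truth.hub_gene])
    return lab if lab > 0 else None


def regulator_connectivity_rank(conn: pd.DataFrame, regulator: str) -> int:
    """1-based kWithin rank of the regulator inside its own module."""
    if regulator not in conn.index:
        raise KeyError(f"regulator {regulator!r} absent")
    module = conn.loc[regulator, "module"]
    sub = conn[conn["module"] == module].sort_values(
        "kWithin", ascending=False, kind="mergesort")
    return int(np.flatnonzero(sub.index == regulator)[0]) + 1


def compare_networks(result_a: PipelineResult, result_b: PipelineResult,
                     regulator: str) -> dict:
    """Side-by-side comparison of the regulator's module in two runs.

    Reports the overlap of the two regulator modules, each module's hub,
    the regulator's within-module connectivity rank, its exported-edge
    degree at the configured threshold, and template-match counts.
    """
    out: dict = {"regulator": regulator}
    for tag, res in (("a", result_a), ("b", result_b)):
        if regulator not in res.assignment.labels.index:
            raise ValueError(f"regulator {regulator!r} absent from run {tag!r}")
    shared = set(result_a.assignment.labels.index) & \
        set(result_b.assignment.labels.index)
    mod_a = int(result_a.assignment.labels[regulator])
    mod_b = int(result_b.assignment.labels[regulator])
    for tag, res, mod in (("a", result_a, mod_a), ("b", result_b, mod_b)):
        conn = res.connectivity
        rank = regulator_connectivity_rank(conn, regulator) if mod else None
        hub = _first_hub(conn, mod) if mod else None
        degree = None
        if mod:
            _, degrees = export_module_edges(
                res.network, res.assignment, mod,
                res.config.edge_weight_threshold)
            degree = int(degrees.get(regulator, 0))
        out[tag] = {
            "module": mod,
            "module_size": int((res.assignment.labels == mod).sum()) if mod else 0,
            "hub": hub,
            "regulator_rank": rank,
            "regulator_degree": degree,
            "template_matches": (int(res.template_result.n_matched)
                                 if res.template_result is not None else None),
        }
    if mod_a and mod_b:
        out["overlap"] = module_overlap(result_a.assignment,
                                        result_b.assignment,
                                        shared, mod_a, mod_b)
    else:
        out["overlap"] = None
    return out
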