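"""One-shot orchestration of all permitted analyses.

``run_pipeline`` executes the stages in a fixed order — literature
bridging, correlation network + clusters + exports, coexpression
heatmap, pathway enrichment, GO enrichment, phenotype mapping — writes
every table and image into the output directory and finishes with a
``manifest.json`` listing the outputs and the parameters used. Output
is deterministic for fixed inputs and seeds. Input files are never
copied into the output directory unless explicitly requested.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import capabilities, corrnet, enrichment, phenotype
from .coexpression import coexpression as _coexpression_profile, render_heatmap
from .capabilities import ExecutionPlan
from .ids import Layer, MoleculeID
from .knowledgebase import KnowledgeBase, bridge_missing_layer
from .table import OmicsTable, write_omics_csv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisReport:
    """Outputs of one pipeline run."""

    outdir: Path
    manifest: dict

    @property
    def outputs(self) -> dict[str, list[str]]:
        return self.manifest["outputs"]


def run_pipeline(
    tables: Mapping[Layer, OmicsTable],
    kb: KnowledgeBase,
    outdir: str | Path,
    requested: Sequence[str] | None = None,
    config: corrnet.NetworkConfig = corrnet.NetworkConfig(),
    linkage: str = "complete",
    scale: str = "none",
    go_method: str = "ease",
    alpha: float = 0.05,
    significant_metabolites: Iterable[MoleculeID] | None = None,
    keep_inputs: bool = False,
    write_png: bool = False,
) -> AnalysisReport:
    """Run every requested (and permitted) analysis on the input layers.

    Pathway enrichment runs in enrichment mode when a significant
    metabolite set is supplied, otherwise in normal (mapping) mode.
    GO enrichment consumes the transcriptomics layer only; query genes
    without any annotation in the knowledgebase background are dropped
    with a logged note before testing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir)

    mode = frozenset(tables.keys())
    exec_plan = capabilities.plan(mode, requested)
    table_list = [tables[l] for l in (Layer.T, Layer.P, Layer.M) if l in tables]

    manifest: dict = {
        "mode": exec_plan.name,
        "analyses": list(exec_plan.analyses),
        "parameters": {
            "pcc_threshold": config.pcc_threshold,
            "use_absolute": config.use_absolute,
            "repulsion": config.repulsion,
            "attraction": config.attraction,
            "min_shared_obs": config.min_shared_obs,
            "layout_seed": config.layout_seed,
            "linkage": linkage,
            "scale": scale,
            "go_method": go_method,
            "alpha": alpha,
        },
        "outputs": {},
        "stages": [],
    }

    def record(stage: str, paths: list[Path]) -> None:
        manifest["outputs"][stage] = sorted(p.name for p in paths)
        manifest["stages"].append(stage)

    def run_stage(stage: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except (phenotype.CapabilityError,) as exc:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)

    if keep_inputs:
        kept = []
        for layer, table in sorted(tables.items()):
            p = outdir / f"input_{layer.value}.csv"
            write_omics_csv(table, p)
            kept.append(p)
        record("inputs", kept)

    bridged: list = []
    if "correlation" in exec_plan.analyses and exec_plan.bridged_layer is not None:
        def _bridge() -> None:
            nonlocal bridged
            bridged = bridge_missing_layer(table_list, kb)
            p = outdir / "bridged.csv"
            with p.open("w", encoding="utf-8") as fh:
                fh.write("bridged_id,linked_inputs,evidence\n")
                for item in bridged:
                    linked = ";".join(str(m) for m in sorted(item.linked))
                    fh.write(f"{item.molecule},{linked},{item.evidence}\n")
            record("bridge", [p])

        run_stage("bridge", _bridge)
        manifest["bridged_layer"] = exec_plan.bridged_layer.value
        manifest["n_bridged"] = len(bridged)

    if "correlation" in exec_plan.analyses:
        def _correlation() -> None:
            cm = corrnet.correlation_matrix(table_list, config.min_shared_obs)
            network = corrnet.build_network(cm, config, bridged)
            clusters, summary = corrnet.find_clusters(network)
            pos = corrnet.layout(network, config)
            paths = [
                outdir / "network.sif",
                outdir / "network.svg",
                outdir / "clusters.csv",
                outdir / "correlation_matrix.csv",
            ]
            corrnet.export_sif(network, paths[0])
            corrnet.export_svg(network, pos, paths[1])
            corrnet.write_cluster_csv(summary, paths[2])
            cm.as_dataframe().to_csv(paths[3])
            if write_png:
                png = outdir / "network.png"
                corrnet.export_png(network, pos, png)
                paths.append(png)
            record("correlation", paths)
            manifest["n_nodes"] = len(network.nodes)
            manifest["n_correlation_edges"] = network.n_edges("correlation")
            manifest["n_literature_edges"] = network.n_edges("literature")
            manifest["n_clusters"] = len(clusters)

        run_stage("correlation", _correlation)

    if "coexpression" in exec_plan.analyses:
        def _coexpression() -> None:
            result = _coexpression_profile(table_list, scale=scale, linkage=linkage)
            paths = [outdir / "heatmap.svg", outdir / "coexpression_orders.csv"]
            render_heatmap(result, paths[0])
            result.orders_frame().to_csv(paths[1], index=False)
            if write_png:
                png = outdir / "heatmap.png"
                render_heatmap(result, png)
                paths.append(png)
            record("coexpression", paths)
            manifest["n_heatmap_rows"] = len(result.ids)

        run_stage("coexpression", _coexpression)

    if "pathway_enrichment" in exec_plan.analyses:
        def _pathway() -> None:
            overall = frozenset(tables[Layer.M].ids)
            if significant_metabolites is not None:
                data = enrichment.EnrichmentInput(
                    overall, frozenset(significant_metabolites)
                )
                frame = enrichment.pathway_enrichment(data, kb, mode="enrichment")
                manifest["pathway_mode"] = "enrichment"
            else:
                frame = enrichment.pathway_enrichment(overall, kb, mode="normal")
                manifest["pathway_mode"] = "normal"
            p = outdir / "pathway_enrichment.csv"
            frame.to_csv(p, index=False)
            record("pathway_enrichment", [p])
            manifest["n_pathways_mapped"] = int(len(frame))

        run_stage("pathway_enrichment", _pathway)

    if "go_enrichment" in exec_plan.analyses:
        def _go() -> None:
            if not kb.has_go:
                raise PipelineError(
                    "stage 'go_enrichment' failed: knowledgebase has no GO table"
                )
            background = kb.annotated_genes()
            query = frozenset(tables[Layer.T].ids)
            unannotated = query - background
            if unannotated:
                logger.info(
                    "go_enrichment: %d query gene(s) lack GO annotation and are "
                    "excluded from the test", len(unannotated),
                )
            query &= background
            if not query:
                raise ValueError("no query gene has GO annotation")
            result = enrichment.go_enrichment(
                query, kb, background=background, method=go_method, alpha=alpha
            )
            paths = [outdir / "go_enrichment.csv", outdir / "go_enrichment.svg"]
            result.combined().to_csv(paths[0], index=False)
            enrichment.plot_go_bars(result, paths[1])
            record("go_enrichment", paths)
            manifest["n_go_terms_tested"] = int(
                sum(len(t) for t in result.tables.values())
            )

        run_stage("go_enrichment", _go)

    if "phenotype" in exec_plan.analyses:
        def _phenotype() -> None:
            hits = phenotype.phenotype_map(
                [t for t in table_list if t.layer in (Layer.T, Layer.P)], kb
            )
            p = outdir / "phenotype.csv"
            phenotype.phenotype_table(hits).to_csv(p, index=False)
            record("phenotype", [p])
            manifest["n_phenotype_hits"] = len(hits)

        run_stage("phenotype", _phenotype)

    manifest_path = outdir / "manifest.json"
    with manifest_path.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return AnalysisReport(outdir=outdir, manifest=manifest)


def _setup_log(outdir: Path) -> None:
    root = logging.getLogger("crossomics")
    for handler in list(root.handlers):
        if getattr(handler, "_crossomics_run_log", False):
            root.removeHandler(handler)
            handler.close()
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    handler._crossomics_run_log = True  # type: ignore[attr-defined]
    root.addHandler(handler)
    root.setLevel(logging.INFO)
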