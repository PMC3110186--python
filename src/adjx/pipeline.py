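"""Configuration-driven orchestration of the full analysis.

Stages run in order — simulate (or load), preprocess, differential
expression, reporter enrichment, co-expression modules, hub ranking —
each writing its TSV outputs into the run directory. Stages whose
inputs are absent (no gene sets, no edge list) are skipped with a log
line. A JSON manifest records the configuration, seed and per-stage row
counts; identical config + seed reproduces identical counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .coexpression import (
    CoexprConfig,
    adjacency_matrix,
    detect_modules,
    module_enrichment,
    pick_soft_threshold,
    select_coexpr_genes,
    topological_overlap,
)
from .datatypes import ExpressionDataset, GeneSetCollection, InteractionGraph
from .diffexpr import (
    ContrastSpec,
    add_qvalues,
    common_upregulated,
    contrast_ttest,
    overlap_counts,
    significance_filter,
)
from .hubs import induced_subgraph, main_interactors, shared_and_exclusive
from .preprocess import quantile_normalize, svd_projection
from .reporter import build_significance_matrix, reporter_analysis
from .simulate import SimulationConfig, simulate_dataset, simulate_gene_sets, simulate_graph

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "de", "reporter", "coexpr", "hubs")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulation`` is set (simulation-backed run: gene sets and
    interaction graph are generated alongside the matrix) or
    ``matrix_path``/``design_path`` point at files; ``gmt_path`` and
    ``edges_path`` are optional — their stages are skipped when absent.
    """

    outdir: str | Path = "adjx_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    edges_path: str | None = None
    contrasts: list[ContrastSpec] = field(default_factory=list)
    q_de: float = 0.001
    q_coexpr: float = 0.01
    q_hubs: float = 0.01
    p_reporter: float = 0.001
    reporter_null_samples: int = 10_000
    quantile: bool = True
    coexpr: CoexprConfig = field(default_factory=CoexprConfig)
    hub_top_n: int = 10

    def __post_init__(self) -> None:
        for name in ("q_de", "q_coexpr", "q_hubs", "p_reporter"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.simulation is None and (self.matrix_path is None or self.design_path is None):
            raise ValueError("need either a simulation config or matrix+design paths")


def _default_contrasts(data: ExpressionDataset,
                       groups: list[tuple[str, str]]) -> list[ContrastSpec]:
    out = []
    for treatment, control in groups:
        tps = sorted(set(data.design.loc[data.design["group"] == treatment,
                                         "timepoint_h"]))
        for tp in tps:
            out.append(ContrastSpec(treatment, control, tp))
    return out


class _StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; return the manifest dict (also written to
    ``<outdir>/manifest.json``). Any stage failure aborts the run with
    the stage name and cause."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # one root seed split into independent per-stage streams
    seeds = {s: int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
             for i, s in enumerate(STAGES)}
    manifest: dict = {"seed": config.seed, "stages": {}, "counts": {}}
    truth = None
    sets: GeneSetCollection | None = None
    graph: InteractionGraph | None = None

    # ---- simulate / load ------------------------------------------------
    stage = "simulate"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            data, truth = simulate_dataset(sim)
            sets = simulate_gene_sets(sim, truth)
            graph = simulate_graph(sim, truth)
            io.write_expression_matrix(data, outdir / "matrix.tsv", outdir / "design.tsv")
            io.write_gmt(sets, outdir / "gene_sets.gmt")
            io.write_edge_list(graph, outdir / "edges.tsv")
            groups = list(sim.groups)
            manifest["stages"][stage] = "ran"
            manifest["counts"][stage] = {
                "genes": data.n_genes, "samples": data.n_samples,
                "sets": len(sets), "edges": graph.n_edges(),
            }
        else:
            data = io.read_expression_matrix(config.matrix_path, config.design_path)
            if config.gmt_path:
                sets = io.read_gmt(config.gmt_path)
            if config.edges_path:
                graph = io.read_edge_list(config.edges_path)
            groups = []
            manifest["stages"][stage] = "loaded"
            manifest["counts"][stage] = {"genes": data.n_genes, "samples": data.n_samples}
        logger.info("[simulate] %d genes x %d samples", data.n_genes, data.n_samples)
    except Exception as e:  # noqa: BLE001
        raise _StageError(stage, e) from e

    # ---- preprocess ------------------------------------------------------
    stage = "preprocess"
    try:
        if config.quantile:
            data = quantile_normalize(data)
        proj = svd_projection(data, n_components=min(3, data.n_samples, data.n_genes))
        svd_out = proj.coordinates.copy()
        for k, vf in enumerate(proj.variance_fraction, start=1):
            svd_out[f"varfrac{k}"] = vf
        svd_out.insert(0, "sample", svd_out.index)
        io.write_table(svd_out.reset_index(drop=True), outdir / "svd_coordinates.tsv")
        manifest["stages"][stage] = "ran"
        manifest["counts"][stage] = {"svd_rows": len(svd_out)}
    except Exception as e:  # noqa: BLE001
        raise _StageError(stage, e) from e

    # ---- differential expression ----------------------------------------
    stage = "de"
    try:
        contrasts = config.contrasts or _default_contrasts(data, groups)
        if not contrasts:
            raise ValueError("no contrasts defined and none derivable from design")
        de_tables: dict[ContrastSpec, pd.DataFrame] = {}
        sig_sets: dict[str, dict[float, set]] = {}
        sig_up_sets: dict[str, dict[float, set]] = {}
        for c in contrasts:
            table = add_qvalues(contrast_ttest(data, c))
            de_tables[c] = table
            out = table.reset_index(names="gene")
            io.write_table(out, outdir / f"de_{c.label()}.tsv")
            sig = set(significance_filter(table, config.q_de, "any"))
            sig_up = set(significance_filter(table, config.q_de, "up"))
            sig_sets.setdefault(c.treatment, {})[c.timepoint_h] = sig
            sig_up_sets.setdefault(c.treatment, {})[c.timepoint_h] = sig_up
            logger.info("[de] %s: %d significant at Q<=%g",
                        c.label(), len(sig), config.q_de)
        overlap_rows = []
        for treatment, per_tp in sig_sets.items():
            summary = overlap_counts(per_tp)
            frame = summary.as_frame()
            frame.insert(0, "treatment", treatment)
            overlap_rows.append(frame)
        overlaps = pd.concat(overlap_rows, ignore_index=True)
        treatments = list(sig_sets)
        n_common_up = None
        if len(treatments) >= 2:
            common = common_upregulated(sig_up_sets[treatments[0]],
                                        sig_up_sets[treatments[1]])
            n_common_up = len(common)
            overlaps = pd.concat(
                [overlaps, pd.DataFrame([{"treatment": "+".join(treatments[:2]),
                                          "region": "common_up", "count": n_common_up}])],
                ignore_index=True,
            )
        io.write_table(overlaps, outdir / "overlap_summary.tsv")
        manifest["stages"][stage] = "ran"
        manifest["counts"][stage] = {
            "contrasts": len(contrasts),
            "significant": {c.label(): len(sig_sets[c.treatment][c.timepoint_h])
                            for c in contrasts},
        }
        if n_common_up is not None:
            manifest["counts"][stage]["common_up"] = n_common_up
    except Exception as e:  # noqa: BLE001
        raise _StageError(stage, e) from e

    # ---- reporter enrichment --------------------------------------------
    stage = "reporter"
    if sets is None:
        logger.info("[reporter] no gene-set collection supplied; stage skipped")
        manifest["stages"][stage] = "skipped"
    else:
        try:
            all_rows = []
            for c, table in de_tables.items():
                for direction in ("up", "down"):
                    rep = reporter_analysis(
                        table, sets, direction=direction,
                        n_samples=config.reporter_null_samples,
                        seed=seeds["reporter"], condition=c.label(),
                    )
                    all_rows.append(rep)
            reporter_table = pd.concat(all_rows, ignore_index=True)
            io.write_table(reporter_table, outdir / "reporter.tsv")
            sig_mat = build_significance_matrix(
                reporter_table[reporter_table["direction"] == "up"],
                p_select=config.p_reporter,
            )
            sig_out = sig_mat.reset_index() if not sig_mat.empty else pd.DataFrame()
            io.write_table(sig_out, outdir / "significance_matrix_up.tsv")
            manifest["stages"][stage] = "ran"
            manifest["counts"][stage] = {
                "reporter_rows": len(reporter_table),
                "matrix_sets": int(sig_mat.shape[0]) if not sig_mat.empty else 0,
            }
        except Exception as e:  # noqa: BLE001
            raise _StageError(stage, e) from e

    # ---- co-expression ----------------------------------------------------
    stage = "coexpr"
    try:
        cc = config.coexpr
        coexpr_counts = {}
        arm_pairs = groups or list(dict.fromkeys(
            (c.treatment, c.control) for c in contrasts))
        for treatment, control in arm_pairs:
            per_tp = {c.timepoint_h: de_tables[c] for c in de_tables
                      if c.treatment == treatment}
            try:
                genes = select_coexpr_genes(per_tp, config.q_coexpr)
            except ValueError as err:
                logger.info("[coexpr] %s: %s; skipped", treatment, err)
                coexpr_counts[treatment] = {"genes": 0, "modules": 0}
                continue
            arm_samples = [s for s in data.sample_ids
                           if data.design.loc[s, "group"] in (treatment, control)]
            arm = ExpressionDataset(data.values[arm_samples],
                                    data.design.loc[arm_samples])
            beta = cc.beta
            if beta == "auto":
                beta = pick_soft_threshold(arm, genes, cc.candidate_betas,
                                           cc.r2_target, cc.signed)
            adj = adjacency_matrix(arm, genes, beta=beta, signed=cc.signed)
            tom = topological_overlap(adj)
            part = detect_modules(tom, cc.cut_height, cc.min_module_size)
            labels_out = part.labels.reset_index()
            labels_out.columns = ["gene", "module"]
            io.write_table(labels_out, outdir / f"modules_{treatment}.tsv")
            if sets is not None:
                enr = module_enrichment(part, sets, data.gene_ids)
                io.write_table(enr, outdir / f"module_enrichment_{treatment}.tsv")
            coexpr_counts[treatment] = {
                "genes": len(genes), "beta": int(beta),
                "modules": part.n_modules(),
            }
            logger.info("[coexpr] %s: %d genes, beta=%d, %d modules",
                        treatment, len(genes), beta, part.n_modules())
        manifest["stages"][stage] = "ran"
        manifest["counts"][stage] = coexpr_counts
    except _StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise _StageError(stage, e) from e

    # ---- hubs --------------------------------------------------------------
    stage = "hubs"
    if graph is None:
        logger.info("[hubs] no interaction graph supplied; stage skipped")
        manifest["stages"][stage] = "skipped"
    else:
        try:
            up_sets = {}
            for c, table in de_tables.items():
                genes = set(significance_filter(table, config.q_hubs, "up"))
                up_sets.setdefault(c.treatment, set()).update(genes)
            treatments = list(up_sets)
            membership: dict[str, str] = {}
            if len(treatments) >= 2:
                a_only, b_only, shared = shared_and_exclusive(
                    up_sets[treatments[0]], up_sets[treatments[1]])
                membership.update({g: treatments[0] for g in a_only})
                membership.update({g: treatments[1] for g in b_only})
                membership.update({g: "shared" for g in shared})
            hub_counts = {}
            for treatment in treatments:
                sub = induced_subgraph(graph, up_sets[treatment])
                ranking = main_interactors(sub, top_n=config.hub_top_n,
                                           full_graph=graph, membership=membership)
                io.write_table(ranking, outdir / f"hubs_{treatment}.tsv")
                hub_counts[treatment] = {
                    "subgraph_nodes": sub.n_nodes(),
                    "subgraph_edges": sub.n_edges(),
                    "main_interactor": (ranking.iloc[0]["gene"]
                                        if len(ranking) else None),
                }
            manifest["stages"][stage] = "ran"
            manifest["counts"][stage] = hub_counts
        except Exception as e:  # noqa: BLE001
            raise _StageError(stage, e) from e

    if truth is not None:
        truth_rows = [
            {"treatment": t, "timepoint_h": tp, "gene": g, "effect": eff}
            for (t, tp), cell in truth.effects.items()
            for g, eff in sorted(cell.items())
        ]
        io.write_table(pd.DataFrame(
            truth_rows, columns=["treatment", "timepoint_h", "gene", "effect"]),
            outdir / "ground_truth.tsv")

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
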