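"""End-to-end orchestration: simulate -> summarize -> de -> select ->
associate -> enrich -> graph.

Every stage is a pure function of (inputs, config, derived stage seed),
so re-running with an identical configuration reproduces byte-identical
result files.  The single global seed fans out deterministically to
per-stage seeds, letting any stage be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import boruta as boruta_mod
from . import cohort as cohort_mod
from .de import PairedContrast, UnpairedContrast, run_de
from .enrichment import enrich, enrichment_frame
from .graph import build_graph, graph_edge_table
from .io_formats import (
    read_abundance,
    read_gmt,
    read_metadata,
    write_abundance,
    write_gmt,
    write_graphml,
    write_metadata,
)
from .outcome import correlate_panel
from .synthetic import SimConfig, config_to_dict, generate_clinical, generate_cohort, generate_gene_sets

__all__ = ["RunConfig", "StageError", "run_pipeline"]

logger = logging.getLogger("sepsisprot")

_FLOAT = "%.17g"

STAGES = ("simulate", "summarize", "de", "select", "associate", "enrich", "graph")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sim: SimConfig | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    alpha: float = 0.05
    fc_min: float = 2.0
    boruta_trees: int = 500
    boruta_max_iter: int = 100
    forest_trees: int = 5000
    forest_depth: int = 5
    aggregate: str = "sum"
    graph_variables: tuple[str, ...] = ("PELOD2_D1", "PELOD2_D3", "mortality")
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.fc_min <= 0:
            raise ValueError("thresholds must be positive")
        if self.sim is None and (self.abundance_path is None or self.metadata_path is None):
            raise ValueError("provide either a SimConfig or abundance+metadata paths")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31))


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT, lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    The directory collects each stage's tables, a GraphML network, a
    ``manifest.json`` (configuration echo, seed, per-stage row counts)
    and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "seed": int(config.seed),
        "alpha": config.alpha,
        "fc_min": config.fc_min,
        "aggregate": config.aggregate,
        "stages": {},
    }

    def _log(stage: str, t0: float, **shapes) -> None:
        dt = time.perf_counter() - t0
        logger.info("stage=%s elapsed=%.2fs %s", stage, dt, " ".join(f"{k}={v}" for k, v in shapes.items()))
        manifest["stages"][stage] = {k: v for k, v in shapes.items()}

    try:
        # -- simulate (or load) ------------------------------------------
        t0 = time.perf_counter()
        stage = "simulate"
        try:
            if config.sim is not None:
                sim = config.sim
                matrix, records, truth = generate_cohort(sim)
                records = generate_clinical(truth, records, sim, matrix)
                gene_sets = generate_gene_sets(sim, truth)
                write_abundance(matrix, out / "abundance.tsv")
                write_metadata(records, out / "metadata.tsv")
                write_gmt(gene_sets, out / "gene_sets.gmt")
                (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
                manifest["sim_config"] = config_to_dict(sim)
            else:
                matrix = read_abundance(config.abundance_path)
                records = read_metadata(config.metadata_path)
                gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
                truth = None
            _log(stage, t0, n_samples=matrix.shape[0], n_proteins=matrix.shape[1])
        except Exception as exc:
            raise StageError(stage, exc) from exc

        meta_cols = sorted({k for r in records for k in r.clinical})

        # -- summarize ---------------------------------------------------
        t0 = time.perf_counter()
        stage = "summarize"
        try:
            rows = cohort_mod.summarize_cohort(records)
            summary = pd.DataFrame([vars(r) for r in rows])
            _write_table(summary.set_index("variable"), out / "cohort_summary.tsv")
            sepsis = [r for r in records if r.group == "SEPSIS"]
            tiers = cohort_mod.association_matrix(sepsis, variables=meta_cols, alpha=config.alpha)
            _write_table(tiers.set_index(["var_a", "var_b"]), out / "association_tiers.tsv")
            pca = cohort_mod.pca_embedding(matrix, k=2)
            _write_table(pca, out / "pca.tsv")
            _log(stage, t0, summary_rows=len(summary), pairs=len(tiers))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # -- differential expression --------------------------------------
        t0 = time.perf_counter()
        stage = "de"
        try:
            c1 = UnpairedContrast("SEPSIS", "D1", "HC", None)
            de_d1 = run_de(matrix, records, c1, fc_min=config.fc_min, alpha=config.alpha)
            _write_table(de_d1, out / "de_d1_vs_hc.tsv")
            c2 = PairedContrast("D3", "D1", "SEPSIS")
            de_d3 = run_de(matrix, records, c2, fc_min=config.fc_min, alpha=config.alpha)
            _write_table(de_d3, out / "de_d3_vs_d1_paired.tsv")
            n_dep1 = int((de_d1["status"] != "ns").sum())
            n_dep3 = int((de_d3["status"] != "ns").sum())
            _log(stage, t0, deps_d1_vs_hc=n_dep1, deps_d3_vs_d1=n_dep3)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # -- feature selection --------------------------------------------
        t0 = time.perf_counter()
        stage = "select"
        try:
            sel_records = [r for r in records if r.group == "HC" or r.timepoint == "D1"]
            sids = [r.sample_id for r in sel_records]
            X = matrix.values_for(sids).to_numpy()
            y = np.array([1 if r.group == "SEPSIS" else 0 for r in sel_records])
            seed = stage_seed(config.seed, stage)
            decisions = boruta_mod.boruta_select(
                X, y, feature_ids=matrix.protein_ids,
                n_trees=config.boruta_trees, max_depth=config.forest_depth,
                max_iter=config.boruta_max_iter, alpha=config.alpha, seed=seed,
            )
            confirmed = [d.feature_id for d in decisions if d.decision == "confirmed"]
            ranking = boruta_mod.rerank_selected(
                X, y, confirmed, matrix.protein_ids,
                n_trees=config.forest_trees, max_depth=config.forest_depth, seed=seed,
            )
            imp = dict(zip(ranking["feature_id"], ranking["importance"]))
            table = pd.DataFrame(
                {
                    "feature_id": [d.feature_id for d in decisions],
                    "decision": [d.decision for d in decisions],
                    "hits": [d.hits for d in decisions],
                    "n_iter": [d.n_iter for d in decisions],
                    "final_importance": [imp.get(d.feature_id, np.nan) for d in decisions],
                }
            ).set_index("feature_id")
            _write_table(table, out / "boruta_d1_vs_hc.tsv")
            _log(stage, t0, confirmed=len(confirmed), n_iter=decisions[0].n_iter if decisions else 0)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # -- outcome associations -----------------------------------------
        t0 = time.perf_counter()
        stage = "associate"
        try:
            panels = []
            for var, method, tp in (
                ("PELOD2_D1", "pearson", "D1"),
                ("PELOD2_D3", "pearson", "D3"),
                ("mortality", "point_biserial", "D1"),
                ("mortality", "point_biserial", "D3"),
            ):
                panel = correlate_panel(matrix, records, var, method=method, timepoint=tp)
                panel.insert(0, "timepoint", tp)
                panels.append(panel)
            associations = pd.concat(panels)
            _write_table(associations, out / "associations.tsv")
            _log(stage, t0, records=len(associations))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # -- enrichment ----------------------------------------------------
        t0 = time.perf_counter()
        stage = "enrich"
        try:
            if gene_sets is None:
                enr_records = []
            else:
                hit_ids = set(de_d1.index[de_d1["status"] != "ns"])
                enr_records = enrich(gene_sets, hit_ids, matrix.protein_ids, de_table=de_d1)
            _write_table(enrichment_frame(enr_records), out / "enrichment_d1_vs_hc.tsv")
            _log(stage, t0, terms_tested=len(enr_records))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # -- association graph ---------------------------------------------
        t0 = time.perf_counter()
        stage = "graph"
        try:
            sig_terms = [r for r in enr_records if r.fdr <= config.alpha]
            graph_assoc = associations.loc[
                associations["variable"].isin(config.graph_variables)
            ].copy()
            # distinguish the two mortality panels as separate clinical nodes
            multi = graph_assoc.groupby("variable")["timepoint"].nunique() > 1
            for var in multi.index[multi]:
                mask = graph_assoc["variable"] == var
                graph_assoc.loc[mask, "variable"] = (
                    var + "_" + graph_assoc.loc[mask, "timepoint"]
                )
            g = build_graph(sig_terms, de_d1, graph_assoc, alpha=config.alpha, aggregate=config.aggregate)
            write_graphml(g, out / "association_graph.graphml")
            edges = graph_edge_table(g)
            _write_table(edges.set_index(["pathway", "variable"]), out / "graph_edges.tsv")
            _log(stage, t0, pathways=len(sig_terms), edges=g.number_of_edges())
        except Exception as exc:
            raise StageError(stage, exc) from exc

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
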