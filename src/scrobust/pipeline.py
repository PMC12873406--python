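"""End-to-end pipeline: QC -> DE -> robustness grid -> enrichment ->
composition -> meta-programs, driven by a YAML config.

Each stage writes its result tables as TSV under the configured output
directory; a run log records the seed, package versions, and per-stage
status so a run is auditable and, with a fixed seed, bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (
    betabinom_dx_test,
    build_table,
    normalize_10k,
    subsample_robustness,
)
from .data_model import CellGeneDataset, load_dataset, normalize, qc_filter
from .enrichment import preranked_gsea, rank_genes, read_gmt
from .grid import make_grid, robustness_scores, term_robustness
from .hurdle import run_de
from .metaprograms import (
    classify_span,
    consensus_mps,
    downsample_cells,
    mp_group_test,
    nmf_multi_rank,
    score_cells,
    select_variable_genes,
)
from .synthetic import fixture_small, generate

logger = logging.getLogger("scrobust")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_input(conf: dict, seed: int) -> CellGeneDataset:
    data = conf.get("dataset", {})
    if "simulate" in data:
        if data["simulate"] == "fixture_small":
            ds, truth = fixture_small(seed)
        else:
            raise ValueError(f"unknown simulate preset {data['simulate']!r}")
        return ds
    paths = data["paths"]
    return load_dataset(
        paths["matrix"], paths["cells"], paths["samples"], paths["genes"]
    )


def run_pipeline(config_path: str | Path) -> dict:
    """Execute all configured stages; returns the run log as a dict."""
    with open(config_path) as fh:
        conf = yaml.safe_load(fh)
    seed = int(conf.get("seed", 0))
    outdir = Path(conf.get("outdir", "scrobust_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": seed,
        "versions": {"scrobust": __version__, "python": platform.python_version()},
        "stages": {},
        "complete": False,
    }
    stage = "load"
    try:
        dataset = _load_input(conf, seed)
        log["stages"]["load"] = {"n_cells": dataset.n_cells, "n_genes": dataset.n_genes}

        stage = "qc"
        qc_conf = conf.get("qc")
        if qc_conf is not None:
            dataset = qc_filter(
                dataset,
                min_genes=qc_conf.get("min_genes", 300),
                max_genes=qc_conf.get("max_genes", 15000),
                max_mito_frac=qc_conf.get("max_mito_frac", 0.05),
            )
            log["stages"]["qc"] = {"n_cells": dataset.n_cells}
        else:
            log["stages"]["qc"] = "skipped"

        norm = normalize(dataset)
        gene_sets = None
        enr_conf = conf.get("enrichment") or {}
        if "gene_sets" in enr_conf:
            stage = "enrichment"
            gene_sets = read_gmt(enr_conf["gene_sets"])
        elif conf.get("enrichment") is None:
            log["stages"]["enrichment"] = "skipped (no gene sets configured)"

        stage = "de"
        de_conf = conf.get("de", {})
        de_tables: dict[str, pd.DataFrame] = {}
        clusters = de_conf.get(
            "clusters", sorted(dataset.cell_meta["cluster_label"].unique())
        )
        for cluster in clusters:
            table = run_de(
                dataset,
                cluster,
                min_cells=de_conf.get("min_cells", 1000),
                min_rate=de_conf.get("min_rate", 0.10),
                coding_only=de_conf.get("coding_only", True),
                mode=de_conf.get("mode", "mixed"),
                norm=norm,
            )
            if table is None:
                log["stages"].setdefault("de", {})[cluster] = "skipped (too few nuclei)"
                continue
            de_tables[cluster] = table
            table.to_csv(outdir / f"de_{cluster}.tsv", sep="\t")
            log["stages"].setdefault("de", {})[cluster] = int(
                (table["fit_flag"] == "ok").sum()
            )

        stage = "grid"
        grid_conf = conf.get("grid", {})
        grid = make_grid(
            tuple(grid_conf.get("rates", (0.10, 0.30, 0.01))),
            tuple(grid_conf.get("fcs", (1.10, 1.20, 0.01))),
            tuple(grid_conf.get("fdrs", (0.05, 0.10, 0.01))),
        )
        log["stages"]["grid"] = {
            "axes": [
                int(grid.rate_thresholds.size),
                int(grid.fc_thresholds.size),
                int(grid.fdr_thresholds.size),
            ],
            "n_combos": grid.n_combos,
        }
        robustness: dict[str, pd.DataFrame] = {}
        for cluster, table in de_tables.items():
            rob = robustness_scores(table, grid)
            robustness[cluster] = rob
            rob.to_csv(outdir / f"robustness_{cluster}.tsv", sep="\t", index=False)

        stage = "enrichment"
        if gene_sets is not None:
            for cluster, table in de_tables.items():
                background = set(table.index[table["expr_rate"] > 0.10])
                for direction in ("down", "up"):
                    terms = term_robustness(
                        table, grid, gene_sets, background, direction
                    )
                    terms.to_csv(
                        outdir / f"term_robustness_{cluster}_{direction}.tsv",
                        sep="\t", index=False,
                    )
                ranked = rank_genes(table)
                gsea_rows = []
                rng = np.random.default_rng(seed + 101)
                for term_id in sorted(gene_sets):
                    res = preranked_gsea(
                        ranked, gene_sets[term_id],
                        n_perm=int(enr_conf.get("n_perm", 200)), seed=rng,
                    )
                    if res is not None:
                        gsea_rows.append(
                            {"term_id": term_id, "es": res.es, "nes": res.nes,
                             "p_value": res.p_value}
                        )
                pd.DataFrame(gsea_rows).to_csv(
                    outdir / f"gsea_{cluster}.tsv", sep="\t", index=False
                )
            log["stages"]["enrichment"] = "done"

        stage = "composition"
        comp_conf = conf.get("composition", {})
        table = build_table(dataset)
        if comp_conf.get("normalize_10k", False):
            table = normalize_10k(table)
        comp = betabinom_dx_test(table)
        comp.to_csv(outdir / "composition.tsv", sep="\t")
        log["stages"]["composition"] = "done"
        sub_conf = comp_conf.get("subsample")
        if sub_conf:
            sub = subsample_robustness(
                table,
                n_per_group=sub_conf.get("n_per_group", 10),
                n_iter=sub_conf.get("n_iter", 1000),
                seed=seed + 7,
            )
            sub["summary"].to_csv(outdir / "composition_subsample.tsv", sep="\t")

        stage = "metaprograms"
        mp_conf = conf.get("metaprograms")
        if mp_conf is not None:
            down = downsample_cells(dataset, cap=mp_conf.get("cap", 2000),
                                    seed=seed + 11)
            dnorm = normalize(down)
            var_genes = select_variable_genes(
                dnorm, down.gene_ids, n=mp_conf.get("n_variable", 5000)
            )
            cols = pd.Index(down.gene_ids).get_indexer(var_genes)
            lo, hi = mp_conf.get("ranks", (20, 30))
            factors = nmf_multi_rank(
                dnorm.values[:, cols], ranks=range(lo, hi + 1), seed=seed + 13
            )
            mps = consensus_mps(
                factors, var_genes,
                max_mps=mp_conf.get("max_mps", 20),
                top_genes=mp_conf.get("top_genes", 300),
            )
            rows = []
            for mp in mps:
                mp.scores = score_cells(dnorm, down.gene_ids, mp)
                mp.class_span = classify_span(
                    mp.scores, down.cell_meta["major_class"].to_numpy()
                )
                mp.group_test = mp_group_test(
                    mp.scores, down.cell_meta["sample_id"].to_numpy(),
                    down.sample_meta, n_mps=len(mps),
                )
                rows.append(
                    {"mp_id": mp.mp_id, "n_genes": len(mp.signature),
                     "class_span": ",".join(mp.class_span),
                     "trans_cellular": mp.trans_cellular,
                     "estimate": mp.group_test["estimate"],
                     "p_value": mp.group_test["p_value"],
                     "adjusted_p": mp.group_test["adjusted_p"]}
                )
            pd.DataFrame(rows).to_csv(outdir / "metaprograms.tsv", sep="\t",
                                      index=False)
            log["stages"]["metaprograms"] = {"n_mps": len(mps)}
        else:
            log["stages"]["metaprograms"] = "skipped"

        log["complete"] = True
    except Exception as exc:  # noqa: BLE001 - stage attribution then re-raise
        log["stages"][stage] = f"failed: {exc}"
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)
        raise PipelineError(stage, exc) from exc
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return log
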