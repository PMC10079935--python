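"""End-to-end workflow: preprocess -> explore -> screen -> GSEA -> balance.

A single :func:`run_pipeline` call takes a linear-scale signal matrix plus
a gene-set collection, runs the full signature analysis, and writes one
TSV per stage, a machine-readable JSON summary, and a log recording seed,
parameters and item counts at every filtering step.  The pipeline is a
pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .balance import stress_growth_balance
from .core_io import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
)
from .exploratory import hierarchical_cluster, pca
from .gsea import gsea_table, run_gsea
from .preprocess import NormalizationParams, preprocess, to_linear
from .screening import overrep_table, screen_component

logger = logging.getLogger("ltsp_sig")


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs.

    Thresholds default to the analysis conventions used throughout the
    package: low-signal cutoff -1.5 (linear units), loading screen at the
    3% quantile with |loading| >= 0.8 and hypergeometric alpha 0.01,
    gene-set sizes 6-200, GSEA FDR threshold 0.05.
    """

    cond_a: str = "LTSsn"
    cond_b: str = "STS"
    rs_set_id: str = "GO:0006950"
    mbs_set_id: str = "GO:0009059"
    low_signal_threshold: float = -1.5
    epsilon_floor: float = 0.01
    percent: float = 3.0
    loading_cutoff: float = 0.8
    alpha_hypergeom: float = 0.01
    min_set_size: int = 6
    max_set_size: int = 200
    q_fdr_threshold: float = 0.05
    n_permutations: int = 1000
    weight_p: float = 1.0
    component: int = 1
    seed: int = 0
    out_dir: str = "ltsp_sig_out"

    def validate(self) -> None:
        if not 0 < self.alpha_hypergeom < 1:
            raise ValueError("alpha_hypergeom must be in (0, 1)")
        if not 0 < self.q_fdr_threshold < 1:
            raise ValueError("q_fdr_threshold must be in (0, 1)")
        if not 0 < self.percent <= 50:
            raise ValueError("percent must be in (0, 50]")
        if self.loading_cutoff < 0 or self.loading_cutoff > 1:
            raise ValueError("loading_cutoff must be in [0, 1]")
        if self.min_set_size < 1 or self.max_set_size < self.min_set_size:
            raise ValueError("invalid set size bounds")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.epsilon_floor <= 0:
            raise ValueError("epsilon_floor must be > 0")


def run_pipeline(matrix: ExpressionMatrix, collection: GeneSetCollection,
                 config: PipelineConfig) -> dict:
    """Run the full signature analysis and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _attach_file_log(out / "pipeline.log")
    logger.info("ltsp-sig %s | seed=%d | config=%s", __version__, config.seed,
                dataclasses.asdict(config))

    n_input_genes = matrix.n_genes
    params = NormalizationParams(low_signal_threshold=config.low_signal_threshold,
                                 epsilon_floor=config.epsilon_floor)
    norm = preprocess(matrix, params)
    write_expression_matrix(norm, out / "normalized.tsv")

    dendro = hierarchical_cluster(norm, axis="samples")
    (out / "samples.nwk").write_text(dendro.to_newick() + "\n")

    pca_res = pca(norm)
    pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t",
                          index_label="sample_id", float_format="%.12g")
    pca_res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t",
                            index_label="gene_id", float_format="%.12g")

    screen = screen_component(pca_res, config.component, collection, norm,
                              percent=config.percent, cutoff=config.loading_cutoff,
                              alpha=config.alpha_hypergeom,
                              min_size=config.min_set_size,
                              max_size=config.max_set_size)
    for direction in ("top", "bottom"):
        overrep_table(screen.tables[direction]).to_csv(
            out / f"screen_{direction}.tsv", sep="\t", index=False,
            float_format="%.12g")

    gsea_results = run_gsea(norm, config.cond_a, config.cond_b, collection,
                            n_permutations=config.n_permutations,
                            weight_p=config.weight_p, seed=config.seed,
                            min_size=config.min_set_size,
                            max_size=config.max_set_size)
    gsea_table(gsea_results).to_csv(out / "gsea.tsv", sep="\t", index=False,
                                    float_format="%.12g")

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "conditions": {c: len(matrix.samples_of(c)) for c in matrix.conditions},
        "n_input_genes": n_input_genes,
        "n_analyzed_genes": norm.n_genes,
        "pc_variance_fraction": [round(float(v), 10)
                                 for v in pca_res.variance_fraction[:5]],
        "screen": {
            d: {"n_screened_genes": len(screen.screens[d].genes),
                "n_significant_sets": sum(r.significant
                                          for r in screen.tables[d])}
            for d in ("top", "bottom")
        },
        "gsea": {
            "contrast": [config.cond_a, config.cond_b],
            "n_sets_tested": len(gsea_results),
            "n_sets_q_below_threshold": sum(
                r.q_fdr < config.q_fdr_threshold for r in gsea_results),
            "top_set": dataclasses.asdict(
                min(gsea_results, key=lambda r: (r.q_fdr, -abs(r.nes)))),
        },
    }

    try:
        rs = collection[config.rs_set_id].members
        mbs = collection[config.mbs_set_id].members
        bal = stress_growth_balance(to_linear(norm), rs, mbs)
        bal.per_condition.to_csv(out / "balance.tsv", sep="\t",
                                 float_format="%.12g")
        summary["balance"] = {
            "per_condition": {c: {"mean": round(float(r["mean"]), 10),
                                  "sd": round(float(r["sd"]), 10),
                                  "n": int(r["n"])}
                              for c, r in bal.per_condition.iterrows()},
            "pairwise": [{"pair": [p.cond_a, p.cond_b],
                          "difference": round(p.mean_difference, 10),
                          "p_adjusted": round(p.p_adjusted, 10)}
                         for p in bal.pairwise],
        }
    except KeyError:
        logger.warning("balance stage skipped: RS/MBS set IDs %r / %r not in "
                       "collection", config.rs_set_id, config.mbs_set_id)
        summary["balance"] = None

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary


def run_pipeline_from_paths(matrix_path, condition_path, gmt_path,
                            config: PipelineConfig) -> dict:
    matrix = read_expression_matrix(matrix_path, condition_path)
    collection = read_gmt(gmt_path)
    return run_pipeline(matrix, collection, config)


def _attach_file_log(path: Path) -> None:
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
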